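"""Detection and measurement of stimulus trains in isometric force recordings.

Computes the physiological statistics of the superimposed-stimulation
protocol: strip specific force, initial neuromuscular transmission failure
(NMTF), the 15-s NMTF time course and its final value, and within-train
(intratrain) fatigue.

NMTF at each assessment epoch is

    NMTF = [(MF/MF_init) - (NF/NF_init)] / (MF/MF_init) x 100

where MF is the directly muscle-evoked peak force and NF the nerve-evoked
peak force of the same train.  The formula yields a positive magnitude; the
reported value is negated so that negative numbers denote failure, matching
the usual reporting convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .force_sim import MUSCLE_DENSITY_G_PER_CM3, ForceRecording

#: Default moving-average width used to de-noise before peak extraction.
DEFAULT_SMOOTH_MS = 5.0


@dataclass(frozen=True)
class TrainEvent:
    """One detected stimulus train with its measurement windows (seconds)."""

    onset_s: float
    offset_s: float
    kind: str  # "nerve_only" | "superimposed"
    nerve_window_s: tuple[float, float]
    muscle_window_s: tuple[float, float] | None
    peak_force_n: float
    post_peak_min_force_n: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("onset must precede offset")
        if self.kind == "superimposed" and self.muscle_window_s is None:
            raise ValueError("superimposed trains need a muscle window")


@dataclass
class NMTFSeries:
    """The 15-s grid of muscle/nerve peak forces and derived NMTF values."""

    epoch_times_s: np.ndarray
    mf_n: np.ndarray
    nf_n: np.ndarray
    nmtf_t: np.ndarray  # signed %, negative = failure
    initial_nmtf: float

    @property
    def mf_init_n(self) -> float:
        return float(self.mf_n[0])

    @property
    def nf_init_n(self) -> float:
        return float(self.nf_n[0])

    @property
    def final_nmtf(self) -> float:
        return float(self.nmtf_t[-1])


@dataclass
class IntratrainSeries:
    """Within-train force droop (signed %, negative = droop) per epoch."""

    epoch_times_s: np.ndarray
    intratrain_fatigue: np.ndarray

    @property
    def final_value(self) -> float:
        return float(self.intratrain_fatigue[-1])


def _smooth(force: np.ndarray, fs: float, smooth_ms: float) -> tuple[np.ndarray, int]:
    w = max(1, int(round(smooth_ms * fs / 1000.0)))
    if w == 1:
        return np.asarray(force, dtype=float), 1
    kernel = np.ones(w) / w
    return np.convolve(force, kernel, mode="same"), w


def _window_slice(fs: float, t0: float, t1: float, trim: int, n: int) -> slice:
    i0 = int(round(t0 * fs))
    i1 = int(round(t1 * fs)) - trim
    i0 = max(0, min(i0, n - 1))
    i1 = max(i0 + 1, min(i1, n))
    return slice(i0, i1)


def detect_trains(
    recording: ForceRecording,
    fallback_threshold: float = 0.05,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> list[TrainEvent]:
    """Find stimulus trains from the marker channels (or force as fallback).

    The nerve marker gate defines onsets/offsets; a train is superimposed iff
    muscle-stimulation markers fall within it, in which case the nerve window
    ends at the muscle-stimulation onset.  Without markers, contiguous
    regions of force above ``fallback_threshold`` x the per-train maximum are
    used.  Onset spacing inconsistent with the recording's protocol grid
    produces a warning, not an error.
    """
    fs = recording.sampling_rate_hz
    nerve = np.asarray(recording.nerve_stim_marker) > 0
    if nerve.any():
        padded = np.concatenate(([False], nerve, [False])).astype(np.int8)
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
    else:
        starts, ends = _trains_from_force(recording, fallback_threshold)
    if len(starts) == 0:
        raise ValueError("no stimulus trains found in recording")

    if recording.protocol is not None and len(starts) > 1:
        period = np.median(np.diff(starts)) / fs
        if abs(period - recording.protocol.train_period_s) > 2.0 / fs:
            warnings.warn(
                f"marker grid period {period:.4f} s differs from protocol "
                f"{recording.protocol.train_period_s:.4f} s; proceeding with detected grid",
                stacklevel=2,
            )

    muscle = np.asarray(recording.muscle_stim_marker) > 0
    smoothed, w = _smooth(recording.force_n, fs, smooth_ms)
    trim = w // 2 + 1
    n = len(smoothed)

    events: list[TrainEvent] = []
    for i0, i1 in zip(starts, ends):
        onset, offset = i0 / fs, i1 / fs
        m_idx = np.flatnonzero(muscle[i0:i1])
        if m_idx.size:
            m_start = (i0 + m_idx[0]) / fs
            kind = "superimposed"
            nerve_win = (onset, m_start)
            muscle_win = (m_start, offset)
        else:
            kind = "nerve_only"
            nerve_win = (onset, offset)
            muscle_win = None
        sl = _window_slice(fs, onset, offset, trim, n)
        seg = smoothed[sl]
        peak_i = int(np.argmax(seg))
        peak = float(seg[peak_i])
        post_min = float(seg[peak_i:].min())
        events.append(TrainEvent(onset, offset, kind, nerve_win, muscle_win,
                                 peak, post_min))
    return events


def _trains_from_force(recording: ForceRecording, threshold_frac: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Fallback detection: contiguous supra-threshold force regions, with the
    onset refined against each train's own maximum."""
    fs = recording.sampling_rate_hz
    force = np.asarray(recording.force_n, dtype=float)
    coarse = force > threshold_frac * force.max()
    padded = np.concatenate(([False], coarse, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    # merge regions separated by < 100 ms (droop/noise dips within a train)
    if len(starts) > 1:
        gap = starts[1:] - ends[:-1]
        keep = gap > int(0.1 * fs)
        starts = np.concatenate((starts[:1], starts[1:][keep]))
        ends = np.concatenate((ends[:-1][keep], ends[-1:]))
    # refine each onset against the train's own early plateau: the coarse
    # pass uses the global maximum, which lags on late (fatigued) trains, and
    # the within-train maximum is inflated on superimposed trains
    ref_starts = []
    lookback = int(0.05 * fs)
    early = int(0.15 * fs)
    for i0, i1 in zip(starts, ends):
        j0 = max(0, i0 - lookback)
        seg = force[j0:i1]
        local_ref = seg[:i0 - j0 + early].max()
        above = np.flatnonzero(seg > threshold_frac * local_ref)
        ref_starts.append(j0 + (above[0] if above.size else i0 - j0))
    return np.asarray(ref_starts), ends


def compute_muscle_csa(strip_weight_g: float, optimal_length_cm: float) -> float:
    """Strip cross-sectional area in cm^2: weight / (Lo x 1.056 g/cm^3)."""
    if strip_weight_g <= 0 or optimal_length_cm <= 0:
        raise ValueError("strip weight and optimal length must be positive")
    return strip_weight_g / (optimal_length_cm * MUSCLE_DENSITY_G_PER_CM3)


def compute_specific_force(peak_force_n: float, csa_cm2: float) -> float:
    """Force normalized to strip cross-sectional area, N/cm^2."""
    if csa_cm2 <= 0:
        raise ValueError("csa must be positive")
    return peak_force_n / csa_cm2


def compute_nmtf_timecourse(
    epoch_times_s: np.ndarray,
    mf_n: np.ndarray,
    nf_n: np.ndarray,
) -> NMTFSeries:
    """NMTF per assessment epoch from per-epoch muscle/nerve peak forces.

    Epoch 0 is identically 0 by construction of the formula.
    """
    epoch_times_s = np.asarray(epoch_times_s, dtype=float)
    mf = np.asarray(mf_n, dtype=float)
    nf = np.asarray(nf_n, dtype=float)
    if not (len(epoch_times_s) == len(mf) == len(nf)):
        raise ValueError("epoch, MF and NF series must have equal length")
    if mf[0] <= 0 or nf[0] <= 0:
        raise ValueError("initial muscle and nerve forces must be positive")
    mfn = mf / mf[0]
    nfn = nf / nf[0]
    nmtf = -100.0 * (mfn - nfn) / mfn
    return NMTFSeries(
        epoch_times_s=epoch_times_s,
        mf_n=mf,
        nf_n=nf,
        nmtf_t=nmtf,
        initial_nmtf=compute_initial_nmtf(nf[0], mf[0]),
    )


def compute_initial_nmtf(first_nerve_peak_n: float, first_muscle_peak_n: float) -> float:
    """Percent difference of first nerve- vs muscle-evoked force (negative when
    the nerve-evoked force is lower)."""
    if first_muscle_peak_n <= 0:
        raise ValueError("first muscle-evoked peak must be positive")
    return 100.0 * (first_nerve_peak_n - first_muscle_peak_n) / first_muscle_peak_n


def compute_intratrain_fatigue(
    train: TrainEvent,
    recording: ForceRecording,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> float:
    """Within-train force droop, signed %: -100 x (max - min_after_peak) / max.

    The minimum is taken between the within-train maximum and the train
    offset (relaxation after the offset is excluded).  For superimposed
    trains only the nerve-evoked portion is assessed.

    The smoothed trace locates the extrema; the plateau and trough *levels*
    are estimated as 10-ms means of the raw trace anchored at those locations
    (plateau mean ending at the peak, trough mean starting at the minimum).
    Taking the raw extrema instead would exaggerate the droop on weak, late
    trains, where extreme-value noise rivals the true within-train decline.
    """
    fs = recording.sampling_rate_hz
    smoothed, w = _smooth(recording.force_n, fs, smooth_ms)
    trim = w // 2 + 1
    if train.kind == "superimposed":
        t0, t1 = train.nerve_window_s
    else:
        t0, t1 = train.onset_s, train.offset_s
    sl = _window_slice(fs, t0, t1, trim, len(smoothed))
    seg = smoothed[sl]
    raw = np.asarray(recording.force_n, dtype=float)[sl]
    if seg.size == 0:
        raise ValueError("empty train window")
    peak_i = int(np.argmax(seg))
    min_i = peak_i + int(np.argmin(seg[peak_i:]))
    w10 = max(1, int(round(0.010 * fs)))
    peak = float(raw[max(0, peak_i - w10): peak_i + 1].mean())
    if peak <= 0:
        raise ValueError("train maximum force is zero")
    trough = float(raw[min_i: min(len(raw), min_i + w10)].mean())
    return min(0.0, -100.0 * (peak - trough) / peak)


def measure_duty_cycle(recording: ForceRecording) -> float:
    """Stimulation duty cycle (%) measured from the emitted nerve marker gate."""
    trains = detect_trains(recording)
    durations = np.array([t.offset_s - t.onset_s for t in trains])
    if len(trains) < 2:
        raise ValueError("need at least two trains to measure the period")
    period = float(np.median(np.diff([t.onset_s for t in trains])))
    return 100.0 * float(durations.mean()) / period


def _window_peak(smoothed: np.ndarray, fs: float, window: tuple[float, float],
                 trim: int) -> float:
    sl = _window_slice(fs, window[0], window[1], trim, len(smoothed))
    return float(smoothed[sl].max())


@dataclass
class RecordingResult:
    """Tidy per-animal result of one analyzed recording."""

    animal_id: str
    group: str
    sex: str
    specific_force_n_per_cm2: float
    initial_nmtf: float
    final_nmtf: float
    final_intratrain_fatigue: float
    nmtf_series: NMTFSeries
    intratrain_series: IntratrainSeries

    def to_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "group": self.group,
            "sex": self.sex,
            "specific_force_n_per_cm2": self.specific_force_n_per_cm2,
            "initial_nmtf_pct": self.initial_nmtf,
            "final_nmtf_pct": self.final_nmtf,
            "final_intratrain_fatigue_pct": self.final_intratrain_fatigue,
        }

    def to_long(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_id,
            "group": self.group,
            "epoch_s": self.nmtf_series.epoch_times_s,
            "mf_n": self.nmtf_series.mf_n,
            "nf_n": self.nmtf_series.nf_n,
            "nmtf_pct": self.nmtf_series.nmtf_t,
            "intratrain_fatigue_pct": self.intratrain_series.intratrain_fatigue,
        })


def analyze_recording(
    recording: ForceRecording,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> RecordingResult:
    """Full measurement chain for one recording: detect trains, read MF/NF at
    each 15-s epoch, derive NMTF, initial NMTF, intratrain fatigue and
    specific force."""
    trains = detect_trains(recording, smooth_ms=smooth_ms)
    sup = [tr for tr in trains if tr.kind == "superimposed"]
    if not sup:
        raise ValueError("no superimposed (assessment) trains found")
    proto = recording.protocol
    if proto is not None:
        expected_final = proto.total_duration_s
        if sup[-1].onset_s < expected_final - proto.train_period_s / 2:
            raise ValueError(
                f"recording ends before the final {expected_final:.0f}-s epoch "
                f"(last assessment at {sup[-1].onset_s:.0f} s)"
            )

    fs = recording.sampling_rate_hz
    smoothed, w = _smooth(recording.force_n, fs, smooth_ms)
    trim = w // 2 + 1

    epochs = np.array([tr.onset_s for tr in sup])
    mf = np.array([_window_peak(smoothed, fs, tr.muscle_window_s, trim) for tr in sup])
    nf = np.array([_window_peak(smoothed, fs, tr.nerve_window_s, trim) for tr in sup])
    series = compute_nmtf_timecourse(epochs, mf, nf)

    # Intratrain droop is assessed on the nerve-only train immediately
    # preceding each assessment train (the assessment train's own nerve
    # window is used at epoch 0, where no predecessor exists).
    by_onset = {round(tr.onset_s, 6): tr for tr in trains}
    period = proto.train_period_s if proto is not None else float(
        np.median(np.diff([tr.onset_s for tr in trains])))
    itf = []
    for tr in sup:
        prev = by_onset.get(round(tr.onset_s - period, 6))
        target = prev if (prev is not None and prev.kind == "nerve_only") else tr
        itf.append(compute_intratrain_fatigue(target, recording, smooth_ms))
    intratrain = IntratrainSeries(epochs, np.asarray(itf))

    meta = recording.metadata
    csa = compute_muscle_csa(meta.strip_weight_g, meta.optimal_length_cm)
    return RecordingResult(
        animal_id=meta.animal_id,
        group=meta.group,
        sex=meta.sex,
        specific_force_n_per_cm2=compute_specific_force(series.mf_init_n, csa),
        initial_nmtf=series.initial_nmtf,
        final_nmtf=series.final_nmtf,
        final_intratrain_fatigue=intratrain.final_value,
        nmtf_series=series,
        intratrain_series=intratrain,
    )


def analyze_trace_cohort(
    recordings: list[ForceRecording],
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze a cohort; returns (per-animal wide table, per-epoch long table)."""
    results = [analyze_recording(r, smooth_ms=smooth_ms) for r in recordings]
    wide = pd.DataFrame([r.to_row() for r in results])
    long = pd.concat([r.to_long() for r in results], ignore_index=True)
    return wide, long
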