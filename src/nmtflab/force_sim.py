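"""Synthetic isometric force recordings from a nerve-muscle strip preparation.

Simulates the classic superimposed-stimulation protocol used to separate
neuromuscular transmission failure (NMTF) from muscle fatigue in an ex vivo
phrenic nerve-diaphragm preparation: the nerve is stimulated at 40 Hz in
330-ms trains repeated each second (33% duty cycle) for 120 s, and every
15 s the muscle is additionally stimulated directly during the second half
of the train.  Nerve-evoked force declines with both transmission failure
and muscle fatigue; the superimposed directly-evoked force declines with
muscle fatigue alone, so the two can be separated.

The failure model is phenomenological: a failure fraction ``f(t)`` removes
force from the nerve-driven pathway, a capacity factor ``m(t)`` models
muscle fatigue common to both pathways, and a within-train droop ``d(t)``
is applied to nerve-evoked trains only.  Every simulated recording carries
its own closed-form ground truth so downstream analyzers can be verified
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Skeletal muscle density used for strip cross-sectional area, g/cm^3.
MUSCLE_DENSITY_G_PER_CM3 = 1.056

#: The four treatment arms of the study design.
GROUPS = ("vehicle", "vehicle+1NMPP1", "TKI", "TKI+BDNF")


@dataclass(frozen=True)
class StimulationProtocol:
    """Timing of the repetitive nerve stimulation with superimposed muscle stimulation.

    Defaults reproduce the standard diaphragm NMTF protocol: 40 Hz pulses in
    330-ms trains each second for 120 s, direct muscle stimulation
    superimposed on the second half of every 15th train.
    """

    pulse_rate_hz: float = 40.0
    train_duration_s: float = 0.330
    train_period_s: float = 1.0
    total_duration_s: float = 120.0
    superimpose_interval_s: float = 15.0
    superimpose_onset_within_train_s: float = 0.165
    nerve_pulse_width_ms: float = 0.05
    muscle_pulse_width_ms: float = 0.5

    def __post_init__(self) -> None:
        if not self.train_duration_s < self.train_period_s:
            raise ValueError("train_duration_s must be < train_period_s")
        ratio = self.superimpose_interval_s / self.train_period_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "superimpose_interval_s must be an integer multiple of train_period_s"
            )
        if not 0.0 < self.superimpose_onset_within_train_s < self.train_duration_s:
            raise ValueError(
                "superimpose_onset_within_train_s must fall inside the train"
            )
        if self.total_duration_s <= 0 or self.pulse_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")

    @property
    def duty_cycle_percent(self) -> float:
        """Percentage of each stimulation period occupied by the train."""
        return 100.0 * self.train_duration_s / self.train_period_s

    @property
    def train_onsets_s(self) -> np.ndarray:
        """Train onset times; includes the train at ``total_duration_s`` so the
        final (120-s) superimposed assessment exists."""
        n = int(round(self.total_duration_s / self.train_period_s)) + 1
        return np.arange(n) * self.train_period_s

    def is_superimposed(self, onset_s: float) -> bool:
        k = onset_s / self.superimpose_interval_s
        return abs(k - round(k)) < 1e-9

    @property
    def epoch_times_s(self) -> np.ndarray:
        """Onset times of the superimposed (assessment) trains: 0, 15, ... 120 s."""
        onsets = self.train_onsets_s
        return onsets[[self.is_superimposed(t) for t in onsets]]

    def to_dict(self) -> dict:
        return {
            "pulse_rate_hz": self.pulse_rate_hz,
            "train_duration_s": self.train_duration_s,
            "train_period_s": self.train_period_s,
            "total_duration_s": self.total_duration_s,
            "superimpose_interval_s": self.superimpose_interval_s,
            "superimpose_onset_within_train_s": self.superimpose_onset_within_train_s,
            "nerve_pulse_width_ms": self.nerve_pulse_width_ms,
            "muscle_pulse_width_ms": self.muscle_pulse_width_ms,
        }


@dataclass(frozen=True)
class PrepMetadata:
    """Physical metadata of one muscle strip preparation."""

    strip_weight_g: float = 0.04224
    optimal_length_cm: float = 2.0
    group: str = "vehicle"
    animal_id: str = "animal-0"
    sex: str = "f"

    def __post_init__(self) -> None:
        if self.strip_weight_g <= 0:
            raise ValueError("strip_weight_g must be positive")
        if self.optimal_length_cm <= 0:
            raise ValueError("optimal_length_cm must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def csa_cm2(self) -> float:
        """Strip cross-sectional area: weight / (Lo * density)."""
        return self.strip_weight_g / (self.optimal_length_cm * MUSCLE_DENSITY_G_PER_CM3)

    def to_dict(self) -> dict:
        return {
            "strip_weight_g": self.strip_weight_g,
            "Lo_cm": self.optimal_length_cm,
            "group": self.group,
            "animal_id": self.animal_id,
            "sex": self.sex,
        }


def _check_fraction(name: str, x: float, lo: float = 0.0, hi: float = 1.0,
                    inclusive_hi: bool = False) -> None:
    ok = (lo <= x < hi) or (inclusive_hi and x == hi)
    if not ok:
        rng = f"[{lo}, {hi}{']' if inclusive_hi else ')'}"
        raise ValueError(f"{name} must lie in {rng}, got {x}")


@dataclass(frozen=True)
class FailureModel:
    """Parametric model of transmission failure, muscle fatigue and droop.

    ``f(t) = f0 + (f120 - f0) * (t/T)**ramp_exponent`` is the failure
    fraction removed from the nerve-driven force; ``m(t) = 1 - (1 - m120) *
    (t/T)**muscle_fatigue_shape`` is the muscle capacity common to both
    pathways; ``d(t)`` ramps linearly from 0 to ``d120`` and sets the
    within-train min/max ratio ``1 - d(t)`` of nerve-evoked trains.
    """

    f0: float = 0.126
    f120: float = 0.654
    ramp_exponent: float = 1.5
    m120: float = 1.0
    muscle_fatigue_shape: float = 1.0
    d120: float = 0.0
    tetanus_rise_tau_s: float = 0.020
    relaxation_tau_s: float = 0.035
    peak_specific_force_n_per_cm2: float = 22.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_fraction("f0", self.f0)
        _check_fraction("f120", self.f120)
        _check_fraction("m120", self.m120, lo=0.0, hi=1.0, inclusive_hi=True)
        if self.m120 <= 0:
            raise ValueError("m120 must lie in (0, 1]")
        _check_fraction("d120", self.d120)
        if self.ramp_exponent <= 0 or self.muscle_fatigue_shape <= 0:
            raise ValueError("shape exponents must be positive")
        if self.tetanus_rise_tau_s <= 0 or self.relaxation_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_normalized_forces(
        cls,
        muscle_norm_end: float,
        nerve_norm_end: float,
        f0: float = 0.126,
        **kwargs,
    ) -> "FailureModel":
        """Build a model whose normalized end-of-run forces are prescribed.

        ``muscle_norm_end`` is MF(T)/MF_init (= m120); ``nerve_norm_end`` is
        NF(T)/NF_init.  Since NF(t)/NF_init = m(t)(1-f(t))/(1-f0), the final
        failure fraction follows as f120 = 1 - nerve_norm_end*(1-f0)/m120.
        """
        if not 0 < nerve_norm_end <= muscle_norm_end <= 1:
            raise ValueError("require 0 < nerve_norm_end <= muscle_norm_end <= 1")
        f120 = 1.0 - nerve_norm_end * (1.0 - f0) / muscle_norm_end
        return cls(f0=f0, f120=f120, m120=muscle_norm_end, **kwargs)

    def failure_fraction(self, t: float | np.ndarray, total_s: float) -> np.ndarray:
        x = np.clip(np.asarray(t, dtype=float) / total_s, 0.0, 1.0)
        return self.f0 + (self.f120 - self.f0) * x**self.ramp_exponent

    def muscle_capacity(self, t: float | np.ndarray, total_s: float) -> np.ndarray:
        x = np.clip(np.asarray(t, dtype=float) / total_s, 0.0, 1.0)
        return 1.0 - (1.0 - self.m120) * x**self.muscle_fatigue_shape

    def droop(self, t: float | np.ndarray, total_s: float) -> np.ndarray:
        x = np.clip(np.asarray(t, dtype=float) / total_s, 0.0, 1.0)
        return self.d120 * x

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "f120": self.f120,
            "ramp_exponent": self.ramp_exponent,
            "m120": self.m120,
            "muscle_fatigue_shape": self.muscle_fatigue_shape,
            "d120": self.d120,
            "tetanus_rise_tau_s": self.tetanus_rise_tau_s,
            "relaxation_tau_s": self.relaxation_tau_s,
            "peak_specific_force_n_per_cm2": self.peak_specific_force_n_per_cm2,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TraceGroundTruth:
    """Closed-form truth for every statistic the trace analyzers estimate.

    Sign convention matches the reporting convention: negative values denote
    failure/droop.
    """

    true_final_nmtf: float
    true_initial_nmtf: float
    true_intratrain_fatigue_at_end: float
    true_specific_force: float
    epoch_times_s: np.ndarray
    true_mf: np.ndarray
    true_nf: np.ndarray
    true_nmtf_t: np.ndarray

    def to_dict(self) -> dict:
        return {
            "true_final_nmtf": self.true_final_nmtf,
            "true_initial_nmtf": self.true_initial_nmtf,
            "true_intratrain_fatigue_at_end": self.true_intratrain_fatigue_at_end,
            "true_specific_force": self.true_specific_force,
            "epoch_times_s": list(map(float, self.epoch_times_s)),
            "true_mf": list(map(float, self.true_mf)),
            "true_nf": list(map(float, self.true_nf)),
            "true_nmtf_t": list(map(float, self.true_nmtf_t)),
        }


@dataclass
class ForceRecording:
    """A sampled force trace with stimulus gate channels and prep metadata."""

    sampling_rate_hz: float
    time_s: np.ndarray
    force_n: np.ndarray
    nerve_stim_marker: np.ndarray
    muscle_stim_marker: np.ndarray
    metadata: PrepMetadata
    protocol: StimulationProtocol
    ground_truth: TraceGroundTruth | None = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.force_n) == len(self.nerve_stim_marker)
                == len(self.muscle_stim_marker) == n):
            raise ValueError("all channel vectors must have equal length")


def render_nerve_train(
    plateau: float,
    droop: float,
    protocol: StimulationProtocol | None = None,
    sampling_rate_hz: float = 1000.0,
    rise_tau_s: float = 0.020,
    relaxation_tau_s: float = 0.035,
    droop_flat_margin_s: float = 0.010,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one nerve-evoked train envelope over a full stimulation period.

    The envelope rises mono-exponentially toward ``plateau`` (individual
    40 Hz pulses are fused), droops linearly from mid-train so that the
    within-train min/max force ratio equals exactly ``1 - droop``, holds
    flat for the last ``droop_flat_margin_s`` of the train, and relaxes
    exponentially after the train ends.  Returns ``(t, force)`` for one
    train period.
    """
    protocol = protocol or StimulationProtocol()
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    _check_fraction("droop", droop)
    fs = sampling_rate_hz
    T = protocol.train_duration_s
    u0 = protocol.superimpose_onset_within_train_s
    u1 = T - droop_flat_margin_s
    n = int(round(protocol.train_period_s * fs))
    u = np.arange(n) / fs
    env = np.zeros(n)
    in_train = u < T
    ut = u[in_train]
    rise = 1.0 - np.exp(-ut / rise_tau_s)
    rise_u0 = 1.0 - math.exp(-u0 / rise_tau_s)
    rise_u1 = 1.0 - math.exp(-u1 / rise_tau_s)
    # Normalize the droop endpoint so min/max over the train is exactly
    # 1 - droop despite the residual exponential rise.
    d_eff = 1.0 - (1.0 - droop) * rise_u0 / rise_u1
    ramp = np.clip((ut - u0) / (u1 - u0), 0.0, 1.0)
    env[in_train] = plateau * rise * (1.0 - d_eff * ramp)
    tail = u >= T
    end_val = env[in_train][-1] if in_train.any() else 0.0
    env[tail] = end_val * np.exp(-(u[tail] - ut[-1]) / relaxation_tau_s)
    return u, env


def _render_superimposed_train(
    nerve_plateau: float,
    muscle_plateau: float,
    protocol: StimulationProtocol,
    fs: float,
    rise_tau_s: float,
    relaxation_tau_s: float,
) -> np.ndarray:
    """Envelope for an assessment train: nerve-only first half, direct muscle
    stimulation recruiting the failing fibers in the second half."""
    T = protocol.train_duration_s
    u_s = protocol.superimpose_onset_within_train_s
    n = int(round(protocol.train_period_s * fs))
    u = np.arange(n) / fs
    env = np.zeros(n)
    in_train = u < T
    ut = u[in_train]
    rise = 1.0 - np.exp(-ut / rise_tau_s)
    nerve = nerve_plateau * rise
    env_t = nerve.copy()
    sup = ut >= u_s
    n_at_us = nerve_plateau * (1.0 - math.exp(-u_s / rise_tau_s))
    env_t[sup] = muscle_plateau - (muscle_plateau - n_at_us) * np.exp(
        -(ut[sup] - u_s) / rise_tau_s
    )
    env[in_train] = env_t
    tail = u >= T
    env[tail] = env_t[-1] * np.exp(-(u[tail] - ut[-1]) / relaxation_tau_s)
    return env


def _ground_truth(model: FailureModel, protocol: StimulationProtocol,
                  f0_peak_n: float) -> TraceGroundTruth:
    total = protocol.total_duration_s
    epochs = protocol.epoch_times_s
    m = model.muscle_capacity(epochs, total)
    f = model.failure_fraction(epochs, total)
    true_mf = f0_peak_n * m
    true_nf = f0_peak_n * m * (1.0 - f)
    mfn = true_mf / true_mf[0]
    nfn = true_nf / true_nf[0]
    nmtf_t = -100.0 * (mfn - nfn) / mfn
    # The last droop assessment comes from the nerve-only train immediately
    # preceding the final superimposed train.
    t_last_nerve_only = epochs[-1] - protocol.train_period_s
    return TraceGroundTruth(
        true_final_nmtf=float(nmtf_t[-1]),
        true_initial_nmtf=-100.0 * model.f0,
        true_intratrain_fatigue_at_end=float(-100.0 * model.droop(t_last_nerve_only, total)),
        true_specific_force=model.peak_specific_force_n_per_cm2,
        epoch_times_s=epochs,
        true_mf=true_mf,
        true_nf=true_nf,
        true_nmtf_t=nmtf_t,
    )


def simulate_recording(
    protocol: StimulationProtocol | None = None,
    prep: PrepMetadata | None = None,
    model: FailureModel | None = None,
    sampling_rate_hz: float = 1000.0,
) -> tuple[ForceRecording, TraceGroundTruth]:
    """Simulate one full NMTF run and return the recording with its ground truth.

    Noise (additive Gaussian, SD = ``model.noise_sd`` x initial peak force) is
    applied after the analytic ground truth is recorded.
    """
    protocol = protocol or StimulationProtocol()
    prep = prep or PrepMetadata()
    model = model or FailureModel()
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    fs = sampling_rate_hz
    total = protocol.total_duration_s
    onsets = protocol.train_onsets_s
    period_n = int(round(protocol.train_period_s * fs))
    n_samples = period_n * len(onsets)
    t = np.arange(n_samples) / fs
    force = np.zeros(n_samples)
    nerve_marker = np.zeros(n_samples, dtype=np.uint8)
    muscle_marker = np.zeros(n_samples, dtype=np.uint8)

    f0_peak = model.peak_specific_force_n_per_cm2 * prep.csa_cm2
    train_n = int(round(protocol.train_duration_s * fs))
    sup_start = int(round(protocol.superimpose_onset_within_train_s * fs))

    for k, onset in enumerate(onsets):
        i0 = k * period_n
        m = float(model.muscle_capacity(onset, total))
        f = float(model.failure_fraction(onset, total))
        nerve_plateau = f0_peak * m * (1.0 - f)
        if protocol.is_superimposed(onset):
            env = _render_superimposed_train(
                nerve_plateau, f0_peak * m, protocol, fs,
                model.tetanus_rise_tau_s, model.relaxation_tau_s,
            )
            muscle_marker[i0 + sup_start: i0 + train_n] = 1
        else:
            _, env = render_nerve_train(
                nerve_plateau, float(model.droop(onset, total)), protocol, fs,
                model.tetanus_rise_tau_s, model.relaxation_tau_s,
            )
        force[i0: i0 + period_n] = env
        nerve_marker[i0: i0 + train_n] = 1

    gt = _ground_truth(model, protocol, f0_peak)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        force = force + rng.normal(0.0, model.noise_sd * f0_peak, size=n_samples)
        np.clip(force, 0.0, None, out=force)

    rec = ForceRecording(
        sampling_rate_hz=fs,
        time_s=t,
        force_n=force,
        nerve_stim_marker=nerve_marker,
        muscle_stim_marker=muscle_marker,
        metadata=prep,
        protocol=protocol,
        ground_truth=gt,
    )
    return rec, gt


# Per-group calibrations. Normalized end-of-run forces and droop are set so
# the closed-form statistics equal the group means the study design targets
# (final NMTF, initial NMTF, end-of-run intratrain fatigue, specific force).
GROUP_CALIBRATIONS: dict[str, FailureModel] = {
    "vehicle": FailureModel.from_normalized_forces(
        0.700, 0.2422, f0=0.126, d120=0.019,
        peak_specific_force_n_per_cm2=22.3),
    "vehicle+1NMPP1": FailureModel.from_normalized_forces(
        0.700, 0.0952, f0=0.205, d120=0.201,
        peak_specific_force_n_per_cm2=23.4),
    "TKI": FailureModel.from_normalized_forces(
        0.700, 0.1057, f0=0.172, d120=0.221,
        peak_specific_force_n_per_cm2=22.9),
    "TKI+BDNF": FailureModel.from_normalized_forces(
        0.700, 0.1162, f0=0.150, d120=0.215,
        peak_specific_force_n_per_cm2=21.9),
}


def draw_cohort_models(
    n_per_group: int,
    calibrations: dict[str, FailureModel] | None = None,
    base_seed: int = 0,
    jitter_cv: float = 0.05,
    f0_jitter_sd: float = 0.03,
    prep_template: PrepMetadata | None = None,
) -> list[tuple[PrepMetadata, FailureModel]]:
    """Draw per-animal jittered failure models and preps, deterministically.

    Multiplicative Gaussian jitter (CV ``jitter_cv``) is applied to f120,
    m120, d120 and peak specific force; f0 gets additive Gaussian jitter
    (SD ``f0_jitter_sd``). All fractions are clipped back into their valid
    ranges. Set ``jitter_cv = f0_jitter_sd = 0`` for identical animals.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    calibrations = calibrations if calibrations is not None else GROUP_CALIBRATIONS
    prep_template = prep_template or PrepMetadata()
    ss = np.random.SeedSequence(base_seed)
    members: list[tuple[PrepMetadata, FailureModel]] = []
    groups = list(calibrations.keys())
    children = ss.spawn(len(groups) * n_per_group)
    idx = 0
    for group in groups:
        base = calibrations.get(group)
        if not isinstance(base, FailureModel):
            raise KeyError(f"missing or invalid calibration for group {group!r}")
        for i in range(n_per_group):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            seed_int = int(child.generate_state(1)[0] % (2**31))

            def jit(x: float) -> float:
                return float(x * (1.0 + rng.normal(0.0, jitter_cv))) if jitter_cv > 0 else x

            f0 = base.f0 + (rng.normal(0.0, f0_jitter_sd) if f0_jitter_sd > 0 else 0.0)
            model = replace(
                base,
                f0=float(np.clip(f0, 0.0, 0.6)),
                f120=float(np.clip(jit(base.f120), 0.0, 0.999)),
                m120=float(np.clip(jit(base.m120), 0.05, 1.0)),
                d120=float(np.clip(jit(base.d120), 0.0, 0.95)),
                peak_specific_force_n_per_cm2=max(1.0, jit(base.peak_specific_force_n_per_cm2)),
                seed=seed_int,
            )
            prep = replace(
                prep_template,
                strip_weight_g=max(1e-4, jit(prep_template.strip_weight_g)),
                optimal_length_cm=max(0.5, jit(prep_template.optimal_length_cm)),
                group=group,
                animal_id=f"{group}-{i + 1:02d}",
                sex="f" if i % 2 == 0 else "m",
            )
            members.append((prep, model))
    return members


def simulate_cohort(
    n_per_group: int,
    calibrations: dict[str, FailureModel] | None = None,
    base_seed: int = 0,
    protocol: StimulationProtocol | None = None,
    sampling_rate_hz: float = 1000.0,
    jitter_cv: float = 0.05,
    f0_jitter_sd: float = 0.03,
    noise_sd: float | None = 0.005,
) -> list[tuple[ForceRecording, TraceGroundTruth]]:
    """Simulate ``n_per_group`` recordings per group, reproducibly.

    ``noise_sd`` overrides the calibration noise for every animal unless
    None.  Determinism contract: the same ``base_seed`` yields bit-identical
    force vectors.
    """
    protocol = protocol or StimulationProtocol()
    members = draw_cohort_models(
        n_per_group, calibrations, base_seed,
        jitter_cv=jitter_cv, f0_jitter_sd=f0_jitter_sd,
    )
    out = []
    for prep, model in members:
        if noise_sd is not None:
            model = replace(model, noise_sd=noise_sd)
        out.append(simulate_recording(protocol, prep, model, sampling_rate_hz))
    return out
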