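"""Morphometry of two-channel NMJ confocal stacks.

Measures pre/post apposition (% of post-synaptic endplate area overlapped by
pre-synaptic terminal label), endplate and terminal cross-sectional areas in
a maximum-intensity projection, relative planar area (endplate area divided
by its axis-aligned bounding-rectangle, a complexity/fill measure), and the
fiber-type class proxy based on endplate planar area and fiber diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

#: Classification thresholds: endplate planar area (um^2) and fiber diameter (um).
AREA_BOUNDARY_UM2 = 500.0
DIAMETER_BOUNDARY_UM = 50.0

#: Objects smaller than this are removed as noise specks after thresholding.
MIN_OBJECT_AREA_UM2 = 2.0


@dataclass
class NMJMeasurement:
    """Morphometric readout for one NMJ."""

    apposition_pct: float
    endplate_csa_um2: float
    terminal_csa_um2: float
    orthogonal_area_um2: float
    relative_planar_area_pct: float
    fiber_diameter_um: float
    fiber_type_class: str
    n_projected_slices: int
    threshold_log: dict

    def to_row(self) -> dict:
        return {
            "apposition_pct": self.apposition_pct,
            "endplate_csa_um2": self.endplate_csa_um2,
            "terminal_csa_um2": self.terminal_csa_um2,
            "orthogonal_area_um2": self.orthogonal_area_um2,
            "relative_planar_area_pct": self.relative_planar_area_pct,
            "fiber_diameter_um": self.fiber_diameter_um,
            "fiber_type_class": self.fiber_type_class,
            "n_projected_slices": self.n_projected_slices,
        }


def _signal_slices(vol: np.ndarray) -> np.ndarray:
    """Indices of slices whose in-mask mean exceeds twice the background.

    Background is the volume median; the mask is the set of pixels above the
    volume-wide Otsu threshold in the projection.
    """
    bg = float(np.median(vol))
    flat = vol.reshape(vol.shape[0], -1)
    try:
        thr = filters.threshold_otsu(vol.ravel())
    except ValueError:
        return np.array([], dtype=int)
    mask2d = vol.max(axis=0) > thr
    if not mask2d.any():
        return np.array([], dtype=int)
    in_mask = flat[:, mask2d.ravel()]
    means = in_mask.mean(axis=1)
    return np.flatnonzero(means > 2.0 * bg)


def project_stack(stack, slice_range: tuple[int, int] | None = None
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Maximum-intensity projection of both channels.

    ``slice_range`` is an inclusive (start, stop) pair; by default the union
    of slices carrying signal in either channel (in-mask mean above twice the
    background estimate) is projected.  Returns (post image, pre image,
    number of projected slices).
    """
    post = np.asarray(stack.post, dtype=float)
    pre = np.asarray(stack.pre, dtype=float)
    if slice_range is not None:
        z0, z1 = slice_range
        if z0 > z1 or z0 < 0 or z1 >= post.shape[0]:
            raise ValueError("empty or out-of-range slice range")
        idx = np.arange(z0, z1 + 1)
    else:
        idx = np.union1d(_signal_slices(post), _signal_slices(pre))
        if idx.size == 0:
            raise ValueError("no signal slices found in stack")
    return post[idx].max(axis=0), pre[idx].max(axis=0), int(idx.size)


def threshold_channel(image: np.ndarray, method: str | float = "otsu"
                      ) -> tuple[np.ndarray, dict]:
    """Binarize one projected channel.

    ``method`` is "otsu", a number, or "fixed:<value>".  Returns the mask and
    a log recording the method and the threshold actually applied.
    """
    image = np.asarray(image, dtype=float)
    if isinstance(method, str) and method.startswith("fixed:"):
        method = float(method.split(":", 1)[1])
    if method == "otsu":
        if image.min() == image.max():
            raise ValueError("otsu thresholding requires a non-constant image")
        thr = float(filters.threshold_otsu(image))
        name = "otsu"
    else:
        thr = float(method)
        name = "fixed"
    return image > thr, {"method": name, "threshold": thr}


def clean_mask(mask: np.ndarray, pixel_size_um: float,
               min_object_area_um2: float = MIN_OBJECT_AREA_UM2,
               keep_largest: bool = False) -> np.ndarray:
    """Suppress noise specks (< ``min_object_area_um2``); optionally keep only
    the largest connected component (sensible for the single endplate, not
    for the legitimately multi-blob terminal channel)."""
    min_px = max(1, int(round(min_object_area_um2 / pixel_size_um**2)))
    out = morphology.remove_small_objects(mask, max_size=min_px - 1)
    if keep_largest and out.any():
        labels = measure.label(out)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        out = labels == counts.argmax()
    return out


def compute_apposition(pre_mask: np.ndarray, post_mask: np.ndarray) -> float:
    """Percent of the post-synaptic endplate area covered by pre-synaptic label."""
    n_post = int(np.count_nonzero(post_mask))
    if n_post == 0:
        raise ValueError("empty post-synaptic mask")
    overlap = int(np.count_nonzero(np.logical_and(pre_mask, post_mask)))
    return 100.0 * overlap / n_post


def compute_areas(mask: np.ndarray, pixel_size_um: float
                  ) -> tuple[float, float, float]:
    """(CSA, orthogonal area, relative planar area %) of a binary mask.

    The orthogonal area is the axis-aligned bounding rectangle of the mask.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    px2 = pixel_size_um**2
    csa = float(mask.sum()) * px2
    ortho = float((rows[-1] - rows[0] + 1) * (cols[-1] - cols[0] + 1)) * px2
    return csa, ortho, 100.0 * csa / ortho


def classify_fiber_type(endplate_planar_area_um2: float,
                        fiber_diameter_um: float) -> str:
    """Fiber-type class proxy from endplate planar area and fiber diameter.

    Small endplate (<500 um^2) on a thin fiber (<50 um) -> "I_IIa"; large
    endplate (>500 um^2) on a thick fiber (>50 um) -> "IIx_IIb"; every other
    combination (including exact boundary values) -> "excluded".  Excluded
    NMJs are flagged, not dropped, so they still contribute to overall
    per-animal estimates.
    """
    if endplate_planar_area_um2 <= 0 or fiber_diameter_um <= 0:
        raise ValueError("area and diameter must be positive")
    small = endplate_planar_area_um2 < AREA_BOUNDARY_UM2
    thin = fiber_diameter_um < DIAMETER_BOUNDARY_UM
    large = endplate_planar_area_um2 > AREA_BOUNDARY_UM2
    thick = fiber_diameter_um > DIAMETER_BOUNDARY_UM
    if small and thin:
        return "I_IIa"
    if large and thick:
        return "IIx_IIb"
    return "excluded"


def measure_nmj(stack, fiber_diameter_um: float,
                threshold: str | float = "otsu",
                slice_range: tuple[int, int] | None = None,
                min_object_area_um2: float = MIN_OBJECT_AREA_UM2) -> NMJMeasurement:
    """Full morphometry chain for one stack: project, threshold, clean, measure."""
    post_img, pre_img, n_slices = project_stack(stack, slice_range)
    px = stack.pixel_size_um
    post_mask, post_log = threshold_channel(post_img, threshold)
    pre_mask, pre_log = threshold_channel(pre_img, threshold)
    post_mask = clean_mask(post_mask, px, min_object_area_um2, keep_largest=True)
    pre_mask = clean_mask(pre_mask, px, min_object_area_um2, keep_largest=False)
    if not post_mask.any():
        raise ValueError("no endplate found after thresholding")
    csa, ortho, rel = compute_areas(post_mask, px)
    terminal_csa = float(pre_mask.sum()) * px**2 if pre_mask.any() else 0.0
    return NMJMeasurement(
        apposition_pct=compute_apposition(pre_mask, post_mask),
        endplate_csa_um2=csa,
        terminal_csa_um2=terminal_csa,
        orthogonal_area_um2=ortho,
        relative_planar_area_pct=rel,
        fiber_diameter_um=fiber_diameter_um,
        fiber_type_class=classify_fiber_type(csa, fiber_diameter_um),
        n_projected_slices=n_slices,
        threshold_log={"post": post_log, "pre": pre_log},
    )


def analyze_nmj_cohort(samples, threshold: str | float = "otsu"
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Measure a cohort of stacks.

    ``samples`` is an iterable of ``(stack, meta)`` where meta carries at
    least ``animal_id`` and ``fiber_diameter_um`` (and optionally ``group``).
    Returns (per-NMJ table, per-animal-per-class table restricted to
    classified NMJs, overall per-animal table including excluded NMJs).
    """
    rows = []
    for stack, meta in samples:
        m = measure_nmj(stack, meta["fiber_diameter_um"], threshold)
        row = m.to_row()
        row["animal_id"] = meta["animal_id"]
        row["group"] = meta.get("group", "")
        rows.append(row)
    if not rows:
        raise ValueError("need at least one stack")
    per_nmj = pd.DataFrame(rows)
    value_cols = ["apposition_pct", "endplate_csa_um2", "terminal_csa_um2",
                  "relative_planar_area_pct"]
    keys = ["animal_id"]
    if per_nmj["group"].astype(bool).any():
        keys = ["animal_id", "group"]
    typed = per_nmj[per_nmj["fiber_type_class"] != "excluded"]
    if len(typed):
        per_class = (typed.groupby([*keys, "fiber_type_class"])[value_cols]
                     .mean().reset_index())
    else:
        per_class = pd.DataFrame(
            columns=[*keys, "fiber_type_class", *value_cols])
    per_animal = per_nmj.groupby(keys)[value_cols].mean().reset_index()
    return per_nmj, per_class, per_animal
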