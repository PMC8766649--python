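"""Perfusion-fraction quantification.

SPECT/CT route: with a lobe label map in hand, each lobe's perfusion is the
sum of SPECT counts over its voxels, and its fraction is that sum divided by
the whole-lung total (background excluded — counts blurred outside the lung
field do not enter the denominator).

Planar route: conjugate anterior/posterior views are combined per side by the
geometric mean of the ROI count sums, the standard depth-compensating way to
count activity on opposed planar views; side fractions are then normalised to
sum to 1. ROIs are given in anterior-view orientation and mirrored
internally for the posterior view.

The interobserver analysis compares the lobar fractions produced by two
independent sets of fissure traces (Pearson r, OLS slope/intercept,
Bland–Altman limits, absolute differences; differences are A − B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import agreement as agr
from .anatomy import LEFT_LOBES, LOBE_LABELS, LOBES, RIGHT_LOBES
from .errors import DegenerateInputError, InsufficientDataError, ParameterError
from .volume import VoxelVolume, require_same_grid

__all__ = [
    "LobarPerfusion",
    "InterobserverResult",
    "lobar_fractions",
    "resected_fraction",
    "side_fractions",
    "planar_side_fraction",
    "side_rois_from_labels",
    "interobserver_agreement",
]


def _values(volume) -> np.ndarray:
    return volume.values if isinstance(volume, VoxelVolume) else np.asarray(volume)


@dataclass(frozen=True)
class LobarPerfusion:
    """Per-lobe perfusion counts and fractions of the whole-lung total."""

    counts: dict[str, float]
    total: float
    fractions: dict[str, float]


def lobar_fractions(spect, labels) -> LobarPerfusion:
    """Masked pixel counting: per-lobe SPECT count sums and fractions."""
    values = _values(spect).astype(float)
    labels = np.asarray(_values(labels))
    require_same_grid(values, labels, "SPECT volume and label map")
    if (values < 0).any():
        raise ParameterError("SPECT volume must be non-negative")
    sums = np.bincount(
        labels.ravel().astype(np.int64), weights=values.ravel(), minlength=6
    )
    counts = {lobe: float(sums[lab]) for lobe, lab in LOBE_LABELS.items()}
    total = float(sum(counts.values()))
    if total <= 0:
        raise DegenerateInputError("zero total lung counts")
    fractions = {lobe: c / total for lobe, c in counts.items()}
    return LobarPerfusion(counts=counts, total=total, fractions=fractions)


def resected_fraction(perf: LobarPerfusion, resected_lobes) -> float:
    """Summed fraction of the named lobes (supports bilobectomy)."""
    resected = frozenset(resected_lobes)
    if not resected:
        raise ParameterError("resected_lobes must name at least one lobe")
    unknown = resected - set(LOBES)
    if unknown:
        raise ParameterError(f"unknown lobes: {sorted(unknown)}")
    return float(sum(perf.fractions[l] for l in resected))


def side_fractions(perf: LobarPerfusion) -> dict[str, float]:
    """Volumetric left/right perfusion shares (sum of lobe fractions)."""
    return {
        "right": float(sum(perf.fractions[l] for l in RIGHT_LOBES)),
        "left": float(sum(perf.fractions[l] for l in LEFT_LOBES)),
    }


def side_rois_from_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    """(left_roi, right_roi) planar masks: the anterior-view projection of
    each lung side's label volume."""
    labels = np.asarray(_values(labels))
    left_ids = [LOBE_LABELS[l] for l in LEFT_LOBES]
    right_ids = [LOBE_LABELS[l] for l in RIGHT_LOBES]
    left = np.isin(labels, left_ids).any(axis=1).astype(np.uint8)
    right = np.isin(labels, right_ids).any(axis=1).astype(np.uint8)
    return left, right


def planar_side_fraction(
    anterior: np.ndarray,
    posterior: np.ndarray,
    left_roi: np.ndarray,
    right_roi: np.ndarray,
) -> dict[str, float]:
    """Conjugate-view side fractions from anterior/posterior planar images.

    ROIs are in anterior-view orientation; the posterior image (mirrored
    along x by the projection) has its ROIs mirrored to match. Per-side
    counts are the geometric mean of the two views' ROI sums; the returned
    fractions are normalised to sum to 1.
    """
    anterior = np.asarray(anterior, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    left_roi = np.asarray(left_roi).astype(bool)
    right_roi = np.asarray(right_roi).astype(bool)
    for img in (anterior, posterior):
        if img.ndim != 2:
            raise ParameterError("planar images must be 2-D")
        if (img < 0).any():
            raise ParameterError("planar images must be non-negative")
    if anterior.shape != posterior.shape or anterior.shape != left_roi.shape:
        raise ParameterError("planar images and ROIs must share a grid")
    if (left_roi & right_roi).any():
        raise ParameterError("left and right ROIs must be disjoint")
    gm = {}
    for name, roi in (("left", left_roi), ("right", right_roi)):
        a = float(anterior[roi].sum())
        p = float(posterior[roi[:, ::-1]].sum())
        gm[name] = float(np.sqrt(a * p))
    total = gm["left"] + gm["right"]
    if total <= 0:
        raise DegenerateInputError("zero counts in both planar ROIs")
    return {name: v / total for name, v in gm.items()}


@dataclass(frozen=True)
class InterobserverResult:
    """Agreement between two measurers' lobar fraction series (A vs B)."""

    n: int
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    r2: float
    bland_altman: agr.BlandAltmanResult
    abs_differences: agr.AbsDiffSummary


def interobserver_agreement(fractions_a, fractions_b) -> InterobserverResult:
    """Full agreement analysis of paired fraction measurements.

    Differences follow the A − B convention, so the Bland–Altman block is
    computed with B as the reference series.
    """
    a = np.asarray(list(fractions_a), dtype=float)
    b = np.asarray(list(fractions_b), dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired fraction lists must have equal length")
    if len(a) < 3:
        raise InsufficientDataError(f"interobserver analysis needs n >= 3, got {len(a)}")
    ba = agr.bland_altman(b, a)
    if np.array_equal(a, b):
        # identical measurements: perfect agreement by definition
        r, p = 1.0, 0.0
        slope, intercept, r2 = 1.0, 0.0, 1.0
    else:
        r, p = agr.pearson_correlation(a, b)
        slope, intercept, r2 = agr.regression_r2(a, b)
    absdiff = agr.absolute_differences(b, a)
    return InterobserverResult(
        n=len(a),
        pearson_r=r,
        pearson_p=p,
        slope=slope,
        intercept=intercept,
        r2=r2,
        bland_altman=ba,
        abs_differences=absdiff,
    )
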