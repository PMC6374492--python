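"""Two-level evaluation of lesion segmentations.

Voxel level: overlap metrics (sensitivity, specificity, Dice) inside the
intracranial mask, ROC curves by threshold sweep and their AUC, and
largest-connected-component lesion volumetry.

Region level: the ten ASPECTS regions per hemisphere (M1-M6, insular ribbon
I, lentiform nucleus L, caudate C, internal capsule IC) are called
stroke-positive when even a single predicted-positive voxel falls inside
them; the resulting 2x2 contingency counts over cases yield sensitivity,
specificity and a region-count Dice coefficient, and the per-hemisphere
positive-region counts yield the ASPECTS score (10 minus positives, worst
hemisphere reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_curve as _sk_roc_curve

from .grid import (
    BinaryMask,
    ParameterError,
    ProbabilityMap,
    RegionAtlas,
)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (0.815 -> 0.82)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# voxel level
# ---------------------------------------------------------------------------

def threshold_map(p: ProbabilityMap, t: float) -> BinaryMask:
    """Binarize a probability map; ties at the threshold count as positive."""
    if not (0.0 <= t <= 1.0):
        raise ParameterError(f"threshold must lie in [0,1], got {t}")
    pos = (p.values >= t) & p.mask.as_bool()
    return BinaryMask.from_array(pos, p.volume)


@dataclass(frozen=True)
class VoxelMetrics:
    sensitivity: float  # NaN when truth is empty
    specificity: float
    dsc: float
    threshold: float | None = None
    undefined_reason: str | None = None


def voxel_metrics(pred: BinaryMask, truth: BinaryMask, mask: BinaryMask, threshold: float | None = None) -> VoxelMetrics:
    """Sensitivity, specificity and Dice over in-mask voxels.

    With empty truth, sensitivity is NaN (flagged via ``undefined_reason``)
    and Dice follows the convention: 1 if the prediction is also empty, else 0.
    """
    pred.volume.require_congruent(truth.volume, "truth mask")
    pred.volume.require_congruent(mask.volume, "evaluation mask")
    m = mask.as_bool()
    p = pred.as_bool()[m]
    t = truth.as_bool()[m]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    if tp + fn == 0:
        dsc = 1.0 if fp == 0 else 0.0
        return VoxelMetrics(float("nan"), specificity, dsc, threshold, "empty truth: sensitivity undefined")
    sensitivity = tp / (tp + fn)
    dsc = 2 * tp / (2 * tp + fp + fn)
    return VoxelMetrics(sensitivity, specificity, dsc, threshold)


@dataclass(frozen=True)
class RocCurve:
    """Threshold-sweep operating points; FPR non-decreasing, endpoints included."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(p: ProbabilityMap, truth: BinaryMask, mask: BinaryMask) -> RocCurve:
    """ROC over in-mask voxels by sweeping all distinct probability values.

    Positivity uses the same >= tie rule as :func:`threshold_map`; the AUC is
    the trapezoidal integral, which equals the pairwise concordance
    (rank-sum) estimator with ties counted half.
    """
    m = mask.as_bool()
    y = truth.as_bool()[m].astype(int)
    s = p.values[m]
    if y.min() == y.max():
        raise ParameterError("ROC needs both positive and negative voxels in the mask")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn always ends at (1,1)
        fpr, tpr = np.append(fpr, 1.0), np.append(tpr, 1.0)
        thr = np.append(thr, 0.0)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def largest_component_volume(mask: BinaryMask) -> float:
    """Volume (cm^3) of the largest 26-connected component; 0 for empty masks."""
    arr = mask.as_bool()
    if not arr.any():
        return 0.0
    labels, n = ndimage.label(arr, structure=np.ones((3, 3, 3)))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return float(counts.max()) * mask.volume.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# region level
# ---------------------------------------------------------------------------

def region_positivity(pred: BinaryMask, atlas: RegionAtlas) -> np.ndarray:
    """Boolean vector over the 20 atlas regions (>=1 positive voxel => positive).

    Regions whose label never occurs in the atlas volume trigger a warning
    and are reported negative (they have zero voxels to be positive in).
    """
    pred.volume.require_congruent(atlas.volume, "atlas")
    labels = np.asarray(atlas.values, dtype=np.int64)
    n = atlas.n_regions
    present = np.bincount(labels.ravel(), minlength=n + 1)[1:] > 0
    missing = [name for name, lab in atlas.label_table.items() if not present[lab - 1]]
    if missing:
        warnings.warn(f"atlas labels absent from volume, evaluated with 0 voxels: {missing}")
    hit = np.bincount(labels[pred.as_bool()], minlength=n + 1)[1:]
    return hit > 0


@dataclass(frozen=True)
class RegionContingency:
    """Accumulated region-level 2x2 counts over evaluated cases."""

    tn: int = 0
    tp: int = 0
    fn: int = 0
    fp: int = 0

    def __post_init__(self):
        if min(self.tn, self.tp, self.fn, self.fp) < 0:
            raise ParameterError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.tp + self.fn + self.fp

    def __add__(self, other: "RegionContingency") -> "RegionContingency":
        return RegionContingency(
            self.tn + other.tn, self.tp + other.tp, self.fn + other.fn, self.fp + other.fp
        )


def region_contingency(pred_regions, truth_regions) -> RegionContingency:
    """Element-wise 2x2 tally over per-case region vectors.

    Both arguments are sequences of equal-length boolean vectors (or a single
    pair of vectors).
    """
    pred_regions = np.atleast_2d(np.asarray(pred_regions, dtype=bool))
    truth_regions = np.atleast_2d(np.asarray(truth_regions, dtype=bool))
    if pred_regions.shape != truth_regions.shape:
        raise ParameterError(
            f"prediction/truth region vectors differ in shape: "
            f"{pred_regions.shape} vs {truth_regions.shape}"
        )
    p, t = pred_regions.ravel(), truth_regions.ravel()
    return RegionContingency(
        tn=int(np.sum(~p & ~t)),
        tp=int(np.sum(p & t)),
        fn=int(np.sum(~p & t)),
        fp=int(np.sum(p & ~t)),
    )


def metrics_from_contingency(c: RegionContingency) -> dict:
    """Sensitivity, specificity and region-count Dice from 2x2 counts.

    Dice over region calls is 2TP/(2TP+FP+FN).  Metrics with a zero
    denominator are NaN.  Each metric is reported at full precision and
    half-up rounded to 2 decimals (key suffix ``_2dp``).
    """
    out = {}
    pairs = {
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "dsc": (2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }
    for name, (num, den) in pairs.items():
        val = num / den if den else float("nan")
        out[name] = val
        out[f"{name}_2dp"] = round_half_up(val) if den else float("nan")
    return out


def combined_dsc(c_group_a: RegionContingency, fp_group_b: int) -> float:
    """Region Dice pooled over both groups.

    Stroke-negative subjects contribute only false-positive (and true
    negative) regions, so the pooled Dice is 2TP/(2TP + FP_A + FP_B + FN).
    Returns NaN on a zero denominator.
    """
    if fp_group_b < 0:
        raise ParameterError("fp_group_b must be non-negative")
    den = 2 * c_group_a.tp + c_group_a.fp + fp_group_b + c_group_a.fn
    return 2 * c_group_a.tp / den if den else float("nan")


def aspects_score(region_positives) -> int:
    """ASPECTS points: 10 minus positive regions, worst hemisphere reported.

    The 20-entry vector holds the left-hemisphere regions first, then the
    right.  Adding positive regions can only lower (never raise) the score.
    """
    v = np.asarray(region_positives, dtype=bool)
    if v.shape != (20,):
        raise ParameterError(f"expected a 20-entry region vector, got shape {v.shape}")
    left = 10 - int(v[:10].sum())
    right = 10 - int(v[10:].sum())
    return min(left, right)
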