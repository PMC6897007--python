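"""Quantitative validation: overlap, confusion statistics, paired t-tests.

Segmentations are scored against ground truth with the volumetric overlap
(the Jaccard index as a percentage), detection performance with per-polyp
confusion counts, and measurement agreement with a paired t-test.  The
reporting layer truncates percentages to one decimal (it does not round),
matching radiological reporting conventions; full-precision values are
always available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats


def truncate(value: float, decimals: int = 1) -> float:
    """Truncate (not round) toward zero at the given number of decimals."""
    factor = 10.0**decimals
    return math.trunc(value * factor) / factor


# --- volumetric overlap ------------------------------------------------------

def volumetric_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Volumetric overlap of two masks: ``100 * |A n B| / |A u B|`` percent.

    Symmetric, bounded in [0, 100], and 100 iff the masks are equal.  Two
    empty masks overlap perfectly (100) by convention.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 100.0
    inter = int(np.logical_and(a, b).sum())
    return 100.0 * inter / union


# --- confusion statistics ----------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Per-polyp confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ConfusionStats:
    """Sensitivity, specificity and accuracy as full-precision percentages."""

    tpr_pct: float
    tnr_pct: float
    accuracy_pct: float

    def printed(self) -> dict[str, float]:
        """Reported form: percentages truncated at one decimal (TPR/TNR)
        and two decimals (accuracy)."""
        return {
            "tpr_pct": truncate(self.tpr_pct, 1),
            "tnr_pct": truncate(self.tnr_pct, 1),
            "accuracy_pct": truncate(self.accuracy_pct, 2),
        }


def confusion_stats(c: ConfusionCounts) -> ConfusionStats:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, in percent."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: TP + FN = 0")
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: TN + FP = 0")
    total = c.tp + c.fp + c.fn + c.tn
    return ConfusionStats(
        tpr_pct=100.0 * c.tp / (c.tp + c.fn),
        tnr_pct=100.0 * c.tn / (c.tn + c.fp),
        accuracy_pct=100.0 * (c.tp + c.tn) / total,
    )


# --- paired t-test -----------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, standard deviation and standard error of the mean."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(n=len(values), mean=float(values.mean()),
                   sd=float(values.std(ddof=1)))


@dataclass(frozen=True)
class PairedTResult:
    n: int
    dof: int
    mean_diff: float
    sd_diff: float
    sem_diff: float
    t: float
    p: float
    groups: tuple[GroupSummary, GroupSummary] | None = None


def paired_t_summary(
    diffs: np.ndarray,
    group_b: np.ndarray | None = None,
) -> PairedTResult:
    """Paired t-test summary.

    Called either with the paired differences, or with two paired groups
    (``diffs`` then being group A); in the latter case both group
    summaries are included.  dof = n - 1; t = mean(d) / SEM(d); the
    two-tailed p comes from the t distribution.  All-zero differences make
    t undefined: p = 1 is reported with a warning.
    """
    a = np.asarray(diffs, dtype=float)
    groups = None
    if group_b is not None:
        b = np.asarray(group_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired groups must have equal length")
        groups = (GroupSummary.from_values(a), GroupSummary.from_values(b))
        d = a - b
    else:
        d = a
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    dof = n - 1
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        warnings.warn("all paired differences equal; t undefined, reporting p=1",
                      stacklevel=2)
        return PairedTResult(n, dof, mean, sd, 0.0, float("nan"), 1.0, groups)
    sem = sd / math.sqrt(n)
    t = mean / sem
    p = 2.0 * float(_stats.t.sf(abs(t), dof))
    return PairedTResult(n, dof, mean, sd, sem, t, p, groups)


# --- per-polyp matching ------------------------------------------------------

def per_polyp_match(
    detections: np.ndarray,
    truths: np.ndarray,
    tolerance_mm: float = 5.0,
    negatives: np.ndarray | None = None,
) -> ConfusionCounts:
    """Greedy nearest-neighbour matching of detections to true polyps.

    ``detections`` and ``truths`` are (n, 3) arrays of physical positions
    (mm).  Pairs closer than ``tolerance_mm`` are matched greedily by
    increasing distance: matches are TP, unmatched detections FP, unmatched
    truths FN.  ``negatives`` are truth-negative structures (e.g. folds);
    each one with no detection within tolerance counts as a TN.
    """
    det = np.asarray(detections, dtype=float).reshape(-1, 3)
    tru = np.asarray(truths, dtype=float).reshape(-1, 3)
    pairs = []
    for i in range(len(det)):
        for j in range(len(tru)):
            d = float(np.linalg.norm(det[i] - tru[j]))
            if d <= tolerance_mm:
                pairs.append((d, i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for d, i, j in pairs:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    fp = len(det) - tp
    fn = len(tru) - tp
    tn = 0
    if negatives is not None:
        neg = np.asarray(negatives, dtype=float).reshape(-1, 3)
        for j in range(len(neg)):
            hit = any(
                float(np.linalg.norm(det[i] - neg[j])) <= tolerance_mm
                for i in range(len(det))
            )
            if not hit:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
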