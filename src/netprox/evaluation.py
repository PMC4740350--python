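"""Discrimination of known from unknown drug-disease pairs.

Proximity z is "smaller is better", so every ranking here scores pairs by
-z. Provides trapezoidal ROC/AUC, balanced-negative resampled AUC, the
sensitivity/specificity-intersection cutoff with F-scores, Fisher
exact-test enrichment (sample odds ratio, matching how 2x2 enrichments are
conventionally reported), and a locality summary of observed closest
distances.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import contingency, fisher_exact
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "ContingencyTable2x2",
    "FisherResult",
    "CutoffResult",
    "DistanceHistogram",
    "roc_auc",
    "balanced_auc",
    "optimal_cutoff",
    "fisher_enrichment",
    "closest_distance_histogram",
]


@dataclass
class RocResult:
    auc: float
    curve: list  # of (false_positive_rate, true_positive_rate)
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d): rows condition present/absent, columns outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class FisherResult:
    odds_ratio: float  # sample (cross-product) OR
    p_two_sided: float
    odds_ratio_conditional: float  # conditional MLE, for reference
    infinite: bool = False


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    grid: np.ndarray
    f_scores: np.ndarray
    crossed: bool = True


@dataclass
class DistanceHistogram:
    counts: dict  # observed closest distance -> count
    fraction_within_two: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and trapezoidal AUC; higher score = more likely positive.

    Thresholds sweep the distinct score values, which makes the trapezoidal
    area equal to the Mann-Whitney statistic with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, curve=list(zip(fpr.tolist(), tpr.tolist())),
                     n_pos=n_pos, n_neg=n_neg)


def balanced_auc(
    scores_known,
    scores_unknown,
    n_neg: int = 402,
    reps: int = 100,
    rng=None,
) -> tuple[float, float]:
    """Mean and s.d. of the AUC over repeated balanced negative subsamples.

    Each repetition keeps all positives and draws ``n_neg`` negatives
    without replacement from the unknown-pair scores, countering the heavy
    class imbalance of the known/unknown split.
    """
    scores_known = np.asarray(scores_known, dtype=float)
    scores_unknown = np.asarray(scores_unknown, dtype=float)
    if len(scores_unknown) < n_neg:
        raise ValueError(
            f"need at least n_neg={n_neg} unknown-pair scores, got {len(scores_unknown)}"
        )
    rng = np.random.default_rng(rng)
    labels = np.concatenate([np.ones(len(scores_known), dtype=int), np.zeros(n_neg, dtype=int)])
    aucs = np.empty(reps)
    for r in range(reps):
        neg = rng.choice(scores_unknown, size=n_neg, replace=False)
        aucs[r] = roc_auc(np.concatenate([scores_known, neg]), labels).auc
    return float(aucs.mean()), float(aucs.std(ddof=0))


def optimal_cutoff(z_known, z_unknown, grid=None, step: float = 0.05) -> CutoffResult:
    """Proximity cutoff where the sensitivity and specificity curves intersect.

    sensitivity(c) = fraction of known pairs with z <= c (proximal = predicted
    positive); specificity(c) = fraction of negatives with z > c. Sensitivity
    rises and specificity falls with c, so the curves cross once; the crossing
    is located by linear interpolation between neighboring grid points. The
    per-grid-point F-score (harmonic mean of precision and sensitivity) is
    returned alongside.
    """
    z_known = np.asarray(z_known, dtype=float)
    z_unknown = np.asarray(z_unknown, dtype=float)
    if grid is None:
        lo = min(z_known.min(), z_unknown.min())
        hi = max(z_known.max(), z_unknown.max())
        grid = np.arange(np.floor(lo / step) * step, hi + step, step)
    grid = np.asarray(grid, dtype=float)
    sens = np.array([(z_known <= c).mean() for c in grid])
    spec = np.array([(z_unknown > c).mean() for c in grid])
    tp = np.array([(z_known <= c).sum() for c in grid], dtype=float)
    fp = np.array([(z_unknown <= c).sum() for c in grid], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f = np.where(precision + sens > 0,
                     2 * precision * sens / (precision + sens), 0.0)
    diff = sens - spec
    if len(grid) == 1:
        logger.warning("cutoff grid has a single point; returning it")
        return CutoffResult(float(grid[0]), float(sens[0]), float(spec[0]),
                            grid, f, crossed=False)
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if diff[0] >= 0:  # curves already crossed below the grid
        logger.warning("sensitivity >= specificity over the whole grid")
        return CutoffResult(float(grid[0]), float(sens[0]), float(spec[0]),
                            grid, f, crossed=False)
    if len(sign_change) == 0:
        logger.warning("sensitivity and specificity curves do not cross in the grid")
        return CutoffResult(float(grid[-1]), float(sens[-1]), float(spec[-1]),
                            grid, f, crossed=False)
    i = int(sign_change[0])
    x0, x1 = grid[i], grid[i + 1]
    h0, h1 = diff[i], diff[i + 1]
    frac = 0.0 if h1 == h0 else -h0 / (h1 - h0)
    cutoff = float(x0 + frac * (x1 - x0))
    sens_c = float(sens[i] + frac * (sens[i + 1] - sens[i]))
    spec_c = float(spec[i] + frac * (spec[i + 1] - spec[i]))
    return CutoffResult(cutoff, sens_c, spec_c, grid, f, crossed=True)


def fisher_enrichment(table) -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    The reported odds ratio is the sample (cross-product) estimate
    ``(a*d)/(b*c)``; the conditional maximum-likelihood estimate used by
    some exact-test implementations is also returned for reference. A zero
    ``b*c`` margin yields an infinite OR with a flag.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    arr = table.as_array()
    stat, p = fisher_exact(arr, alternative="two-sided")
    infinite = table.b * table.c == 0
    if infinite:
        sample_or = np.inf if table.a * table.d > 0 else np.nan
    else:
        sample_or = (table.a * table.d) / (table.b * table.c)
    try:
        cond = float(contingency.odds_ratio(arr, kind="conditional").statistic)
    except ValueError:
        cond = float("nan")
    return FisherResult(
        odds_ratio=float(sample_or),
        p_two_sided=float(p),
        odds_ratio_conditional=cond,
        infinite=infinite,
    )


def closest_distance_histogram(results) -> DistanceHistogram:
    """Histogram of observed closest distances with the fraction at d <= 2.

    The locality summary behind "drugs act within two links of the disease
    proteins": accepts ProximityResult objects (closest measure only) or
    raw distances.
    """
    ds = []
    for r in results:
        if hasattr(r, "measure"):
            if r.measure != "closest":
                raise ValueError("histogram is defined for the closest measure only")
            ds.append(float(r.d))
        else:
            ds.append(float(r))
    counts = Counter(ds)
    frac = sum(1 for d in ds if d <= 2) / len(ds) if ds else 0.0
    return DistanceHistogram(counts=dict(sorted(counts.items())), fraction_within_two=frac)
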