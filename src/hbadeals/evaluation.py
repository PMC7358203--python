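"""Benchmarking: OSTP oracle baseline and precision-recall machinery.

OSTP ("optimal splicing using the t-statistic and proportions") is an
evaluation-time oracle usable only on simulated data: isoform levels are
converted to proportions (each isoform divided by the sum of the *other*
isoforms of its gene), a two-sample t-statistic is computed per isoform, and
for every false-positive count the |t| cutoff maximizing true-positive
detection is chosen.  It upper-bounds what any t-statistic-derived
significance on proportions could achieve.

Precision-recall curves for probability-valued statistics sweep a fixed
threshold grid on [0, 1] (default step 1e-4).  True positives for splicing
are isoforms of differentially spliced genes whose within-gene fraction
changes at least 2-fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_normalize import CountMatrix, cpm_log_transform, gene_level_sum

__all__ = [
    "PRCurve",
    "isoform_proportions",
    "welch_t",
    "ostp_curve",
    "pr_curve",
    "mean_pr_curve",
    "t_test_de_scores",
]

DEFAULT_GRID_STEP = 1e-4


@dataclass
class PRCurve:
    """Operating points of a detector plus the area under the curve."""

    recall: np.ndarray
    precision: np.ndarray
    auprc: float
    thresholds: np.ndarray | None = None


def _auprc(recall: np.ndarray, precision: np.ndarray) -> float:
    """Trapezoidal area under the recall-sorted operating points.

    Several thresholds can share one recall (score ties); the achievable
    operating point at that recall is the one with the highest precision, so
    duplicates are collapsed to their maximum before integrating.  Recall 0
    is anchored with the precision of the lowest observed recall.
    """
    ok = np.isfinite(precision)
    r, p = recall[ok], precision[ok]
    if r.size == 0:
        return float("nan")
    distinct = np.unique(r)
    best = np.array([p[r == d].max() for d in distinct])
    if distinct[0] > 0.0:
        distinct = np.concatenate([[0.0], distinct])
        best = np.concatenate([[best[0]], best])
    return float(np.trapezoid(best, distinct))


def isoform_proportions(cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Each isoform's count divided by the summed counts of its gene's other
    isoforms, per sample.

    Single-isoform genes are excluded.  Cells whose complement sums to zero
    are undefined (NaN) and trigger a warning.  Returns ``(props, keep)``
    where ``keep`` is the boolean row mask into ``cm`` of retained isoforms.
    """
    gene_sums = gene_level_sum(cm)
    sums_by_gene = {g: gene_sums.counts[i] for i, g in enumerate(gene_sums.gene_ids)}
    t_per_gene = cm.isoforms_per_gene()
    keep = np.array([t_per_gene[g] >= 2 for g in cm.gene_ids])
    counts = cm.counts[keep]
    others = np.stack([sums_by_gene[g] for g in cm.gene_ids[keep]]) - counts
    with np.errstate(divide="ignore", invalid="ignore"):
        props = counts / others
    props[~np.isfinite(props)] = np.nan
    n_bad = int(np.isnan(props).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} proportion cells have a zero complement and are excluded",
            UserWarning,
            stacklevel=2,
        )
    return props, keep


def welch_t(values: np.ndarray, is_control: np.ndarray) -> np.ndarray:
    """Row-wise two-sample t-statistic (unequal variances), NaN-tolerant.

    Rows with fewer than two finite values in either group, or zero variance
    in both, return NaN.
    """
    out = np.full(values.shape[0], np.nan)
    a = values[:, is_control]
    b = values[:, ~is_control]
    for r in range(values.shape[0]):
        x = a[r][np.isfinite(a[r])]
        y = b[r][np.isfinite(b[r])]
        if x.size < 2 or y.size < 2:
            continue
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0.0 and vy == 0.0:
            continue
        out[r] = (x.mean() - y.mean()) / np.sqrt(vx / x.size + vy / y.size)
    return out


def _envelope_curve(scores: np.ndarray, positives: np.ndarray, n_pos_total: int) -> PRCurve:
    """Upper envelope over all score cutoffs: max TP at each FP count."""
    order = np.argsort(-scores, kind="stable")
    pos = positives[order]
    tp = np.cumsum(pos)
    fp = np.cumsum(~pos)
    best: dict = {}
    for k in range(scores.size):
        f, t = int(fp[k]), int(tp[k])
        if t > best.get(f, -1):
            best[f] = t
    fps = np.array(sorted(best))
    tps = np.array([best[f] for f in fps])
    ok = (tps + fps) > 0
    fps, tps = fps[ok], tps[ok]
    precision = tps / (tps + fps)
    recall = tps / n_pos_total
    return PRCurve(recall=recall, precision=precision,
                   auprc=_auprc(recall, precision))


def ostp_curve(
    props: np.ndarray,
    is_control: np.ndarray,
    truth_flags: np.ndarray,
) -> PRCurve:
    """OSTP oracle PR curve from isoform proportions and splicing truth.

    ``truth_flags`` marks truth positives (DS isoforms with fold change >= 2)
    among the rows of ``props``.  Isoforms with an undefined t-statistic are
    skipped as detections but still count in the recall denominator.
    """
    truth_flags = np.asarray(truth_flags, dtype=bool)
    if truth_flags.size != props.shape[0]:
        raise ValueError("truth_flags length must match proportion rows")
    n_pos = int(truth_flags.sum())
    if n_pos == 0:
        raise ValueError("no truth positives")
    t = welch_t(props, is_control)
    valid = np.isfinite(t)
    return _envelope_curve(np.abs(t[valid]), truth_flags[valid], n_pos)


def pr_curve(
    scores: np.ndarray,
    truth_flags: np.ndarray,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PRCurve:
    """Threshold sweep over [0, 1] for a probability-valued statistic.

    At threshold ``t`` an item is called positive when its score is >= ``t``;
    precision is undefined (and omitted) where nothing is called.
    """
    scores = np.asarray(scores, dtype=float)
    truth_flags = np.asarray(truth_flags, dtype=bool)
    if scores.shape != truth_flags.shape:
        raise ValueError("scores and truth_flags must align")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    n_pos = int(truth_flags.sum())
    if n_pos == 0:
        raise ValueError("no truth positives")
    grid = np.linspace(0.0, 1.0, int(round(1.0 / grid_step)) + 1)
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = truth_flags[order]
    # cum_pos[k] = number of positives among the k smallest scores
    cum_pos = np.concatenate([[0], np.cumsum(pos_sorted)])
    first_ge = np.searchsorted(s_sorted, grid, side="left")
    n_called = scores.size - first_ge
    tp = n_pos - cum_pos[first_ge]
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(n_called > 0, tp / np.maximum(n_called, 1), np.nan)
    recall = tp / n_pos
    return PRCurve(recall=recall, precision=precision,
                   auprc=_auprc(recall, precision), thresholds=grid)


def _carry_lower(recall_pts: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Value at each grid recall: the value at the nearest lower (or equal)
    observed recall; the smallest observed recall backfills below it."""
    order = np.argsort(recall_pts, kind="stable")
    r = recall_pts[order]
    v = values[order]
    idx = np.searchsorted(r, grid, side="right") - 1
    idx = np.clip(idx, 0, r.size - 1)
    return v[idx]


def mean_pr_curve(curves: list, grid_points: int = 101, span: float = 0.3) -> PRCurve:
    """Pointwise mean of LOWESS-smoothed curves on a common recall grid.

    Each curve's precision is smoothed over recall with LOWESS; missing
    precision at a grid recall is imputed by carrying the value at the
    nearest lower recall.  The mean over curves is returned.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    grid = np.linspace(0.0, 1.0, grid_points)
    stack = []
    for c in curves:
        ok = np.isfinite(c.precision)
        r, p = c.recall[ok], c.precision[ok]
        if np.unique(r).size >= 5:
            sm = lowess(p, r, frac=span, it=0, return_sorted=True)
            r, p = sm[:, 0], sm[:, 1]
        stack.append(_carry_lower(r, np.clip(p, 0.0, 1.0), grid))
    mean_p = np.mean(stack, axis=0)
    return PRCurve(recall=grid, precision=mean_p, auprc=_auprc(grid, mean_p))


def t_test_de_scores(cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Welch t-test on gene-level log2-cpm: ``1 - p`` as a score.

    Returns ``(gene_ids, scores)`` with scores in [0, 1]; degenerate genes
    (zero variance in both groups) score 0.
    """
    gene_cm = gene_level_sum(cm)
    logv = cpm_log_transform(gene_cm).values
    t = welch_t(logv, gene_cm.is_control)
    a = logv[:, gene_cm.is_control]
    b = logv[:, ~gene_cm.is_control]
    # Welch-Satterthwaite degrees of freedom per gene
    vx = a.var(axis=1, ddof=1) / a.shape[1]
    vy = b.var(axis=1, ddof=1) / b.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        dof = (vx + vy) ** 2 / (vx**2 / (a.shape[1] - 1) + vy**2 / (b.shape[1] - 1))
    pvals = 2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(dof), dof, 1.0))
    scores = np.where(np.isfinite(t), 1.0 - pvals, 0.0)
    return gene_cm.gene_ids, scores
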