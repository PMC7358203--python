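"""Posterior summaries: DE/DS probabilities, fold changes, categories.

A gene is called differentially expressed when the bulk of the marginal
posterior of the expression shift ``beta`` lies on one side of zero: the
reported probability is the fraction of draws sharing the sign of the
posterior mean.  Differential splicing is read off the perturbation vector
``alpha``: under no splicing change ``alpha`` is uniform, so the probability
for isoform ``i`` is the larger of the fractions of ``alpha_i`` draws above
and below ``1/T`` (gene-level mode) or above and below the draw-wise dot
product ``alpha . p`` (isoform-level mode); the gene-level call reports the
maximum over isoforms.

Fold changes are posterior means: ``beta`` for expression (log2 units), and
for splicing the ratio of the perturbed mean control fractions to the mean
control fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import aitchison_perturb, as_simplex
from .inference import GeneDraws, PosteriorDraws

__all__ = [
    "GeneCall",
    "CohortSummary",
    "prob_de",
    "prob_ds_gene",
    "prob_ds_isoform",
    "fold_changes",
    "classify_comparison",
    "summarize_gene",
    "summarize_all",
    "results_table",
    "aggregate_cohorts",
]

CATEGORIES = ("DGE", "DAST", "DAST/DGE", "static")

DEFAULT_PROB_DE = 0.99
DEFAULT_PROB_DS = 0.99
DEFAULT_PROB_DS_ISOFORM = 0.999


@dataclass
class GeneCall:
    """Posterior call for one gene in one two-condition comparison."""

    gene_id: str
    isoform_ids: list
    T: int
    prob_de: float
    prob_ds_gene: float                 # NaN for single-isoform genes
    prob_ds_isoforms: np.ndarray | None
    expr_log2fc: float
    splicing_fc: np.ndarray | None
    category: str = ""


def prob_de(beta_draws) -> float:
    """Fraction of draws with the same sign as the posterior mean of beta.

    Draws exactly at zero count to neither side; a posterior mean of exactly
    zero returns 0.5 by convention.
    """
    b = np.asarray(beta_draws, dtype=float)
    if b.size == 0:
        raise ValueError("empty draws")
    m = b.mean()
    if m == 0.0:
        return 0.5
    same = (b > 0.0) if m > 0.0 else (b < 0.0)
    return float(same.sum() / b.size)


def _two_sided_bulk(draws: np.ndarray, center, eps: float = 1e-12) -> np.ndarray:
    """Per column: max of the fractions strictly above / below ``center``.

    ``center`` may be a scalar or per-draw vector broadcast over columns.
    Draws within ``eps`` of the reference count to neither side (the exact
    null point, up to floating-point rounding).
    """
    center = np.asarray(center, dtype=float)
    if center.ndim == 1:
        center = center[:, None]
    diff = draws - center
    above = (diff > eps).mean(axis=0)
    below = (diff < -eps).mean(axis=0)
    return np.maximum(above, below)


def prob_ds_gene(alpha_draws) -> tuple[float, np.ndarray]:
    """Gene-level splicing probability and per-isoform probabilities.

    For each isoform the probability is the larger of the fractions of its
    ``alpha`` draws above and below the no-splicing value ``1/T``; the gene
    probability is the maximum over isoforms.
    """
    a = np.asarray(alpha_draws, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("alpha_draws must be (draws, T) with T >= 2")
    per_iso = _two_sided_bulk(a, 1.0 / a.shape[1])
    return float(per_iso.max()), per_iso


def prob_ds_isoform(alpha_draws, p_draws) -> np.ndarray:
    """Isoform-level splicing probabilities against the draw-wise null.

    The no-splicing reference for each draw is the dot product
    ``c = alpha . p`` (equal to ``1/T`` exactly when ``alpha`` is uniform);
    the probability for isoform ``i`` is the larger of the fractions of draws
    with ``alpha_i`` above and below ``c``.
    """
    a = np.asarray(alpha_draws, dtype=float)
    p = np.asarray(p_draws, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"draw shape mismatch: alpha {a.shape} vs p {p.shape}")
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("draws must be (draws, T) with T >= 2")
    c = (a * p).sum(axis=1)
    return _two_sided_bulk(a, c)


def fold_changes(gd: GeneDraws) -> tuple[float, np.ndarray | None]:
    """Posterior-mean fold changes.

    Expression: mean of the ``beta`` draws (log2 scale).  Splicing, per
    isoform: ``perturb(mean p, mean alpha)_i / (mean p)_i``, with both mean
    vectors renormalized onto the simplex first.
    """
    expr = float(gd.beta.mean())
    if gd.T == 1:
        return expr, None
    mean_p = as_simplex(gd.p.mean(axis=0))
    mean_a = as_simplex(gd.alpha.mean(axis=0))
    fc = aitchison_perturb(mean_p, mean_a) / mean_p
    return expr, fc


def classify_comparison(
    p_de: float,
    p_ds: float,
    thresh_de: float = DEFAULT_PROB_DE,
    thresh_ds: float = DEFAULT_PROB_DS,
) -> str:
    """Four-way category from the two posterior probabilities.

    DGE if only the expression probability clears its threshold, DAST if only
    the splicing one does, DAST/DGE if both, static otherwise.  A NaN
    splicing probability (single-isoform gene) never clears the threshold.
    """
    de = p_de >= thresh_de
    ds = (not np.isnan(p_ds)) and p_ds >= thresh_ds
    if de and ds:
        return "DAST/DGE"
    if de:
        return "DGE"
    if ds:
        return "DAST"
    return "static"


def summarize_gene(
    gd: GeneDraws,
    thresh_de: float = DEFAULT_PROB_DE,
    thresh_ds: float = DEFAULT_PROB_DS,
    isoform_level: bool = False,
) -> GeneCall:
    """All posterior summaries for one gene.

    ``isoform_level=True`` switches the per-isoform probabilities to the
    draw-wise ``alpha . p`` reference (the gene-level call still uses the
    ``1/T`` reference with the max-over-isoforms rule).
    """
    p_de = prob_de(gd.beta)
    if gd.T == 1:
        pg, per_iso = float("nan"), None
    else:
        pg, per_iso = prob_ds_gene(gd.alpha)
        if isoform_level:
            per_iso = prob_ds_isoform(gd.alpha, gd.p)
    expr, fc = fold_changes(gd)
    call = GeneCall(
        gene_id=gd.gene_id,
        isoform_ids=gd.isoform_ids,
        T=gd.T,
        prob_de=p_de,
        prob_ds_gene=pg,
        prob_ds_isoforms=per_iso,
        expr_log2fc=expr,
        splicing_fc=fc,
    )
    call.category = classify_comparison(p_de, pg, thresh_de, thresh_ds)
    return call


def summarize_all(
    draws: PosteriorDraws,
    thresh_de: float = DEFAULT_PROB_DE,
    thresh_ds: float = DEFAULT_PROB_DS,
    isoform_level: bool = False,
) -> list:
    return [
        summarize_gene(gd, thresh_de=thresh_de, thresh_ds=thresh_ds,
                       isoform_level=isoform_level)
        for gd in draws
    ]


def results_table(calls: list) -> pd.DataFrame:
    """Long-format results: one gene-level row per gene (Isoform column holds
    the literal token ``Expression``) plus one row per isoform of
    multi-isoform genes."""
    rows = []
    for call in calls:
        rows.append(
            (call.gene_id, "Expression", call.expr_log2fc, call.prob_de, call.category)
        )
        if call.T >= 2:
            for i, iso in enumerate(call.isoform_ids):
                rows.append(
                    (
                        call.gene_id,
                        iso,
                        float(call.splicing_fc[i]),
                        float(call.prob_ds_isoforms[i]),
                        call.category,
                    )
                )
    return pd.DataFrame(
        rows, columns=["Gene", "Isoform", "log2FC_or_FC", "PosteriorProb", "Category"]
    )


@dataclass
class CohortSummary:
    """Across-comparison dominance summary for one gene."""

    gene_id: str
    n_de: int
    n_ds: int
    group: str


def aggregate_cohorts(
    categories: dict,
    min_cohorts: int = 3,
) -> list:
    """Assign each gene to a final group from many sub-cohort categories.

    ``categories`` maps gene id -> list of per-(comparison, sub-cohort)
    category lists; a gene counts as DE (resp. DS) in a comparison when
    called so in at least ``min_cohorts`` of its sub-cohorts.  With ``d``
    DE comparisons and ``s`` DS comparisons, the group is DAST when
    ``s >= 2 d`` (and ``s > 0``), DGE when ``d >= 2 s`` (and ``d > 0``),
    DAST/DGE when both counts are positive without either dominance, and
    static when both are zero.  Ties at exactly twice the other count take
    the dominant label ("at least twice").
    """
    out = []
    for gene_id, comparisons in categories.items():
        d = s = 0
        for subcohort_cats in comparisons:
            n_de = sum(c in ("DGE", "DAST/DGE") for c in subcohort_cats)
            n_ds = sum(c in ("DAST", "DAST/DGE") for c in subcohort_cats)
            d += n_de >= min_cohorts
            s += n_ds >= min_cohorts
        if s >= 2 * d and s > 0:
            group = "DAST"
        elif d >= 2 * s and d > 0:
            group = "DGE"
        elif d > 0 and s > 0:
            group = "DAST/DGE"
        else:
            group = "static"
        out.append(CohortSummary(gene_id=gene_id, n_de=d, n_ds=s, group=group))
    return out
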