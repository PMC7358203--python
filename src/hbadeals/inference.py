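"""Hierarchical Bayesian model of gene expression and isoform usage, with MCMC.

Model, per gene with ``T`` isoforms observed in two conditions on the log2-cpm
scale (all variances come from the fitted mean-variance trends):

* ``beta0 ~ Normal(mu1, 5)`` — control mean log2-cpm of the gene, where
  ``mu1`` is the observed control mean (weakly informative, variance 5);
* ``beta ~ Normal(0, 5)`` — case-minus-control expression shift in log2 units;
* gene-level observations: ``y ~ Normal(beta0, var)`` in controls and
  ``Normal(beta0 + beta, var)`` in cases, with the gene-trend variances;
* ``p ~ Dirichlet(1, ..., 1)`` — control isoform fractions;
* ``alpha ~ Dirichlet(1, ..., 1)`` — multiplicative splicing perturbation;
  case fractions are the Aitchison perturbation ``p' = perturb(p, alpha)``;
* isoform observations: ``Normal(beta0 + log2 p_i, var)`` in controls and
  ``Normal(beta0 + beta + log2 p'_i, var)`` in cases, with the isoform-trend
  variances.  (The gene mean is thereby the log2 of the summed mean isoform
  levels: ``sum_i p_i 2**beta0 = 2**beta0``.)

Single-isoform genes carry the expression block only; ``p`` and ``alpha`` are
undefined for them.

Genes are conditionally independent given the two variance trends, so the
joint model over all genes factorizes and is sampled gene-wise.  The sampler
alternates an exact Gibbs draw of ``(beta0, beta)`` — whose full conditional
is bivariate normal — with adaptive random-walk Metropolis updates of ``p``
and ``alpha`` in additive-log-ratio (ALR) coordinates, vectorized across all
genes sharing the same isoform count.  Proposal scales adapt toward a target
acceptance rate during warmup only, so retained draws come from a fixed
kernel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_normalize import CountMatrix, cpm_log_transform, gene_level_sum
from .variance_trend import fit_trend, observation_variances

__all__ = [
    "GeneModel",
    "ModelInputs",
    "GeneDraws",
    "PosteriorDraws",
    "build_model_inputs",
    "gene_log_posterior",
    "initialize_chain",
    "run_mcmc",
    "geweke_diagnostic",
]

PRIOR_VARIANCE = 5.0  # shared by the beta and beta0 priors (log2-cpm scale)
_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# model inputs
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Per-gene data entering the hierarchical model."""

    gene_id: str
    isoform_ids: list
    T: int
    mu1: float                 # observed control mean of the gene log2-cpm
    y_gene: np.ndarray         # (S,) gene-level log2-cpm
    var_gene: np.ndarray       # (S,) gene-trend variances
    y_iso: np.ndarray | None   # (T, S) isoform log2-cpm (None when T == 1)
    var_iso: np.ndarray | None  # (T, S) isoform-trend variances
    is_control: np.ndarray     # (S,) bool


@dataclass
class ModelInputs:
    """All per-gene models plus the sample-condition layout."""

    genes: list  # of GeneModel
    is_control: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("no genes to model")
        if not self.is_control.any() or self.is_control.all():
            raise ValueError("both conditions must be present")

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for gm in self.genes:
            if gm.gene_id == gene_id:
                return gm
        raise KeyError(gene_id)


def build_model_inputs(
    cm: CountMatrix,
    span: float = 0.5,
    iterations: int = 3,
) -> ModelInputs:
    """Assemble per-gene model inputs from a filtered count matrix.

    Computes gene-level sums, log2-cpm transforms of both matrices, fits the
    gene and isoform mean-variance trends, and reads back per-observation
    variances.  Isoform log2-cpm uses the library sizes of the full isoform
    matrix (the gene matrix has identical column sums, so the scales agree).
    """
    gene_cm = gene_level_sum(cm)
    iso_log = cpm_log_transform(cm)
    gene_log = cpm_log_transform(gene_cm)
    gene_trend = fit_trend(gene_log, span=span, iterations=iterations)
    iso_trend = fit_trend(iso_log, span=span, iterations=iterations)
    gene_var = observation_variances(gene_trend, gene_log)
    iso_var = observation_variances(iso_trend, iso_log)

    is_control = cm.is_control
    gene_index = {g: k for k, g in enumerate(gene_cm.gene_ids)}
    rows_of: dict = {}
    for row, g in enumerate(cm.gene_ids):
        rows_of.setdefault(g, []).append(row)

    genes = []
    for g, rows in rows_of.items():
        gi = gene_index[g]
        y_gene = gene_log.values[gi]
        mu1 = float(y_gene[is_control].mean())
        T = len(rows)
        if T == 1:
            y_iso = var_iso = None
        else:
            y_iso = iso_log.values[rows]
            var_iso = iso_var[rows]
        genes.append(
            GeneModel(
                gene_id=g,
                isoform_ids=[cm.isoform_ids[r] for r in rows],
                T=T,
                mu1=mu1,
                y_gene=y_gene,
                var_gene=gene_var[gi],
                y_iso=y_iso,
                var_iso=var_iso,
                is_control=is_control,
            )
        )
    return ModelInputs(genes=genes, is_control=is_control, sample_ids=cm.sample_ids)


# ---------------------------------------------------------------------------
# log posterior (reference form, used by tests and as the model specification)
# ---------------------------------------------------------------------------

def gene_log_posterior(gm: GeneModel, beta0, beta, p=None, alpha=None) -> float:
    """Unnormalized log posterior density of one gene's parameters.

    This scalar form is the executable model specification; the vectorized
    sampler targets the same density (up to constants).  ``p`` and ``alpha``
    must be given for multi-isoform genes and omitted for ``T == 1``.
    """
    c = gm.is_control
    lp = -0.5 * (beta - 0.0) ** 2 / PRIOR_VARIANCE
    lp += -0.5 * (beta0 - gm.mu1) ** 2 / PRIOR_VARIANCE
    lp += float(np.sum(-0.5 * (gm.y_gene[c] - beta0) ** 2 / gm.var_gene[c]))
    lp += float(np.sum(-0.5 * (gm.y_gene[~c] - beta0 - beta) ** 2 / gm.var_gene[~c]))
    if gm.T == 1:
        if p is not None or alpha is not None:
            raise ValueError("p/alpha are undefined for a single-isoform gene")
        return lp
    p = np.asarray(p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if p.size != gm.T or alpha.size != gm.T:
        raise ValueError("p and alpha must have length T")
    if np.any(p <= 0) or np.any(alpha <= 0):
        return -np.inf
    p = p / p.sum()
    alpha = alpha / alpha.sum()
    pprime = p * alpha / np.sum(p * alpha)
    mu_c = beta0 + np.log2(p)[:, None]
    mu_k = beta0 + beta + np.log2(pprime)[:, None]
    lp += float(np.sum(-0.5 * (gm.y_iso[:, c] - mu_c) ** 2 / gm.var_iso[:, c]))
    lp += float(np.sum(-0.5 * (gm.y_iso[:, ~c] - mu_k) ** 2 / gm.var_iso[:, ~c]))
    # Dirichlet(1) priors are flat on the simplex
    return lp


def initialize_chain(gm: GeneModel) -> dict:
    """Initial values: beta = 0, beta0 = observed control mean, p = observed
    control fractions ``2**tr_i / sum_j 2**tr_j``, alpha uniform."""
    init = {"beta0": gm.mu1, "beta": 0.0}
    if gm.T >= 2:
        tr = gm.y_iso[:, gm.is_control].mean(axis=1)
        w = np.exp2(tr - tr.max())
        init["p"] = w / w.sum()
        init["alpha"] = np.full(gm.T, 1.0 / gm.T)
    return init


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class GeneDraws:
    """Post-warmup draws for one gene (``p``/``alpha`` are None for T = 1)."""

    gene_id: str
    isoform_ids: list
    T: int
    beta0: np.ndarray          # (D,)
    beta: np.ndarray           # (D,)
    p: np.ndarray | None       # (D, T)
    alpha: np.ndarray | None   # (D, T)
    accept_p: float = float("nan")
    accept_alpha: float = float("nan")


@dataclass
class PosteriorDraws:
    """Draws for every gene plus the sampler settings that produced them."""

    genes: dict  # gene_id -> GeneDraws
    warmup: int
    steps: int
    seed: int
    chains: int = 1

    @property
    def n_draws(self) -> int:
        gd = next(iter(self.genes.values()))
        return int(gd.beta.size)

    def __getitem__(self, gene_id: str) -> GeneDraws:
        return self.genes[gene_id]

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _precompute(group: list, is_control: np.ndarray) -> dict:
    """Sufficient statistics for a group of genes sharing one isoform count.

    All quantities that do not depend on the parameters are reduced over
    samples once, so each MCMC step costs O(G*T).
    """
    c = is_control
    k = ~is_control
    Yg = np.stack([gm.y_gene for gm in group])
    Wg = 1.0 / np.stack([gm.var_gene for gm in group])
    out = {
        "mu1": np.array([gm.mu1 for gm in group]),
        "Wg_all": Wg.sum(axis=1),
        "Wg_case": Wg[:, k].sum(axis=1),
        "WYg_all": (Wg * Yg).sum(axis=1),
        "WYg_case": (Wg * Yg)[:, k].sum(axis=1),
    }
    T = group[0].T
    if T >= 2:
        Yi = np.stack([gm.y_iso for gm in group])        # (G, T, S)
        Wi = 1.0 / np.stack([gm.var_iso for gm in group])
        for name, m in (("c", c), ("k", k)):
            out[f"Wi_{name}"] = Wi[:, :, m].sum(axis=2)              # (G, T)
            out[f"WYi_{name}"] = (Wi * Yi)[:, :, m].sum(axis=2)
            out[f"QYi_{name}"] = (Wi * Yi * Yi)[:, :, m].sum(axis=2)
    return out


def _log_fracs(z: np.ndarray) -> np.ndarray:
    """ALR coordinates (G, T-1) -> log fractions (G, T), stable."""
    zfull = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    zfull -= zfull.max(axis=1, keepdims=True)
    lse = np.log(np.exp(zfull).sum(axis=1, keepdims=True))
    return zfull - lse


def _quad(W, WY, QY, mu):
    """``sum_i QY_i - 2 mu_i WY_i + mu_i^2 W_i`` over isoforms -> (G,)."""
    return (QY - 2.0 * mu * WY + mu * mu * W).sum(axis=1)


def _gibbs_expression(pc, logp, logpp, rng):
    """Exact bivariate-normal draw of (beta0, beta) given the fractions."""
    tau = 1.0 / PRIOR_VARIANCE
    if logp is None:
        eta1 = pc["WYg_all"] + pc["mu1"] * tau
        eta2 = pc["WYg_case"].copy()
        l11 = pc["Wg_all"] + tau
        l12 = pc["Wg_case"]
    else:
        o_c = logp / _LN2    # log2 p, (G, T)
        o_k = logpp / _LN2
        eta1 = (
            pc["WYg_all"]
            + (pc["WYi_c"] - pc["Wi_c"] * o_c).sum(axis=1)
            + (pc["WYi_k"] - pc["Wi_k"] * o_k).sum(axis=1)
            + pc["mu1"] * tau
        )
        eta2 = pc["WYg_case"] + (pc["WYi_k"] - pc["Wi_k"] * o_k).sum(axis=1)
        l11 = pc["Wg_all"] + pc["Wi_c"].sum(axis=1) + pc["Wi_k"].sum(axis=1) + tau
        l12 = pc["Wg_case"] + pc["Wi_k"].sum(axis=1)
    l22 = l12 + tau
    det = l11 * l22 - l12 * l12
    m1 = (l22 * eta1 - l12 * eta2) / det
    m2 = (l11 * eta2 - l12 * eta1) / det
    s11 = l22 / det
    s12 = -l12 / det
    s22 = l11 / det
    ch11 = np.sqrt(s11)
    ch21 = s12 / ch11
    ch22 = np.sqrt(np.maximum(s22 - ch21 * ch21, 1e-300))
    u = rng.standard_normal((2, m1.size))
    beta0 = m1 + ch11 * u[0]
    beta = m2 + ch21 * u[0] + ch22 * u[1]
    return beta0, beta


def _splice_loglik(pc, beta0, beta, logp, logalpha):
    """Isoform-block log likelihood pieces given expression parameters.

    Returns (control part + case part, case part) so the alpha update can
    reuse the case-only term.
    """
    logpp = logp + logalpha
    logpp = logpp - _logsumexp_rows(logpp)
    mu_c = beta0[:, None] + logp / _LN2
    mu_k = (beta0 + beta)[:, None] + logpp / _LN2
    ll_c = -0.5 * _quad(pc["Wi_c"], pc["WYi_c"], pc["QYi_c"], mu_c)
    ll_k = -0.5 * _quad(pc["Wi_k"], pc["WYi_k"], pc["QYi_k"], mu_k)
    return ll_c + ll_k, ll_k, logpp


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return m + np.log(np.exp(a - m).sum(axis=1, keepdims=True))


def _run_group(group, pc, warmup, steps, thin, rng, target_accept=0.28,
               mh_substeps=3):
    """Run the Gibbs/Metropolis chain for one isoform-count group.

    Returns dict of stacked draw arrays plus acceptance rates.
    """
    G = len(group)
    T = group[0].T
    n_keep = (steps - warmup) // thin
    beta0_d = np.empty((G, n_keep))
    beta_d = np.empty((G, n_keep))
    multi = T >= 2

    if multi:
        # ALR coordinates of the initial values
        zp = np.empty((G, T - 1))
        for g, gm in enumerate(group):
            p0 = initialize_chain(gm)["p"]
            zp[g] = np.log(np.maximum(p0[:-1], 1e-300)) - math.log(max(p0[-1], 1e-300))
        za = np.zeros((G, T - 1))
        logp = _log_fracs(zp)
        logalpha = _log_fracs(za)
        step_p = np.full(G, 0.5)
        step_a = np.full(G, 0.5)
        acc_p = np.zeros(G)
        acc_a = np.zeros(G)
        p_d = np.empty((G, n_keep, T))
        a_d = np.empty((G, n_keep, T))
        jac_p = logp.sum(axis=1)       # ALR Jacobian = sum of log fractions
        jac_a = logalpha.sum(axis=1)
        _, _, logpp = _splice_loglik(
            pc, np.zeros(G), np.zeros(G), logp, logalpha
        )
    else:
        logp = logpp = None
    beta0 = np.array([gm.mu1 for gm in group])
    beta = np.zeros(G)

    kept = 0
    adapt_batch = 25
    # random-walk mixing degrades with block dimension; add sub-steps with T
    n_sub = mh_substeps + max(T - 2, 0)
    for it in range(steps):
        beta0, beta = _gibbs_expression(pc, logp, logpp, rng)
        if multi:
            for _ in range(n_sub):
                # p block: control and case likelihoods both depend on p
                ll_both, _, logpp = _splice_loglik(pc, beta0, beta, logp, logalpha)
                prop = zp + step_p[:, None] * rng.standard_normal((G, T - 1))
                logp_prop = _log_fracs(prop)
                ll_both_p, _, logpp_p = _splice_loglik(pc, beta0, beta, logp_prop, logalpha)
                jac_prop = logp_prop.sum(axis=1)
                logr = (ll_both_p + jac_prop) - (ll_both + jac_p)
                acc = np.log(rng.random(G)) < logr
                zp[acc] = prop[acc]
                logp[acc] = logp_prop[acc]
                logpp[acc] = logpp_p[acc]
                jac_p[acc] = jac_prop[acc]
                acc_p += acc

                # alpha block: only the case likelihood depends on alpha
                _, ll_case, logpp = _splice_loglik(pc, beta0, beta, logp, logalpha)
                prop = za + step_a[:, None] * rng.standard_normal((G, T - 1))
                logalpha_prop = _log_fracs(prop)
                _, ll_case_a, logpp_a = _splice_loglik(pc, beta0, beta, logp, logalpha_prop)
                jac_prop = logalpha_prop.sum(axis=1)
                logr = (ll_case_a + jac_prop) - (ll_case + jac_a)
                acc = np.log(rng.random(G)) < logr
                za[acc] = prop[acc]
                logalpha[acc] = logalpha_prop[acc]
                logpp[acc] = logpp_a[acc]
                jac_a[acc] = jac_prop[acc]
                acc_a += acc

            if it < warmup and (it + 1) % adapt_batch == 0:
                denom = adapt_batch * n_sub
                step_p *= np.exp(0.6 * (acc_p / denom - target_accept))
                step_a *= np.exp(0.6 * (acc_a / denom - target_accept))
                acc_p[:] = 0.0
                acc_a[:] = 0.0

        if it >= warmup and (it - warmup) % thin == 0 and kept < n_keep:
            beta0_d[:, kept] = beta0
            beta_d[:, kept] = beta
            if multi:
                p_d[:, kept, :] = np.exp(logp)
                a_d[:, kept, :] = np.exp(logalpha)
            kept += 1
        if multi and it == warmup:
            acc_p[:] = 0.0
            acc_a[:] = 0.0

    out = {"beta0": beta0_d, "beta": beta_d}
    if multi:
        post = max(steps - warmup, 1) * n_sub
        out["p"] = p_d
        out["alpha"] = a_d
        out["accept_p"] = acc_p / post
        out["accept_alpha"] = acc_a / post
    return out


def run_mcmc(
    mi: ModelInputs,
    warmup: int = 2000,
    steps: int = 10000,
    seed: int = 1,
    chains: int = 1,
    thin: int = 1,
    mh_substeps: int = 3,
) -> PosteriorDraws:
    """Sample the posterior of every gene's parameters.

    Parameters
    ----------
    mi
        Model inputs from :func:`build_model_inputs`.
    warmup, steps
        Warmup iterations (discarded, with proposal adaptation) and total
        iterations per chain; post-warmup draws number ``steps - warmup``.
    seed
        Seeds all randomness; identical seeds give identical draws.
    chains
        Independent chains; their post-warmup draws are concatenated.
    thin
        Keep every ``thin``-th post-warmup draw.
    """
    if warmup < 1 or steps <= warmup:
        raise ValueError("need steps > warmup >= 1")
    groups: dict = {}
    for gm in mi.genes:
        groups.setdefault(gm.T, []).append(gm)

    seedseq = np.random.SeedSequence(seed)
    chain_seeds = seedseq.spawn(chains)
    per_chain: list = []
    for ch in range(chains):
        rng = np.random.default_rng(chain_seeds[ch])
        chain_out = {}
        for T in sorted(groups):
            group = groups[T]
            pc = _precompute(group, mi.is_control)
            res = _run_group(group, pc, warmup, steps, thin, rng,
                             mh_substeps=mh_substeps)
            for g, gm in enumerate(group):
                rec = {
                    "beta0": res["beta0"][g],
                    "beta": res["beta"][g],
                    "p": res["p"][g] if T >= 2 else None,
                    "alpha": res["alpha"][g] if T >= 2 else None,
                    "accept_p": float(res["accept_p"][g]) if T >= 2 else float("nan"),
                    "accept_alpha": float(res["accept_alpha"][g]) if T >= 2 else float("nan"),
                }
                chain_out[gm.gene_id] = rec
        per_chain.append(chain_out)

    genes: dict = {}
    for gm in mi.genes:
        recs = [pc_out[gm.gene_id] for pc_out in per_chain]
        genes[gm.gene_id] = GeneDraws(
            gene_id=gm.gene_id,
            isoform_ids=gm.isoform_ids,
            T=gm.T,
            beta0=np.concatenate([r["beta0"] for r in recs]),
            beta=np.concatenate([r["beta"] for r in recs]),
            p=None if gm.T == 1 else np.concatenate([r["p"] for r in recs]),
            alpha=None if gm.T == 1 else np.concatenate([r["alpha"] for r in recs]),
            accept_p=float(np.mean([r["accept_p"] for r in recs])),
            accept_alpha=float(np.mean([r["accept_alpha"] for r in recs])),
        )
    return PosteriorDraws(genes=genes, warmup=warmup, steps=steps, seed=seed, chains=chains)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of ``x`` at frequency zero via a Yule-Walker AR fit.

    The AR order is chosen by AIC up to ``max_order`` (default
    ``min(20, n // 10)``); order 0 reduces to the sample variance.  The
    Yule-Walker equations are solved for all orders at once with the
    Levinson-Durbin recursion on the biased autocovariances.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(x.var())
    if var == 0.0 or n < 10:
        return var
    if max_order is None:
        max_order = min(50, n // 10)
    acov = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(max_order + 1)])
    best_aic = n * math.log(var)
    best_s2, best_phi_sum = var, 0.0
    phi = np.zeros(max_order + 1)
    sigma2 = acov[0]
    for order in range(1, max_order + 1):
        k = acov[order] - np.dot(phi[1:order], acov[order - 1:0:-1])
        k /= sigma2
        if not np.isfinite(k) or abs(k) >= 1.0:
            break
        prev = phi[1:order].copy()
        phi[order] = k
        phi[1:order] = prev - k * prev[::-1]
        sigma2 *= 1.0 - k * k
        if sigma2 <= 0:
            break
        aic = n * math.log(sigma2) + 2.0 * order
        if aic < best_aic:
            best_aic = aic
            best_s2 = float(sigma2)
            best_phi_sum = float(phi[1: order + 1].sum())
    denom = max((1.0 - best_phi_sum) ** 2, 1e-12)
    return best_s2 / denom


def geweke_diagnostic(
    draws: PosteriorDraws,
    first_frac: float = 0.1,
    last_frac: float = 0.5,
    alpha_level: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Geweke convergence z-scores for every parameter of every gene.

    Compares the mean of the first ``first_frac`` of each (single-chain)
    series with the mean of the last ``last_frac``, standardized by
    spectral-density standard errors:
    ``z = (m_first - m_last) / sqrt(s0_first/n_first + s0_last/n_last)``.

    Returns the per-parameter table (gene, parameter, z, p) and the fraction
    of parameters significant after Benjamini-Hochberg correction at
    ``alpha_level``.  Constant chain segments yield NaN with a warning.
    """
    if draws.chains != 1:
        raise ValueError("Geweke's diagnostic applies to a single chain")
    if not (0.0 < first_frac and 0.0 < last_frac and first_frac + last_frac < 1.0):
        raise ValueError("need 0 < first_frac + last_frac < 1")
    rows = []
    n_constant = 0
    for gd in draws:
        series = [("beta0", gd.beta0), ("beta", gd.beta)]
        if gd.T >= 2:
            for i in range(gd.T):
                series.append((f"p[{gd.isoform_ids[i]}]", gd.p[:, i]))
                series.append((f"alpha[{gd.isoform_ids[i]}]", gd.alpha[:, i]))
        for name, x in series:
            n = x.size
            n1 = max(int(first_frac * n), 2)
            n2 = max(int(last_frac * n), 2)
            a, b = x[:n1], x[n - n2:]
            if a.var() == 0.0 or b.var() == 0.0:
                n_constant += 1
                rows.append((gd.gene_id, name, np.nan, np.nan))
                continue
            se2 = _spectrum0_ar(a) / n1 + _spectrum0_ar(b) / n2
            z = (a.mean() - b.mean()) / math.sqrt(se2)
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((gd.gene_id, name, z, p))
    if n_constant:
        warnings.warn(
            f"{n_constant} constant chain segments: Geweke p undefined there",
            UserWarning,
            stacklevel=2,
        )
    table = pd.DataFrame(rows, columns=["gene", "parameter", "z", "p"])
    valid = table["p"].dropna()
    if len(valid):
        rej = multipletests(valid.to_numpy(), alpha=alpha_level, method="fdr_bh")[0]
        frac = float(rej.mean())
    else:
        frac = float("nan")
    return table, frac
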