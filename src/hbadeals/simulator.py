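"""Isoform-level RNA-seq count simulation with DE/DS ground truth.

The generator extends a voom-style expression simulation down to isoforms.
Each gene receives a random number of isoforms ``T`` between 2 and 10 with
probabilities (0.4, 0.2, 0.1, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05); the
gene's expected library proportion is split evenly across its isoforms.
Differential expression doubles the whole gene's proportion in one randomly
chosen condition.  Differential splicing doubles the proportion of one
random isoform in cases and of a different isoform in controls, which leaves
the gene's expected total unchanged.  Counts are then drawn negative
binomially with per-sample means ``library_size * proportion`` and a
genewise dispersion.

Baseline abundances and dispersions are not pinned down by the scheme being
extended, so this module supplies self-contained choices: gene proportions
are normalized draws from a log-normal(0, 1.5), and the genewise dispersion
is ``0.1 + 1/Gamma(shape=10, scale=25)`` (typical value ~0.104, i.e. a
biological coefficient of variation near 0.32, in line with bulk RNA-seq).
Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_normalize import CASE, CONTROL, CountMatrix

__all__ = [
    "ISOFORM_COUNT_PROBS",
    "SimulationConfig",
    "TruthTable",
    "draw_isoform_counts",
    "build_true_proportions",
    "sample_counts",
    "simulate_dataset",
    "write_truth",
]

#: P(T = 2), ..., P(T = 10) for the per-gene isoform count.
ISOFORM_COUNT_PROBS = np.array(
    [0.4, 0.2, 0.1, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05]
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n_genes: int = 1000
    n_samples_per_group: int = 5
    library_size_mode: str = "equal"      # "equal" | "unequal"
    base_library_size: float = 2e6
    de_fraction: float = 0.1
    ds_fraction: float = 0.1
    de_log2fc: float = 1.0                # whole-gene doubling
    lognormal_sigma: float = 1.5          # spread of gene abundances
    dispersion_offset: float = 0.1        # phi = offset + 1/Gamma(shape, scale)
    dispersion_shape: float = 10.0
    dispersion_scale: float = 25.0
    allow_overlap: bool = False           # DE and DS gene sets disjoint by default
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.de_fraction <= 1.0 and 0.0 <= self.ds_fraction <= 1.0):
            raise ValueError("de_fraction and ds_fraction must lie in [0, 1]")
        if not self.allow_overlap and self.de_fraction + self.ds_fraction > 1.0:
            raise ValueError("disjoint DE and DS sets need de_fraction + ds_fraction <= 1")
        if self.library_size_mode not in ("equal", "unequal"):
            raise ValueError("library_size_mode must be 'equal' or 'unequal'")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset.

    ``genes`` has one row per gene: T, is_de, de_direction (+1 case-up, -1
    control-up, 0), is_ds, iso_up_case / iso_up_control (within-gene isoform
    indices of the doubled isoforms, -1 if none).  ``isoforms`` has one row
    per isoform: expected library proportions per condition, the within-gene
    fractions per condition, and the true splicing fold change
    (case fraction / control fraction).
    """

    genes: pd.DataFrame
    isoforms: pd.DataFrame

    def ds_isoform_flags(self, min_fc: float = 2.0) -> np.ndarray:
        """Truth positives for splicing evaluation: isoforms of DS genes whose
        within-gene fraction changes by ``min_fc``-fold or more in either
        direction."""
        fc = self.isoforms["true_splicing_fc"].to_numpy()
        is_ds = self.isoforms["is_ds"].to_numpy()
        big = np.maximum(fc, 1.0 / fc) >= min_fc
        return is_ds & big


def draw_isoform_counts(n_genes: int, seed: int) -> np.ndarray:
    """Isoforms per gene: T in {2..10} with the configured probabilities."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(np.arange(2, 11), size=n_genes, p=ISOFORM_COUNT_PROBS)


def build_true_proportions(
    gene_props: np.ndarray,
    T_vec: np.ndarray,
    de_genes: np.ndarray,
    ds_genes: np.ndarray,
    seed: int,
    de_directions: np.ndarray | None = None,
) -> TruthTable:
    """Expected isoform proportions per condition with DE/DS modifications.

    Each gene's proportion is split evenly over its ``T`` isoforms.  DE genes
    have every isoform doubled in one random condition; DS genes have one
    random isoform doubled in cases and a different one doubled in controls.
    Condition-wise proportions are renormalized over all isoforms at the end.
    """
    gene_props = np.asarray(gene_props, dtype=float)
    if np.any(gene_props <= 0):
        raise ValueError("gene proportions must be positive")
    gene_props = gene_props / gene_props.sum()
    n_genes = gene_props.size
    rng = np.random.default_rng(seed)

    is_de = np.zeros(n_genes, dtype=bool)
    is_de[np.asarray(de_genes, dtype=int)] = True
    is_ds = np.zeros(n_genes, dtype=bool)
    is_ds[np.asarray(ds_genes, dtype=int)] = True

    if de_directions is None:
        de_directions = np.where(rng.random(n_genes) < 0.5, 1, -1)
    de_directions = np.where(is_de, de_directions, 0)

    gene_rows, iso_rows = [], []
    for g in range(n_genes):
        T = int(T_vec[g])
        base = np.full(T, gene_props[g] / T)
        prop_ctrl = base.copy()
        prop_case = base.copy()
        up_case = up_ctrl = -1
        if is_de[g]:
            if de_directions[g] > 0:
                prop_case *= 2.0
            else:
                prop_ctrl *= 2.0
        if is_ds[g]:
            up_case, up_ctrl = rng.choice(T, size=2, replace=False)
            prop_case[up_case] *= 2.0
            prop_ctrl[up_ctrl] *= 2.0
        gene_rows.append((f"G{g:05d}", T, is_de[g], int(de_directions[g]),
                          is_ds[g], int(up_case), int(up_ctrl)))
        frac_ctrl = prop_ctrl / prop_ctrl.sum()
        frac_case = prop_case / prop_case.sum()
        for i in range(T):
            iso_rows.append(
                (
                    f"G{g:05d}", f"G{g:05d}.I{i + 1}", g, i,
                    prop_ctrl[i], prop_case[i],
                    frac_ctrl[i], frac_case[i],
                    frac_case[i] / frac_ctrl[i],
                    is_ds[g],
                )
            )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene", "T", "is_de", "de_direction", "is_ds",
                 "iso_up_case", "iso_up_control"],
    )
    isoforms = pd.DataFrame(
        iso_rows,
        columns=["gene", "isoform", "gene_index", "iso_index",
                 "prop_control", "prop_case",
                 "frac_control", "frac_case", "true_splicing_fc", "is_ds"],
    )
    # keep the raw (pre-renormalization) proportions: the DS invariant — a
    # gene's expected total is unchanged — holds exactly on the raw scale
    for col in ("prop_control", "prop_case"):
        isoforms[f"{col}_raw"] = isoforms[col]
        isoforms[col] = isoforms[col] / isoforms[col].sum()
    return TruthTable(genes=genes, isoforms=isoforms)


def sample_counts(truth: TruthTable, config: SimulationConfig) -> CountMatrix:
    """Negative-binomial counts with genewise dispersion.

    Mean of isoform ``i`` in sample ``s`` is ``library_size[s] *
    expected_proportion[i, condition(s)]``; the dispersion ``phi`` is drawn
    once per gene and shared by its isoforms.  ``phi -> 0`` recovers Poisson
    sampling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_samples_per_group
    if config.library_size_mode == "equal":
        lib = np.full(2 * n, config.base_library_size)
    else:
        lib = rng.uniform(config.base_library_size / 3.0,
                          config.base_library_size * 3.0, size=2 * n)
    gene_index = truth.isoforms["gene_index"].to_numpy()
    n_genes = len(truth.genes)
    phi_gene = config.dispersion_offset + 1.0 / rng.gamma(
        config.dispersion_shape, config.dispersion_scale, size=n_genes
    )
    phi = phi_gene[gene_index]
    prop = np.column_stack(
        [
            np.repeat(truth.isoforms["prop_control"].to_numpy()[:, None], n, axis=1),
            np.repeat(truth.isoforms["prop_case"].to_numpy()[:, None], n, axis=1),
        ]
    )
    mean = prop * lib[None, :]
    counts = np.empty_like(mean)
    tiny = phi < 1e-8
    if tiny.any():
        counts[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        r = 1.0 / phi[~tiny]
        pnb = r[:, None] / (r[:, None] + mean[~tiny])
        counts[~tiny] = rng.negative_binomial(r[:, None], pnb)
    labels = np.array([CONTROL] * n + [CASE] * n, dtype=object)
    samples = np.array(
        [f"ctrl_{s + 1}" for s in range(n)] + [f"case_{s + 1}" for s in range(n)],
        dtype=object,
    )
    return CountMatrix(
        isoform_ids=truth.isoforms["isoform"].to_numpy(dtype=object),
        gene_ids=truth.isoforms["gene"].to_numpy(dtype=object),
        counts=counts,
        sample_ids=samples,
        condition_labels=labels,
    )


def simulate_dataset(config: SimulationConfig) -> tuple[CountMatrix, TruthTable]:
    """End-to-end simulation: isoform counts, truth table, NB counts.

    Deterministic given ``config.seed``; DE and DS gene sets are disjoint
    unless ``allow_overlap`` is set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    T_vec = draw_isoform_counts(config.n_genes, seed=int(config.seed))
    raw = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=config.n_genes)
    gene_props = raw / raw.sum()
    n_de = int(round(config.de_fraction * config.n_genes))
    n_ds = int(round(config.ds_fraction * config.n_genes))
    if config.allow_overlap:
        de_genes = rng.choice(config.n_genes, size=n_de, replace=False)
        ds_genes = rng.choice(config.n_genes, size=n_ds, replace=False)
    else:
        both = rng.choice(config.n_genes, size=n_de + n_ds, replace=False)
        de_genes, ds_genes = both[:n_de], both[n_de:]
    truth = build_true_proportions(
        gene_props, T_vec, de_genes, ds_genes,
        seed=int(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31)),
    )
    cm = sample_counts(truth, config)
    return cm, truth


def write_truth(truth: TruthTable, prefix: str) -> None:
    """Write ``<prefix>.truth_genes.tsv`` and ``<prefix>.truth_isoforms.tsv``."""
    truth.genes.to_csv(f"{prefix}.truth_genes.tsv", sep="\t", index=False)
    truth.isoforms.to_csv(f"{prefix}.truth_isoforms.tsv", sep="\t", index=False)
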