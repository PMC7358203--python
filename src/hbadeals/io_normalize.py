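"""Isoform count-matrix input, filtering, and log-cpm normalization.

The expected input is the standard assembled quantification matrix: a
tab-delimited file with a header row, a gene-identifier column, an
isoform-identifier column, and one column of (possibly fractional, e.g. RSEM
expected) counts per sample, control samples first.  Counts are normalized to
counts-per-million on raw library sizes and transformed with
``log2(cpm + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "LogCpmMatrix",
    "read_counts",
    "write_counts",
    "filter_low_counts",
    "cpm_log_transform",
    "gene_level_sum",
]

CONTROL = "control"
CASE = "case"


@dataclass
class CountMatrix:
    """Isoform-by-sample count matrix with gene mapping and condition labels.

    Invariants (checked on construction): counts are non-negative and finite,
    isoform identifiers are unique, each condition has at least two samples,
    and the column order of ``counts`` matches ``condition_labels``.
    """

    isoform_ids: np.ndarray
    gene_ids: np.ndarray
    counts: np.ndarray
    sample_ids: np.ndarray
    condition_labels: np.ndarray

    def __post_init__(self) -> None:
        self.isoform_ids = np.asarray(self.isoform_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.condition_labels = np.asarray(self.condition_labels, dtype=object)
        n_iso, n_samp = self.counts.shape
        if self.isoform_ids.size != n_iso or self.gene_ids.size != n_iso:
            raise ValueError("isoform/gene id length does not match count rows")
        if self.sample_ids.size != n_samp or self.condition_labels.size != n_samp:
            raise ValueError("sample id/label length does not match count columns")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            i, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at isoform {self.isoform_ids[i]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if len(set(self.isoform_ids)) != n_iso:
            seen: set = set()
            dup = next(i for i in self.isoform_ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate isoform id {dup!r}")
        labels = set(self.condition_labels)
        if labels != {CONTROL, CASE}:
            raise ValueError(f"condition labels must be {{{CONTROL!r}, {CASE!r}}}, got {labels}")
        for lab in (CONTROL, CASE):
            if int(np.sum(self.condition_labels == lab)) < 2:
                raise ValueError(f"condition {lab!r} has fewer than 2 samples")

    # -- derived views ---------------------------------------------------

    @property
    def n_isoforms(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def is_control(self) -> np.ndarray:
        return self.condition_labels == CONTROL

    @property
    def library_sizes(self) -> np.ndarray:
        """Total counts per sample (column sums)."""
        return self.counts.sum(axis=0)

    def gene_order(self) -> list:
        """Unique gene ids in order of first appearance."""
        return list(pd.unique(self.gene_ids))

    def isoforms_per_gene(self) -> pd.Series:
        """Number of isoforms per gene, indexed by gene id."""
        return pd.Series(1, index=self.gene_ids).groupby(level=0, sort=False).sum()

    def expression_only_genes(self) -> list:
        """Genes with a single isoform: analyzed for expression only."""
        t = self.isoforms_per_gene()
        return list(t.index[t == 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.sample_ids))
        df.insert(0, "Isoform", self.isoform_ids)
        df.insert(0, "Gene", self.gene_ids)
        return df


@dataclass
class LogCpmMatrix:
    """``log2(cpm + 0.5)`` values with the metadata of the source counts."""

    values: np.ndarray
    library_sizes: np.ndarray
    isoform_ids: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    condition_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-cpm values contain non-finite entries")

    @property
    def is_control(self) -> np.ndarray:
        return np.asarray(self.condition_labels) == CONTROL


def read_counts(path, n_control: int) -> CountMatrix:
    """Read an isoform count TSV (Gene, Isoform, then sample columns).

    The first ``n_control`` sample columns are labeled control, the rest case.

    Raises
    ------
    ValueError
        On fewer than 4 sample columns, out-of-range ``n_control``, malformed
        (non-numeric) rows, negative counts, or duplicate isoform ids.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    if df.shape[1] < 6:
        raise ValueError(
            f"{path}: expected Gene, Isoform and >= 4 sample columns, got {df.shape[1]} columns"
        )
    n_samples = df.shape[1] - 2
    n_control = int(n_control)
    if n_control < 2 or n_control > n_samples - 2:
        raise ValueError(
            f"n_control must be in [2, {n_samples - 2}] for {n_samples} samples, got {n_control}"
        )
    sample_cols = df.columns[2:]
    counts = np.empty((df.shape[0], n_samples), dtype=float)
    for j, col in enumerate(sample_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or vals.isna().any():
            row = (bad if len(bad) else vals.index[vals.isna()])[0]
            raise ValueError(
                f"{path}: malformed count in row {row + 2} "
                f"(isoform {df.iloc[row, 1]!r}, sample column {col!r})"
            )
        counts[:, j] = vals.to_numpy()
    labels = np.array([CONTROL] * n_control + [CASE] * (n_samples - n_control), dtype=object)
    return CountMatrix(
        isoform_ids=df.iloc[:, 1].to_numpy(dtype=object),
        gene_ids=df.iloc[:, 0].to_numpy(dtype=object),
        counts=counts,
        sample_ids=sample_cols.to_numpy(dtype=object),
        condition_labels=labels,
    )


def write_counts(cm: CountMatrix, path) -> None:
    """Write a CountMatrix in the TSV layout accepted by :func:`read_counts`."""
    cm.to_frame().to_csv(path, sep="\t", index=False)


def filter_low_counts(cm: CountMatrix, min_count: float = 1.0) -> CountMatrix:
    """Keep isoforms with a count of at least ``min_count`` in every sample.

    Genes whose isoforms are all removed are dropped; genes left with a single
    isoform stay in the matrix (expression-only analysis downstream).
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    keep = np.all(cm.counts >= min_count, axis=1)
    if not keep.any():
        raise ValueError("no isoforms pass filter")
    return CountMatrix(
        isoform_ids=cm.isoform_ids[keep],
        gene_ids=cm.gene_ids[keep],
        counts=cm.counts[keep],
        sample_ids=cm.sample_ids,
        condition_labels=cm.condition_labels,
    )


def cpm_log_transform(cm: CountMatrix) -> LogCpmMatrix:
    """``log2(count / library_size * 1e6 + 0.5)`` per cell.

    Library size is the per-sample total over all isoforms currently in the
    matrix; a zero library size is an error.
    """
    lib = cm.library_sizes
    if np.any(lib <= 0):
        s = int(np.argmax(lib <= 0))
        raise ValueError(f"sample {cm.sample_ids[s]!r} has zero library size")
    cpm = cm.counts / lib[None, :] * 1e6
    return LogCpmMatrix(
        values=np.log2(cpm + 0.5),
        library_sizes=lib,
        isoform_ids=cm.isoform_ids,
        gene_ids=cm.gene_ids,
        sample_ids=cm.sample_ids,
        condition_labels=cm.condition_labels,
    )


def gene_level_sum(cm: CountMatrix) -> CountMatrix:
    """Sum isoform counts within genes: one row per gene, same samples.

    The returned matrix reuses the gene id as its row identifier, so it can be
    fed to the same transforms as the isoform matrix.
    """
    order = cm.gene_order()
    idx = {g: k for k, g in enumerate(order)}
    out = np.zeros((len(order), cm.n_samples))
    for row, g in enumerate(cm.gene_ids):
        out[idx[g]] += cm.counts[row]
    genes = np.asarray(order, dtype=object)
    return CountMatrix(
        isoform_ids=genes.copy(),
        gene_ids=genes,
        counts=out,
        sample_ids=cm.sample_ids,
        condition_labels=cm.condition_labels,
    )
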