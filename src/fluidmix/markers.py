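"""Differential expression between body fluids and signature-matrix assembly.

Marker genes for deconvolution come from all pairwise fluid comparisons: a
negative-binomial Wald test with method-of-moments dispersion produces a
DE table per pair; significant genes (|fold change| >= 2, q < 0.05 by
default) are ranked by decreasing |log2 fold change|, a top fraction kept
per direction, and the union over the ten pairs forms the signature's gene
set.  The signature value for a fluid is the mean (normalized) expression
of its reference replicates on those genes.

A pre-computed DE table (e.g. DESeq2 output with columns gene_id, log2fc,
qvalue) can be injected anywhere a :class:`DETable` is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountsMatrix
from .normalize import apply_normalization, size_factor_norm

LOG2FC_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass
class DETable:
    """Per-gene differential expression results for one ordered fluid pair."""

    comparison: tuple[str, str]  # (A, B); log2fc is A over B
    table: pd.DataFrame  # index gene_id; columns log2fc, pvalue, qvalue

    def __post_init__(self) -> None:
        missing = {"log2fc", "pvalue", "qvalue"} - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {missing}")

    def flipped(self) -> "DETable":
        """The same comparison viewed from the other fluid (sign of log2fc)."""
        t = self.table.copy()
        t["log2fc"] = -t["log2fc"]
        return DETable(comparison=(self.comparison[1], self.comparison[0]), table=t)

    def to_tsv(self, path) -> None:
        t = self.table.copy()
        t["comparison"] = f"{self.comparison[0]}_vs_{self.comparison[1]}"
        t.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, comparison: tuple[str, str] | None = None) -> "DETable":
        t = pd.read_csv(path, sep="\t", index_col=0)
        if comparison is None:
            a, b = str(t["comparison"].iloc[0]).split("_vs_")
            comparison = (a, b)
        return cls(comparison=comparison, table=t.drop(columns=["comparison"], errors="ignore"))


def differential_expression(
    counts: CountsMatrix,
    group_a: str,
    group_b: str,
) -> DETable:
    """Negative-binomial Wald test between two fluids' replicate groups.

    Counts are size-factor normalized across the two groups; per-gene
    log2FC uses a pseudocount of 0.5; the Wald statistic uses NB variance
    mu + alpha mu^2 with a pooled method-of-moments dispersion floored at
    1e-8; q-values are Benjamini-Hochberg.
    """
    samples_a = counts.samples_of(group_a)
    samples_b = counts.samples_of(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    sub = counts.values[samples_a + samples_b]
    normed, _ = size_factor_norm(sub)
    a = normed[samples_a].to_numpy(dtype=float)
    b = normed[samples_b].to_numpy(dtype=float)
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((m_a + LOG2FC_PSEUDOCOUNT) / (m_b + LOG2FC_PSEUDOCOUNT))

    # pooled MoM dispersion: alpha = (var - mu) / mu^2, averaged over groups
    def _disp(x, mu):
        var = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mu) / np.square(mu)
        return np.where(np.isfinite(alpha), alpha, 0.0)

    alpha = np.maximum((_disp(a, m_a) + _disp(b, m_b)) / 2.0, DISPERSION_FLOOR)
    var_a = (m_a + alpha * m_a**2) / a.shape[1]
    var_b = (m_b + alpha * m_b**2) / b.shape[1]
    # delta method on log2 of the (pseudocounted) means
    denom_a = (m_a + LOG2FC_PSEUDOCOUNT) * math.log(2)
    denom_b = (m_b + LOG2FC_PSEUDOCOUNT) * math.log(2)
    se = np.sqrt(var_a / denom_a**2 + var_b / denom_b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.clip(pvalue, 0.0, 1.0)
    qvalue = multipletests(pvalue, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "qvalue": qvalue}, index=counts.genes
    )
    return DETable(comparison=(group_a, group_b), table=table)


def select_pairwise_markers(
    de_table: DETable,
    fold_threshold: float = 2.0,
    q_threshold: float = 0.05,
    top_fraction: float = 0.04,
) -> dict[str, list[str]]:
    """Top marker genes of one pairwise comparison, split by direction.

    Genes passing |FC| >= fold_threshold and q < q_threshold are split by
    the sign of log2FC; each direction is sorted by decreasing |log2FC|
    (ties: smaller q, then gene id) and truncated to
    ceil(top_fraction x list length).  Returns {fluid: ranked gene list}.
    """
    if not 0 < top_fraction <= 0.3:
        raise ValueError("top_fraction must lie in (0, 0.3]")
    t = de_table.table
    if t.empty:
        raise ValueError("empty DE table")
    sig = t[(t["log2fc"].abs() >= math.log2(fold_threshold)) & (t["qvalue"] < q_threshold)]
    out: dict[str, list[str]] = {}
    for fluid, direction in zip(de_table.comparison, (1, -1)):
        side = sig[np.sign(sig["log2fc"]) == direction].copy()
        side["absfc"] = side["log2fc"].abs()
        side = side.sort_values(
            by=["absfc", "qvalue"], ascending=[False, True], kind="mergesort"
        )
        # total tie-break: stable sort above, then gene id within exact ties
        side = side.rename_axis("gene_id").reset_index().sort_values(
            by=["absfc", "qvalue", "gene_id"], ascending=[False, True, True]
        )
        k = math.ceil(top_fraction * len(side))
        out[fluid] = side["gene_id"].head(k).tolist()
    return out


@dataclass
class SignatureMatrix:
    """Marker-gene x fluid mean reference expression (the design matrix)."""

    values: pd.DataFrame  # genes x fluids
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("signature values must be nonnegative")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate marker genes in signature")

    @property
    def marker_genes(self) -> pd.Index:
        return self.values.index

    @property
    def fluids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def pairwise_de_tables(
    counts: CountsMatrix, fluids: Sequence[str]
) -> dict[tuple[str, str], DETable]:
    """All unordered pairwise DE tables among the given fluids."""
    return {
        (a, b): differential_expression(counts, a, b) for a, b in combinations(fluids, 2)
    }


def build_signature(
    reference_counts: CountsMatrix,
    fluids: Sequence[str] | None = None,
    top_fraction: float = 0.04,
    normalization: str = "raw",
    fold_threshold: float = 2.0,
    q_threshold: float = 0.05,
    de_tables: Mapping[tuple[str, str], DETable] | None = None,
) -> SignatureMatrix:
    """Assemble the body-fluid signature matrix.

    Runs every pairwise DE comparison (or uses injected ``de_tables``),
    unions the per-pair top marker lists, and fills the signature with each
    fluid's mean normalized expression over its replicate samples,
    restricted to the union.
    """
    if reference_counts.fluids is None:
        raise ValueError("reference counts need fluid labels")
    if fluids is None:
        fluids = sorted(reference_counts.fluids.unique())
    if de_tables is None:
        de_tables = pairwise_de_tables(reference_counts, fluids)

    marker_union: list[str] = []
    sources: dict[str, list[str]] = {}
    for pair, table in de_tables.items():
        try:
            per_dir = select_pairwise_markers(
                table, fold_threshold, q_threshold, top_fraction
            )
        except ValueError:
            continue
        for fluid, genes in per_dir.items():
            for g in genes:
                if g not in sources:
                    marker_union.append(g)
                    sources[g] = []
                sources[g].append(f"{pair[0]}_vs_{pair[1]}:{fluid}")
    if not marker_union:
        raise ValueError("no marker genes survive the thresholds")

    normed = apply_normalization(reference_counts, normalization)
    cols = {}
    for fluid in fluids:
        samples = reference_counts.samples_of(fluid)
        if len(samples) < 2:
            raise ValueError(f"fluid {fluid} has fewer than 2 replicates")
        cols[fluid] = normed.loc[marker_union, samples].mean(axis=1)
    return SignatureMatrix(
        values=pd.DataFrame(cols),
        provenance={
            "top_fraction": top_fraction,
            "normalization": normalization,
            "fold_threshold": fold_threshold,
            "q_threshold": q_threshold,
            "sources": sources,
        },
    )
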