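"""Shared in-memory containers for expression and population data.

The package moves three kinds of tabular data around: gene-by-sample
expression matrices (:class:`CountsMatrix`), per-SNP variant calls
(:class:`VariantRecord`), and population reference data
(:class:`PopulationPanel`).  All of them are thin wrappers over pandas
objects so that the established TSV round-trips stay one-liners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FLUIDS = ("VB", "MB", "SA", "SE", "VS")

POPULATIONS = ("EUR", "EAS", "AMR", "SAS", "AFR")

#: Well-validated body-fluid identification (BFID) marker genes used to
#: confirm composition calls on real data.
BFID_MARKERS: dict[str, tuple[str, ...]] = {
    "MB": ("MMP10", "MMP3"),
    "VB": ("HBB", "HBA1", "HBA2"),
    "SA": ("STATH", "HTN3"),
    "SE": ("PRM1", "PRM2", "TGM4", "SEMG2"),
    "VS": ("SPINK5", "MUC4"),
}

GENOTYPES = ("hom_ref", "het", "hom_alt", "no_call")


@dataclass
class CountsMatrix:
    """Nonnegative gene x sample expression table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    gene_lengths
        Optional per-gene lengths in bases (required for FPKM/TPM).
    fluids
        Optional per-sample body-fluid labels (index = sample ids).
    """

    values: pd.DataFrame
    gene_lengths: pd.Series | None = None
    fluids: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.values.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some genes")
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene_lengths must be positive")
        if self.fluids is not None:
            self.fluids = self.fluids.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame) -> "CountsMatrix":
        """Return a copy carrying the same metadata but new values."""
        return CountsMatrix(values, gene_lengths=self.gene_lengths, fluids=self.fluids)

    def samples_of(self, fluid: str) -> list[str]:
        if self.fluids is None:
            raise ValueError("no fluid labels attached")
        return [s for s, f in self.fluids.items() if f == fluid]

    # --- TSV round trip -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        gene_lengths: str | Path | pd.Series | None = None,
        fluids: Mapping[str, str] | pd.Series | None = None,
    ) -> "CountsMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        lengths = gene_lengths
        if isinstance(gene_lengths, (str, Path)):
            lengths = read_gene_lengths(gene_lengths)
        if fluids is not None and not isinstance(fluids, pd.Series):
            fluids = pd.Series(dict(fluids))
        if fluids is None:
            fluids = infer_fluid_labels(values.columns)
        return cls(values, gene_lengths=lengths, fluids=fluids)


def infer_fluid_labels(samples: Iterable[str]) -> pd.Series | None:
    """Derive fluid labels from sample names like ``VB_1`` when possible."""
    labels = {}
    for s in samples:
        prefix = str(s).split("_")[0]
        if prefix not in FLUIDS:
            return None
        labels[s] = prefix
    return pd.Series(labels)


def read_gene_lengths(path: str | Path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length_bp"])
    return tab.set_index("gene_id")["length_bp"]


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", header=False)


@dataclass
class VariantRecord:
    """One biallelic SNP call from a mixture (or single-source) sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    dp: int
    gq: int
    ad: tuple[int, int]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.ad is not None and self.dp != sum(self.ad):
            raise ValueError("DP must equal ref_depth + alt_depth")

    @property
    def snp_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def is_autosomal(self) -> bool:
        c = str(self.chrom).removeprefix("chr")
        return c.isdigit() and 1 <= int(c) <= 22

    @property
    def is_biallelic_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.alt != "."


@dataclass
class PopulationPanel:
    """Per-population allele frequencies plus a reference genotype matrix.

    ``freqs`` is SNP x population (alt-allele frequency), ``genotypes`` is
    individual x SNP (alt dosage 0/1/2), ``ind_pop`` maps individual id to
    population label, ``snp_meta`` carries chrom/pos (and ref/alt).
    """

    freqs: pd.DataFrame
    genotypes: pd.DataFrame
    ind_pop: pd.Series
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if ((self.freqs.values < 0) | (self.freqs.values > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        if not np.isin(self.genotypes.values, [0, 1, 2]).all():
            raise ValueError("panel dosages must be 0, 1 or 2")

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def snp_ids(self) -> pd.Index:
        return self.freqs.index

    def alt_freq(self, snp_id: str, population: str) -> float:
        if population not in self.freqs.columns:
            raise KeyError(f"unknown population {population!r}")
        return float(self.freqs.at[snp_id, population])

    def maf(self, snp_id: str, population: str) -> float:
        p = self.alt_freq(snp_id, population)
        return min(p, 1.0 - p)

    def individuals_of(self, population: str) -> list[str]:
        return [i for i, p in self.ind_pop.items() if p == population]

    def dosages(self, snp_id: str, population: str | None = None) -> np.ndarray:
        col = self.genotypes[snp_id]
        if population is not None:
            col = col.loc[self.individuals_of(population)]
        return col.to_numpy()

    def genotype_counts(self, snp_id: str, population: str) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) among the population's individuals."""
        d = self.dosages(snp_id, population)
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())

    # --- TSV round trip -------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        freq_tab = pd.concat([self.snp_meta, self.freqs], axis=1)
        freq_tab.to_csv(outdir / "allele_freqs.tsv", sep="\t", index_label="snp_id")
        geno = self.genotypes.copy()
        geno.insert(0, "population", self.ind_pop)
        geno.to_csv(outdir / "panel_genotypes.tsv", sep="\t", index_label="individual")

    @classmethod
    def read(cls, indir: str | Path) -> "PopulationPanel":
        indir = Path(indir)
        freq_tab = pd.read_csv(indir / "allele_freqs.tsv", sep="\t", index_col=0)
        meta_cols = [c for c in ("chrom", "pos", "ref", "alt") if c in freq_tab.columns]
        snp_meta = freq_tab[meta_cols]
        freqs = freq_tab.drop(columns=meta_cols)
        geno = pd.read_csv(indir / "panel_genotypes.tsv", sep="\t", index_col=0)
        ind_pop = geno.pop("population")
        geno.columns.name = "snp_id"
        return cls(freqs=freqs, genotypes=geno, ind_pop=ind_pop, snp_meta=snp_meta)


@dataclass
class DonorGenome:
    """Truth genotypes of one donor: SNP id -> alt-allele dosage in {0,1,2}."""

    donor_id: str
    genotypes: pd.Series

    def __post_init__(self) -> None:
        if not np.isin(self.genotypes.to_numpy(), [0, 1, 2]).all():
            raise ValueError("dosages must be 0, 1 or 2")

    def dosage(self, snp_id: str) -> int:
        return int(self.genotypes[snp_id])


def dosage_to_genotype(dosage: int) -> str:
    return {0: "hom_ref", 1: "het", 2: "hom_alt"}[int(dosage)]
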