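"""Donor identification from mixture SNP calls.

Once the body-fluid composition of a mixture is known, SNPs falling in
genes expressed (almost) exclusively by one contributing fluid carry that
donor's genotype rather than a mixed signal.  This module implements the
selection cascade - quality filters (DP/GQ), imprinted-gene and RNA-editing
blocklists, population coverage and MAF, LD pruning, Hardy-Weinberg
screening - followed by gene-specificity-based assignment of SNPs to
donors, grouping of linked SNPs within a gene into phenotypes, and the
random-match-probability / likelihood-ratio arithmetic (LR = 1/RMP under
the single-donor, error-free assumption).

The RMP is the plain product of population genotype (or multi-locus
phenotype) frequencies under independence after LD pruning - the standard
forensic product rule, without theta/subpopulation correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DonorGenome, PopulationPanel, VariantRecord, dosage_to_genotype
from .deconv import CompositionCall
from .markers import DETable

log = logging.getLogger(__name__)

DP_MIN = 60
GQ_MIN = 40
MAF_MIN = 0.1
R2_MAX = 0.2
WINDOW_BP = 1_000_000
HWE_ALPHA = 0.05
TOP_N_TWO_WAY = 200
TOP_N_MULTI_WAY = 250


# ---------------------------------------------------------------------------
# variant-level filters
# ---------------------------------------------------------------------------

def filter_variants(
    records: Iterable[VariantRecord],
    dp_min: int = DP_MIN,
    gq_min: int = GQ_MIN,
    imprinted_genes: set[str] | None = None,
    editing_sites: set[tuple[str, int]] | None = None,
) -> list[VariantRecord]:
    """Quality cascade: biallelic autosomal SNVs with DP > dp_min and
    GQ > gq_min (both strict), excluding imprinted genes and known
    A-to-I RNA-editing positions.

    A-to-G / T-to-C substitutions are only removed when their position is
    listed in ``editing_sites``; there is no blanket transition removal.
    """
    imprinted_genes = imprinted_genes or set()
    editing_sites = editing_sites or set()
    kept: list[VariantRecord] = []
    skipped = 0
    for r in records:
        try:
            ok = (
                r.is_biallelic_snv
                and r.is_autosomal
                and r.genotype != "no_call"
                and r.dp > dp_min
                and r.gq > gq_min
                and (r.gene_id not in imprinted_genes)
                and ((str(r.chrom), int(r.pos)) not in editing_sites)
            )
        except Exception:
            skipped += 1
            continue
        if ok:
            kept.append(r)
    if skipped:
        log.warning("skipped %d malformed variant records", skipped)
    return kept


def _panel_lookup(panel: PopulationPanel) -> dict[tuple[str, int], str]:
    meta = panel.snp_meta
    return {
        (str(c), int(p)): sid
        for sid, c, p in zip(meta.index, meta["chrom"], meta["pos"])
    }


def maf_filter(
    records: Sequence[VariantRecord],
    panel: PopulationPanel,
    population: str = "EAS",
    maf_min: float = MAF_MIN,
) -> list[VariantRecord]:
    """Keep SNPs covered by the reference panel whose minor allele frequency
    in the stated population exceeds ``maf_min`` (strict)."""
    if population not in panel.freqs.columns:
        raise KeyError(f"unknown population {population!r}")
    lookup = _panel_lookup(panel)
    kept = []
    for r in records:
        sid = lookup.get((str(r.chrom), int(r.pos)))
        if sid is None:
            continue  # not covered by the reference panel
        if panel.maf(sid, population) > maf_min:
            kept.append(r)
    return kept


def ld_prune(
    records: Sequence[VariantRecord],
    panel: PopulationPanel,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
    population: str | None = None,
    maf_population: str = "EAS",
) -> list[VariantRecord]:
    """Greedy LD pruning on panel dosages.

    Scanning in (chrom, pos) order, whenever two retained SNPs within
    ``window_bp`` on the same chromosome have squared Pearson correlation
    of panel dosages above ``r2_max``, the SNP with the LOWER panel MAF is
    dropped (ties: the downstream SNP).  Records not covered by the panel
    are dropped.
    """
    lookup = _panel_lookup(panel)
    ordered = sorted(
        (r for r in records if (str(r.chrom), int(r.pos)) in lookup),
        key=lambda r: (r.chrom, r.pos),
    )
    mafs = {}
    dosage_cols = {}
    for r in ordered:
        sid = lookup[(str(r.chrom), int(r.pos))]
        mafs[id(r)] = panel.maf(sid, maf_population)
        dosage_cols[id(r)] = panel.dosages(sid, population).astype(float)

    retained: list[VariantRecord] = []
    for cand in ordered:
        drop_candidate = False
        to_remove = []
        for prev in retained:
            if prev.chrom != cand.chrom or cand.pos - prev.pos > window_bp:
                continue
            r2 = _r2(dosage_cols[id(prev)], dosage_cols[id(cand)])
            if r2 > r2_max:
                if mafs[id(cand)] > mafs[id(prev)]:
                    to_remove.append(prev)
                else:
                    drop_candidate = True
                    break
        if drop_candidate:
            continue
        for prev in to_remove:
            retained.remove(prev)
        retained.append(cand)
    return retained


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if (sx == 0 and sy == 0 and np.array_equal(x, y)) else 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg test (conditional enumeration of heterozygote
    counts given the allele counts; two-sided by probability mass).

    ``genotype_counts`` is (n_hom_ref, n_het, n_hom_alt).  Monomorphic
    sites have a single attainable outcome and return p = 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count is zero")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    obs_het = n_ab
    # heterozygote counts attainable given the allele counts (parity of rare)
    het_values = list(range(rare % 2, rare + 1, 2))
    # log P(n_het = h | allele counts) up to a constant:
    #   2^h / (hom_rare! * h! * hom_common!)
    logs = np.array(
        [
            h * math.log(2.0)
            - math.lgamma((rare - h) // 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n - h - (rare - h) // 2 + 1)
            for h in het_values
        ]
    )
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[het_values.index(obs_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(
    records: Sequence[VariantRecord],
    panel: PopulationPanel,
    population: str = "EAS",
    alpha: float = HWE_ALPHA,
) -> list[VariantRecord]:
    """Keep SNPs whose panel genotype distribution shows no HWE deviation
    (exact-test p > alpha) in the stated population."""
    lookup = _panel_lookup(panel)
    kept = []
    for r in records:
        sid = lookup.get((str(r.chrom), int(r.pos)))
        if sid is None:
            continue
        if hwe_test(panel.genotype_counts(sid, population)) > alpha:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# donor-specific gene selection and SNP assignment
# ---------------------------------------------------------------------------

def select_specific_genes(
    de_tables: Mapping[tuple[str, str], DETable],
    composition: CompositionCall | Sequence[str],
    top_n: int | None = None,
    fold_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Relatively specific genes per present fluid.

    Two present fluids: the pair's significant DEGs split by fold-change
    direction; each fluid receives the ``top_n`` (default 200) genes
    overexpressed in it, ranked by decreasing |log2FC|.  Three or four
    present fluids: a gene qualifies for fluid f only when significantly
    overexpressed in f versus EVERY other present fluid; genes are ranked
    by their minimum |log2FC| across those comparisons and the ``top_n``
    (default 250) kept.
    """
    fluids = (
        composition.fluids_present
        if isinstance(composition, CompositionCall)
        else list(composition)
    )
    if not 2 <= len(fluids) <= 4:
        raise ValueError("composition must contain 2-4 fluids")

    def get_table(a: str, b: str) -> DETable:
        if (a, b) in de_tables:
            return de_tables[(a, b)]
        if (b, a) in de_tables:
            return de_tables[(b, a)].flipped()
        raise KeyError(f"no DE table for pair ({a}, {b})")

    lfc_min = math.log2(fold_threshold)
    out: dict[str, list[str]] = {}
    if len(fluids) == 2:
        n = top_n or TOP_N_TWO_WAY
        a, b = fluids
        t = get_table(a, b).table
        sig = t[(t["log2fc"].abs() >= lfc_min) & (t["qvalue"] < q_threshold)]
        for fluid, sign in ((a, 1), (b, -1)):
            side = sig[np.sign(sig["log2fc"]) == sign].copy()
            side["absfc"] = side["log2fc"].abs()
            side = side.rename_axis("gene_id").reset_index().sort_values(
                by=["absfc", "qvalue", "gene_id"], ascending=[False, True, True]
            )
            if len(side) < n:
                log.info("%s: only %d specific genes available (top_n=%d)", fluid, len(side), n)
            out[fluid] = side["gene_id"].head(n).tolist()
    else:
        n = top_n or TOP_N_MULTI_WAY
        for fluid in fluids:
            per_comparison = []
            for other in fluids:
                if other == fluid:
                    continue
                t = get_table(fluid, other).table
                per_comparison.append(
                    t[(t["log2fc"] >= lfc_min) & (t["qvalue"] < q_threshold)]["log2fc"]
                )
            # qualify only when overexpressed versus EVERY other component
            common = per_comparison[0].index
            for up in per_comparison[1:]:
                common = common.intersection(up.index)
            min_lfc = (
                pd.concat([up.reindex(common) for up in per_comparison], axis=1).min(axis=1)
                if len(common)
                else pd.Series(dtype=float)
            )
            if min_lfc.empty:
                log.warning("no specific genes for %s", fluid)
                out[fluid] = []
                continue
            ranked = (
                min_lfc.rename("min_absfc")
                .rename_axis("gene_id")
                .reset_index()
                .sort_values(by=["min_absfc", "gene_id"], ascending=[False, True])
            )
            if len(ranked) < n:
                log.info("%s: only %d specific genes available (top_n=%d)", fluid, len(ranked), n)
            out[fluid] = ranked["gene_id"].head(n).tolist()
    return out


def assign_snps_to_donor(
    records: Sequence[VariantRecord],
    gene_sets: Mapping[str, Sequence[str]],
) -> dict[str, list[VariantRecord]]:
    """Route each SNP to the fluid whose specific-gene set contains its gene;
    SNPs in no set are discarded."""
    sets = {f: set(genes) for f, genes in gene_sets.items()}
    out: dict[str, list[VariantRecord]] = {f: [] for f in gene_sets}
    for r in records:
        for fluid, genes in sets.items():
            if r.gene_id in genes:
                out[fluid].append(r)
                break
    for fluid, recs in out.items():
        if not recs:
            log.warning("no SNPs assigned to %s", fluid)
    return out


# ---------------------------------------------------------------------------
# phenotypes, RMP and LR
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeGroup:
    """Linked SNPs within one gene, treated as a single frequency unit."""

    gene_id: str
    snps: tuple[VariantRecord, ...]  # ordered by (chrom, pos)
    frequency: float = float("nan")

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(r.genotype for r in self.snps)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self.snps)


@dataclass
class DonorSnpProfile:
    """Per-donor phenotype-grouped SNP profile feeding the RMP/LR."""

    fluid: str
    groups: list[PhenotypeGroup]

    @property
    def n_snps(self) -> int:
        return sum(len(g.snps) for g in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def group_linked_snps(records: Sequence[VariantRecord], fluid: str = "") -> DonorSnpProfile:
    """Partition a donor's SNPs by gene; SNPs sharing a gene are linked and
    recorded as one multi-locus phenotype."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    groups = [
        PhenotypeGroup(gene_id=g, snps=tuple(sorted(rs, key=lambda r: (r.chrom, r.pos))))
        for g, rs in sorted(by_gene.items())
    ]
    return DonorSnpProfile(fluid=fluid, groups=groups)


def phenotype_frequency(
    group: PhenotypeGroup,
    panel: PopulationPanel,
    population: str = "EAS",
) -> float:
    """Population frequency of one phenotype group.

    Singleton groups use HWE genotype frequencies from the population's
    allele frequency (p^2 / 2pq / q^2); multi-SNP groups use the empirical
    fraction of panel individuals matching the joint genotype exactly,
    floored at 1/(2N+1) so a never-seen phenotype cannot zero the RMP.
    """
    lookup = _panel_lookup(panel)
    sids = []
    for r in group.snps:
        sid = lookup.get((str(r.chrom), int(r.pos)))
        if sid is None:
            raise KeyError(f"SNP {r.snp_id} not covered by the panel")
        sids.append(sid)
    if len(group.snps) == 1:
        p = min(max(panel.alt_freq(sids[0], population), 1e-6), 1 - 1e-6)
        geno = group.snps[0].genotype
        return {"hom_ref": (1 - p) ** 2, "het": 2 * p * (1 - p), "hom_alt": p**2}[geno]
    inds = panel.individuals_of(population)
    sub = panel.genotypes.loc[inds, sids].to_numpy()
    target = np.array(
        [{"hom_ref": 0, "het": 1, "hom_alt": 2}[r.genotype] for r in group.snps]
    )
    freq = (sub == target).all(axis=1).sum() / len(inds)
    return float(max(freq, 1.0 / (2 * len(inds) + 1)))


@dataclass
class LRResult:
    """Random match probability and the matching likelihood ratio."""

    n_snps: int
    n_groups: int
    log10_rmp: float

    @property
    def log10_lr(self) -> float:
        return -self.log10_rmp

    @property
    def rmp(self) -> float:
        return 10.0 ** self.log10_rmp

    @property
    def lr(self) -> float:
        return 10.0 ** self.log10_lr


def rmp_and_lr(profile: DonorSnpProfile) -> LRResult:
    """RMP = product of phenotype-group frequencies; LR = 1/RMP.

    Accumulated in log10 so profiles with hundreds of SNPs do not
    underflow.
    """
    if not profile.groups:
        raise ValueError("empty SNP profile; RMP undefined")
    log10_rmp = 0.0
    for g in profile.groups:
        if not (0.0 < g.frequency <= 1.0):
            raise ValueError(f"group {g.gene_id} has no valid frequency")
        log10_rmp += math.log10(g.frequency)
    return LRResult(n_snps=profile.n_snps, n_groups=profile.n_groups, log10_rmp=log10_rmp)


def attach_frequencies(
    profile: DonorSnpProfile, panel: PopulationPanel, population: str = "EAS"
) -> DonorSnpProfile:
    """Fill in every group's population phenotype frequency (in place)."""
    for g in profile.groups:
        g.frequency = phenotype_frequency(g, panel, population)
    return profile


@dataclass
class MatchReport:
    """Concordance of a separated donor profile against a reference."""

    n_compared: int
    n_concordant: int
    discordant_snps: list[str]
    missing_snps: list[str]
    excluded_groups: list[str]
    lr: LRResult | None

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else float("nan")


def match_against_reference(
    profile: DonorSnpProfile,
    reference: DonorGenome | Mapping[str, str],
    panel: PopulationPanel | None = None,
) -> MatchReport:
    """Compare a separated profile to a reference genotype set.

    The LR is computed over fully concordant phenotype groups only (the
    no-dropout / no-drop-in assumption); groups containing any discordant
    or missing SNP are excluded and reported.  ``reference`` may be keyed
    by ``chrom:pos`` or, when a panel is supplied for translation, by the
    panel's SNP ids.
    """
    if isinstance(reference, DonorGenome):
        ref_geno = {
            sid: dosage_to_genotype(d) for sid, d in reference.genotypes.items()
        }
    else:
        ref_geno = {k: v for k, v in reference.items()}
    if panel is not None:
        meta = panel.snp_meta
        translated = {}
        for sid, g in ref_geno.items():
            if sid in meta.index:
                translated[f"{meta.at[sid, 'chrom']}:{meta.at[sid, 'pos']}"] = g
            else:
                translated[sid] = g
        ref_geno = translated
    concordant_groups: list[PhenotypeGroup] = []
    discordant, missing, excluded = [], [], []
    n_comp = n_conc = 0
    for g in profile.groups:
        ok = True
        for r in g.snps:
            ref = ref_geno.get(r.snp_id)
            if ref is None:
                missing.append(r.snp_id)
                ok = False
                continue
            n_comp += 1
            if ref == r.genotype:
                n_conc += 1
            else:
                discordant.append(r.snp_id)
                ok = False
        if ok:
            concordant_groups.append(g)
        else:
            excluded.append(g.gene_id)
    if n_comp == 0:
        log.warning("no overlap between profile and reference; no LR computed")
        lr = None
    elif concordant_groups:
        lr = rmp_and_lr(DonorSnpProfile(fluid=profile.fluid, groups=concordant_groups))
    else:
        lr = None
    return MatchReport(
        n_compared=n_comp,
        n_concordant=n_conc,
        discordant_snps=discordant,
        missing_snps=missing,
        excluded_groups=excluded,
        lr=lr,
    )


# ---------------------------------------------------------------------------
# single-source feasibility
# ---------------------------------------------------------------------------

def single_source_rmp(
    records: Sequence[VariantRecord],
    panel: PopulationPanel,
    population: str = "EAS",
    dp_min: int = DP_MIN,
    gq_min: int = GQ_MIN,
    maf_min: float = MAF_MIN,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
    hwe_alpha: float = HWE_ALPHA,
    imprinted_genes: set[str] | None = None,
    editing_sites: set[tuple[str, int]] | None = None,
) -> LRResult:
    """RMP/LR of a single-source transcriptome: the full selection cascade
    (quality -> MAF -> LD pruning -> HWE) followed by independent-SNP HWE
    genotype frequencies.  No gene-specificity step: every surviving SNP
    counts, each as its own group."""
    recs = filter_variants(records, dp_min, gq_min, imprinted_genes, editing_sites)
    recs = maf_filter(recs, panel, population, maf_min)
    recs = ld_prune(recs, panel, r2_max, window_bp, maf_population=population)
    recs = hwe_filter(recs, panel, population, hwe_alpha)
    if not recs:
        raise ValueError("no SNPs survive the selection cascade")
    profile = DonorSnpProfile(
        fluid="single_source",
        groups=[
            PhenotypeGroup(gene_id=r.snp_id, snps=(r,)) for r in recs
        ],
    )
    attach_frequencies(profile, panel, population)
    return rmp_and_lr(profile)
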