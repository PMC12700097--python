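"""Synthetic data generation for body-fluid mixture experiments.

Real casework transcriptomes are restricted material, so every downstream
stage of the package is exercised against synthetic data built here: five
body-fluid expression profiles with fluid-specific marker genes, reference
panels with negative-binomial replicate noise, in-silico mixtures drawn at
the read level (multinomial thinning of the mixed profile), donor genotypes
under Hardy-Weinberg equilibrium, and mixture variant calls whose allele
depths are weighted by each donor's per-gene expression share.

All generators are pure functions of their parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    FLUIDS,
    POPULATIONS,
    CountsMatrix,
    DonorGenome,
    PopulationPanel,
    VariantRecord,
    dosage_to_genotype,
)

BASES = ("A", "C", "G", "T")

#: Read total used by the original mixture experiments; the package default
#: is scaled down to keep simulation grids fast.
PAPER_TOTAL_READS = 56_000_000
DEFAULT_TOTAL_READS = 1_000_000


# ---------------------------------------------------------------------------
# fluid expression profiles
# ---------------------------------------------------------------------------

@dataclass
class FluidProfile:
    """Per-gene relative transcript abundance of one body fluid."""

    fluid: str
    relative_abundance: pd.Series  # sums to 1
    dispersion: pd.Series  # per-gene NB dispersion, > 0
    marker_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValueError(f"unknown fluid {self.fluid!r}")
        pi = self.relative_abundance
        if (pi < 0).any():
            raise ValueError("abundances must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if (self.dispersion <= 0).any():
            raise ValueError("dispersions must be positive")
        if not self.marker_genes <= set(pi.index):
            raise ValueError("marker genes outside gene universe")

    @property
    def genes(self) -> pd.Index:
        return self.relative_abundance.index


def make_fluid_profiles(
    n_genes: int,
    n_markers_per_fluid: int,
    marker_fold: float,
    seed: int,
    dispersion: float = 0.1,
    sa_vs_overlap: float = 0.0,
) -> list[FluidProfile]:
    """Construct 5 fluid profiles over a shared gene universe.

    Each fluid receives ``n_markers_per_fluid`` marker genes whose relative
    abundance is ``marker_fold`` times their abundance in the other fluids.
    ``sa_vs_overlap`` optionally makes a fraction of the SA marker set also
    a VS marker, emulating the saliva / vaginal-secretion expression
    cross-talk that confounds composition calls on real samples.
    """
    if n_genes < 5 * n_markers_per_fluid:
        raise ValueError("n_genes must be at least 5 x n_markers_per_fluid")
    if n_genes <= 0 or n_markers_per_fluid <= 0:
        raise ValueError("sizes must be positive")
    if marker_fold <= 1:
        raise ValueError("marker_fold must exceed 1")
    if not 0.0 <= sa_vs_overlap <= 1.0:
        raise ValueError("sa_vs_overlap must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    base = pd.Series(rng.lognormal(mean=0.0, sigma=1.0, size=n_genes), index=genes)

    # Marker blocks occupy the first 5*m genes; rescale each block to equal
    # total base mass so that normalized specificity is exactly marker_fold.
    m = n_markers_per_fluid
    blocks = {f: list(genes[i * m : (i + 1) * m]) for i, f in enumerate(FLUIDS)}
    block_mass = np.mean([base[b].sum() for b in blocks.values()])
    for b in blocks.values():
        base[b] *= block_mass / base[b].sum()

    marker_sets = {f: set(b) for f, b in blocks.items()}
    n_shared = int(round(sa_vs_overlap * m))
    if n_shared:
        shared = blocks["SA"][:n_shared]
        marker_sets["VS"] |= set(shared)

    profiles = []
    for fluid in FLUIDS:
        w = base.copy()
        w[list(marker_sets[fluid])] *= marker_fold
        pi = w / w.sum()
        profiles.append(
            FluidProfile(
                fluid=fluid,
                relative_abundance=pi,
                dispersion=pd.Series(dispersion, index=genes),
                marker_genes=frozenset(marker_sets[fluid]),
            )
        )
    return profiles


def make_gene_lengths(genes: Sequence[str], seed: int = 0) -> pd.Series:
    """Deterministic per-gene lengths (bases), lognormal around ~2 kb."""
    rng = np.random.default_rng(seed)
    lengths = np.round(rng.lognormal(mean=7.6, sigma=0.5, size=len(genes))).astype(int)
    return pd.Series(np.maximum(lengths, 200), index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# mixture designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureDesign:
    """One in-silico mixture: which fluids, whose, and at what read fraction."""

    components: tuple[tuple[str, str, float], ...]  # (fluid, donor_id, fraction)
    total_reads: int = DEFAULT_TOTAL_READS
    seed: int = 0

    def __post_init__(self) -> None:
        fluids = [c[0] for c in self.components]
        fracs = [c[2] for c in self.components]
        if not 2 <= len(fluids) <= 4 and len(fluids) != 1:
            raise ValueError("designs carry 1-4 components (2-4 for mixtures)")
        if len(set(fluids)) != len(fluids):
            raise ValueError("fluids must be distinct within a design")
        if any(w <= 0 for w in fracs):
            raise ValueError("fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")

    @property
    def fluids(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.components)

    @property
    def fractions(self) -> dict[str, float]:
        return {c[0]: c[2] for c in self.components}

    @property
    def donors(self) -> dict[str, str]:
        return {c[0]: c[1] for c in self.components}

    @property
    def name(self) -> str:
        parts = [f"{f}{w:g}" for f, _, w in self.components]
        return "_".join(parts) + f"_d{self.seed}"


def _pairs(items: Sequence[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(items) for b in items[i + 1 :]]


def make_design_grid(
    kind: str,
    total_reads: int = DEFAULT_TOTAL_READS,
    base_seed: int = 0,
) -> list[MixtureDesign]:
    """Enumerate the mixture design grids used by the study.

    ``two_person_full``: 10 unordered fluid pairs x 9 read splits
    (0.1..0.9 step 0.1) x 2 donor assignments = 180 designs.
    ``two_person_subset``: the 5 saliva-free pairs x splits 0.1..0.9 step
    0.2, used for donor-identification evaluation.
    ``multi_person``: equal-fraction 3- and 4-fluid combinations x 2 donor
    assignments = 30 designs.
    """
    designs: list[MixtureDesign] = []
    idx = 0

    def donor(fluid: str, assignment: int) -> str:
        return f"{fluid}{assignment + 1}"

    if kind == "two_person_full":
        splits = [round(0.1 * i, 1) for i in range(1, 10)]
        for a, b in _pairs(FLUIDS):
            for w in splits:
                for assign in (0, 1):
                    designs.append(
                        MixtureDesign(
                            components=(
                                (a, donor(a, assign), w),
                                (b, donor(b, assign), round(1 - w, 1)),
                            ),
                            total_reads=total_reads,
                            seed=base_seed + idx,
                        )
                    )
                    idx += 1
    elif kind == "two_person_subset":
        pairs = [("MB", "SE"), ("VB", "MB"), ("VB", "SE"), ("VB", "VS"), ("VS", "SE")]
        splits = [0.1, 0.3, 0.5, 0.7, 0.9]
        for a, b in pairs:
            for w in splits:
                designs.append(
                    MixtureDesign(
                        components=((a, donor(a, 0), w), (b, donor(b, 0), round(1 - w, 1))),
                        total_reads=total_reads,
                        seed=base_seed + idx,
                    )
                )
                idx += 1
    elif kind == "multi_person":
        combos = [c for c in _combinations(FLUIDS, 3)] + [c for c in _combinations(FLUIDS, 4)]
        for combo in combos:
            k = len(combo)
            w = 1.0 / k
            fracs = [w] * (k - 1) + [1.0 - w * (k - 1)]
            for assign in (0, 1):
                designs.append(
                    MixtureDesign(
                        components=tuple(
                            (f, donor(f, assign), frac) for f, frac in zip(combo, fracs)
                        ),
                        total_reads=total_reads,
                        seed=base_seed + idx,
                    )
                )
                idx += 1
    else:
        raise ValueError(f"unknown design grid kind {kind!r}")
    return designs


def _combinations(items: Sequence[str], k: int) -> list[tuple[str, ...]]:
    import itertools

    return list(itertools.combinations(items, k))


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Negative binomial with var = mu + alpha * mu^2; Poisson limit at alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = dispersion < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        a = dispersion[~tiny]
        mu = mean[~tiny]
        n = 1.0 / a
        p = n / (n + mu)
        out[~tiny] = rng.negative_binomial(n, p)
    return out


def simulate_reference_samples(
    profiles: Sequence[FluidProfile],
    n_reps: int,
    library_size: float,
    dispersion: float | None = None,
    seed: int = 0,
    library_sd: float = 0.2,
    gene_lengths: pd.Series | None = None,
) -> CountsMatrix:
    """Simulate a reference panel of ``n_reps`` replicate samples per fluid.

    Counts for gene g in a sample of fluid f are NB with mean
    ``library_size * pi_fg`` (library sizes jittered lognormally with sd
    ``library_sd``) and the given dispersion (profile dispersions when None).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (differential testing needs replicates)")
    rng = np.random.default_rng(seed)
    genes = profiles[0].genes
    cols = {}
    fluids = {}
    for prof in profiles:
        disp = prof.dispersion.to_numpy() if dispersion is None else dispersion
        for rep in range(n_reps):
            lib = library_size * (
                math.exp(rng.normal(0.0, library_sd)) if library_sd > 0 else 1.0
            )
            name = f"{prof.fluid}_{rep + 1}"
            cols[name] = _nb_draw(rng, lib * prof.relative_abundance.to_numpy(), disp)
            fluids[name] = prof.fluid
    values = pd.DataFrame(cols, index=genes)
    if gene_lengths is None:
        gene_lengths = make_gene_lengths(genes, seed=seed)
    return CountsMatrix(values, gene_lengths=gene_lengths, fluids=pd.Series(fluids))


def mixture_expectation(
    profiles: Sequence[FluidProfile], design: MixtureDesign
) -> pd.Series:
    """Expected per-gene read counts of a design: total * sum_f w_f pi_fg."""
    by_fluid = {p.fluid: p for p in profiles}
    missing = [f for f in design.fluids if f not in by_fluid]
    if missing:
        raise KeyError(f"design fluids missing from profiles: {missing}")
    genes = profiles[0].genes
    p = np.zeros(len(genes))
    for fluid, _, w in design.components:
        p += w * by_fluid[fluid].relative_abundance.to_numpy()
    return pd.Series(design.total_reads * p, index=genes, name=design.name)


def simulate_mixture_counts(
    profiles: Sequence[FluidProfile], design: MixtureDesign
) -> pd.Series:
    """Draw one mixture expression column: reads are multinomial over genes
    with P(g) proportional to the fraction-weighted fluid abundances.

    Read-fraction semantics: ``w_f`` is each fluid's share of sequenced
    READS, so the mixture distribution is the w-weighted average of the
    per-fluid read distributions.
    """
    expected = mixture_expectation(profiles, design)
    p = expected.to_numpy() / design.total_reads
    rng = np.random.default_rng(design.seed)
    counts = rng.multinomial(design.total_reads, p)
    return pd.Series(counts, index=expected.index, name=design.name)


# ---------------------------------------------------------------------------
# population panel and donors
# ---------------------------------------------------------------------------

def make_population_panel(
    n_snps: int,
    n_pops: int,
    n_individuals: int,
    fst: float,
    seed: int,
    ld_copy_prob: float = 0.0,
    spacing_bp: int = 10_000,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> PopulationPanel:
    """Simulate a continental reference panel under the Balding-Nichols model.

    Ancestral alt-allele frequencies are Uniform over ``freq_range``;
    population frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F); panel genotypes
    are drawn under HWE within each population. ``ld_copy_prob`` creates LD
    blocks by copying the previous SNP's haplotype alleles with that
    probability. SNPs are laid out on autosomes 1..22 every ``spacing_bp``.
    ``n_individuals`` is the panel size per population.
    """
    if not 1 <= n_pops <= 5:
        raise ValueError("n_pops must be 1..5")
    if not 0.0 <= fst <= 0.3:
        raise ValueError("fst must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    pops = list(POPULATIONS[:n_pops])
    snp_ids = [f"s{i:05d}" for i in range(n_snps)]

    anc = rng.uniform(freq_range[0], freq_range[1], size=n_snps)
    if fst == 0.0:
        freqs = np.tile(anc[:, None], (1, n_pops))
    else:
        a = anc * (1 - fst) / fst
        b = (1 - anc) * (1 - fst) / fst
        freqs = rng.beta(a[:, None], b[:, None], size=(n_snps, n_pops))

    # haplotype-level draw so LD copying is well defined
    inds = []
    ind_pop = {}
    hap_blocks = []
    for k, pop in enumerate(pops):
        haps = (
            rng.random((2 * n_individuals, n_snps)) < freqs[:, k][None, :]
        ).astype(np.int8)
        if ld_copy_prob > 0:
            copy = rng.random((2 * n_individuals, n_snps)) < ld_copy_prob
            for j in range(1, n_snps):
                haps[copy[:, j], j] = haps[copy[:, j], j - 1]
        hap_blocks.append(haps)
        for i in range(n_individuals):
            name = f"{pop}_{i + 1}"
            inds.append(name)
            ind_pop[name] = pop
    geno = np.vstack([h[0::2] + h[1::2] for h in hap_blocks])

    # genome layout: consecutive SNPs on the same chromosome, wrapping at ~2000
    per_chrom = max(1, math.ceil(n_snps / 22))
    chroms = [str(1 + i // per_chrom) for i in range(n_snps)]
    positions = [1 + (i % per_chrom) * spacing_bp for i in range(n_snps)]
    ref = rng.choice(BASES, size=n_snps)
    alt = np.array(
        [rng.choice([b for b in BASES if b != r]) for r in ref]
    )
    snp_meta = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": ref, "alt": alt},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return PopulationPanel(
        freqs=pd.DataFrame(freqs, index=snp_meta.index, columns=pops),
        genotypes=pd.DataFrame(geno, index=pd.Index(inds, name="individual"), columns=snp_meta.index),
        ind_pop=pd.Series(ind_pop),
        snp_meta=snp_meta,
    )


def sample_donor(
    panel: PopulationPanel, population: str, donor_id: str, seed: int
) -> DonorGenome:
    """Draw one donor's genotypes under HWE from a population's frequencies."""
    if population not in panel.freqs.columns:
        raise KeyError(f"unknown population {population!r}")
    rng = np.random.default_rng(seed)
    p = panel.freqs[population].to_numpy()
    dosage = rng.binomial(2, p)
    return DonorGenome(donor_id=donor_id, genotypes=pd.Series(dosage, index=panel.snp_ids))


def make_snp_map(
    panel: PopulationPanel,
    genes: Sequence[str],
    seed: int = 0,
    marker_genes: Mapping[str, Sequence[str]] | None = None,
    snps_per_marker_gene: int = 3,
) -> pd.DataFrame:
    """Assign every panel SNP to exactly one gene.

    When ``marker_genes`` (fluid -> gene list) is given, the first SNPs are
    concentrated on marker genes (``snps_per_marker_gene`` each, in panel
    order) so that fluid-specific genes carry callable variation; the rest
    are spread over the remaining genes round-robin.
    """
    rng = np.random.default_rng(seed)
    snp_ids = list(panel.snp_ids)
    assignment: dict[str, str] = {}
    cursor = 0
    if marker_genes:
        for fluid in sorted(marker_genes):
            for g in marker_genes[fluid]:
                for _ in range(snps_per_marker_gene):
                    if cursor >= len(snp_ids):
                        break
                    assignment[snp_ids[cursor]] = g
                    cursor += 1
    other_genes = [g for g in genes if g not in set(assignment.values())]
    if not other_genes:
        other_genes = list(genes)
    for i, s in enumerate(snp_ids[cursor:]):
        assignment[s] = other_genes[i % len(other_genes)]
    out = panel.snp_meta.copy()
    out["gene_id"] = pd.Series(assignment)
    return out


# ---------------------------------------------------------------------------
# genotype calling and mixture variants
# ---------------------------------------------------------------------------

NO_CALL = ("no_call", 0)


def call_genotype(
    ref_depth: int, alt_depth: int, error_rate: float
) -> tuple[str, int]:
    """Diploid genotype from allele depths under a binomial error model.

    Likelihoods assume each read reports the alt allele with probability e
    (hom-ref), 1/2 (het) or 1-e (hom-alt); the call is the maximum-posterior
    genotype under a uniform prior, with GQ the phred-scaled probability
    that the call is wrong, capped at 99.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be nonnegative")
    total = ref_depth + alt_depth
    if total == 0:
        return NO_CALL
    e = min(max(error_rate, 1e-10), 0.5)
    probs = np.array([e, 0.5, 1.0 - e])
    loglik = alt_depth * np.log(probs) + ref_depth * np.log1p(-probs)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    best = int(np.argmax(post))
    p_err = max(1.0 - post[best], 1e-10)
    gq = min(99, int(round(-10.0 * math.log10(p_err))))
    return dosage_to_genotype(best), gq


def simulate_mixture_variants(
    profiles: Sequence[FluidProfile],
    design: MixtureDesign,
    donors: Mapping[str, DonorGenome],
    snp_map: pd.DataFrame,
    depth_scale: float,
    error_rate: float = 0.005,
    seed: int = 0,
) -> list[VariantRecord]:
    """Simulate mixture variant calls with expression-weighted allele depths.

    For SNP s in gene g the total depth is Poisson with mean
    ``depth_scale * sum_f w_f pi_fg``; each donor contributes reads in
    proportion to ``w_f pi_fg``, and their reads carry the alt allele with
    probability dosage/2 perturbed by the sequencing error rate.  Genotype,
    GQ and DP are then derived by :func:`call_genotype`.
    """
    by_fluid = {p.fluid: p for p in profiles}
    for fluid, donor_id, _ in design.components:
        if donor_id not in donors:
            raise KeyError(f"donor {donor_id!r} missing for fluid {fluid}")
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    genes = set(profiles[0].genes)
    for snp_id, row in snp_map.iterrows():
        gene = row["gene_id"]
        if gene not in genes:
            raise KeyError(f"SNP {snp_id} mapped to unknown gene {gene!r}")
        shares = np.array(
            [w * by_fluid[f].relative_abundance[gene] for f, _, w in design.components]
        )
        mean_depth = depth_scale * shares.sum()
        depth = int(rng.poisson(mean_depth))
        if depth == 0:
            continue
        if shares.sum() == 0:
            continue
        per_donor = rng.multinomial(depth, shares / shares.sum())
        e = min(max(error_rate, 0.0), 0.5)
        alt = 0
        for (fluid, donor_id, _), n_reads in zip(design.components, per_donor):
            d = donors[donor_id].dosage(snp_id)
            p_alt = (d / 2.0) * (1 - e) + (1 - d / 2.0) * e
            alt += int(rng.binomial(n_reads, p_alt))
        ref = depth - alt
        genotype, gq = call_genotype(ref, alt, max(error_rate, 1e-3))
        records.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                genotype=genotype,
                dp=depth,
                gq=gq,
                ad=(ref, alt),
                gene_id=gene,
            )
        )
    return records


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Everything a benchmark needs: reference panel, mixtures, and truth."""

    profiles: list[FluidProfile]
    reference_counts: CountsMatrix
    mixture_counts: CountsMatrix
    designs: list[MixtureDesign]
    truth_proportions: pd.DataFrame  # design x fluid
    mixture_variants: dict[str, list[VariantRecord]] = field(default_factory=dict)
    truth_genotypes: dict[str, DonorGenome] = field(default_factory=dict)
    panel: PopulationPanel | None = None
    snp_map: pd.DataFrame | None = None


def make_bundle(
    designs: Sequence[MixtureDesign],
    n_genes: int = 1000,
    n_markers_per_fluid: int = 20,
    marker_fold: float = 8.0,
    dispersion: float = 0.1,
    n_reps: int = 5,
    library_size: float = 1e6,
    seed: int = 0,
    sa_vs_overlap: float = 0.0,
    with_variants: bool = False,
    population: str = "EAS",
    n_panel_snps: int = 400,
    n_panel_individuals: int = 100,
    fst: float = 0.1,
    depth_scale: float = 50_000.0,
    error_rate: float = 0.005,
) -> SyntheticBundle:
    """Build a complete synthetic study: profiles, reference panel, mixtures
    (and, optionally, donor genotypes plus mixture variant calls)."""
    profiles = make_fluid_profiles(
        n_genes, n_markers_per_fluid, marker_fold, seed, dispersion, sa_vs_overlap
    )
    reference = simulate_reference_samples(
        profiles, n_reps=n_reps, library_size=library_size, seed=seed + 1
    )
    mix_cols = {}
    truth = []
    for design in designs:
        mix_cols[design.name] = simulate_mixture_counts(profiles, design)
        row = {f: 0.0 for f in FLUIDS}
        row.update(design.fractions)
        truth.append(pd.Series(row, name=design.name))
    mixture_counts = CountsMatrix(
        pd.DataFrame(mix_cols, index=profiles[0].genes),
        gene_lengths=reference.gene_lengths,
    )
    truth_proportions = pd.DataFrame(truth)[list(FLUIDS)]
    bundle = SyntheticBundle(
        profiles=profiles,
        reference_counts=reference,
        mixture_counts=mixture_counts,
        designs=list(designs),
        truth_proportions=truth_proportions,
    )
    if with_variants:
        panel = make_population_panel(
            n_panel_snps, n_pops=5, n_individuals=n_panel_individuals, fst=fst, seed=seed + 2
        )
        marker_map = {p.fluid: sorted(p.marker_genes) for p in profiles}
        snp_map = make_snp_map(panel, list(profiles[0].genes), seed=seed + 3, marker_genes=marker_map)
        donor_ids = sorted({d for design in designs for d in design.donors.values()})
        donors = {
            did: sample_donor(panel, population, did, seed=seed + 10 + i)
            for i, did in enumerate(donor_ids)
        }
        for j, design in enumerate(designs):
            bundle.mixture_variants[design.name] = simulate_mixture_variants(
                profiles, design, donors, snp_map, depth_scale, error_rate, seed=seed + 100 + j
            )
        bundle.truth_genotypes = donors
        bundle.panel = panel
        bundle.snp_map = snp_map
    return bundle


# ---------------------------------------------------------------------------
# on-disk output (TSV / VCF 4.2)
# ---------------------------------------------------------------------------

_GT_FIELD = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "no_call": "./."}


def write_vcf(records: Sequence[VariantRecord], path: str | Path, sample: str = "MIXTURE") -> None:
    """Write variant records as a minimal single-sample VCF 4.2 text file."""
    chroms = sorted({r.chrom for r in records}, key=_chrom_key)
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Source gene">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for r in sorted(records, key=lambda r: (_chrom_key(r.chrom), r.pos)):
        info = f"GENE={r.gene_id}" if r.gene_id else "."
        gt = _GT_FIELD[r.genotype]
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\t"
            f"GT:DP:GQ:AD\t{gt}:{r.dp}:{r.gq}:{r.ad[0]},{r.ad[1]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _chrom_key(chrom: str):
    c = str(chrom).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write a bundle's tables (counts, truth, variants, panel) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.reference_counts.to_tsv(outdir / "reference_counts.tsv")
    bundle.mixture_counts.to_tsv(outdir / "mixture_counts.tsv")
    from .containers import write_gene_lengths

    if bundle.reference_counts.gene_lengths is not None:
        write_gene_lengths(bundle.reference_counts.gene_lengths, outdir / "gene_lengths.tsv")
    bundle.truth_proportions.to_csv(outdir / "truth_proportions.tsv", sep="\t", index_label="mixture")
    if bundle.truth_genotypes:
        pd.DataFrame(
            {d: g.genotypes for d, g in bundle.truth_genotypes.items()}
        ).to_csv(outdir / "truth_genotypes.tsv", sep="\t", index_label="snp_id")
    for name, records in bundle.mixture_variants.items():
        write_vcf(records, outdir / f"{name}.vcf")
    if bundle.panel is not None:
        bundle.panel.write(outdir / "panel")
    if bundle.snp_map is not None:
        bundle.snp_map.to_csv(outdir / "snp_map.tsv", sep="\t", index_label="snp_id")
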