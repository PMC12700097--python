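"""End-to-end orchestration: body-fluid deconvolution followed by
separation of donor SNP profiles (and optional ancestry inference).

The pipeline mirrors the two-step workflow: (1) build the signature from
the reference panel, normalize reference and mixture consistently, estimate
fractions (FARDEEP on raw counts by default - the operating point of
maximum performance) and call the composition; (2) select relatively
specific genes for the present fluids, route the mixture's SNPs to donors,
group linked SNPs into phenotypes and compute each donor's RMP/LR, with an
optional ancestry step on the separated profiles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import ancestry as ancestry_mod
from . import deconv, io, markers, normalize, snpid
from .containers import CountsMatrix, PopulationPanel

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    reference_counts: str
    mixture_counts: str
    out_dir: str
    mixture: str | None = None  # mixture column; default first
    vcf: str | None = None
    gene_lengths: str | None = None
    gene_bed: str | None = None
    panel: str | None = None
    reference_genotypes: str | None = None
    method: str = "FARDEEP"
    normalization: str = "raw"
    top_fraction: float = 0.04
    fraction_threshold: float = 0.05
    count_threshold: int = 10
    dp_min: int = 60
    gq_min: int = 40
    maf_min: float = 0.1
    top_n: int | None = None
    population: str = "EAS"
    imprinted_genes: list[str] = field(default_factory=list)
    editing_sites: list[list] = field(default_factory=list)
    run_ancestry: bool = False
    delta_min: float = 0.3
    r2_max: float = 0.2
    window_bp: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in deconv.METHODS:
            raise ValueError(
                f"method {self.method!r} not implemented; registry: {sorted(deconv.METHODS)}"
            )
        if self.normalization not in normalize.STRATEGIES:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not 0 < self.top_fraction <= 0.3:
            raise ValueError("top_fraction must lie in (0, 0.3]")
        if not 0 <= self.fraction_threshold < 1:
            raise ValueError("fraction_threshold must lie in [0, 1)")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0 <= self.delta_min < 1:
            raise ValueError("delta_min must lie in [0, 1)")
        if self.dp_min < 0 or self.gq_min < 0 or self.count_threshold < 0:
            raise ValueError("thresholds must be nonnegative")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config YAML must map keys to values")
        return cls.from_dict(data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write report.json + summary.txt."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "thresholds": {
            "method": config.method,
            "normalization": config.normalization,
            "top_fraction": config.top_fraction,
            "fraction_threshold": config.fraction_threshold,
            "count_threshold": config.count_threshold,
            "dp_min": config.dp_min,
            "gq_min": config.gq_min,
            "maf_min": config.maf_min,
            "population": config.population,
        },
    }
    log.info("thresholds applied: %s", report["thresholds"])

    # --- step 1: body-fluid deconvolution -------------------------------
    reference = CountsMatrix.from_tsv(
        config.reference_counts, gene_lengths=config.gene_lengths
    )
    if reference.fluids is None:
        raise ValueError("reference sample names must encode fluids (e.g. VB_1)")
    mixtures = CountsMatrix.from_tsv(config.mixture_counts, gene_lengths=config.gene_lengths)
    mix_name = config.mixture or str(mixtures.samples[0])
    if mix_name not in mixtures.samples:
        raise ValueError(f"mixture column {mix_name!r} not found")

    signature = markers.build_signature(
        reference,
        top_fraction=config.top_fraction,
        normalization=config.normalization,
    )
    de_tables = markers.pairwise_de_tables(
        reference, sorted(reference.fluids.unique())
    )
    _, mix_normed = normalize.normalize_pair(reference, mixtures, config.normalization)
    estimate = deconv.deconvolve(signature, mix_normed[mix_name], method=config.method)
    composition = deconv.call_composition(
        estimate,
        mixture_counts=mixtures.values[mix_name],
        fraction_threshold=config.fraction_threshold,
        count_threshold=config.count_threshold,
    )
    report["mixture"] = mix_name
    report["fractions"] = {k: float(v) for k, v in estimate.fractions.items()}
    report["composition"] = composition.present
    report["n_markers"] = estimate.n_markers

    # --- step 2: donor SNP separation -----------------------------------
    if config.vcf and config.panel:
        panel = PopulationPanel.read(config.panel)
        records = io.read_vcf(config.vcf, gene_bed=config.gene_bed)
        records = snpid.filter_variants(
            records,
            dp_min=config.dp_min,
            gq_min=config.gq_min,
            imprinted_genes=set(config.imprinted_genes),
            editing_sites={(str(c), int(p)) for c, p in config.editing_sites},
        )
        records = snpid.maf_filter(records, panel, config.population, config.maf_min)
        present = composition.fluids_present
        donors_report: dict[str, Any] = {}
        if not 2 <= len(present) <= 4:
            log.warning("composition has %d fluids; SNP separation skipped", len(present))
        else:
            gene_sets = snpid.select_specific_genes(
                de_tables, composition, top_n=config.top_n
            )
            assigned = snpid.assign_snps_to_donor(records, gene_sets)
            ref_geno = (
                pd.read_csv(config.reference_genotypes, sep="\t", index_col=0)
                if config.reference_genotypes
                else None
            )
            for fluid, recs in assigned.items():
                entry: dict[str, Any] = {"n_snps": len(recs)}
                if recs:
                    profile = snpid.group_linked_snps(recs, fluid=fluid)
                    snpid.attach_frequencies(profile, panel, config.population)
                    lr = snpid.rmp_and_lr(profile)
                    entry.update(
                        n_groups=lr.n_groups,
                        log10_rmp=lr.log10_rmp,
                        log10_lr=lr.log10_lr,
                        groups=[
                            {
                                "gene": g.gene_id,
                                "snps": list(g.snp_ids),
                                "genotypes": list(g.genotypes),
                                "frequency": g.frequency,
                            }
                            for g in profile.groups
                        ],
                    )
                    if ref_geno is not None:
                        matches = {}
                        pos_ids = {}
                        for donor in ref_geno.columns:
                            genod = ref_geno[donor]
                            keyed = _genotypes_by_position(genod, panel)
                            rep = snpid.match_against_reference(profile, keyed)
                            matches[donor] = {
                                "concordance": rep.concordance,
                                "n_compared": rep.n_compared,
                                "log10_lr": rep.lr.log10_lr if rep.lr else None,
                            }
                        entry["reference_matches"] = matches
                    if config.run_ancestry:
                        aisnps = ancestry_mod.select_aisnps(
                            recs, panel, config.delta_min, config.r2_max, config.window_bp
                        )
                        if len(aisnps):
                            geno = {  # genotype per AISNP from the record calls
                                snp: r.genotype
                                for snp, r in zip(aisnps.snp_ids, aisnps.records)
                            }
                            est = ancestry_mod.estimate_admixture(geno, aisnps)
                            entry["ancestry"] = {
                                "q": {k: float(v) for k, v in est.q.items()},
                                "n_aisnps": est.n_snps,
                            }
                donors_report[fluid] = entry
        report["donors"] = donors_report

    _write_report(report, out_dir)
    return report


def _genotypes_by_position(dosages: pd.Series, panel: PopulationPanel) -> dict[str, str]:
    """Reference dosages keyed by panel snp_id -> genotype keyed chrom:pos."""
    from .containers import dosage_to_genotype

    meta = panel.snp_meta
    out = {}
    for sid, d in dosages.items():
        if sid in meta.index:
            out[f"{meta.at[sid, 'chrom']}:{meta.at[sid, 'pos']}"] = dosage_to_genotype(d)
    return out


def _write_report(report: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = [
        f"pipeline run {report['config_hash']} (seed {report['seed']})",
        f"mixture: {report.get('mixture', '-')}",
        "estimated fractions:",
    ]
    for fluid, frac in report.get("fractions", {}).items():
        mark = "present" if report["composition"].get(fluid) else "absent"
        lines.append(f"  {fluid}: {frac:.4f} ({mark})")
    for fluid, entry in report.get("donors", {}).items():
        lr = entry.get("log10_lr")
        lines.append(
            f"donor {fluid}: {entry['n_snps']} SNPs"
            + (f", log10 LR = {lr:.2f}" if lr is not None else "")
        )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
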