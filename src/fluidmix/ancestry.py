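"""Biogeographic ancestry from a separated donor SNP profile.

Ancestry-informative SNPs (AISNPs) are selected from the donor's SNPs by
requiring an alt-allele frequency difference > 0.3 between at least one
pair of continental reference populations (the MAF filter is deliberately
NOT applied), followed by the same LD pruning as donor identification.

Admixture proportions are estimated with a supervised maximum-likelihood
model: population allele frequencies are taken as known from the reference
panel and the donor's ancestry fractions q are fit on the simplex by EM
over allele-level responsibilities.  This is a deterministic supervised
substitute for unsupervised MCMC clustering (STRUCTURE-style analysis):
the reference populations are known, so K is fixed to the panel and no
label alignment is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import PopulationPanel, VariantRecord
from .snpid import R2_MAX, WINDOW_BP, _panel_lookup, ld_prune

log = logging.getLogger(__name__)

DELTA_MIN = 0.3
FREQ_CLIP = 1e-4


@dataclass
class AisnpSet:
    """Selected AISNPs with their per-population frequencies."""

    freqs: pd.DataFrame  # snp_id x population
    max_delta: pd.Series  # per-SNP max pairwise |freq difference|
    records: list[VariantRecord]

    @property
    def snp_ids(self) -> pd.Index:
        return self.freqs.index

    def __len__(self) -> int:
        return len(self.freqs)


def select_aisnps(
    records: Sequence[VariantRecord],
    panel: PopulationPanel,
    delta_min: float = DELTA_MIN,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
) -> AisnpSet:
    """AISNPs: max pairwise population allele-frequency difference strictly
    above ``delta_min``, then LD-pruned.  Alt-allele (not MAF) differences."""
    lookup = _panel_lookup(panel)
    pops = panel.populations
    kept: list[VariantRecord] = []
    deltas: dict[str, float] = {}
    for r in records:
        sid = lookup.get((str(r.chrom), int(r.pos)))
        if sid is None:
            continue
        p = panel.freqs.loc[sid, pops].to_numpy(dtype=float)
        delta = float(p.max() - p.min())
        if delta > delta_min:
            kept.append(r)
            deltas[sid] = delta
    pruned = ld_prune(kept, panel, r2_max, window_bp)
    sids = [lookup[(str(r.chrom), int(r.pos))] for r in pruned]
    return AisnpSet(
        freqs=panel.freqs.loc[sids, pops].copy(),
        max_delta=pd.Series({s: deltas[s] for s in sids}),
        records=list(pruned),
    )


@dataclass
class AncestryEstimate:
    """Admixture fractions over the reference populations."""

    q: pd.Series  # simplex over populations
    log_likelihood: float
    n_snps: int
    n_iter: int
    ll_path: list[float]

    @property
    def top_population(self) -> str:
        return str(self.q.idxmax())


def _dosages_from(genotypes, snp_ids) -> np.ndarray:
    code = {"hom_ref": 0, "het": 1, "hom_alt": 2}
    if isinstance(genotypes, Mapping):
        return np.array([
            code.get(genotypes[s], genotypes[s]) if isinstance(genotypes[s], str) else int(genotypes[s])
            for s in snp_ids
        ])
    return np.asarray(genotypes, dtype=int)


def estimate_admixture(
    donor_genotypes: Mapping[str, int | str] | Sequence[int],
    aisnp_set: AisnpSet,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> AncestryEstimate:
    """Supervised admixture maximum likelihood via EM.

    Maximizes sum_s [ g_s log(sum_k q_k p_ks) + (2 - g_s) log(sum_k q_k (1 - p_ks)) ]
    over the simplex, where g_s is the donor's alt dosage and p_ks the
    population allele frequency (clipped away from 0/1 so an observed
    allele can never zero the likelihood).  EM responsibilities are
    computed per allele copy; the log-likelihood is nondecreasing and
    iteration stops when its gain falls below ``tol``.
    """
    if len(aisnp_set) == 0:
        raise ValueError("need at least one AISNP with a genotype")
    P = np.clip(aisnp_set.freqs.to_numpy(dtype=float), FREQ_CLIP, 1 - FREQ_CLIP)
    pops = list(aisnp_set.freqs.columns)
    g = _dosages_from(donor_genotypes, aisnp_set.snp_ids)
    if g.shape[0] != P.shape[0]:
        raise ValueError("genotypes do not cover the AISNP set")
    K = P.shape[1]
    q = np.full(K, 1.0 / K)
    ll_path: list[float] = []
    n_alleles = 2.0 * P.shape[0]
    for it in range(max_iter):
        alt_mix = P @ q  # per-SNP P(alt | q)
        ref_mix = (1.0 - P) @ q
        ll = float(np.sum(g * np.log(alt_mix) + (2 - g) * np.log(ref_mix)))
        ll_path.append(ll)
        if it > 0 and ll - ll_path[-2] < tol:
            break
        # E step: responsibilities per allele copy; M step: average them
        r_alt = (P * q[None, :]) / alt_mix[:, None]
        r_ref = ((1.0 - P) * q[None, :]) / ref_mix[:, None]
        q = (g[:, None] * r_alt + (2 - g)[:, None] * r_ref).sum(axis=0) / n_alleles
        q = np.clip(q, 0.0, None)
        q /= q.sum()
    return AncestryEstimate(
        q=pd.Series(q, index=pops),
        log_likelihood=ll_path[-1],
        n_snps=int(P.shape[0]),
        n_iter=len(ll_path),
        ll_path=ll_path,
    )
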