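"""Shared independent oracles and record builders used across test modules."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd

from fluidmix.containers import VariantRecord
from fluidmix.markers import SignatureMatrix


def make_signature(matrix: np.ndarray, fluids=None) -> SignatureMatrix:
    fluids = fluids or [f"F{i}" for i in range(matrix.shape[1])]
    return SignatureMatrix(
        pd.DataFrame(
            matrix, columns=fluids, index=[f"g{i}" for i in range(matrix.shape[0])]
        )
    )


def make_record(
    chrom="5", pos=100, genotype="het", dp=100, gq=80, gene="gA", ref="A", alt="G"
) -> VariantRecord:
    alt_d = {"hom_ref": 0, "het": dp // 2, "hom_alt": dp, "no_call": 0}[genotype]
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
        dp=dp, gq=gq, ad=(dp - alt_d, alt_d), gene_id=gene,
    )


def grid_search_2fluid(sig: SignatureMatrix, mixture: pd.Series, step=1e-4):
    """Exhaustive fraction search with the overall scale profiled out
    (matches the fit-then-renormalize convention of the cone solvers)."""
    S = sig.values.to_numpy()
    m = mixture.to_numpy()
    best, best_sse = None, np.inf
    for w1 in np.arange(0.0, 1.0 + step / 2, step):
        w = np.array([w1, 1.0 - w1])
        sw = S @ w
        c = max(float(sw @ m) / float(sw @ sw), 0.0)
        sse = np.sum((c * sw - m) ** 2)
        if sse < best_sse:
            best, best_sse = w, sse
    return best


def grid_search_2fluid_simplex(sig: SignatureMatrix, mixture: pd.Series, step=1e-4):
    """Exhaustive SSE search over the simplex at unit scale (for the
    sum-constrained quadratic program)."""
    S = sig.values.to_numpy()
    m = mixture.to_numpy()
    best, best_sse = None, np.inf
    for w1 in np.arange(0.0, 1.0 + step / 2, step):
        w = np.array([w1, 1.0 - w1])
        sse = np.sum((S @ w - m) ** 2)
        if sse < best_sse:
            best, best_sse = w, sse
    return best


def hwe_enumeration_oracle(n_aa, n_ab, n_bb) -> float:
    """Exact-rational enumeration of the conditional heterozygote
    distribution given the allele counts (brute-force oracle)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c),
        )
    total = sum(weights.values())
    p_obs = weights[n_ab] / total
    return float(sum(w for w in weights.values() if w / total <= p_obs) / total)
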