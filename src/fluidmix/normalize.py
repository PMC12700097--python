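"""Expression scalings compared in the deconvolution benchmark.

Five strategies: raw counts, FPKM, TPM, DESeq2-style median-of-ratios size
factors, and edgeR-style TMM. The same strategy must be applied to the
reference panel and the mixture column; the pipeline enforces that contract.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CountsMatrix

log = logging.getLogger(__name__)

STRATEGIES = ("raw", "FPKM", "TPM", "size_factor", "TMM")


def _as_frame(counts: CountsMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.values if isinstance(counts, CountsMatrix) else counts


def _lengths(counts: CountsMatrix | pd.DataFrame, gene_lengths: pd.Series | None) -> pd.Series:
    if gene_lengths is None and isinstance(counts, CountsMatrix):
        gene_lengths = counts.gene_lengths
    if gene_lengths is None:
        raise ValueError("gene lengths are required for FPKM/TPM")
    return gene_lengths.reindex(_as_frame(counts).index)


def _warn_zero_columns(frame: pd.DataFrame) -> pd.Index:
    zero = frame.columns[frame.sum(axis=0) == 0]
    if len(zero):
        log.warning("all-zero columns left as zero vectors: %s", list(zero))
    return zero


def tpm(counts: CountsMatrix | pd.DataFrame, gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts per million: length-rate normalized, columns sum to 1e6."""
    frame = _as_frame(counts)
    lengths_kb = _lengths(counts, gene_lengths) / 1e3
    rate = frame.div(lengths_kb, axis=0)
    totals = rate.sum(axis=0)
    _warn_zero_columns(frame)
    totals = totals.replace(0, np.nan)
    out = rate.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def fpkm(counts: CountsMatrix | pd.DataFrame, gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads."""
    frame = _as_frame(counts)
    lengths = _lengths(counts, gene_lengths)
    totals = frame.sum(axis=0)
    _warn_zero_columns(frame)
    totals = totals.replace(0, np.nan)
    out = frame.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return out.fillna(0.0)


def size_factor_norm(
    counts: CountsMatrix | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalization.

    The per-gene reference is the geometric mean across samples (genes with
    any zero excluded); each sample's size factor is the median ratio of its
    counts to that reference, and the output is counts / size factor.
    """
    frame = _as_frame(counts)
    usable = (frame > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = frame.loc[usable]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.log(sub).sub(log_ref, axis=0).median(axis=0))
    return frame.div(factors, axis=1), factors


def _upper_quartile_reference(frame: pd.DataFrame) -> str:
    scaled = frame.div(frame.sum(axis=0), axis=1)
    uq = scaled.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    counts: CountsMatrix | pd.DataFrame,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
    a_cutoff: float = -1e10,
) -> pd.Series:
    """Trimmed mean of M-values scaling factors (edgeR defaults).

    Library-size-scaled log ratios (M) against a reference sample are
    trimmed 30% on M and 5% on A, averaged with inverse-variance weights,
    and the resulting factors rescaled to geometric mean 1.  The reference
    is the sample whose upper quartile is closest to the mean upper quartile.
    """
    frame = _as_frame(counts)
    if frame.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = frame.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("TMM undefined for all-zero samples")
    if ref_sample is None:
        ref_sample = _upper_quartile_reference(frame)
    ref = frame[ref_sample].to_numpy(dtype=float)
    nref = lib[ref_sample]
    factors = {}
    for col in frame.columns:
        if col == ref_sample:
            factors[col] = 1.0
            continue
        obs = frame[col].to_numpy(dtype=float)
        nobs = lib[col]
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep] / nobs, ref[keep] / nref
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        finite = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
        m, a = m[finite], a[finite]
        o, r = o[finite], r[finite]
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            factors[col] = 1.0
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep2.any():
            factors[col] = 1.0
            continue
        if weighted:
            w = 1.0 / ((1 - o) / (o * nobs) + (1 - r) / (r * nref))
            f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
        else:
            f = np.mean(m[keep2])
        factors[col] = 2.0 ** f
    out = pd.Series(factors).reindex(frame.columns)
    out /= np.exp(np.log(out).mean())
    return out


def tmm_norm(counts: CountsMatrix | pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Counts scaled by effective library size (library size x TMM factor),
    expressed per million (edgeR-style CPM on TMM-corrected libraries)."""
    frame = _as_frame(counts)
    factors = tmm_factors(counts, **kwargs)
    eff_lib = frame.sum(axis=0) * factors
    return frame.div(eff_lib, axis=1) * 1e6


def apply_normalization(
    counts: CountsMatrix | pd.DataFrame,
    strategy: str,
    gene_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Dispatch one of the five scalings; ``raw`` is the identity."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown normalization {strategy!r}; choose from {STRATEGIES}")
    frame = _as_frame(counts)
    if strategy == "raw":
        return frame.copy()
    if strategy == "TPM":
        return tpm(counts, gene_lengths)
    if strategy == "FPKM":
        return fpkm(counts, gene_lengths)
    if strategy == "size_factor":
        if frame.shape[1] == 1:
            return frame.copy()
        return size_factor_norm(counts)[0]
    return tmm_norm(counts)


def normalize_pair(
    reference: CountsMatrix,
    mixture: CountsMatrix | pd.DataFrame,
    strategy: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the SAME strategy to a reference panel and mixture matrix.

    Between-sample strategies (size_factor, TMM) need several samples to
    estimate factors, so reference and mixture columns are normalized
    jointly on the shared gene set, then split back apart.
    """
    mix_frame = _as_frame(mixture)
    ref_frame = reference.values
    genes = ref_frame.index.intersection(mix_frame.index)
    ref_frame = ref_frame.loc[genes]
    mix_frame = mix_frame.loc[genes]
    if strategy in ("size_factor", "TMM"):
        joint = pd.concat([ref_frame, mix_frame], axis=1)
        normed = apply_normalization(joint, strategy)
        return normed[ref_frame.columns], normed[mix_frame.columns]
    lengths = reference.gene_lengths
    return (
        apply_normalization(ref_frame, strategy, lengths),
        apply_normalization(mix_frame, strategy, lengths),
    )
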