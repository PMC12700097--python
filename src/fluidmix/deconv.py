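"""Body-fluid read-fraction estimation from a mixture expression profile.

The mixture vector m (restricted to marker genes) is regressed on the
signature matrix S, m ~ S w, and the nonnegative coefficients are
renormalized to the simplex.  Four solvers are provided:

* ``NNLS``     - nonnegative least squares (active set);
* ``RLR``      - Huber M-estimation (IRLS), negatives truncated;
* ``FARDEEP``  - adaptive trimmed NNLS: alternately fit and drop genes
  whose squared residual exceeds a multiple of the retained mean, a
  least-trimmed-squares scheme that makes raw-count deconvolution robust
  to outlier transcripts (hemoglobin-type dominance);
* ``QP``       - least squares constrained to the probability simplex.

Scoring (RMSE, Pearson R per fluid across mixtures), composition calling
with the >5% rule and BFID-marker override, and the full
method x normalization benchmark grid live here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .containers import BFID_MARKERS, CountsMatrix
from .markers import SignatureMatrix, build_signature
from .normalize import STRATEGIES, normalize_pair

log = logging.getLogger(__name__)

METHODS = ("NNLS", "RLR", "FARDEEP", "QP")

#: Estimated fraction above which a fluid is called present (strict ">").
PRESENCE_THRESHOLD = 0.05
#: Raw-count floor below which a BFID marker counts as unexpressed.
BFID_COUNT_THRESHOLD = 10


@dataclass
class ProportionEstimate:
    """Per-fluid estimated read fractions with provenance."""

    fractions: pd.Series  # simplex over fluids
    method: str
    normalization: str = "raw"
    raw_coefficients: pd.Series | None = None
    residual_norm: float = float("nan")
    n_markers: int = 0
    converged: bool = True
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.fractions < 0).any():
            raise ValueError("fractions must be nonnegative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def finalize_fractions(raw: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Rescale nonnegative coefficients to sum to 1."""
    arr = np.asarray(raw, dtype=float)
    if (arr < 0).any():
        raise ValueError("raw coefficients must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all coefficients are zero; fractions undefined")
    out = arr / total
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index)
    return out


def _prepare(signature: SignatureMatrix, mixture: pd.Series) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    genes = signature.marker_genes
    missing = genes.difference(mixture.index)
    if len(missing):
        raise ValueError(f"mixture lacks {len(missing)} marker genes")
    S = signature.values.to_numpy(dtype=float)
    m = mixture.reindex(genes).to_numpy(dtype=float)
    if S.shape[0] < S.shape[1]:
        raise ValueError("need at least as many marker genes as fluids")
    return S, m, genes


def _estimate(
    signature: SignatureMatrix,
    coef: np.ndarray,
    resid_norm: float,
    method: str,
    n_markers: int,
    **extra,
) -> ProportionEstimate:
    raw = pd.Series(coef, index=signature.fluids)
    return ProportionEstimate(
        fractions=finalize_fractions(raw),
        method=method,
        raw_coefficients=raw,
        residual_norm=float(resid_norm),
        n_markers=n_markers,
        **extra,
    )


def nnls_fit(signature: SignatureMatrix, mixture: pd.Series) -> ProportionEstimate:
    """Nonnegative least squares: argmin ||S w - m||^2 s.t. w >= 0."""
    S, m, genes = _prepare(signature, mixture)
    try:
        coef, rnorm = optimize.nnls(S, m)
    except Exception:  # rank-deficient pathological systems
        log.warning("NNLS solver failed; falling back to truncated pseudo-inverse")
        coef = np.clip(np.linalg.pinv(S) @ m, 0.0, None)
        rnorm = float(np.linalg.norm(S @ coef - m))
    if np.linalg.matrix_rank(S) < S.shape[1]:
        log.warning("signature is rank deficient; coefficients not unique")
    return _estimate(signature, coef, rnorm, "NNLS", len(genes))


def rlr_fit(
    signature: SignatureMatrix,
    mixture: pd.Series,
    tuning: float = 1.345,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ProportionEstimate:
    """Huber robust linear regression, negatives truncated to zero.

    IRLS with Huber's psi (tuning constant 1.345 x the MAD-based robust
    scale); the unconstrained robust coefficients are clipped at zero and
    renormalized.
    """
    S, m, genes = _prepare(signature, mixture)
    if not m.any():
        raise ValueError("all-zero mixture vector; fractions undefined")
    model = sm.RLM(m, S, M=sm.robust.norms.HuberT(t=tuning))
    res = model.fit(scale_est="mad", conv="coefs", tol=tol, maxiter=max_iter)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        log.warning("RLR did not converge in %d iterations; returning last iterate", max_iter)
    coef = np.clip(res.params, 0.0, None)
    rnorm = float(np.linalg.norm(S @ coef - m))
    return _estimate(signature, coef, rnorm, "RLR", len(genes), converged=converged)


def fardeep_fit(
    signature: SignatureMatrix,
    mixture: pd.Series,
    k_outlier: float = 10.0,
    max_iter: int = 20,
) -> ProportionEstimate:
    """Adaptive trimmed NNLS in the spirit of least-trimmed-squares robust
    deconvolution.

    Alternates (1) NNLS on the retained genes with (2) dropping genes whose
    squared residual exceeds ``k_outlier`` times the mean squared residual
    of the retained set, until stable or ``max_iter``; the final NNLS refit
    is reported together with the dropped-gene list.
    """
    if k_outlier <= 1:
        raise ValueError("k_outlier must exceed 1")
    S, m, genes = _prepare(signature, mixture)
    retained = np.ones(len(genes), dtype=bool)
    floor = 1e-12 * float(np.mean(np.square(m)))  # exact fits trim nothing
    for _ in range(max_iter):
        coef, _ = optimize.nnls(S[retained], m[retained])
        resid2 = np.square(S @ coef - m)
        cutoff = k_outlier * max(resid2[retained].mean(), floor)
        new_retained = retained & (resid2 <= cutoff)
        if new_retained.sum() < S.shape[1]:
            break
        if (new_retained == retained).all():
            retained = new_retained
            break
        retained = new_retained
    if retained.sum() < S.shape[1]:
        raise ValueError("trimming removed too many genes to fit")
    coef, rnorm = optimize.nnls(S[retained], m[retained])
    dropped = [g for g, keep in zip(genes, retained) if not keep]
    return _estimate(
        signature, coef, rnorm, "FARDEEP", int(retained.sum()), dropped_genes=dropped
    )


def qp_fit(
    signature: SignatureMatrix, mixture: pd.Series, tol: float = 1e-12
) -> ProportionEstimate:
    """Least squares constrained to the probability simplex (quadratic
    program): argmin ||S w - m||^2 s.t. w >= 0, sum w = 1.

    S and m share a single scale factor for conditioning, which preserves
    the constrained solution.
    """
    S, m, genes = _prepare(signature, mixture)
    scale = np.abs(S).max()
    if scale == 0:
        raise ValueError("zero signature")
    Ss, ms = S / scale, m / scale
    n = S.shape[1]
    H = Ss.T @ Ss
    f = Ss.T @ ms

    def objective(w):
        r = Ss @ w - ms
        return 0.5 * float(r @ r)

    def grad(w):
        return H @ w - f

    w0 = np.full(n, 1.0 / n)
    res = optimize.minimize(
        objective,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(n)}],
        options={"ftol": tol, "maxiter": 500},
    )
    coef = np.clip(res.x, 0.0, None)
    rnorm = float(np.linalg.norm(S @ (coef / coef.sum()) - m)) if coef.sum() else float("nan")
    return _estimate(signature, coef, rnorm, "QP", len(genes), converged=bool(res.success))


_FITTERS = {"NNLS": nnls_fit, "RLR": rlr_fit, "FARDEEP": fardeep_fit, "QP": qp_fit}


def deconvolve(
    signature: SignatureMatrix, mixture: pd.Series, method: str = "FARDEEP", **kwargs
) -> ProportionEstimate:
    """Run one deconvolution method by name (registry: NNLS/RLR/FARDEEP/QP)."""
    if method not in _FITTERS:
        raise ValueError(
            f"method {method!r} is not implemented; registry: {sorted(_FITTERS)}"
        )
    est = _FITTERS[method](signature, mixture, **kwargs)
    return est


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def rmse(expected: Sequence[float], observed: Sequence[float]) -> float:
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean(np.square(e - o))))


def pearson_r(expected: Sequence[float], observed: Sequence[float]) -> float:
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or e.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    if e.std() == 0 or o.std() == 0:
        log.warning("zero variance; Pearson R undefined")
        return float("nan")
    return float(stats.pearsonr(e, o)[0])


# ---------------------------------------------------------------------------
# composition calling
# ---------------------------------------------------------------------------

@dataclass
class CompositionCall:
    """Present/absent decision per fluid with the supporting evidence."""

    present: dict[str, bool]
    evidence: pd.DataFrame  # fluid x (fraction, marker_max_count, overridden)

    @property
    def fluids_present(self) -> list[str]:
        return [f for f, p in self.present.items() if p]


def call_composition(
    estimate: ProportionEstimate,
    mixture_counts: pd.Series | None = None,
    bfid_table: Mapping[str, Sequence[str]] | None = None,
    fraction_threshold: float = PRESENCE_THRESHOLD,
    count_threshold: int = BFID_COUNT_THRESHOLD,
    override_fluids: Sequence[str] = ("SA",),
) -> CompositionCall:
    """Call which fluids are present in the mixture.

    A fluid is present iff its estimated fraction exceeds
    ``fraction_threshold`` (strict).  For fluids in ``override_fluids``
    (saliva by default), a presence call is overridden to absent when ALL
    of that fluid's BFID marker genes have raw counts below
    ``count_threshold`` - the expression-evidence veto that rescues the
    specificity of saliva calls.
    """
    if bfid_table is None:
        bfid_table = BFID_MARKERS
    present: dict[str, bool] = {}
    rows = []
    for fluid, frac in estimate.fractions.items():
        is_present = frac > fraction_threshold
        overridden = False
        marker_max = np.nan
        if is_present and fluid in override_fluids and mixture_counts is not None:
            markers = [g for g in bfid_table.get(fluid, ()) if g in mixture_counts.index]
            if not markers:
                log.warning("BFID markers for %s absent from counts; override skipped", fluid)
            else:
                marker_counts = mixture_counts.loc[markers]
                marker_max = float(marker_counts.max())
                if (marker_counts < count_threshold).all():
                    is_present = False
                    overridden = True
        present[fluid] = bool(is_present)
        rows.append(
            {
                "fluid": fluid,
                "fraction": float(frac),
                "marker_max_count": marker_max,
                "overridden": overridden,
            }
        )
    if not any(present.values()):
        log.warning("no fluid exceeds the presence threshold; empty composition")
    return CompositionCall(present=present, evidence=pd.DataFrame(rows).set_index("fluid"))


def confusion_stats(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity and accuracy from confusion counts (in %)."""
    sn = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    return {"sensitivity": sn, "specificity": sp, "accuracy": acc}


# ---------------------------------------------------------------------------
# benchmark grid
# ---------------------------------------------------------------------------

def estimate_bundle(
    bundle,
    method: str = "FARDEEP",
    normalization: str = "raw",
    top_fraction: float = 0.04,
    signature: SignatureMatrix | None = None,
) -> pd.DataFrame:
    """Estimate fractions for every mixture of a synthetic bundle.

    Returns a design x fluid DataFrame aligned with
    ``bundle.truth_proportions``.
    """
    if signature is None:
        signature = build_signature(
            bundle.reference_counts, top_fraction=top_fraction, normalization=normalization
        )
    _, mix_normed = normalize_pair(bundle.reference_counts, bundle.mixture_counts, normalization)
    rows = {}
    for name in bundle.mixture_counts.samples:
        est = deconvolve(signature, mix_normed[name], method=method)
        rows[name] = est.fractions
    out = pd.DataFrame(rows).T
    return out.reindex(columns=bundle.truth_proportions.columns, fill_value=0.0)


def evaluate_grid(
    bundle,
    methods: Sequence[str] = METHODS,
    normalizations: Sequence[str] = STRATEGIES,
    top_fractions: Sequence[float] = (0.10,),
    fraction_threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Benchmark every method x normalization x marker-fraction combination.

    For each combination and fluid: RMSE and Pearson R between true and
    estimated fractions across mixtures, plus presence/absence confusion
    counts at the fraction threshold.
    """
    truth = bundle.truth_proportions
    records = []
    for top_fraction in top_fractions:
        for normalization in normalizations:
            signature = build_signature(
                bundle.reference_counts,
                top_fraction=top_fraction,
                normalization=normalization,
            )
            for method in methods:
                est = estimate_bundle(
                    bundle, method=method, normalization=normalization, signature=signature
                )
                for fluid in truth.columns:
                    t = truth[fluid].to_numpy()
                    o = est[fluid].to_numpy()
                    truly = t > 0
                    called = o > fraction_threshold
                    tp = int((truly & called).sum())
                    tn = int((~truly & ~called).sum())
                    fp = int((~truly & called).sum())
                    fn = int((truly & ~called).sum())
                    rec = {
                        "method": method,
                        "normalization": normalization,
                        "top_fraction": top_fraction,
                        "fluid": fluid,
                        "rmse": rmse(t, o),
                        "pearson_r": pearson_r(t, o) if np.std(t) > 0 else float("nan"),
                        "tp": tp,
                        "tn": tn,
                        "fp": fp,
                        "fn": fn,
                    }
                    rec.update(confusion_stats(tp, tn, fp, fn))
                    records.append(rec)
    return pd.DataFrame(records)
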