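"""Variance-component heritability from genome-wide genotypes.

Workflow: build genetic relationship matrices (GRMs) from standardized
genotypes, stratify variants into 7 MAF bins each split at its median
windowed LD score (14 components in the full design), estimate the variance
attached to each component by restricted maximum likelihood with Fisher
scoring, and convert the observed-scale case/control estimate to the
liability scale at lifetime risk K.

The REML log-likelihood, score and expected information use the standard
projection-matrix identities; a single-GRM model takes an exact
eigendecomposition fast path so that large single-component fits cost one
eigendecomposition plus O(n) iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GRMatrix",
    "BinPartition",
    "HeritabilityFit",
    "compute_grm",
    "ld_scores",
    "assign_bins",
    "reml_fit",
    "observed_to_liability",
    "MAF_BIN_EDGES",
]

# MAF bin boundaries, half-open on the left, closed on the right; the first
# bin additionally includes its left endpoint (the global MAF floor).
MAF_BIN_EDGES = (0.0007, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class GRMatrix:
    values: np.ndarray
    n_variants: int
    sample_ids: list

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self._eigen: tuple | None = None

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (used by the single-GRM REML path)."""
        if self._eigen is None:
            w, U = np.linalg.eigh(self.values)
            self._eigen = (np.maximum(w, 0.0), U)
        return self._eigen


@dataclass
class BinPartition:
    """Per-variant MAF x LD bin labels."""

    labels: pd.DataFrame  # columns: maf_bin (int), ld_bin ("lowLD"/"highLD"), bin
    included: np.ndarray  # bool mask of variants that entered a bin


@dataclass
class HeritabilityFit:
    variances: np.ndarray  # per-component genetic variances
    residual_variance: float
    se: np.ndarray  # SE per component + residual (last)
    h2_observed: float
    h2_observed_se: float
    h2_liability: float | None = None
    h2_liability_se: float | None = None
    prevalence_k: float | None = None
    case_proportion: float | None = None
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan
    component_names: list = field(default_factory=list)


def compute_grm(
    genotypes: np.ndarray,
    mafs: np.ndarray | None = None,
    sample_ids: list | None = None,
) -> GRMatrix:
    """Genetic relationship matrix from standardized genotypes.

    ``A_jk = mean_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))`` with
    residual missingness mean-imputed per variant before standardization.
    Monomorphic variants raise (zero standardizing variance).
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    miss = G < 0
    if miss.any():
        G = G.copy()
        G[miss] = np.nan
    if mafs is None:
        p = np.nanmean(G, axis=0) / 2
    else:
        p = np.asarray(mafs, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic variant in GRM input (frequency 0 or 1)")
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z = np.where(np.isnan(Z), 0.0, Z)
    A = (Z @ Z.T) / m
    ids = sample_ids if sample_ids is not None else list(range(n))
    return GRMatrix(values=A, n_variants=m, sample_ids=list(ids))


def ld_scores(
    genotypes: np.ndarray,
    positions: np.ndarray,
    window_kb: float = 10000.0,
    rsq_cutoff: float = 0.0,
    block: int = 512,
) -> np.ndarray:
    """Windowed LD score per variant.

    ``score_i = sum_j r^2(i, j)`` over variants j within ``window_kb`` of
    variant i (self included, so every score is >= 1), with r-squared values
    below ``rsq_cutoff`` ignored (default 0: none ignored). Positions must
    be sorted; variants are assumed to lie on one chromosome per call.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if m != pos.size:
        raise ValueError("positions do not match genotype columns")
    sd = G.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic variant in LD score input")
    Z = (G - G.mean(axis=0)) / sd
    window = int(window_kb * 1000)
    scores = np.zeros(m)
    for lo in range(0, m, block):
        hi = min(lo + block, m)
        j0 = np.searchsorted(pos, pos[lo] - window, side="left")
        j1 = np.searchsorted(pos, pos[hi - 1] + window, side="right")
        r = (Z[:, lo:hi].T @ Z[:, j0:j1]) / n
        r2 = r * r
        if rsq_cutoff > 0:
            r2[r2 < rsq_cutoff] = 0.0
        in_win = np.abs(pos[None, j0:j1] - pos[lo:hi, None]) <= window
        scores[lo:hi] = (r2 * in_win).sum(axis=1)
    return scores


def assign_bins(mafs: np.ndarray, ld: np.ndarray) -> BinPartition:
    """Assign each variant a joint MAF x LD bin.

    Seven MAF bins on (0.0007, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5],
    left-open/right-closed with MAF exactly at the floor included in bin 1;
    each MAF bin is split at its own median LD score (low: < median, high:
    >= median).  Variants below the floor are excluded with a warning; empty
    bins are dropped.
    """
    maf = np.asarray(mafs, dtype=float)
    ldv = np.asarray(ld, dtype=float)
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("MAF must be in (0, 0.5]")
    included = maf >= MAF_BIN_EDGES[0]
    if (~included).any():
        logger.warning("%d variants below the MAF floor excluded", int((~included).sum()))
    maf_bin = np.full(maf.size, -1)
    edges = MAF_BIN_EDGES
    for b in range(7):
        lo, hi = edges[b], edges[b + 1]
        sel = (maf > lo) & (maf <= hi)
        if b == 0:
            sel |= maf == lo
        maf_bin[sel & included] = b + 1
    ld_bin = np.array([""] * maf.size, dtype=object)
    for b in range(1, 8):
        sel = maf_bin == b
        if not sel.any():
            logger.warning("MAF bin %d is empty; dropped", b)
            continue
        med = np.median(ldv[sel])
        ld_bin[sel] = np.where(ldv[sel] >= med, "highLD", "lowLD")
    labels = pd.DataFrame({"maf_bin": maf_bin, "ld_bin": ld_bin})
    labels["bin"] = np.where(
        maf_bin > 0,
        "maf" + labels["maf_bin"].astype(str) + "_" + labels["ld_bin"].astype(str),
        "",
    )
    return BinPartition(labels=labels, included=included & (maf_bin > 0))


# ---------------------------------------------------------------------------
# REML


def reml_fit(
    phenotype: np.ndarray,
    grms: list,
    covariates: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    component_names: list | None = None,
    prevalence_k: float | None = None,
) -> HeritabilityFit:
    """Restricted maximum likelihood variance components by Fisher scoring.

    ``grms`` is a list of GRMatrix (or raw symmetric arrays) over an
    identical sample set.  The model is ``y ~ N(Xb, sum_i s2_i G_i + s2_e I)``
    with the covariate matrix (plus intercept) as fixed effects.  Negative
    component updates are constrained to a small non-negative floor; SEs come
    from the inverse expected information.  When ``prevalence_k`` is given
    and the phenotype is binary 0/1, the observed-scale h2 is also reported
    on the liability scale.

    Single-GRM models use an exact eigendecomposition fast path.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    mats = [g.values if isinstance(g, GRMatrix) else np.asarray(g, float) for g in grms]
    for g in mats:
        if g.shape != (n, n):
            raise ValueError("all GRMs must be n x n over the phenotype samples")
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    k = len(mats)

    if k == 1:
        if isinstance(grms[0], GRMatrix):
            eig = grms[0].eigen()
        else:
            w, U = np.linalg.eigh(mats[0])
            eig = (np.maximum(w, 0.0), U)
        theta, se_theta, ll, converged, it = _reml_single_eigen(
            y, eig, X, max_iter, tol
        )
    else:
        theta, se_theta, ll, converged, it = _reml_dense(y, mats, X, max_iter, tol)

    var_g = theta[:-1]
    var_e = theta[-1]
    total = theta.sum()
    h2 = float(var_g.sum() / total)
    # delta method for h2 = sum(g)/total using the full information inverse
    grad = np.empty(k + 1)
    grad[:k] = (total - var_g.sum()) / total**2
    grad[k] = -var_g.sum() / total**2
    cov_theta = se_theta["cov"]
    h2_se = float(np.sqrt(max(grad @ cov_theta @ grad, 0.0)))

    fit = HeritabilityFit(
        variances=var_g,
        residual_variance=float(var_e),
        se=np.sqrt(np.maximum(np.diag(cov_theta), 0.0)),
        h2_observed=h2,
        h2_observed_se=h2_se,
        converged=converged,
        n_iter=it,
        loglik=ll,
        component_names=list(component_names or [f"G{i+1}" for i in range(k)]),
    )
    uniq = set(np.unique(y))
    if prevalence_k is not None and uniq <= {0.0, 1.0}:
        P = float(y.mean())
        factor = _liability_factor(prevalence_k, P)
        fit.h2_liability = h2 * factor
        fit.h2_liability_se = h2_se * factor
        fit.prevalence_k = prevalence_k
        fit.case_proportion = P
    return fit


def _reml_single_eigen(y, eig, X, max_iter, tol):
    """Exact REML for one GRM + residual via eigendecomposition of G."""
    n = y.size
    w, U = eig
    yt = U.T @ y
    Xt = U.T @ X
    var_y = float(np.var(y))
    theta = np.array([var_y / 2, var_y / 2])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = theta[0] * w + theta[1]
        d = np.maximum(d, 1e-12)
        Winv = 1.0 / d
        WX = Xt * Winv[:, None]
        XtViX = Xt.T @ WX
        XtViX_inv = np.linalg.inv(XtViX)
        Py = yt * Winv - WX @ (XtViX_inv @ (WX.T @ yt))
        ll = -0.5 * (
            np.log(d).sum()
            + np.linalg.slogdet(XtViX)[1]
            + float(yt @ Py)
        )
        # score and expected information for (s2_g, s2_e); G has spectrum w
        diags = (w, np.ones(n))
        score = np.empty(2)
        info = np.empty((2, 2))
        # tr(P D_i) = tr(Winv D_i) - tr(XtViX_inv * X' Winv D_i Winv X)
        for i, di in enumerate(diags):
            tr_PD = float((Winv * di).sum()) - float(
                np.trace(XtViX_inv @ (WX.T @ (di[:, None] * WX)))
            )
            score[i] = -0.5 * (tr_PD - float(Py @ (di * Py)))
        for i, di in enumerate(diags):
            for j, dj in enumerate(diags):
                if j < i:
                    continue
                # tr(P D_i P D_j) with P = Winv - WX XtViX_inv WX'
                t1 = float((Winv * di * Winv * dj).sum())
                M1 = WX.T @ ((di * dj * Winv)[:, None] * WX)
                t2 = float(np.trace(XtViX_inv @ M1))
                M2 = WX.T @ (di[:, None] * WX)
                M3 = WX.T @ (dj[:, None] * WX)
                t3 = float(np.trace(XtViX_inv @ M2 @ XtViX_inv @ M3))
                info[i, j] = info[j, i] = 0.5 * (t1 - 2 * t2 + t3)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        theta = np.maximum(theta + step, 0.0)
        if theta.sum() == 0:
            theta[:] = 1e-8
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    cov = _safe_inv(info)
    return theta, {"cov": cov}, ll, converged, it


def _reml_dense(y, mats, X, max_iter, tol):
    """Fisher-scoring REML with explicit V for multiple components."""
    n = y.size
    k = len(mats)
    var_y = float(np.var(y))
    theta = np.full(k + 1, var_y / (k + 1))
    comps = mats + [np.eye(n)]
    ll_old = -np.inf
    converged = False
    it = 0
    info = np.eye(k + 1)
    for it in range(1, max_iter + 1):
        V = sum(t * M for t, M in zip(theta, comps))
        try:
            c, low = _cho(V)
        except np.linalg.LinAlgError:
            theta = np.maximum(theta, 1e-8)
            V = sum(t * M for t, M in zip(theta, comps))
            c, low = _cho(V)
        from scipy.linalg import cho_solve

        Vinv = cho_solve((c, low), np.eye(n))
        Vinv_X = Vinv @ X
        XtViX = X.T @ Vinv_X
        XtViX_inv = np.linalg.inv(XtViX)
        P = Vinv - Vinv_X @ XtViX_inv @ Vinv_X.T
        Py = P @ y
        logdetV = 2 * np.log(np.diag(c)).sum()
        ll = -0.5 * (logdetV + np.linalg.slogdet(XtViX)[1] + float(y @ Py))
        PM = [P @ M for M in comps]
        score = np.array(
            [-0.5 * (np.trace(PM[i]) - float(Py @ comps[i] @ Py)) for i in range(k + 1)]
        )
        info = np.array(
            [
                [0.5 * np.sum(PM[i] * PM[j].T) for j in range(k + 1)]
                for i in range(k + 1)
            ]
        )
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        theta = np.maximum(theta + step, 0.0)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    cov = _safe_inv(info)
    if not converged:
        logger.warning("REML did not converge in %d iterations (dLL=%.3g)",
                       it, ll - ll_old)
    return theta, {"cov": cov}, ll, converged, it


def _cho(V):
    from scipy.linalg import cho_factor

    return cho_factor(V, lower=True)


def _safe_inv(M):
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M)


def _liability_factor(K: float, P: float) -> float:
    z = stats.norm.pdf(stats.norm.ppf(1 - K))
    return K * K * (1 - K) ** 2 / (z * z * P * (1 - P))


def observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale case/control h2 to the liability scale.

    ``h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P))`` where z is the
    standard-normal density at the liability threshold for prevalence K and
    P is the sample case proportion.  With P = K this reduces to the
    unascertained correction ``K (1-K) / z^2``.
    """
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must be in (0, 1)")
    return h2_obs * _liability_factor(K, P)
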