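"""Candidate adaptive locus detection (genotype-environment association).

Three structure-aware outlier scans plus a consensus rule:

* ``rdadapt`` — Mahalanobis distance of each locus's loadings on the
  leading axes of an environment-constrained RDA, with a genomic inflation
  factor and Benjamini–Hochberg q-values;
* ``pcadapt_like`` — per-locus regression on the leading principal
  components of overall genetic variation (loci unusually correlated with
  neutral structure);
* ``lfmm_like`` — latent factor mixed model: per-locus F-test of all
  environmental coefficients while controlling K latent factors estimated
  from the residual genetic structure.

Candidates retained by at least ``min_methods`` scans form the consensus
set used by the downstream adaptively enriched RDA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genio import GenotypeMatrix
from .ordination import OrdinationModel
from .popstruct import pca_genotypes

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "MethodResult",
    "rdadapt",
    "pcadapt_like",
    "lfmm_like",
    "consensus",
    "bh_qvalues",
]


@dataclass
class MethodResult:
    """Per-locus scan result of one GEA method."""

    method: str
    statistic: np.ndarray   # D² or F, nan where undefined
    p: np.ndarray
    q: np.ndarray
    hits: np.ndarray        # boolean, q < alpha
    inflation: float | None = None
    alpha: float = 0.05

    def hit_indices(self) -> np.ndarray:
        return np.flatnonzero(self.hits)


@dataclass
class CandidateSet:
    """Results of all methods plus the consensus locus set."""

    methods: dict[str, MethodResult]
    consensus_idx: np.ndarray
    min_methods: int

    def counts(self) -> dict[str, int]:
        out = {m: int(r.hits.sum()) for m, r in self.methods.items()}
        out["consensus"] = int(len(self.consensus_idx))
        return out

    def union_idx(self) -> np.ndarray:
        sets = [set(r.hit_indices().tolist()) for r in self.methods.values()]
        return np.array(sorted(set().union(*sets)), dtype=int)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; nan entries stay nan."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _mahalanobis_scan(scores: np.ndarray, df: int, alpha: float,
                      method: str) -> MethodResult:
    """Shared tail of rdadapt/pcadapt: Mahalanobis D², λ, χ² p, BH q.

    ``scores`` is loci x df with nan rows excluded from the covariance and
    from the inflation factor. The covariance across loci is estimated
    robustly (minimum covariance determinant) so that genuine outliers do
    not inflate it and mask themselves.
    """
    from sklearn.covariance import MinCovDet

    L = scores.shape[0]
    d2 = np.full(L, np.nan)
    ok = np.isfinite(scores).all(axis=1)
    S = scores[ok]
    if len(S) > 50:
        mcd = MinCovDet(random_state=0).fit(S)
        center, cov = mcd.location_, mcd.covariance_
    else:
        center, cov = S.mean(axis=0), np.cov(S, rowvar=False)
    cov = np.atleast_2d(cov)
    icov = np.linalg.pinv(cov)
    dev = S - center
    d2[ok] = np.einsum("ij,jk,ik->i", dev, icov, dev)
    lam, df_eff = _empirical_null(d2[ok], df)
    p = np.full(L, np.nan)
    p[ok] = stats.chi2.sf(d2[ok] / lam, df_eff)
    q = bh_qvalues(p)
    hits = np.where(np.isfinite(q), q < alpha, False)
    logger.info("%s: lambda=%.3f, %d hits of %d loci", method, lam,
                int(hits.sum()), L)
    return MethodResult(method, d2, p, q, hits, inflation=lam, alpha=alpha)


def rdadapt(model: OrdinationModel, k_axes: int = 2,
            alpha: float = 0.05) -> MethodResult:
    """RDA outlier scan on locus loadings of the first ``k_axes`` axes."""
    if k_axes < 1:
        raise ValueError("k_axes must be >= 1")
    if model.n_axes < k_axes:
        raise ValueError(
            f"model has {model.n_axes} canonical axes, need {k_axes}"
        )
    loadings = model.locus_loadings[:, :k_axes]
    return _mahalanobis_scan(loadings, k_axes, alpha, "rdadapt")


def pcadapt_like(g: GenotypeMatrix | np.ndarray, n_pcs: int = 2,
                 alpha: float = 0.05) -> MethodResult:
    """Outlier scan for loci unusually correlated with neutral structure.

    Each locus is regressed on the first ``n_pcs`` PC scores of the dosage
    matrix; the vector of regression z-scores is screened by Mahalanobis
    distance with the same inflation-factor correction as ``rdadapt``.
    Zero-variance loci get a missing statistic and are excluded from λ.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    scores, _, _ = pca_genotypes(X, n_components=n_pcs)
    mean = np.nanmean(X, axis=0)
    Xi = np.where(np.isnan(X), mean, X)
    Yc = Xi - Xi.mean(axis=0)

    n = X.shape[0]
    Zd = np.column_stack([np.ones(n), scores])
    # per-locus OLS z-scores of the PC coefficients, vectorized across loci
    G = np.linalg.inv(Zd.T @ Zd)
    beta = G @ Zd.T @ Yc                       # (n_pcs+1) x L
    resid = Yc - Zd @ beta
    dof = n - Zd.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof      # per locus
    se = np.sqrt(np.outer(np.diag(G), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (beta / se)[1:, :].T               # loci x n_pcs
    z[sigma2 <= 0] = np.nan
    return _mahalanobis_scan(z, n_pcs, alpha, "pcadapt_like")


def _ridge_latent_factors(Y: np.ndarray, E: np.ndarray, K: int,
                          ridge: float = 1e-5) -> np.ndarray:
    """Latent factors of the exact ridge latent-factor model.

    Solves min ||Y - W - E Bᵀ||² + ridge·||B||² over rank-K W and B in
    closed form: with E = QΣRᵀ the full SVD, shrink the E-spanned
    directions by d_i = sqrt(ridge / (ridge + σ_i²)), take the rank-K SVD
    of the shrunk response, and map back. The factors thereby reconstruct
    the environment-collinear component of the genetic structure instead of
    attributing it to the environmental coefficients.
    """
    n = Y.shape[0]
    Qf, sig, _ = np.linalg.svd(E, full_matrices=True)
    d = np.ones(n)
    d[: len(sig)] = np.sqrt(ridge / (ridge + sig**2))
    M = d[:, None] * (Qf.T @ Y)
    Um, sm, Vtm = np.linalg.svd(M, full_matrices=False)
    Wk = (Um[:, :K] * sm[:K]) @ Vtm[:K]
    W = Qf @ (Wk / d[:, None])
    U, _, _ = np.linalg.svd(W, full_matrices=False)
    return U[:, :K]


def lfmm_like(g: GenotypeMatrix | np.ndarray, env: pd.DataFrame,
              K_latent: int = 4, alpha: float = 0.05,
              ridge: float = 1e-5) -> MethodResult:
    """Latent-factor association scan.

    Latent factors come from the exact ridge solution of the latent-factor
    mixed model (they absorb the environment-collinear part of neutral
    structure); each locus then gets a joint F-test of all environmental
    coefficients controlling the factors, with a genomic-inflation-factor
    calibration of the resulting chi-square statistic.
    """
    if K_latent < 0:
        raise ValueError("K_latent must be >= 0")
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    mean = np.nanmean(X, axis=0)
    Y = np.where(np.isnan(X), mean, X)
    Y = Y - Y.mean(axis=0)
    E = np.asarray(env, dtype=float)
    if E.ndim == 1:
        E = E[:, None]
    E = (E - E.mean(axis=0)) / E.std(axis=0, ddof=0)
    n, L = Y.shape
    ne = E.shape[1]

    if K_latent > 0:
        U = _ridge_latent_factors(Y, E, K_latent, ridge)
        full = np.column_stack([np.ones(n), U, E])
        reduced = np.column_stack([np.ones(n), U])
    else:
        full = np.column_stack([np.ones(n), E])
        reduced = np.ones((n, 1))

    rank_full = np.linalg.matrix_rank(full)
    if rank_full < full.shape[1]:
        raise ValueError("environment collinear with latent factors")

    rss_full = _rss(full, Y)
    rss_red = _rss(reduced, Y)
    df1 = full.shape[1] - reduced.shape[1]
    df2 = n - full.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    F[~np.isfinite(F)] = np.nan
    chi2 = df1 * F
    p = np.full(L, np.nan)
    ok = np.isfinite(chi2)
    if K_latent > 0:
        # empirical-null calibration: residual structure not captured by U
        # leaves every locus with some association, so the null is wider
        # than chi-square(df1); fit its scale and effective df from the
        # bulk of the statistic distribution
        lam, df_eff = _empirical_null(chi2[ok], df1)
        p[ok] = stats.chi2.sf(chi2[ok] / lam, df_eff)
    else:
        lam = 1.0
        p[ok] = stats.f.sf(F[ok], df1, df2)
    q = bh_qvalues(p)
    hits = np.where(np.isfinite(q), q < alpha, False)
    logger.info("lfmm_like: lambda=%.3f, %d hits of %d loci (K_latent=%d)",
                lam, int(hits.sum()), L, K_latent)
    return MethodResult("lfmm_like", F, p, q, hits, inflation=lam,
                        alpha=alpha)


def _empirical_null(chi2: np.ndarray, df_nominal: int) -> tuple[float, float]:
    """Fit the null statistic distribution as scale * chi-square(df_eff).

    Central-matching in the Efron empirical-null spirit: the scale and the
    effective degrees of freedom are chosen so that the 50th and 95th
    percentiles of the statistic match the fitted distribution. Both
    quantiles sit below the outlier range (candidate adaptive loci are a
    percent or so of a panel), so true signal does not perturb the fit.
    Falls back to the median genomic inflation factor when the quantile
    ratio cannot be matched.
    """
    from scipy.optimize import brentq

    q50, q95 = np.percentile(chi2, [50, 95])
    target = q95 / q50

    def ratio(df):
        return stats.chi2.ppf(0.95, df) / stats.chi2.ppf(0.5, df) - target

    try:
        df_eff = brentq(ratio, 0.2, 500.0)
    except ValueError:
        df_eff = float(df_nominal)
    scale = q50 / stats.chi2.ppf(0.5, df_eff)
    return float(scale), float(df_eff)


def _rss(D: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    R = Y - D @ beta
    return (R**2).sum(axis=0)


def consensus(method_hits: list[set[int] | np.ndarray],
              min_methods: int = 2) -> np.ndarray:
    """Loci flagged by at least ``min_methods`` of the supplied scans."""
    if len(method_hits) < 2:
        raise ValueError("need at least two method hit sets")
    counts: dict[int, int] = {}
    for hits in method_hits:
        for l in set(int(i) for i in hits):
            counts[l] = counts.get(l, 0) + 1
    out = np.array(sorted(l for l, c in counts.items() if c >= min_methods),
                   dtype=int)
    sizes = [len(set(int(i) for i in h)) for h in method_hits]
    logger.info("consensus: per-method hits %s -> %d loci in >= %d methods",
                sizes, len(out), min_methods)
    if len(out) == 0:
        logger.warning(
            "consensus is empty; consider the union or all-loci "
            "sensitivity modes"
        )
    return out


def run_all(
    g: GenotypeMatrix,
    env: pd.DataFrame,
    rda_model: OrdinationModel,
    K_latent: int,
    n_pcs: int = 2,
    k_axes: int = 2,
    alpha: float = 0.05,
    min_methods: int = 2,
) -> CandidateSet:
    """Run the three scans and assemble the consensus candidate set."""
    methods = {
        "rdadapt": rdadapt(rda_model, k_axes=k_axes, alpha=alpha),
        "pcadapt": pcadapt_like(g, n_pcs=n_pcs, alpha=alpha),
        "lfmm": lfmm_like(g, env, K_latent=K_latent, alpha=alpha),
    }
    cons = consensus([m.hit_indices() for m in methods.values()],
                     min_methods=min_methods)
    return CandidateSet(methods=methods, consensus_idx=cons,
                        min_methods=min_methods)
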