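"""Population structure and differentiation.

PCA of genotype dosages, ancestry estimation by least-squares matrix
factorization (an sNMF-style stand-in for model-based clustering, yielding
the same Q/F interface), choice of K by masked-entry cross-validation plus
a biological-plausibility report, spatial interpolation of the Q matrix,
one-level AMOVA, Weir–Cockerham and Nei F_ST, and isolation by distance
via Mantel tests on geodesic distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .genio import EnvLayerSet, GenotypeMatrix, SiteFrame

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "AncestryModel",
    "DifferentiationResult",
    "IBDResult",
    "pca_genotypes",
    "estimate_ancestry",
    "choose_K",
    "select_K",
    "impute_genotypes",
    "interpolate_Q",
    "amova",
    "pairwise_fst",
    "global_fst",
    "geodesic_matrix",
    "haversine_km",
    "mantel_test",
    "ibd_fit",
    "align_clusters",
]


@dataclass
class AncestryModel:
    """Admixture-style ancestry: Q (memberships) and F (cluster frequencies)."""

    K: int
    Q: np.ndarray  # n x K, rows on the simplex
    F: np.ndarray  # K x L, allele frequencies in [0, 1]
    objective: float
    cv_error: float | None = None
    fully_assigned: np.ndarray | None = None  # per-cluster count of q > 0.9
    objective_path: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if self.F.size and (self.F.min() < -1e-9 or self.F.max() > 1 + 1e-9):
            raise ValueError("F outside [0, 1]")

    def expected_freq(self) -> np.ndarray:
        """Per-individual, per-locus expected alternate-allele frequency."""
        return self.Q @ self.F

    def count_fully_assigned(self, threshold: float = 0.9) -> np.ndarray:
        modal = self.Q.argmax(axis=1)
        high = self.Q.max(axis=1) > threshold
        return np.bincount(modal[high], minlength=self.K)


@dataclass
class DifferentiationResult:
    amova_components: tuple[float, float] | None = None  # (among, within)
    phi_st: float | None = None
    p_perm: float | None = None
    global_fst: float | None = None
    pairwise_fst: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None


@dataclass
class IBDResult:
    mantel_r: float
    mantel_p: float
    slope_per_100km: float
    r2: float


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_genotypes(g: GenotypeMatrix | np.ndarray, n_components: int | None = None):
    """PCA of the dosage matrix; missing entries mean-imputed per locus.

    Returns (scores, loadings, eigenvalues) with eigenvalues sorted
    descending; eigenvalue k is the variance of PC k (ddof=1).
    """
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    n, L = X.shape
    if n < 2 or L < 2:
        raise ValueError("need at least 2 individuals and 2 loci")
    mean = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), mean, X) - mean
    if not (Xc != 0).any():
        raise ValueError("zero-variance genotype matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    eig = s**2 / (n - 1)
    scores = U * s
    return scores, Vt.T, eig


# ---------------------------------------------------------------------------
# ancestry by masked least-squares factorization
# ---------------------------------------------------------------------------


def _neg_log_posterior(Xo, W, Q, F, kappa, pbar):
    """Negative binomial log-likelihood plus the BN-prior penalty on F."""
    P = (Q @ F).clip(1e-9, 1 - 1e-9)
    ll = np.where(W, Xo * np.log(P) + (2 - Xo) * np.log1p(-P), 0.0).sum()
    prior = kappa * (pbar[None, :] * np.log(F)
                     + (1 - pbar)[None, :] * np.log1p(-F)).sum()
    return float(-(ll + prior))


def estimate_ancestry(
    g: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> AncestryModel:
    """Estimate Q and F by MAP-EM under the admixture binomial model.

    The observed dosage x_il is Binomial(2, Σ_k q_ik f_kl); missing entries
    are excluded from the likelihood. Cluster frequencies carry a
    Balding–Nichols-style Beta prior centred on the overall locus frequency
    with concentration κ = (1 − θ̂)/θ̂, where θ̂ is the Weir–Cockerham
    differentiation of the k-means initial partition — an empirical-Bayes
    shrinkage that keeps the K·L frequency parameters from overfitting at
    moderate panel sizes. EM makes the penalized objective monotonically
    non-increasing; the best of ``n_restarts`` initializations is returned;
    deterministic given ``seed``.
    """
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    n, L = X.shape
    if K > n:
        raise ValueError(f"K={K} exceeds number of individuals {n}")
    if K < 1:
        raise ValueError("K must be >= 1")
    W = ~np.isnan(X)
    Xo = np.where(W, X, 0.0)

    if K == 1:
        F = (Xo.sum(axis=0) / np.maximum(2 * W.sum(axis=0), 1.0))
        Q = np.ones((n, 1))
        obj = _neg_log_posterior(Xo, W, Q, F[None, :].clip(1e-9, 1 - 1e-9),
                                 0.0, F)
        return AncestryModel(1, Q, F[None, :].clip(0, 1), obj,
                             objective_path=[obj])

    rng = np.random.default_rng(seed)
    pbar = (Xo.sum(axis=0) / np.maximum(2 * W.sum(axis=0), 1.0)).clip(
        1e-4, 1 - 1e-4
    )
    pcs = _init_pcs(X, W)
    best = None
    for _ in range(max(1, n_restarts)):
        Q, F, path = _fit_once_em(Xo, W, K, pcs, pbar, rng, max_iter, tol)
        if best is None or path[-1] < best[2][-1]:
            best = (Q, F, path)
    Q, F, path = best
    model = AncestryModel(K, Q, F.clip(0.0, 1.0), path[-1],
                          objective_path=path)
    model.fully_assigned = model.count_fully_assigned()
    return model


def _init_pcs(X, W):
    mean = np.nanmean(X, axis=0)
    Xi = np.where(W, X, mean)
    Xi = Xi - Xi.mean(axis=0)
    U, s, _ = np.linalg.svd(Xi, full_matrices=False)
    return (U * s)[:, : min(8, min(Xi.shape))]


def _fit_once_em(Xo, W, K, pcs, pbar, rng, max_iter, tol, check_every=10):
    from sklearn.cluster import KMeans

    n, L = Xo.shape
    km = KMeans(n_clusters=K, n_init=4,
                random_state=int(rng.integers(2**31 - 1))).fit(pcs)
    labels = km.labels_
    # empirical-Bayes prior strength from the initial hard partition
    kappa = 0.0
    if len(np.unique(labels)) == K and np.bincount(labels).min() >= 2:
        try:
            Xn = np.where(W, Xo, np.nan)
            theta = wc_theta(Xn, labels)
            if np.isfinite(theta):
                kappa = (1 - theta) / max(abs(theta), 1e-3)
        except ValueError:
            kappa = 0.0

    # EM runs in float32 (the dominant cost is dense n x L algebra); the
    # objective is accumulated in float64
    Xo32 = Xo.astype(np.float32)
    W32 = W.astype(np.float32)
    Q = np.full((n, K), 0.1 / max(K - 1, 1), dtype=np.float32)
    Q[np.arange(n), labels] = 0.9
    Q = Q / Q.sum(axis=1, keepdims=True)
    F = ((Q.T @ (W32 * Xo32)) / np.maximum(Q.T @ (2 * W32), 1e-9)).clip(
        1e-6, 1 - 1e-6
    )
    Li = W.sum(axis=1).astype(np.float32)
    pbar32 = pbar.astype(np.float32)
    path = [_neg_log_posterior(Xo, W, Q, F, kappa, pbar)]
    for it in range(max_iter):
        P = (Q @ F).clip(1e-6, 1 - 1e-6)
        A = W32 * (Xo32 / P)
        B = W32 * ((2 - Xo32) / (1 - P))
        Qn = Q * ((A @ F.T) + (B @ (1 - F).T)) / (2 * Li)[:, None]
        Qn = np.maximum(Qn, 1e-12)
        Qn /= Qn.sum(axis=1, keepdims=True)
        QA = Q.T @ A
        num = F * QA + np.float32(kappa) * pbar32[None, :]
        den = F * QA + (1 - F) * (Q.T @ B) + np.float32(kappa)
        F = (num / np.maximum(den, 1e-12)).clip(1e-6, 1 - 1e-6)
        Q = Qn
        if (it + 1) % check_every == 0 or it == max_iter - 1:
            obj = _neg_log_posterior(Xo, W, Q, F, kappa, pbar)
            path.append(obj)
            if path[-2] - obj < tol * abs(path[0]) * check_every:
                break
    Q64 = Q.astype(float)
    Q64 /= Q64.sum(axis=1, keepdims=True)
    return Q64, F.astype(float), path


def align_clusters(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute columns of Q to best match Q_ref (Hungarian on column L1)."""
    cost = cdist(Q.T, Q_ref.T, metric="cityblock")
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(rows)
    perm[cols] = rows
    return Q[:, perm]


def choose_K(
    g: GenotypeMatrix | np.ndarray,
    K_range=range(1, 7),
    mask_fraction: float = 0.1,
    seed: int = 0,
    sites: SiteFrame | None = None,
    n_restarts: int = 2,
) -> pd.DataFrame:
    """Masked-entry cross-validation over K plus a plausibility report.

    A ``mask_fraction`` of observed entries is hidden; for each K the model
    is fitted on the remainder and scored by the squared error of the
    predicted dosage 2·(QF) at the hidden entries. The report adds the
    per-K minimum count of individuals fully assigned (q > 0.9) to any
    cluster and, when site coordinates are given, a spatial-coherence score
    (mean fraction of the 5 nearest neighbours sharing the modal cluster).
    A K whose worst cluster has no fully assigned individual is flagged
    implausible.
    """
    if not (0.0 < mask_fraction < 0.5):
        raise ValueError("mask_fraction must be in (0, 0.5)")
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    rng = np.random.default_rng(seed)
    obs = np.argwhere(~np.isnan(X))
    n_mask = max(1, int(mask_fraction * len(obs)))
    chosen = obs[rng.choice(len(obs), size=n_mask, replace=False)]
    Xm = X.copy()
    held = X[chosen[:, 0], chosen[:, 1]]
    Xm[chosen[:, 0], chosen[:, 1]] = np.nan

    rows = []
    for K in K_range:
        model = estimate_ancestry(
            Xm, K, seed=int(rng.integers(2**31 - 1)), n_restarts=n_restarts
        )
        pred = 2.0 * model.expected_freq()[chosen[:, 0], chosen[:, 1]]
        sq = (pred - held) ** 2
        cv = float(sq.mean())
        cv_se = float(sq.std(ddof=1) / np.sqrt(len(sq)))
        fully = model.count_fully_assigned() if K > 1 else np.array([len(X)])
        coher = np.nan
        if sites is not None:
            coher = _spatial_coherence(model.Q, sites)
        rows.append(
            {
                "K": K,
                "cv_error": cv,
                "cv_se": cv_se,
                "min_fully_assigned": int(fully.min()),
                "spatial_coherence": coher,
                "plausible": bool(fully.min() > 0),
            }
        )
    return pd.DataFrame(rows)


def select_K(cv: pd.DataFrame, use_plausibility: bool = True) -> int:
    """Pick K from a ``choose_K`` report with the one-standard-error rule.

    The smallest K whose CV error is within one SE of the minimum is
    selected (parsimony under a flat CV tail); implausible K values
    (a cluster with no fully assigned individual) are excluded when any
    plausible ones exist.
    """
    table = cv
    if use_plausibility and cv["plausible"].any():
        table = cv[cv["plausible"]]
    best = table["cv_error"].idxmin()
    cutoff = table.loc[best, "cv_error"] + table.loc[best, "cv_se"]
    ok = table[table["cv_error"] <= cutoff]
    return int(ok["K"].min())


def _spatial_coherence(Q: np.ndarray, sites: SiteFrame, n_neighbors: int = 5) -> float:
    coords = sites.data[["longitude", "latitude"]].to_numpy()
    modal = Q.argmax(axis=1)
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :n_neighbors]
    return float((modal[nn] == modal[:, None]).mean())


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_genotypes(g: GenotypeMatrix, model: AncestryModel) -> GenotypeMatrix:
    """Replace missing entries by the modal genotype under Binomial(2, QF)."""
    X = g.values
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = list(g.locus_meta["id"][all_missing])
        raise ValueError(f"loci with no observed genotypes: {bad}")
    P = model.expected_freq().clip(0.0, 1.0)
    pmf = np.stack([(1 - P) ** 2, 2 * P * (1 - P), P**2])
    mode = pmf.argmax(axis=0).astype(float)
    out = np.where(np.isnan(X), mode, X)
    return GenotypeMatrix(out, g.locus_meta.copy(), list(g.individual_ids))


# ---------------------------------------------------------------------------
# Q-matrix interpolation
# ---------------------------------------------------------------------------


def interpolate_Q(
    model: AncestryModel, sites: SiteFrame, env: EnvLayerSet
) -> tuple[np.ndarray, np.ndarray]:
    """Thin-plate-spline interpolation of site-mean ancestry across the grid.

    Returns (Q_grid with shape (K, rows, cols), modal-group grid of int
    labels starting at 1, ties to the lowest cluster index). Cell values
    are clipped to [0, 1] and renormalized to the simplex.
    """
    df = sites.data.copy()
    for k in range(model.K):
        df[f"q{k}"] = model.Q[:, k]
    per_site = df.groupby("site_id").agg(
        {"longitude": "mean", "latitude": "mean",
         **{f"q{k}": "mean" for k in range(model.K)}}
    )
    pts = per_site[["longitude", "latitude"]].to_numpy()
    if len(np.unique(pts, axis=0)) < 4:
        raise ValueError("need at least 4 distinct site locations")
    span = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-9 * max(1, np.abs(span).max())) < 2:
        raise ValueError("site locations are collinear; TPS is degenerate")

    lon, lat = np.meshgrid(env.lon_centers(), env.lat_centers())
    cells = np.column_stack([lon.ravel(), lat.ravel()])
    K = model.K
    Qg = np.empty((K, *env.shape))
    for k in range(K):
        rbf = RBFInterpolator(
            pts, per_site[f"q{k}"].to_numpy(),
            kernel="thin_plate_spline", smoothing=1e-8,
        )
        Qg[k] = rbf(cells).reshape(env.shape)
    Qg = Qg.clip(0.0, 1.0)
    tot = Qg.sum(axis=0)
    tot[tot == 0] = 1.0
    Qg /= tot
    modal = Qg.argmax(axis=0) + 1
    return Qg, modal


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _complete_dosages(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    mean = np.nanmean(X, axis=0)
    return np.where(np.isnan(X), mean, X)


def amova(
    g: GenotypeMatrix | np.ndarray,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> DifferentiationResult:
    """One-level AMOVA on squared Euclidean genotype distances.

    Variance components use the unequal-group-size n0 coefficient;
    Φ_ST = σ²_among / (σ²_among + σ²_within); the p-value permutes
    individuals among groups with the add-one estimator.
    """
    X = _complete_dosages(g)
    labels = np.asarray(grouping)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = groups[counts < 2]
        raise ValueError(f"groups of size 1: {list(small)}")

    def components(lab):
        N = len(lab)
        gs, cnt = np.unique(lab, return_counts=True)
        ss_total = _ss_within(X, np.zeros(N))
        ss_within = _ss_within(X, lab)
        ss_among = ss_total - ss_within
        df_among, df_within = len(gs) - 1, N - len(gs)
        ms_among, ms_within = ss_among / df_among, ss_within / df_within
        n0 = (N - (cnt**2).sum() / N) / df_among
        sigma_within = ms_within
        sigma_among = (ms_among - ms_within) / n0
        phi = sigma_among / (sigma_among + sigma_within)
        return sigma_among, sigma_within, phi

    s_a, s_w, phi = components(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if components(rng.permutation(labels))[2] >= phi:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return DifferentiationResult(
        amova_components=(s_a, s_w), phi_st=phi, p_perm=p
    )


def _ss_within(X: np.ndarray, labels: np.ndarray) -> float:
    """Sum over groups of (1/n_g) * sum_{i<j in g} d²_ij, via deviations."""
    ss = 0.0
    for gname in np.unique(labels):
        sub = X[labels == gname]
        ss += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return ss


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _wc_components(g_values: np.ndarray, labels: np.ndarray):
    """Weir–Cockerham (1984) per-locus a, b, c for diploid biallelic loci."""
    pops = np.unique(labels)
    r = len(pops)
    L = g_values.shape[1]
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, pop in enumerate(pops):
        sub = g_values[labels == pop]
        called = ~np.isnan(sub)
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[k] = np.nansum(sub, axis=0) / (2 * np.maximum(n_i[k], 1))
            h_i[k] = (sub == 1).sum(axis=0) / np.maximum(n_i[k], 1)
    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    valid = (nbar > 1) & (nc > 0) & np.isfinite(a + b + c)
    return a[valid], b[valid], c[valid]


def wc_theta(g_values: np.ndarray, labels: np.ndarray) -> float:
    """Multi-locus Weir–Cockerham θ as a ratio of sums."""
    a, b, c = _wc_components(g_values, labels)
    denom = (a + b + c).sum()
    if denom == 0 or a.size == 0:
        raise ValueError("F_ST undefined: no polymorphic loci with data")
    return float(a.sum() / denom)


def pairwise_fst(
    g: GenotypeMatrix | np.ndarray,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> DifferentiationResult:
    """Pairwise Weir–Cockerham θ with permutation p-values per pair."""
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    labels = np.asarray(grouping)
    groups, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 individuals")
    m = len(groups)
    fst = pd.DataFrame(0.0, index=groups, columns=groups)
    pmat = pd.DataFrame(np.nan, index=groups, columns=groups)
    rng = np.random.default_rng(seed)
    for i in range(m):
        for j in range(i + 1, m):
            sel = np.isin(labels, [groups[i], groups[j]])
            sub, lab = X[sel], labels[sel]
            theta = wc_theta(sub, lab)
            count = 0
            for _ in range(n_perm):
                try:
                    if wc_theta(sub, rng.permutation(lab)) >= theta:
                        count += 1
                except ValueError:
                    count += 1
            p = (count + 1) / (n_perm + 1)
            fst.iloc[i, j] = fst.iloc[j, i] = theta
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return DifferentiationResult(pairwise_fst=fst, pairwise_p=pmat)


def global_fst(g: GenotypeMatrix | np.ndarray, grouping) -> DifferentiationResult:
    """Nei-style global F_ST = 1 - ΣH_S / ΣH_T over loci."""
    X = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    labels = np.asarray(grouping)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    hs_list, p_list, w_list = [], [], []
    for pop in groups:
        sub = X[labels == pop]
        with np.errstate(invalid="ignore"):
            p = np.nanmean(sub, axis=0) / 2.0
        hs_list.append(2 * p * (1 - p))
        p_list.append(p)
    HS = np.nanmean(hs_list, axis=0)
    pbar = np.nanmean(p_list, axis=0)
    HT = 2 * pbar * (1 - pbar)
    valid = np.isfinite(HS) & np.isfinite(HT) & (HT > 0)
    if not valid.any():
        raise ValueError("F_ST undefined: dataset monomorphic")
    fst = 1.0 - HS[valid].sum() / HT[valid].sum()
    return DifferentiationResult(global_fst=float(fst))


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on the sphere (R = 6371.0088 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def geodesic_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise haversine distances (km) between rows of lon/lat table."""
    lon = coords["longitude"].to_numpy()
    lat = coords["latitude"].to_numpy()
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


def _check_square_symmetric(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return D


def mantel_test(D1, D2, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel correlation of two distance matrices, one-sided upper p.

    r is the Pearson correlation of the off-diagonal elements; rows and
    columns of D2 are permuted jointly.
    """
    A = _check_square_symmetric(getattr(D1, "values", D1))
    B = _check_square_symmetric(getattr(D2, "values", D2))
    if A.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    r_obs = float(np.corrcoef(a, B[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if float(np.corrcoef(a, B[np.ix_(perm, perm)][iu])[0, 1]) >= r_obs:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def ibd_fit(fst_matrix, dist_matrix, n_perm: int = 999, seed: int = 0) -> IBDResult:
    """Isolation by distance: Mantel test plus OLS slope per 100 km."""
    F = _check_square_symmetric(getattr(fst_matrix, "values", fst_matrix))
    D = _check_square_symmetric(getattr(dist_matrix, "values", dist_matrix))
    r, p = mantel_test(F, D, n_perm=n_perm, seed=seed)
    iu = np.triu_indices(F.shape[0], k=1)
    y, x = F[iu], D[iu] / 100.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    return IBDResult(mantel_r=r, mantel_p=p, slope_per_100km=float(slope),
                     r2=float(r2))
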