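"""Constrained ordination: RDA and partial RDA from first principles.

Redundancy analysis regresses a multivariate response Y (here: centered
genotype dosages or site allele frequencies) on a predictor table X, then
ordinates the fitted values. Partial RDA first removes conditioning
variables Z from both Y and X by ordinary least squares. On top of the
fitting engine this module provides the permutation pseudo-F test, the
Ezekiel adjusted R², greedy forward variable selection, Spearman variable
clustering, and variance partitioning across predictor blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "OrdinationModel",
    "PartitionTable",
    "rda_fit",
    "adjusted_r2",
    "permutation_test",
    "forward_select",
    "varclus_spearman",
    "variance_partition",
]


@dataclass
class OrdinationModel:
    """A fitted (partial) redundancy analysis.

    ``site_scores`` are the projections of the (residualized) response onto
    the canonical axes ("wa" scores); ``locus_loadings`` are the response
    column loadings; ``variable_loadings`` are the correlations of each
    predictor with the site scores, the a_i that weight standardized
    environmental values in the adaptive index.
    """

    eigenvalues: np.ndarray          # canonical eigenvalues, descending
    site_scores: np.ndarray          # n x n_axes
    locus_loadings: np.ndarray       # n_resp_cols x n_axes
    variable_loadings: pd.DataFrame  # predictors x axes (correlation scale)
    r2: float
    adj_r2: float
    predictor_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    rank_x: int
    rank_z: int
    n: int
    total_inertia: float
    fitted_inertia: float
    Y_resid: np.ndarray = field(repr=False)   # response after centering/Z
    X_resid: np.ndarray = field(repr=False)   # predictors after std/Z
    pseudo_f: float | None = None
    p_perm: float | None = None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def axis_weights(self, axes, weighting: str = "sqrt_eigenvalue") -> np.ndarray:
        """Per-axis weights for offset distances."""
        axes = np.asarray(axes)
        if weighting == "none":
            return np.ones(len(axes))
        if weighting == "sqrt_eigenvalue":
            share = self.eigenvalues / self.eigenvalues.sum()
            return np.sqrt(share[axes])
        raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class PartitionTable:
    """Variance partitioning across predictor blocks (vegan-varpart style)."""

    table: pd.DataFrame  # rows full/pure_*/confounded

    def __post_init__(self) -> None:
        t = self.table
        pure = t.loc[t.index.str.startswith("pure"), "prop_total"].sum()
        resid = t.loc["full", "prop_total"] - pure - t.loc["confounded", "prop_total"]
        if abs(resid) > 1e-6:
            raise ValueError("partition does not satisfy the accounting identity")


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), [str(c) for c in table.columns]
    arr = np.asarray(table, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of M on [1, Z] (intercept included)."""
    Z1 = np.column_stack([np.ones(len(M)), Z])
    beta, *_ = np.linalg.lstsq(Z1, M, rcond=None)
    return M - Z1 @ beta


def rda_fit(Y, X, Z=None) -> OrdinationModel:
    """Fit an RDA (Z empty) or pRDA (Z a conditioner table).

    Y columns are centered (not scaled); X columns are standardized to unit
    SD. With conditioners, Y and X are replaced by their residuals on
    [1, Z] before fitting. The canonical axes are the SVD of the fitted
    values Ŷ = H_X Y.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X, xnames = _as_matrix(X)
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    if np.isnan(Y).any() or np.isnan(X).any():
        raise ValueError("missing values in Y or X; impute upstream")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    if (x_sd == 0).any():
        bad = [xnames[i] for i in np.flatnonzero(x_sd == 0)]
        raise ValueError(f"constant predictor columns: {bad}")
    Xs = (X - x_mean) / x_sd
    Yc = Y - Y.mean(axis=0)

    rank_z = 0
    if Z is not None and np.size(Z):
        Zm, _ = _as_matrix(Z)
        if Zm.shape[0] != n:
            raise ValueError("Z row count differs from Y")
        rank_z = np.linalg.matrix_rank(Zm - Zm.mean(axis=0))
        Yc = _residualize(Yc, Zm)
        norms_before = np.linalg.norm(Xs, axis=0)
        Xs = _residualize(Xs, Zm)
        # predictors fully absorbed by the conditioner carry no testable
        # variance; keep the rest (a model may legitimately end up empty)
        keep = np.linalg.norm(Xs, axis=0) > 1e-10 * np.maximum(norms_before, 1)
        if not keep.all():
            dropped = [xnames[i] for i in np.flatnonzero(~keep)]
            logger_msg = f"predictors aliased by conditioners dropped: {dropped}"
            import logging as _logging

            _logging.getLogger(__name__).info(logger_msg)
            Xs = Xs[:, keep]
            xnames = [x for x, k in zip(xnames, keep) if k]
            x_mean, x_sd = x_mean[keep], x_sd[keep]
    if Xs.shape[1] == 0:
        return OrdinationModel(
            eigenvalues=np.empty(0), site_scores=np.empty((n, 0)),
            locus_loadings=np.empty((Y.shape[1], 0)),
            variable_loadings=pd.DataFrame(index=[]), r2=0.0, adj_r2=0.0,
            predictor_names=[], x_mean=x_mean, x_sd=x_sd, rank_x=0,
            rank_z=rank_z, n=n, total_inertia=float((Yc**2).sum()) / max(n - 1, 1),
            fitted_inertia=0.0, Y_resid=Yc, X_resid=Xs,
        )

    rank_x = np.linalg.matrix_rank(Xs)
    if rank_x < Xs.shape[1]:
        # name aliased columns: those whose residual on the previous ones
        # is numerically zero
        aliased = []
        for j in range(Xs.shape[1]):
            prev = Xs[:, :j]
            r = Xs[:, j]
            if prev.size:
                r = r - prev @ np.linalg.lstsq(prev, r, rcond=None)[0]
            if np.linalg.norm(r) < 1e-8 * max(1.0, np.linalg.norm(Xs[:, j])):
                aliased.append(xnames[j])
        raise ValueError(f"rank-deficient predictors; aliased columns: {aliased}")

    beta, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)

    # SVD of the fitted values Ŷ = Xs beta through its low-rank factors:
    # with Xs = Qx Rx, svd(Ŷ) = (Qx Um) s Vt where (Um, s, Vt) = svd(Rx beta)
    Qx, Rx = np.linalg.qr(Xs)
    Um, s, Vt = np.linalg.svd(Rx @ beta, full_matrices=False)
    n_axes = min(rank_x, Y.shape[1])
    tol = max(s[0], 1.0) * 1e-12 if s.size else 0.0
    n_axes = min(n_axes, int((s > tol).sum()))
    U, s, V = Qx @ Um[:, :n_axes], s[:n_axes], Vt[:n_axes].T

    eig = s**2 / max(n - 1, 1)
    site_scores = Yc @ V
    total = float((Yc**2).sum())
    fitted = float(((Rx @ beta) ** 2).sum())
    r2 = fitted / total if total > 0 else 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        vl = np.empty((Xs.shape[1], n_axes))
        for a in range(n_axes):
            sc = site_scores[:, a]
            vl[:, a] = [
                _safe_corr(Xs[:, j], sc) for j in range(Xs.shape[1])
            ]
    variable_loadings = pd.DataFrame(
        vl, index=xnames, columns=[f"RDA{a + 1}" for a in range(n_axes)]
    )

    try:
        adj = adjusted_r2(r2, n - rank_z, rank_x)
    except ValueError:
        adj = np.nan
    return OrdinationModel(
        eigenvalues=eig,
        site_scores=site_scores,
        locus_loadings=V,
        variable_loadings=variable_loadings,
        r2=r2,
        adj_r2=adj,
        predictor_names=xnames,
        x_mean=x_mean,
        x_sd=x_sd,
        rank_x=rank_x,
        rank_z=rank_z,
        n=n,
        total_inertia=total / max(n - 1, 1),
        fitted_inertia=fitted / max(n - 1, 1),
        Y_resid=Yc,
        X_resid=Xs,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _pseudo_f(fitted: float, total: float, df_model: int, df_resid: int) -> float:
    resid = total - fitted
    if df_resid <= 0 or resid <= 0:
        return np.inf
    return (fitted / df_model) / (resid / df_resid)


def permutation_test(
    model: OrdinationModel, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation pseudo-F test of the constrained variance.

    Rows of the (Z-residualized, standardized) predictor matrix are
    permuted; the p-value uses the add-one estimator
    (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    Y, X = model.Y_resid, model.X_resid
    n = model.n
    df_model = model.rank_x
    df_resid = n - 1 - model.rank_x - model.rank_z
    total = float((Y**2).sum())

    def fitted_ss(Xp):
        # ||P_X Y||² via QR of the (full-column-rank) predictors — avoids
        # materializing the n x L fitted matrix
        Qm, _ = np.linalg.qr(Xp)
        return float(((Qm.T @ Y) ** 2).sum())

    f_obs = _pseudo_f(fitted_ss(X), total, df_model, df_resid)
    count = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        if _pseudo_f(fitted_ss(Xp), total, df_model, df_resid) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    model.pseudo_f, model.p_perm = f_obs, p
    return f_obs, p


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy forward selection of predictors for an RDA of Y.

    At each step the candidate maximizing the adjusted R² of the augmented
    model is evaluated; selection stops when that candidate's marginal
    permutation p-value exceeds ``alpha``, when adjusted R² would decrease,
    or when the model's adjusted R² surpasses that of the full
    all-candidates model. Ties break to the first-listed variable.

    Returns the selection trace (step, variable, adj_r2, p).
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    names = list(candidates.columns)
    full_adj = rda_fit(Y, candidates).adj_r2
    selected: list[str] = []
    trace = []
    current_adj = 0.0
    rng = np.random.default_rng(seed)
    while len(selected) < len(names):
        best_name, best_adj = None, -np.inf
        for name in names:
            if name in selected:
                continue
            trial = rda_fit(Y, candidates[selected + [name]])
            if trial.adj_r2 > best_adj:
                best_name, best_adj = name, trial.adj_r2
        if best_adj <= current_adj and selected:
            break
        # marginal test of the new variable given those already selected
        Zsel = candidates[selected] if selected else None
        marg = rda_fit(Y, candidates[[best_name]], Zsel)
        _, p = permutation_test(
            marg, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        if p > alpha:
            break
        selected.append(best_name)
        current_adj = best_adj
        trace.append(
            {"step": len(selected), "variable": best_name,
             "adj_r2": best_adj, "p": p}
        )
        if current_adj > full_adj:
            break
    return pd.DataFrame(trace, columns=["step", "variable", "adj_r2", "p"])


def varclus_spearman(env_table: pd.DataFrame, cut: float = 0.7) -> dict[str, int]:
    """Cluster variables by |Spearman ρ| with average linkage.

    The tree is cut at distance 1 - ``cut``; variables in the same branch
    carry |ρ| >= ``cut`` with at least some branch member. Returns
    variable -> cluster id (1-based). Picking one representative per branch
    is left to the caller.
    """
    if env_table.shape[1] < 2:
        raise ValueError("need at least two variables")
    sds = env_table.std(ddof=0)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"constant variables (Spearman undefined): {bad}")
    rho = env_table.corr(method="spearman").to_numpy()
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(linkage, t=1.0 - cut, criterion="distance")
    return dict(zip(env_table.columns, (int(v) for v in labels)))


def variance_partition(
    Y,
    env: pd.DataFrame,
    geo: pd.DataFrame,
    struct: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> PartitionTable:
    """Partition explained variance among environment, geography, structure.

    Pure fractions are differences of Ezekiel-adjusted R² (full model minus
    the model omitting that block), so the accounting identity
    pure_env + pure_geo + pure_struct + confounded = full holds exactly.
    p-values come from permutation tests of the corresponding partial RDA
    (the block of interest conditioned on the union of the other two).
    """
    blocks = {"env": env, "geo": geo, "struct": struct}
    for name, b in blocks.items():
        if b is None or b.shape[1] == 0:
            raise ValueError(f"predictor block {name!r} is empty")
    rng = np.random.default_rng(seed)

    def adj(of: list[str]) -> float:
        X = pd.concat([blocks[b] for b in of], axis=1)
        return rda_fit(Y, X).adj_r2

    full_model = rda_fit(Y, pd.concat(list(blocks.values()), axis=1))
    full = full_model.adj_r2
    _, p_full = permutation_test(
        full_model, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
    )

    rows = {"full": {"prop_explained": 1.0, "prop_total": full, "p": p_full}}
    pure_sum = 0.0
    for name in blocks:
        others = [b for b in blocks if b != name]
        pure = full - adj(others)
        Zo = pd.concat([blocks[b] for b in others], axis=1)
        partial = rda_fit(Y, blocks[name], Zo)
        _, p = permutation_test(
            partial, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        rows[f"pure_{name}"] = {
            "prop_explained": pure / full if full != 0 else np.nan,
            "prop_total": pure,
            "p": p,
        }
        pure_sum += pure
    rows["confounded"] = {
        "prop_explained": (full - pure_sum) / full if full != 0 else np.nan,
        "prop_total": full - pure_sum,
        "p": np.nan,
    }
    return PartitionTable(pd.DataFrame(rows).T)
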