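"""Adaptive landscapes and genomic offsets.

An adaptively enriched RDA describes per-site allele frequencies of
candidate adaptive loci with environmental variables. Its leading axes
define an environmental space in which an *adaptive index* can be computed
for any grid cell c and axis r:

    AI(r, c) = sum_i a_ir * b_ic

with a_ir the loading of variable i on axis r and b_ic the standardized
value of variable i in cell c (calibration mean/SD from present-period
site values). A *genomic offset* is a distance in this space between two
environment vectors: temporal (same cell, present vs future), spatial
(two cells, same period) or donor/spatio-temporal (donor's present vs
recipient's future).

Raw offsets are standardized into z'-scores against the empirical
distribution of all contemporary spatial offsets: z'(x) = Phi^-1((1 +
Fhat(x)) / 2), the half-normal quantile map, so z' = 1 sits at the 68.27th
percentile of the reference and z' = 2 at the 95.45th (the Empirical Rule),
while z' deliberately has no meaning in reference standard deviations.
z' = 1 is the conventional not-to-exceed vulnerability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import EnvLayerSet, GenotypeMatrix, SiteFrame
from .ordination import OrdinationModel, rda_fit

logger = logging.getLogger(__name__)

__all__ = [
    "AdaptiveLandscape",
    "OffsetSurface",
    "ReferenceDistribution",
    "site_allele_freqs",
    "enriched_rda",
    "adaptive_index",
    "genomic_offset",
    "reference_distribution",
    "zprime",
    "threshold_mask",
    "donor_offset",
]


@dataclass
class AdaptiveLandscape:
    """Per-cell adaptive index for a set of RDA axes and one period."""

    period: str
    index: np.ndarray          # n_axes x rows x cols
    axes: tuple[int, ...]      # 0-based axis numbers
    loadings: pd.DataFrame     # variables x axes (a_i)
    weights: np.ndarray        # per-axis distance weights

    @property
    def shape(self) -> tuple[int, int]:
        return self.index.shape[1:]


@dataclass
class ReferenceDistribution:
    """Sorted sample of contemporary spatial offsets."""

    values: np.ndarray
    n_pairs_sampled: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if (self.values < 0).any():
            raise ValueError("offsets must be non-negative")


@dataclass
class OffsetSurface:
    """Raw offsets, their z' scores and the vulnerability mask."""

    raw: np.ndarray
    z: np.ndarray
    reference: ReferenceDistribution
    threshold: float
    mask: np.ndarray

    def n_flagged(self) -> int:
        return int(np.nansum(self.mask))


# ---------------------------------------------------------------------------
# enriched RDA and adaptive index
# ---------------------------------------------------------------------------


def site_allele_freqs(g: GenotypeMatrix, sites: SiteFrame,
                      locus_idx=None) -> pd.DataFrame:
    """Per-site alternate-allele frequencies (missing calls ignored)."""
    vals = g.values if locus_idx is None else g.values[:, locus_idx]
    ids = (g.locus_meta["id"] if locus_idx is None
           else g.locus_meta["id"].iloc[locus_idx])
    order = sites.ordered_for(g.individual_ids)
    df = pd.DataFrame(vals / 2.0, index=order["site_id"].to_numpy(),
                      columns=list(ids))
    return df.groupby(level=0).mean().sort_index()


def enriched_rda(candidate_freqs: pd.DataFrame,
                 env_site_values: pd.DataFrame) -> OrdinationModel:
    """RDA of candidate-locus site frequencies on environmental variables."""
    if candidate_freqs.shape[1] < 1:
        raise ValueError("no candidate loci supplied")
    if candidate_freqs.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    env = env_site_values.loc[candidate_freqs.index]
    Y = candidate_freqs.to_numpy(dtype=float)
    if np.isnan(Y).any():
        # a site may have no calls at some candidate locus
        col_mean = np.nanmean(Y, axis=0)
        Y = np.where(np.isnan(Y), col_mean, Y)
    return rda_fit(Y, env)


def adaptive_index(model: OrdinationModel, env: EnvLayerSet, period: str,
                   axes: tuple[int, ...] = (0, 1),
                   weighting: str = "sqrt_eigenvalue") -> AdaptiveLandscape:
    """Project the enriched RDA onto the environmental grids of one period.

    AI(r, c) = sum_i a_ir b_ic with b from the layer set's calibration
    statistics (present-period site values).
    """
    axes = tuple(a for a in axes if a < model.n_axes)
    if not axes:
        raise ValueError("model has no canonical axes to project")
    for var in model.predictor_names:
        if var not in env.grids:
            raise KeyError(f"variable {var!r} missing from layer set")
    rows, cols = env.shape
    index = np.zeros((len(axes), rows, cols))
    for ai, axis in enumerate(axes):
        for var in model.predictor_names:
            a = model.variable_loadings.loc[var].iloc[axis]
            index[ai] += a * env.standardized_grid(var, period)
    loadings = model.variable_loadings.iloc[:, list(axes)]
    weights = model.axis_weights(list(axes), weighting)
    return AdaptiveLandscape(period=period, index=index, axes=axes,
                             loadings=loadings, weights=weights)


# ---------------------------------------------------------------------------
# offsets
# ---------------------------------------------------------------------------


def genomic_offset(a: AdaptiveLandscape, b: AdaptiveLandscape) -> np.ndarray:
    """Per-cell Euclidean distance between two adaptive landscapes.

    Axis vectors are weighted by the landscapes' per-axis weights (square
    root of the canonical-eigenvalue share by default, or unit weights).
    """
    if a.index.shape != b.index.shape or a.axes != b.axes:
        raise ValueError("landscapes have mismatched axes or grids")
    w = a.weights[:, None, None]
    return np.sqrt((((a.index - b.index) * w) ** 2).sum(axis=0))


def reference_distribution(landscape: AdaptiveLandscape,
                           max_pairs: int = 2_000_000,
                           seed: int = 0) -> ReferenceDistribution:
    """Contemporary spatial offsets between sampled unordered cell pairs.

    All pairs are used when their number does not exceed ``max_pairs``;
    otherwise pairs are sampled uniformly with the given seed.
    """
    flat = landscape.index.reshape(len(landscape.axes), -1)
    valid = np.isfinite(flat).all(axis=0)
    pts = (flat[:, valid] * landscape.weights[:, None]).T  # cells x axes
    m = len(pts)
    if m < 2:
        raise ValueError("fewer than 2 valid cells")
    n_all = m * (m - 1) // 2
    rng = np.random.default_rng(seed)
    if n_all <= max_pairs:
        iu = np.triu_indices(m, k=1)
        d = np.sqrt(((pts[iu[0]] - pts[iu[1]]) ** 2).sum(axis=1))
        n_pairs = n_all
    else:
        i = rng.integers(0, m, size=max_pairs)
        j = rng.integers(0, m - 1, size=max_pairs)
        j = np.where(j >= i, j + 1, j)
        d = np.sqrt(((pts[i] - pts[j]) ** 2).sum(axis=1))
        n_pairs = max_pairs
    return ReferenceDistribution(values=d, n_pairs_sampled=n_pairs, seed=seed)


# ---------------------------------------------------------------------------
# z' standardization
# ---------------------------------------------------------------------------


def _ecdf(reference: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Empirical CDF with linear interpolation between order statistics.

    Order statistic i (1-based) carries plotting position i/(n+1); values
    outside the sample range are clamped to [1/(n+1), n/(n+1)].
    """
    n = len(reference)
    pos = np.arange(1, n + 1) / (n + 1)
    return np.interp(x, reference, pos, left=pos[0], right=pos[-1])


def zprime(raw_offsets: np.ndarray,
           reference: ReferenceDistribution) -> np.ndarray:
    """Standardize offsets by rank within the contemporary reference.

    z'(x) = Phi^-1((1 + Fhat(x)) / 2); by construction z' = 1 at the
    68.27th reference percentile and z' = 2 at the 95.45th.
    """
    ref = reference.values
    if len(np.unique(ref)) < 2:
        raise ValueError("degenerate reference distribution")
    x = np.asarray(raw_offsets, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    F = _ecdf(ref, x[ok])
    out[ok] = stats.norm.ppf((1.0 + F) / 2.0)
    return out


def threshold_mask(z: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Cells whose z' exceeds the not-to-exceed threshold."""
    mask = np.where(np.isfinite(z), z > threshold, False)
    n = int(mask.sum())
    total = int(np.isfinite(z).sum())
    logger.info("threshold_mask: %d of %d cells above z' = %g (%.2f%%)",
                n, total, threshold, 100.0 * n / max(total, 1))
    return mask


def temporal_offset(model: OrdinationModel, env: EnvLayerSet,
                    axes: tuple[int, ...] = (0, 1),
                    weighting: str = "sqrt_eigenvalue",
                    threshold: float = 1.0,
                    max_pairs: int = 2_000_000,
                    seed: int = 0) -> OffsetSurface:
    """Per-cell present-vs-future offset, standardized to z' scores."""
    present = adaptive_index(model, env, "present", axes, weighting)
    future = adaptive_index(model, env, "future", axes, weighting)
    raw = genomic_offset(present, future)
    ref = reference_distribution(present, max_pairs=max_pairs, seed=seed)
    z = zprime(raw, ref)
    return OffsetSurface(raw=raw, z=z, reference=ref, threshold=threshold,
                         mask=threshold_mask(z, threshold))


def donor_offset(model: OrdinationModel, env: EnvLayerSet,
                 recipient_cell: tuple[int, int],
                 reference: ReferenceDistribution,
                 axes: tuple[int, ...] = (0, 1),
                 weighting: str = "sqrt_eigenvalue",
                 threshold: float = 1.0) -> OffsetSurface:
    """Donor suitability for one recipient cell under future conditions.

    For every donor cell d the raw offset is the distance between d's
    present adaptive index and the recipient's *future* index, standardized
    with the same contemporary reference distribution; suitable donors have
    z' < threshold.
    """
    present = adaptive_index(model, env, "present", axes, weighting)
    future = adaptive_index(model, env, "future", axes, weighting)
    r, c = recipient_cell
    target = future.index[:, r, c]
    if not np.isfinite(target).all():
        raise ValueError(f"recipient cell {recipient_cell} has no data")
    w = present.weights[:, None, None]
    diff = (present.index - target[:, None, None]) * w
    raw = np.sqrt((diff**2).sum(axis=0))
    z = zprime(raw, reference)
    return OffsetSurface(raw=raw, z=z, reference=reference,
                         threshold=threshold,
                         mask=threshold_mask(z, threshold))


def donor_ranking(surface: OffsetSurface) -> pd.DataFrame:
    """Donor cells ranked by ascending z' with suitability flag."""
    rows, cols = surface.z.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    ok = np.isfinite(surface.z)
    df = pd.DataFrame(
        {
            "row": rr[ok],
            "col": cc[ok],
            "raw_offset": surface.raw[ok],
            "z_prime": surface.z[ok],
        }
    ).sort_values("z_prime", kind="mergesort").reset_index(drop=True)
    df["suitable"] = df["z_prime"] < surface.threshold
    return df
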