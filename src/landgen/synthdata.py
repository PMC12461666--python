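"""Synthetic genotype, site and environment generator.

The generator produces data with the statistical structure a landscape
genomics analysis assumes: K spatially coherent admixed ancestral clusters
(Balding–Nichols allele-frequency drift), isolation by distance through the
spatial decay of ancestry, a small set of adaptive loci with logistic allele
frequency clines along environmental gradients, missing genotypes at random,
and paired present/future environmental grids.

Default parameters emulate a Germany-wide ddRAD panel of a common grassland
herb: 735 individuals from 534 sites, 8348 biallelic SNPs with 16.6%
missingness, four admixed clusters, and a handful of climate-driven loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit, softmax

from .genio import EnvLayerSet, GenotypeMatrix, SiteFrame

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_environment",
    "make_populations",
    "make_genotypes",
    "simulate",
]

# default environmental variables: name -> spatial autocorrelation length
# scale in cells (bioclim-like climate fields are smoother than soil fields)
DEFAULT_ENV_VARS = {
    "temp_seas": 12.0,
    "prec_driest": 10.0,
    "prec_seas": 8.0,
    "isotherm": 12.0,
    "soil_clay": 4.0,
    "soil_carbon": 4.0,
    "soil_density": 5.0,
    "soil_frag": 3.0,
}

# additive climate shift by 2081-2100 (standard-deviation-sized for climate
# variables, zero for soils which are held constant across periods)
DEFAULT_FUTURE_DELTA = {
    "temp_seas": 1.5,
    "prec_driest": -1.0,
    "prec_seas": 1.0,
    "isotherm": 0.5,
    "soil_clay": 0.0,
    "soil_carbon": 0.0,
    "soil_density": 0.0,
    "soil_frag": 0.0,
}


@dataclass
class SimConfig:
    """Knobs of the generating model.

    ``drift`` is the Balding–Nichols F of each cluster; ``effect_size`` is
    the slope of the adaptive logistic cline per SD of environment;
    ``future_delta`` maps variable -> (shift, gradient) where the optional
    gradient adds a west-to-east linear component to the shift.
    ``driver_vars`` designates which variables drive adaptive loci
    (round-robin across loci).
    """

    n_individuals: int = 735
    n_sites: int = 534
    grid_shape: tuple[int, int] = (40, 60)
    K_true: int = 4
    n_neutral: int = 8328
    n_adaptive: int = 20
    drift: float = 0.03
    effect_size: float = 2.0
    missing_rate: float = 0.166
    env_vars: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENV_VARS)
    )
    future_delta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUTURE_DELTA)
    )
    driver_vars: tuple[str, ...] = ("temp_seas", "prec_driest")
    temperature: float = 4.0  # softmax temperature of ancestry decay, in cells
    shared_contig_fraction: float = 0.05
    lon0: float = 6.0
    lat0: float = 47.0
    lon_span: float = 6.0
    lat_span: float = 4.0
    n_zones: tuple[int, int] = (2, 4)  # zone blocks (rows, cols)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adaptive > self.n_neutral:
            raise ValueError("n_adaptive must not exceed n_neutral")
        if not (0.0 < self.drift < 1.0):
            raise ValueError("drift F must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.grid_shape[0] * self.grid_shape[1] < self.n_sites:
            raise ValueError("grid has fewer cells than sites")
        for v in self.driver_vars:
            if v not in self.env_vars:
                raise ValueError(f"driver variable {v!r} not in env_vars")

    @property
    def n_loci(self) -> int:
        return self.n_neutral + self.n_adaptive

    @property
    def cellsize(self) -> float:
        return self.lon_span / self.grid_shape[1]


@dataclass
class SimTruth:
    """Ground truth of one simulation, for recovery tests."""

    true_Q: np.ndarray  # individuals x K, rows on the simplex
    true_cluster_freqs: np.ndarray  # K x loci
    adaptive_locus_ids: list[str]
    locus_effects: pd.DataFrame  # id, driver variable, slope, p0

    def __post_init__(self) -> None:
        if not np.allclose(self.true_Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("true_Q rows must sum to 1")
        F = self.true_cluster_freqs
        if F.size and (F.min() < 0 or F.max() > 1):
            raise ValueError("cluster frequencies outside [0, 1]")


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def _gaussian_field(shape, length_scale, rng):
    """Unit-variance Gaussian random field via smoothed white noise."""
    pad = int(np.ceil(3 * length_scale))
    noise = rng.standard_normal((shape[0] + 2 * pad, shape[1] + 2 * pad))
    smooth = ndimage.gaussian_filter(noise, sigma=length_scale, mode="reflect")
    core = smooth[pad: pad + shape[0], pad: pad + shape[1]]
    sd = core.std()
    if sd == 0:
        raise ValueError("degenerate grid for requested autocorrelation")
    return (core - core.mean()) / sd


def make_environment(config: SimConfig, rng: np.random.Generator | None = None,
                     sites: SiteFrame | None = None) -> EnvLayerSet:
    """Generate paired present/future environmental grids.

    Each present grid is a smooth Gaussian random field plus a deterministic
    geographic gradient (alternating N-S / W-E per variable, so variables
    are not mutually redundant). Future grids add the configured per-variable
    shift. Per-site values are bilinear samples of the grids; standardization
    statistics come from the present-period site values (grid-cell statistics
    when no sites are supplied yet).
    """
    nrows, ncols = config.grid_shape
    if (nrows < 2 or ncols < 2) and any(s > 0 for s in config.env_vars.values()):
        raise ValueError("degenerate grid with autocorrelation requested")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    rowg, colg = np.meshgrid(
        np.linspace(-1, 1, nrows), np.linspace(-1, 1, ncols), indexing="ij"
    )
    grids: dict[str, dict[str, np.ndarray]] = {}
    for i, (var, ls) in enumerate(config.env_vars.items()):
        if ls <= 0:
            raise ValueError(f"length scale for {var!r} must be > 0")
        grf = _gaussian_field((nrows, ncols), ls, rng)
        gradient = rowg if i % 2 == 0 else colg
        present = grf + 1.0 * gradient
        delta = config.future_delta.get(var, 0.0)
        if np.ndim(delta) == 0:
            shift = float(delta)
        else:  # (shift, west-east gradient amplitude)
            shift = float(delta[0]) + float(delta[1]) * colg
        grids[var] = {"present": present, "future": present + shift}

    env = EnvLayerSet(
        variables=list(config.env_vars),
        grids=grids,
        xllcorner=config.lon0,
        yllcorner=config.lat0,
        cellsize=config.cellsize,
        site_values={},
        standardization=pd.DataFrame(
            {"mean": 0.0, "sd": 1.0}, index=list(config.env_vars)
        ),
    )
    if sites is not None:
        attach_site_values(env, sites)
    else:
        # provisional calibration from grid cells; replaced once sites exist
        stats = {
            v: (grids[v]["present"].mean(), grids[v]["present"].std())
            for v in env.variables
        }
        env.standardization = pd.DataFrame(stats, index=["mean", "sd"]).T
    return env


def _bilinear(grid: np.ndarray, env: EnvLayerSet, lon, lat):
    """Bilinear interpolation at lon/lat points (cell-center registration)."""
    lonc, latc = env.lon_centers(), env.lat_centers()
    x = (np.asarray(lon) - lonc[0]) / env.cellsize
    y = (latc[0] - np.asarray(lat)) / env.cellsize  # row coordinate
    coords = np.vstack([y, x])
    return ndimage.map_coordinates(grid, coords, order=1, mode="nearest")


def attach_site_values(env: EnvLayerSet, sites: SiteFrame) -> None:
    """Sample the grids at site coordinates and set calibration statistics."""
    coords = sites.site_coords()
    for period in env.PERIODS:
        vals = {
            v: _bilinear(env.grids[v][period], env,
                         coords["longitude"], coords["latitude"])
            for v in env.variables
        }
        env.site_values[period] = pd.DataFrame(vals, index=coords.index)
    present = env.site_values["present"]
    env.standardization = pd.DataFrame(
        {"mean": present.mean(), "sd": present.std(ddof=0)}
    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


def make_populations(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SiteFrame, SimTruth]:
    """Place sites, assign individuals (1-2 per site) and draw ancestry.

    Cluster membership decays with distance from K focal points: row i of
    the true Q matrix is softmax(-d_ik / temperature) over clusters k, so
    clusters are spatially coherent and admixture increases away from the
    focal points.
    """
    if config.K_true < 1:
        raise ValueError("K_true must be >= 1")
    rng = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        if rng is None
        else rng
    )
    nrows, ncols = config.grid_shape
    n_cells = nrows * ncols
    if config.n_sites > n_cells:
        raise ValueError("more sites than grid cells")

    cells = rng.choice(n_cells, size=config.n_sites, replace=False)
    srow, scol = np.divmod(cells, ncols)
    cellsize = config.cellsize
    lon = config.lon0 + (scol + 0.5) * cellsize
    lat = config.lat0 + config.lat_span - (srow + 0.5) * (
        config.lat_span / nrows
    )

    # individuals: one per site, extras get a second individual
    site_ids = [f"site_{i:04d}" for i in range(config.n_sites)]
    extra = rng.choice(
        config.n_sites,
        size=max(0, config.n_individuals - config.n_sites),
        replace=False,
    )
    site_index = np.concatenate(
        [np.arange(config.n_sites), np.sort(extra)]
    )[: config.n_individuals]

    zr, zc = config.n_zones
    zone_row = np.minimum((srow * zr) // nrows, zr - 1)
    zone_col = np.minimum((scol * zc) // ncols, zc - 1)
    zone = zone_row * zc + zone_col + 1

    rows = []
    for j, s in enumerate(site_index):
        rows.append(
            {
                "individual_id": f"ind_{j:04d}",
                "site_id": site_ids[s],
                "longitude": lon[s],
                "latitude": lat[s],
                "zone": f"zone_{zone[s]:02d}",
            }
        )
    sites = SiteFrame(pd.DataFrame(rows))

    # focal points of the K clusters, well separated on the grid
    if config.K_true == 1:
        Q = np.ones((config.n_individuals, 1))
    else:
        theta = 2 * np.pi * np.arange(config.K_true) / config.K_true
        frow = nrows / 2 + 0.38 * nrows * np.sin(theta)
        fcol = ncols / 2 + 0.38 * ncols * np.cos(theta)
        irow, icol = srow[site_index], scol[site_index]
        d = np.hypot(
            irow[:, None] - frow[None, :], icol[:, None] - fcol[None, :]
        )
        if config.temperature <= 0:
            Q = np.zeros((config.n_individuals, config.K_true))
            Q[np.arange(config.n_individuals), d.argmin(axis=1)] = 1.0
        else:
            Q = softmax(-d / config.temperature, axis=1)

    truth = SimTruth(
        true_Q=Q,
        true_cluster_freqs=np.empty((config.K_true, 0)),
        adaptive_locus_ids=[],
        locus_effects=pd.DataFrame(columns=["id", "driver", "slope", "p0"]),
    )
    return sites, truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def make_genotypes(
    sites: SiteFrame,
    truth: SimTruth,
    env: EnvLayerSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw genotypes under Balding–Nichols drift plus logistic clines.

    Neutral locus l: ancestral frequency p0 ~ U(0.1, 0.9); cluster k
    frequency ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F); individual i expects
    frequency sum_k q_ik p_kl. Adaptive locus: expected frequency
    logistic(logit(p0) + effect_size * standardized driver value at the
    individual's site). Genotype ~ Binomial(2, expected frequency); entries
    then go missing completely at random at ``missing_rate``.
    """
    if not np.isfinite(config.effect_size):
        raise ValueError("effect_size must be finite")
    rng = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        if rng is None
        else rng
    )
    n = len(sites.data)
    if truth.true_Q.shape[0] != n:
        raise ValueError("truth and site table sizes differ")
    K = truth.true_Q.shape[1]
    Ln, La = config.n_neutral, config.n_adaptive
    L = Ln + La
    F = config.drift

    p0 = rng.uniform(0.1, 0.9, size=L)
    a = p0 * (1 - F) / F
    b = (1 - p0) * (1 - F) / F
    cluster_freqs = rng.beta(a[None, :], b[None, :], size=(K, L))
    expected = truth.true_Q @ cluster_freqs  # n x L

    # adaptive loci override: cline on one designated driver variable each
    if not env.site_values:
        attach_site_values(env, sites)
    site_of = sites.data["site_id"].to_numpy()
    present = env.site_values["present"]
    std = env.standardization
    adaptive_ids, effects = [], []
    drivers = list(config.driver_vars)
    for j in range(La):
        l = Ln + j
        var = drivers[j % len(drivers)]
        z = (
            present.loc[site_of, var].to_numpy() - std.loc[var, "mean"]
        ) / std.loc[var, "sd"]
        expected[:, l] = expit(logit(p0[l]) + config.effect_size * z)
        cluster_freqs[:, l] = p0[l]
        adaptive_ids.append(f"locus_{l:05d}")
        effects.append(
            {"id": adaptive_ids[-1], "driver": var,
             "slope": config.effect_size, "p0": p0[l]}
        )

    geno = rng.binomial(2, expected).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        # keep at least one call per locus
        all_gone = mask.all(axis=0)
        if all_gone.any():
            mask[rng.integers(0, n), all_gone] = False
        geno[mask] = np.nan

    # contig assignment: mostly unique, a fraction share the previous contig
    contigs = [f"ctg_{i:05d}" for i in range(L)]
    share = rng.random(L) < config.shared_contig_fraction
    for l in range(1, L):
        if share[l]:
            contigs[l] = contigs[l - 1]
    meta = pd.DataFrame(
        {
            "id": [f"locus_{l:05d}" for l in range(L)],
            "contig": contigs,
            "position": rng.integers(100, 10000, size=L),
            "ref": "A",
            "alt": "T",
        }
    )
    g = GenotypeMatrix(geno, meta, list(sites.data["individual_id"]))

    truth.true_cluster_freqs = cluster_freqs
    truth.adaptive_locus_ids = adaptive_ids
    truth.locus_effects = pd.DataFrame(effects, columns=["id", "driver", "slope", "p0"])
    return g


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SiteFrame, EnvLayerSet, SimTruth]:
    """Run the three generator stages with one master seed."""
    sites, truth = make_populations(config)
    env = make_environment(config, sites=sites)
    g = make_genotypes(sites, truth, env, config)
    return g, sites, env, truth
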