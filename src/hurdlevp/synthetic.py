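"""Synthetic study generator.

Emulates a national light-trap monitoring design: a categorical land-cover
raster with spatially clustered classes over several epochs, daily climate
with a latitudinal gradient, a warming trend and interannual noise, species
traits, model parameters drawn from the model's own prior family (so the
fitted model is well-specified), and hurdle-model community observations at
a southern-biased subset of grid cells. Ground-truth parameters feed the
recovery tests and the true variance partition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import climate as clim
from . import community as comm
from .design import DesignMatrix, build_design_matrix
from .landscape import LEGEND, FOREST_CODES, LandscapeRaster, habitat_features
from .model import PosteriorDraws

#: Target class proportions for terrestrial classes (codes 1,2,3,4,7,8)
#: and the water/wetland overlay (codes 6, 5), loosely boreal.
TERRESTRIAL_PROPS = {1: 0.08, 2: 0.34, 3: 0.16, 4: 0.18, 7: 0.06, 8: 0.18}
WATER_PROP = 0.07
WETLAND_PROP = 0.08


def generate_landscape(
    seed: int,
    rows: int = 128,
    cols: int = 128,
    n_epochs: int = 1,
    autocorr_scale: float = 6.0,
    change_rate: float = 0.05,
    pixel_size: float = 20.0,
    epoch_years: tuple[int, ...] | None = None,
    change_target_class: int | None = None,
    change_directional_frac: float = 0.0,
) -> list[LandscapeRaster]:
    """Generate one clustered categorical raster per epoch.

    Classes come from quantile-slicing a smoothed Gaussian random field
    (terrestrial classes) overlaid with an independent water/wetland
    field, so classes form spatial clusters whose aggregation and
    diversity vary across buffers. Between consecutive epochs at most
    ``change_rate`` of pixels change; each changed pixel copies a random
    rook neighbour's class (spatially coherent churn), except that a
    ``change_directional_frac`` fraction converts to
    ``change_target_class`` instead — a directional land-use conversion
    that accumulates into habitat trends across epochs.
    """
    if rows < 32 or cols < 32:
        raise ValueError("rows and cols must be >= 32")
    if not 0 <= change_rate < 1:
        raise ValueError("change_rate must be in [0, 1)")
    if autocorr_scale <= 0:
        raise ValueError("autocorr_scale must be positive")
    rng = np.random.default_rng(seed)

    f_land = gaussian_filter(rng.normal(size=(rows, cols)), autocorr_scale)
    f_water = gaussian_filter(rng.normal(size=(rows, cols)), autocorr_scale)

    cat = np.empty((rows, cols), dtype=np.int64)
    codes = list(TERRESTRIAL_PROPS)
    props = np.array([TERRESTRIAL_PROPS[c] for c in codes])
    edges = np.quantile(f_land, np.cumsum(props / props.sum())[:-1])
    cat[:] = codes[-1]
    idx = np.digitize(f_land, edges)
    for i, c in enumerate(codes):
        cat[idx == i] = c
    qw = np.quantile(f_water, [1 - WATER_PROP - WETLAND_PROP, 1 - WATER_PROP])
    cat[f_water > qw[1]] = 6
    cat[(f_water > qw[0]) & (f_water <= qw[1])] = 5

    if epoch_years is None:
        epoch_years = tuple(2000 + 6 * i for i in range(n_epochs))
    rasters = [LandscapeRaster(cat, pixel_size, epoch_years[0])]
    n_change = int(math.floor(change_rate * rows * cols))
    for e in range(1, n_epochs):
        prev = rasters[-1].categories
        nxt = prev.copy()
        if n_change > 0:
            flat = rng.choice(rows * cols, size=n_change, replace=False)
            rr, cc = np.unravel_index(flat, (rows, cols))
            dr, dc = np.array([(0, 1), (0, -1), (1, 0), (-1, 0)])[
                rng.integers(0, 4, size=n_change)
            ].T
            nr = np.clip(rr + dr, 0, rows - 1)
            nc = np.clip(cc + dc, 0, cols - 1)
            nxt[rr, cc] = prev[nr, nc]
            if change_target_class is not None and change_directional_frac:
                conv = rng.uniform(size=n_change) < change_directional_frac
                nxt[rr[conv], cc[conv]] = change_target_class
        rasters.append(LandscapeRaster(nxt, pixel_size, epoch_years[e]))
    return rasters


@dataclass
class ClimateSeries:
    """Daily climate per cell and year over the fixed season calendar.

    Arrays are (n_cells, n_years, n_days): sampling-season temperature and
    precipitation (198 days, 1 Apr - 15 Oct) and preceding-winter
    temperature and snow depth (167 days, 16 Oct - 31 Mar).
    """

    summer_temp: np.ndarray
    summer_precip: np.ndarray
    winter_temp: np.ndarray
    winter_snow: np.ndarray
    latitudes: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        if (self.winter_snow < 0).any():
            raise ValueError("snow depth must be non-negative")
        if (self.summer_precip < 0).any():
            raise ValueError("precipitation must be non-negative")

    def features(self) -> pd.DataFrame:
        """The four climate covariates for every (cell, year)."""
        rows = []
        for i in range(len(self.latitudes)):
            for t, year in enumerate(self.years):
                rows.append(
                    {
                        "cell": i,
                        "year": int(year),
                        **clim.climate_features(
                            self.summer_temp[i, t],
                            self.winter_temp[i, t],
                            self.winter_snow[i, t],
                            self.summer_precip[i, t],
                        ),
                    }
                )
        return pd.DataFrame(rows)


def generate_climate(
    seed: int,
    latitudes: np.ndarray,
    years: np.ndarray,
    gradient: float = 0.8,
    warming_trend: float = 0.04,
    sd_interannual: float = 0.8,
) -> ClimateSeries:
    """Daily climate series with a latitudinal gradient and warming trend.

    Expected summer temperature decreases by ``gradient`` degC per unit
    latitude and increases by ``warming_trend`` degC per year; cell-year
    deviations are iid normal with SD ``sd_interannual`` (temperature;
    precipitation and snow deviations scale proportionally). With zero
    trend and zero SD every year's daily series is identical per cell.
    """
    latitudes = np.asarray(latitudes, dtype=float)
    years = np.asarray(years, dtype=int)
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    rng = np.random.default_rng(seed)
    n_c, n_y = len(latitudes), len(years)
    sd_day = np.arange(clim.SUMMER_DAYS)
    wd_day = np.arange(clim.WINTER_DAYS)
    # deterministic seasonal shapes
    summer_shape = 11.0 + 9.0 * np.sin(np.pi * (sd_day + 1) / clim.SUMMER_DAYS)
    winter_shape = 2.0 - 9.0 * np.sin(np.pi * (wd_day + 1) / clim.WINTER_DAYS)
    precip_shape = 2.0 + 0.8 * np.sin(2 * np.pi * sd_day / clim.SUMMER_DAYS)
    snow_shape = np.sin(np.pi * (wd_day + 1) / clim.WINTER_DAYS)

    lat0 = latitudes.min()
    dy = years - years[0]
    # summer and winter weather deviate independently (winters more
    # variable), so thermal-sum and chilling covariates are not collinear
    dev_ts = rng.normal(0, 1, size=(n_c, n_y)) * sd_interannual
    dev_tw = rng.normal(0, 1, size=(n_c, n_y)) * (1.5 * sd_interannual)
    dev_p = rng.normal(0, 1, size=(n_c, n_y)) * (0.3 * sd_interannual)
    dev_s = rng.normal(0, 1, size=(n_c, n_y)) * (3.0 * sd_interannual)

    rel_lat = latitudes[:, None] - lat0
    shift_summer = -gradient * rel_lat + warming_trend * dy[None, :] + dev_ts
    shift_winter = (
        -1.3 * gradient * rel_lat + warming_trend * dy[None, :] + dev_tw
    )
    summer_temp = summer_shape[None, None, :] + shift_summer[:, :, None]
    winter_temp = winter_shape[None, None, :] + shift_winter[:, :, None]
    precip = np.clip(
        precip_shape[None, None, :] + dev_p[:, :, None], 0.0, None
    )
    snow_amp = np.clip(
        6.0 + 2.5 * rel_lat - 1.2 * dev_tw + dev_s, 0.0, None
    )
    snow = np.clip(snow_amp[:, :, None] * snow_shape[None, None, :], 0.0, None)
    return ClimateSeries(
        summer_temp=summer_temp,
        summer_precip=precip,
        winter_temp=winter_temp,
        winter_snow=snow,
        latitudes=latitudes,
        years=years,
    )


# ---------------------------------------------------------------------------
# model parameters and community simulation


@dataclass
class TrueParameters:
    """Ground-truth parameters of one hurdle-model part."""

    beta: np.ndarray  # (p, S)
    gamma: np.ndarray  # (p, q)
    omega: np.ndarray  # (p, p)
    lambdas: dict[str, np.ndarray]  # level -> (k, S)
    sigma: np.ndarray  # (S,)
    colnames: list[str]
    blocks: dict[str, list[int]]
    species: list

    def __post_init__(self) -> None:
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")

    def as_single_draw(self) -> PosteriorDraws:
        """Wrap the truth as a one-draw posterior so estimator code paths
        (variance partitioning, prediction) apply to it verbatim."""
        return PosteriorDraws(
            part="TRUE",
            beta=self.beta[None],
            gamma=self.gamma[None],
            omega=self.omega[None],
            lambdas={r: lam[None] for r, lam in self.lambdas.items()},
            etas={
                r: np.zeros((1, 1, lam.shape[0]))
                for r, lam in self.lambdas.items()
            },
            sigma=self.sigma[None],
            colnames=list(self.colnames),
            blocks={k: list(v) for k, v in self.blocks.items()},
            species=list(self.species),
            level_values={r: [] for r in self.lambdas},
        )

    def to_netcdf(self, path: str | Path) -> None:
        self.as_single_draw().to_netcdf(path)


DEFAULT_EFFECT_SCALES = {
    "intercept": 0.6,
    "habitat": 0.45,
    "climate": 0.30,
    "effort": 0.25,
}
DEFAULT_LOADING_SCALES = {"site": 0.4, "year": 0.3, "zone": 0.3}


def generate_parameters(
    seed: int | np.random.Generator,
    trait_matrix: pd.DataFrame | np.ndarray,
    colnames: list[str],
    blocks: Mapping[str, list[int]],
    n_factors: Mapping[str, int] | None = None,
    effect_scales: Mapping[str, float] | None = None,
    loading_scales: Mapping[str, float] | None = None,
    gamma_frac: float = 0.6,
    omega: np.ndarray | None = None,
    omega_frac: float = 0.8,
    sigma_range: tuple[float, float] = (0.3, 0.8),
    species: list | None = None,
    center_design_mean: np.ndarray | None = None,
    intercept_loc: float = 0.0,
) -> TrueParameters:
    """Draw ground-truth parameters from the model's prior family.

    Column k of block b gets scale ``s_k = effect_scales[b]``; trait
    effects are N(0, (gamma_frac s_k)^2) and the coefficient residual
    covariance defaults to ``Omega = diag((omega_frac gamma_frac s_k)^2)``
    so species coefficients scatter around their trait-predicted means.
    ``omega=0`` (or an all-zero matrix) gives B = Gamma t_j exactly; a
    supplied Omega with negative eigenvalues is rejected.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    T = (
        trait_matrix.to_numpy(dtype=float)
        if isinstance(trait_matrix, pd.DataFrame)
        else np.asarray(trait_matrix, dtype=float)
    )
    S, q = T.shape
    p = len(colnames)
    n_factors = dict(
        n_factors if n_factors is not None else {"site": 2, "year": 1, "zone": 1}
    )
    effect_scales = dict(effect_scales or DEFAULT_EFFECT_SCALES)
    loading_scales = dict(loading_scales or DEFAULT_LOADING_SCALES)
    if any(v < 0 for v in n_factors.values()):
        raise ValueError("factor counts must be >= 0")

    col_scale = np.empty(p)
    for b, idx in blocks.items():
        for i in idx:
            col_scale[i] = effect_scales[b]

    gamma = rng.normal(size=(p, q)) * (gamma_frac * col_scale)[:, None]
    if center_design_mean is not None:
        # choose the intercept row of Gamma so the trait-predicted linear
        # predictor at the average unit equals intercept_loc for every
        # species (quadratic columns have non-zero means that would
        # otherwise shift whole species); B then stays exactly
        # prior-distributed around Gamma t_j
        xbar = np.asarray(center_design_mean, dtype=float)
        i0 = blocks["intercept"][0]
        rest = [i for i in range(p) if i != i0]
        gamma[i0, :] = -(xbar[rest] @ gamma[rest, :]) / xbar[i0]
        gamma[i0, 0] += intercept_loc / xbar[i0]
    if omega is None:
        omega_m = np.diag((omega_frac * gamma_frac * col_scale) ** 2)
    else:
        omega_m = np.zeros((p, p)) if np.isscalar(omega) and omega == 0 else (
            np.asarray(omega, dtype=float)
        )
        if omega_m.shape != (p, p):
            raise ValueError("omega must be (p, p)")
        if not np.allclose(omega_m, omega_m.T):
            raise ValueError("omega must be symmetric")
        ev = np.linalg.eigvalsh(omega_m)
        if ev.min() < -1e-10:
            raise ValueError("omega must be positive semi-definite")
    evals, evecs = np.linalg.eigh(omega_m)
    sqrt_omega = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    beta = gamma @ T.T + sqrt_omega @ rng.normal(size=(p, S))

    lambdas = {}
    for r, k in n_factors.items():
        if k <= 0:
            continue
        sd = loading_scales.get(r, 0.3) * np.sqrt(
            0.5 ** np.arange(k)
        )
        lambdas[r] = rng.normal(size=(k, S)) * sd[:, None]
    sigma = rng.uniform(*sigma_range, size=S)
    if species is None:
        species = [f"sp{j}" for j in range(S)]
    return TrueParameters(
        beta=beta,
        gamma=gamma,
        omega=omega_m,
        lambdas=lambdas,
        sigma=sigma,
        colnames=list(colnames),
        blocks={k: list(v) for k, v in blocks.items()},
        species=list(species),
    )


def simulate_community(
    params_pa: TrueParameters,
    params_ab: TrueParameters,
    X: np.ndarray | DesignMatrix,
    levels: Mapping[str, np.ndarray],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate trap-year counts from the hurdle model.

    Presence: z = X B + sum_r eta_r Lambda_r + N(0,1) > 0. Given
    presence, count = round(exp(X B_ab + RE_ab + N(0, sigma_j))) with a
    floor of 1 (the abundance part conditions on presence). Factor scores
    are drawn fresh per level value.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Xa = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    n = Xa.shape[0]
    S = params_pa.beta.shape[1]

    def re_total(params: TrueParameters) -> np.ndarray:
        tot = np.zeros((n, S))
        for r, lam in params.lambdas.items():
            idx = np.asarray(levels[r], dtype=int)
            eta = rng.normal(size=(idx.max() + 1, lam.shape[0]))
            tot += eta[idx] @ lam
        return tot

    z = Xa @ params_pa.beta + re_total(params_pa) + rng.normal(size=(n, S))
    present = z > 0
    logmu = (
        Xa @ params_ab.beta
        + re_total(params_ab)
        + rng.normal(size=(n, S)) * params_ab.sigma[None, :]
    )
    counts = np.where(
        present, np.maximum(1, np.round(np.exp(logmu))), 0
    ).astype(np.int64)
    return counts


def true_variance_partition(
    params: TrueParameters,
    X_grid: DesignMatrix | np.ndarray,
    groups: dict[str, list[int]] | None = None,
):
    """Ground-truth variance partition over a grid (recovery oracle).

    Runs the estimator's own partitioning code on the true parameters
    wrapped as a single posterior draw.
    """
    from .variance import variance_partition

    return variance_partition(
        params.as_single_draw(), X_grid, groups=groups
    )


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyConfig:
    """Scale and condition settings of a synthetic study.

    Defaults are the package's desk-scale study: 15 species at 80 sites
    over 12 years with a 500-cell prediction grid, preserving all the
    structure of the monitoring design (southern-biased sites, four
    latitude-band zones, epoch-wise land cover, effort variation).
    """

    n_species: int = 15
    n_sites: int = 80
    n_years: int = 12
    grid_rows: int = 25
    grid_cols: int = 20
    cell_block_px: int = 10
    margin_px: int = 14
    pixel_size: float = 20.0
    buffer_side: float = 500.0
    year0: int = 1998
    epoch_spacing: int = 6
    autocorr_scale: float = 6.0
    change_rate: float = 0.05
    change_target_class: int | None = None
    change_directional_frac: float = 0.0
    lat_min: float = 60.0
    lat_max: float = 67.5
    gradient: float = 0.8
    warming_trend: float = 0.04
    sd_interannual: float = 0.8
    site_bias: float = 0.5  # sampling probability multiplier per zone band
    effort_days_range: tuple[int, int] = (80, 180)
    grid_effort_days: int = 120
    n_factors: dict = field(
        default_factory=lambda: {"site": 2, "year": 1, "zone": 1}
    )
    effect_scales: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SCALES)
    )
    loading_scales: dict = field(
        default_factory=lambda: dict(DEFAULT_LOADING_SCALES)
    )
    sigma_range: tuple[float, float] = (0.3, 0.8)
    #: abundance-part effects shrunk relative to occurrence so simulated
    #: counts stay in a realistic range (tens, not millions)
    ab_scale_factor: float = 0.55

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year0, self.year0 + self.n_years)

    @property
    def epoch_years(self) -> tuple[int, ...]:
        n_ep = max(1, math.ceil(self.n_years / self.epoch_spacing))
        return tuple(self.year0 + 2 + self.epoch_spacing * i
                     for i in range(n_ep))


def trend_experiment_config(**overrides) -> "StudyConfig":
    """Study conditions for the single-driver scenario experiment:
    habitat-driven trends (directional conversion to agriculture every
    second year) and climate-driven interannual noise (no warming trend).
    """
    base = dict(
        n_years=12,
        warming_trend=0.0,
        change_rate=0.10,
        change_target_class=8,
        change_directional_frac=0.8,
        sd_interannual=1.0,
        epoch_spacing=2,
        grid_rows=12,
        grid_cols=10,
    )
    base.update(overrides)
    return StudyConfig(**base)


@dataclass
class SyntheticStudy:
    """A complete synthetic study with ground truth."""

    config: StudyConfig
    seed: int
    rasters: list[LandscapeRaster]
    grid: pd.DataFrame  # cell, row, col, lat, zone
    grid_covariates: pd.DataFrame  # cell x year features
    sampled_covariates: pd.DataFrame  # site x year features
    community: comm.CommunityTable
    traits: pd.DataFrame
    trait_matrix: pd.DataFrame
    params: dict[str, TrueParameters]
    X_train: DesignMatrix
    X_grid: DesignMatrix
    levels_train: dict[str, np.ndarray]
    levels_grid: dict[str, np.ndarray]
    site_cells: np.ndarray
    composition: pd.DataFrame  # full land-cover composition per cell
    n_clumpiness_imputed: int = 0


def _generate_traits(rng: np.random.Generator, n_species: int) -> pd.DataFrame:
    """Trait table mixing wingless, ordinary and one large-winged species."""
    wing = rng.uniform(18.0, 45.0, size=n_species)
    n_wingless = max(1, round(0.05 * n_species))
    wing[:n_wingless] = 0.0
    if n_species >= 10:
        wing[n_wingless] = 55.5
    groups = rng.choice(
        comm.HOST_GROUPS,
        size=n_species,
        p=[0.35, 0.10, 0.10, 0.25, 0.10, 0.10],
    )
    df = pd.DataFrame(
        {
            "species": [f"sp{j}" for j in range(n_species)],
            "wing_span": wing,
            "host_group": groups,
        }
    ).set_index("species")
    return comm.assign_wing_bins(df)


def _habitat_table(
    raster: LandscapeRaster,
    centers: np.ndarray,
    buffer_side: float,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Habitat features and full composition per cell for one epoch.

    Undefined clumpiness (forest-free or all-forest buffers) is imputed
    at the metric's limit (0 for forest-free, 1 for all-forest)."""
    from .landscape import buffer_proportions

    feats, comps = [], []
    n_imputed = 0
    for r, c in centers:
        f = habitat_features(raster, (r, c), buffer_side)
        if np.isnan(f["hab_clumpiness"]):
            forest_p = (
                f["hab_prop_broadleaf"]
                + f["hab_prop_conifer"]
                + f["hab_prop_mixed"]
            )
            f["hab_clumpiness"] = 1.0 if forest_p > 0.5 else 0.0
            n_imputed += 1
        feats.append(f)
        comps.append(buffer_proportions(raster, (r, c), buffer_side))
    comp = pd.DataFrame(comps)
    comp.columns = [LEGEND[c] for c in comp.columns]
    return pd.DataFrame(feats), comp, n_imputed


def generate_study(
    config: StudyConfig | None = None, seed: int = 0
) -> SyntheticStudy:
    """Generate a full synthetic study: landscape, climate, traits,
    parameters, covariate tables, design matrices and observed community.
    Deterministic given (config, seed)."""
    cfg = config or StudyConfig()
    root = np.random.SeedSequence(seed)
    s_land, s_clim, s_traits, s_pa, s_ab, s_comm, s_sites, s_effort = (
        np.random.default_rng(c) for c in root.spawn(8)
    )

    rows_px = cfg.grid_rows * cfg.cell_block_px + 2 * cfg.margin_px
    cols_px = cfg.grid_cols * cfg.cell_block_px + 2 * cfg.margin_px
    rasters = generate_landscape(
        seed=int(s_land.integers(2**31)),
        rows=rows_px,
        cols=cols_px,
        n_epochs=len(cfg.epoch_years),
        autocorr_scale=cfg.autocorr_scale,
        change_rate=cfg.change_rate,
        pixel_size=cfg.pixel_size,
        epoch_years=cfg.epoch_years,
        change_target_class=cfg.change_target_class,
        change_directional_frac=cfg.change_directional_frac,
    )

    # grid geometry: row 0 is the southern edge
    cells = np.arange(cfg.n_cells)
    rowi, coli = np.divmod(cells, cfg.grid_cols)
    lat = cfg.lat_min + (cfg.lat_max - cfg.lat_min) * rowi / max(
        1, cfg.grid_rows - 1
    )
    zone = np.minimum(3, (4 * rowi) // cfg.grid_rows).astype(int)
    grid = pd.DataFrame(
        {"cell": cells, "row": rowi, "col": coli, "lat": lat, "zone": zone}
    )
    centers = np.column_stack(
        [
            cfg.margin_px + rowi * cfg.cell_block_px + cfg.cell_block_px // 2,
            cfg.margin_px + coli * cfg.cell_block_px + cfg.cell_block_px // 2,
        ]
    )

    hab_by_epoch, comp_by_epoch, n_imp = {}, {}, 0
    for raster in rasters:
        h, cmp_, ni = _habitat_table(raster, centers, cfg.buffer_side)
        hab_by_epoch[raster.epoch] = h
        comp_by_epoch[raster.epoch] = cmp_
        n_imp += ni

    series = generate_climate(
        seed=int(s_clim.integers(2**31)),
        latitudes=lat,
        years=cfg.years,
        gradient=cfg.gradient,
        warming_trend=cfg.warming_trend,
        sd_interannual=cfg.sd_interannual,
    )
    clim_feats = series.features()

    grid_rows_list = []
    for year in cfg.years:
        ep = clim.epoch_for_year(int(year), cfg.epoch_years)
        hab = hab_by_epoch[ep]
        cf = clim_feats[clim_feats["year"] == year].set_index("cell")
        block = hab.copy()
        block["cell"] = cells
        block["year"] = int(year)
        block["zone"] = zone
        block["lat"] = lat
        for c in ("clim_gdd", "clim_cdd", "clim_snow", "clim_precip"):
            block[c] = cf.loc[cells, c].to_numpy()
        block["effort_logdays"] = np.log(cfg.grid_effort_days)
        grid_rows_list.append(block)
    grid_cov = pd.concat(grid_rows_list, ignore_index=True)

    # southern-biased site selection: sampling probability halves per zone
    pr = cfg.site_bias ** zone.astype(float)
    pr = pr / pr.sum()
    site_cells = np.sort(
        s_sites.choice(cells, size=cfg.n_sites, replace=False, p=pr)
    )
    site_of = {c: i for i, c in enumerate(site_cells)}

    samp = grid_cov[grid_cov["cell"].isin(site_cells)].copy()
    samp["site"] = samp["cell"].map(site_of)
    days = s_effort.integers(
        cfg.effort_days_range[0],
        cfg.effort_days_range[1] + 1,
        size=len(samp),
    )
    samp["effort_days"] = days
    samp["effort_logdays"] = np.log(days.astype(float))
    samp = samp.sort_values(["site", "year"]).reset_index(drop=True)

    X_train = build_design_matrix(samp, unit_columns=("site", "year"))
    X_grid = build_design_matrix(
        grid_cov,
        standardization_stats=X_train.stats,
        unit_columns=("cell", "year"),
    )

    traits = _generate_traits(s_traits, cfg.n_species)
    trait_matrix = comm.encode_traits(traits)

    year_index = {int(y): t for t, y in enumerate(cfg.years)}
    levels_train = {
        "site": samp["site"].to_numpy(int),
        "year": samp["year"].map(year_index).to_numpy(int),
        "zone": samp["zone"].to_numpy(int),
    }
    levels_grid = {
        "site": np.full(len(grid_cov), -1, dtype=int),
        "year": grid_cov["year"].map(year_index).to_numpy(int),
        "zone": grid_cov["zone"].to_numpy(int),
    }

    common = dict(
        trait_matrix=trait_matrix,
        colnames=X_train.colnames,
        blocks=X_train.blocks,
        n_factors=cfg.n_factors,
        effect_scales=cfg.effect_scales,
        loading_scales=cfg.loading_scales,
        sigma_range=cfg.sigma_range,
        species=list(traits.index),
    )
    xbar = X_train.X.mean(axis=0)
    ab_common = dict(
        common,
        effect_scales={
            k: v * cfg.ab_scale_factor for k, v in cfg.effect_scales.items()
        },
        loading_scales={
            k: v * cfg.ab_scale_factor for k, v in cfg.loading_scales.items()
        },
    )
    params = {
        "PA": generate_parameters(
            s_pa, **common, center_design_mean=xbar, intercept_loc=0.0
        ),
        "AB": generate_parameters(
            s_ab, **ab_common, center_design_mean=xbar, intercept_loc=3.2
        ),
    }

    counts = simulate_community(
        params["PA"], params["AB"], X_train, levels_train, s_comm
    )
    counts_df = pd.DataFrame(
        counts,
        columns=list(traits.index),
        index=pd.MultiIndex.from_frame(samp[["site", "year"]]),
    )
    community = comm.CommunityTable(
        counts=counts_df,
        effort_days=pd.Series(
            samp["effort_days"].to_numpy(), index=counts_df.index
        ),
        zone=pd.Series(samp["zone"].to_numpy(), index=counts_df.index),
        coords=pd.DataFrame(
            {"lat": samp["lat"].to_numpy()}, index=counts_df.index
        ),
    )

    composition = comp_by_epoch[rasters[0].epoch].copy()
    composition.index = pd.Index(cells, name="cell")
    return SyntheticStudy(
        config=cfg,
        seed=seed,
        rasters=rasters,
        grid=grid,
        grid_covariates=grid_cov,
        sampled_covariates=samp,
        community=community,
        traits=traits,
        trait_matrix=trait_matrix,
        params=params,
        X_train=X_train,
        X_grid=X_grid,
        levels_train=levels_train,
        levels_grid=levels_grid,
        site_cells=site_cells,
        composition=composition,
        n_clumpiness_imputed=n_imp,
    )


def config_to_dict(cfg: StudyConfig) -> dict:
    d = asdict(cfg)
    d["effort_days_range"] = list(d["effort_days_range"])
    d["sigma_range"] = list(d["sigma_range"])
    return d


def config_from_dict(d: Mapping) -> StudyConfig:
    d = dict(d)
    for key in ("effort_days_range", "sigma_range"):
        if key in d:
            d[key] = tuple(d[key])
    return StudyConfig(**d)
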