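"""Counterfactual scenarios and community-diversity surfaces.

Two single-driver scenarios isolate the community-level imprint of each
driver: in the habitat-only scenario climate covariates are frozen at
each cell's mean over the first five years; in the climate-only scenario
habitat covariates are frozen at their first-epoch values. Community
metrics are expected species richness (sum of occurrence probabilities)
and Hill-Simpson evenness (inverse-Simpson diversity over richness);
per-cell linear trends and residual variability summarise their temporal
behaviour.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats as _stats

CLIMATE_BASELINE_YEARS = 5
SCENARIO_KINDS = ("full", "climate_only", "habitat_only")


@dataclass
class DiversitySurface:
    """Grid-cell x year values of one community metric."""

    values: np.ndarray  # (n_cells, n_years)
    cells: np.ndarray
    years: np.ndarray
    metric: str

    def temporal_mean(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        c, y = np.meshgrid(self.cells, self.years, indexing="ij")
        return pd.DataFrame(
            {
                "cell": c.ravel(),
                "year": y.ravel(),
                self.metric: self.values.ravel(),
            }
        )


def build_scenario(
    covariates_by_year: pd.DataFrame,
    kind: str,
    n_baseline_years: int = CLIMATE_BASELINE_YEARS,
) -> pd.DataFrame:
    """Construct a counterfactual covariate table.

    ``covariates_by_year`` has one row per (cell, year) with ``hab_*`` and
    ``clim_*`` feature columns. ``habitat_only`` replaces every climate
    column by the cell's mean over the first ``n_baseline_years`` years;
    ``climate_only`` replaces every habitat column by the cell's
    first-year (first-epoch) values; ``full`` returns a copy unchanged.
    The operation is idempotent.
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"kind must be one of {SCENARIO_KINDS}")
    df = covariates_by_year.copy()
    years = np.sort(df["year"].unique())
    if len(years) <= n_baseline_years:
        raise ValueError(
            f"need more than {n_baseline_years} years of covariates"
        )
    if kind == "full":
        return df
    clim_cols = [c for c in df.columns if c.startswith("clim_")]
    hab_cols = [c for c in df.columns if c.startswith("hab_")]
    if kind == "habitat_only":
        base_years = years[:n_baseline_years]
        base = (
            df[df["year"].isin(base_years)]
            .groupby("cell")[clim_cols]
            .mean()
        )
        df[clim_cols] = base.loc[df["cell"]].to_numpy()
    else:  # climate_only
        first = df[df["year"] == years[0]].set_index("cell")[hab_cols]
        df[hab_cols] = first.loc[df["cell"]].to_numpy()
    return df


def expected_richness(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Expected species richness: sum of occurrence probabilities over the
    species axis."""
    return np.asarray(p).sum(axis=axis)


def hill_simpson_evenness(
    abundances: np.ndarray, n_species: int | None = None
) -> float:
    """Hill-Simpson evenness of one community.

    With relative abundances pi_j, the inverse-Simpson (Hill order 2)
    diversity is D2 = 1 / sum pi_j^2 and evenness = D2 / S. By default S
    counts species with positive abundance; ``n_species`` overrides it
    (e.g. to count all modelled species). An all-zero community is NaN.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    tot = a.sum()
    if tot == 0:
        return float("nan")
    pi = a / tot
    d2 = 1.0 / (pi**2).sum()
    s = int((a > 0).sum()) if n_species is None else int(n_species)
    return float(d2 / s)


def evenness_surface(
    expected_abundance: np.ndarray, n_species: int | None = None
) -> np.ndarray:
    """Vectorised Hill-Simpson evenness over a (..., species) array."""
    a = np.asarray(expected_abundance, dtype=float)
    tot = a.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), 0.0)
        d2 = 1.0 / (pi**2).sum(axis=-1)
    s = (a > 0).sum(axis=-1) if n_species is None else n_species
    out = np.where(tot[..., 0] > 0, d2 / s, np.nan)
    return out


def fit_cell_trends(
    surface: DiversitySurface,
    standardize: str = "cell_mean",
) -> pd.DataFrame:
    """Per-cell OLS trend and residual variability of a diversity metric.

    For each cell, ``metric_t = a + b t`` by ordinary least squares over
    years; the slope is the local trend. Residuals are standardised by
    the cell's temporal mean of the metric (``standardize='cell_mean'``,
    giving relative variability comparable across cells) or left raw
    (``'none'``); variability is their variance. Constant series give
    slope 0 and variability 0.
    """
    if standardize not in ("cell_mean", "none"):
        raise ValueError("standardize must be 'cell_mean' or 'none'")
    Y = np.asarray(surface.values, dtype=float)
    t = np.asarray(surface.years, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 years per cell")
    tc = t - t.mean()
    denom = (tc**2).sum()
    ybar = Y.mean(axis=1, keepdims=True)
    slope = (Y - ybar) @ tc / denom
    resid = Y - ybar - slope[:, None] * tc[None, :]
    if standardize == "cell_mean":
        scale = np.where(np.abs(ybar[:, 0]) > 1e-12, ybar[:, 0], 1.0)
        resid = resid / scale[:, None]
    variability = resid.var(axis=1)
    return pd.DataFrame(
        {
            "cell": surface.cells,
            "mean": ybar[:, 0],
            "slope": slope,
            "variability": variability,
        }
    )


def scenario_comparison(
    full: pd.DataFrame,
    climate_only: pd.DataFrame,
    habitat_only: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cell deltas of mean, slope and variability between scenario
    trend tables (as produced by :func:`fit_cell_trends`).

    Deltas are scenario minus full; summary quantiles are left to the
    caller — no decision logic is applied.
    """
    out = full[["cell"]].copy()
    for name, df in (("climate_only", climate_only),
                     ("habitat_only", habitat_only)):
        if not np.array_equal(df["cell"].to_numpy(), out["cell"].to_numpy()):
            raise ValueError("scenario tables must share the same cells")
        for stat in ("mean", "slope", "variability"):
            out[f"d_{stat}_{name}"] = (
                df[stat].to_numpy() - full[stat].to_numpy()
            )
    return out


def predict_diversity_surfaces(
    draws_pa,
    draws_ab,
    X,
    levels_new: dict,
    cells: np.ndarray,
    years: np.ndarray,
    draw_step: int = 1,
    chunk: int = 50,
) -> dict[str, "DiversitySurface"]:
    """Posterior-mean richness and evenness surfaces over a grid.

    Streams over (optionally thinned) posterior draws, accumulating the
    posterior means of occurrence probability and unconditional expected
    abundance, then folds them into per-cell-year surfaces. Grid units
    must be ordered year-major (all cells of the first year, then the
    next).
    """
    from .model import predict

    D = draws_pa.n_draws
    sel = np.arange(0, D, draw_step)
    Xarr = X.X if hasattr(X, "X") else np.asarray(X)
    n = Xarr.shape[0]
    S = len(draws_pa.species)
    p_sum = np.zeros((n, S))
    pm_sum = np.zeros((n, S))
    for i0 in range(0, len(sel), chunk):
        ds = sel[i0 : i0 + chunk]
        pred = predict(draws_pa, draws_ab, Xarr, levels_new=levels_new,
                       d_slice=ds)
        p_sum += pred["p"].sum(axis=0)
        pm_sum += pred["expected_abundance"].sum(axis=0)
    p_mean = p_sum / len(sel)
    pm_mean = pm_sum / len(sel)

    order_cells = np.unique(cells)
    pos = {c: i for i, c in enumerate(order_cells)}
    ci = np.array([pos[c] for c in cells])
    n_cells, n_years = len(order_cells), len(years)
    P = np.zeros((n_cells, n_years, S))
    M = np.zeros((n_cells, n_years, S))
    per_year = n // n_years
    for t in range(n_years):
        sl = slice(t * per_year, (t + 1) * per_year)
        P[ci[sl], t] = p_mean[sl]
        M[ci[sl], t] = pm_mean[sl]
    return diversity_surfaces(P, M, order_cells, years, n_species=S)


def scenario_slope_agreement(
    grid_covariates: pd.DataFrame,
    standardization_stats: dict,
    draws_pa,
    draws_ab,
    levels_grid: dict | None,
    years: np.ndarray,
    metric: str = "richness",
    n_baseline_years: int = CLIMATE_BASELINE_YEARS,
    draw_step: int = 1,
) -> dict[str, float]:
    """Spearman agreement of single-driver slope maps with the full map.

    Builds the three scenario covariate tables, predicts the diversity
    surfaces, fits per-cell trends, and correlates each single-driver
    scenario's slope map with the full scenario's across cells.
    """
    from .design import build_design_matrix

    trends = {}
    for kind in SCENARIO_KINDS:
        cov = build_scenario(grid_covariates, kind, n_baseline_years)
        Xs = build_design_matrix(
            cov, standardization_stats=standardization_stats
        )
        surf = predict_diversity_surfaces(
            draws_pa, draws_ab, Xs, levels_grid,
            cov["cell"].to_numpy(), years, draw_step=draw_step,
        )[metric]
        trends[kind] = fit_cell_trends(surf)
    full_slope = trends["full"]["slope"].to_numpy()
    return {
        "habitat_only_vs_full": float(
            _stats.spearmanr(
                trends["habitat_only"]["slope"].to_numpy(), full_slope
            ).statistic
        ),
        "climate_only_vs_full": float(
            _stats.spearmanr(
                trends["climate_only"]["slope"].to_numpy(), full_slope
            ).statistic
        ),
    }


def diversity_surfaces(
    p_mean: np.ndarray,
    expected_abundance_mean: np.ndarray,
    cells: np.ndarray,
    years: np.ndarray,
    n_species: int | None = None,
) -> dict[str, DiversitySurface]:
    """Richness and evenness surfaces from posterior-mean predictions.

    ``p_mean`` and ``expected_abundance_mean`` are (n_cells, n_years,
    n_species). Evenness uses the posterior-mean unconditional expected
    abundances with S = the number of modelled species by default (all
    have positive expected abundance under the lognormal part).
    """
    if n_species is None:
        n_species = p_mean.shape[-1]
    rich = expected_richness(p_mean)
    even = evenness_surface(expected_abundance_mean, n_species=n_species)
    return {
        "richness": DiversitySurface(rich, cells, years, "richness"),
        "evenness": DiversitySurface(even, cells, years, "evenness"),
    }
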