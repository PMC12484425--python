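"""Predictive and conditional variance partitioning.

The linear predictor of each species over a prediction grid is decomposed
into habitat, climate and random-effect (site / year / zone) components.
Fixed-effect component variances use the empirical covariance C of the
design columns over the grid units,

    V_g = sum_{k in g} B_kj (C B_.j)_k ,

which splits cross-group covariance symmetrically and is exactly additive
to the total predictor variance (individual V_g may then be negative under
correlated covariates; they are reported raw and flagged). Random-effect
variances are the per-species sums of squared loadings. Computing the
partition over a prediction grid rather than the sampled sites corrects
for non-representative sampling designs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .design import DesignMatrix
from .model import PosteriorDraws

FIXED_COMPONENTS = ("habitat", "climate")


@dataclass
class VariancePartitionResult:
    """Per-draw, per-species component variances and shares."""

    components: list[str]
    variances: np.ndarray  # (draws, species, components)
    shares: np.ndarray  # same shape; rows sum to 1
    species: list
    part: str = ""
    grid_id: str = ""
    n_negative_components: int = 0

    def summary(self) -> pd.DataFrame:
        """Posterior median and 95% interval of shares per species."""
        qs = np.quantile(self.shares, [0.5, 0.025, 0.975], axis=0)
        rows = []
        for j, sp in enumerate(self.species):
            for c, comp in enumerate(self.components):
                rows.append(
                    {
                        "species": sp,
                        "component": comp,
                        "share_median": qs[0, j, c],
                        "share_q2.5": qs[1, j, c],
                        "share_q97.5": qs[2, j, c],
                    }
                )
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        d, s, c = self.variances.shape
        draw, spi, ci = np.meshgrid(
            np.arange(d), np.arange(s), np.arange(c), indexing="ij"
        )
        return pd.DataFrame(
            {
                "draw": draw.ravel(),
                "species": np.asarray(self.species, dtype=object)[spi.ravel()],
                "component": np.asarray(self.components, dtype=object)[
                    ci.ravel()
                ],
                "variance": self.variances.ravel(),
                "share": self.shares.ravel(),
            }
        )

    def component_share(self, name: str) -> np.ndarray:
        """(draws, species) share array for one component."""
        return self.shares[:, :, self.components.index(name)]


@dataclass
class ContextPartition:
    """Conditional variance partition with a within/between decomposition.

    ``within`` and ``between`` refer to the fixed (covariate-driven)
    predictor variance; random-effect variance is cell-invariant per
    species and counts wholly as within-context variation.
    """

    context_of_cell: pd.Series
    per_context: dict[str, VariancePartitionResult]
    within_fixed: np.ndarray  # (draws, species)
    between: np.ndarray
    total_fixed: np.ndarray
    re_variance: np.ndarray
    species: list
    context_sizes: dict[str, int] = field(default_factory=dict)

    def within_share(self) -> np.ndarray:
        tot = self.total_fixed + self.re_variance
        return np.divide(
            self.within_fixed + self.re_variance,
            tot,
            out=np.full_like(tot, np.nan),
            where=tot > 0,
        )

    def between_share(self) -> np.ndarray:
        tot = self.total_fixed + self.re_variance
        return np.divide(
            self.between, tot, out=np.full_like(tot, np.nan), where=tot > 0
        )


def _groups_from_blocks(
    blocks: dict[str, list[int]], groups: dict[str, list[int]] | None
) -> dict[str, list[int]]:
    if groups is None:
        groups = {c: list(blocks[c]) for c in FIXED_COMPONENTS}
    flat = sorted(i for g in groups.values() for i in g)
    expected = sorted(
        i
        for name, idx in blocks.items()
        if name not in ("intercept", "effort")
        for i in idx
    )
    if flat != expected:
        raise ValueError(
            "groups must partition the non-intercept, non-effort columns"
        )
    return groups


def _grid_matrix(
    X_grid: DesignMatrix | np.ndarray,
    blocks: dict[str, list[int]],
    effort_policy: str,
) -> np.ndarray:
    X = X_grid.X if isinstance(X_grid, DesignMatrix) else np.asarray(X_grid)
    X = X.astype(float).copy()
    if effort_policy == "constant":
        for i in blocks.get("effort", []):
            X[:, i] = X[:, i].mean()
    elif effort_policy != "keep":
        raise ValueError("effort_policy must be 'constant' or 'keep'")
    return X


def variance_partition(
    draws: PosteriorDraws,
    X_grid: DesignMatrix | np.ndarray,
    groups: dict[str, list[int]] | None = None,
    effort_policy: str = "constant",
    grid_id: str = "",
) -> VariancePartitionResult:
    """Predictive variance partition of the linear predictor over a grid.

    Effort is held constant (zero variance) by default so that only the
    environmental covariates and random effects carry variance.
    """
    groups = _groups_from_blocks(draws.blocks, groups)
    X = _grid_matrix(X_grid, draws.blocks, effort_policy)
    if X.shape[0] < 2:
        raise ValueError("grid must contain at least 2 units")
    C = np.cov(X, rowvar=False, ddof=0)

    B = draws.beta  # (D, p, S)
    CB = np.einsum("kl,dls->dks", C, B)
    comp_names = list(groups) + list(draws.lambdas)
    D, _, S = B.shape
    V = np.empty((D, S, len(comp_names)))
    for c, g in enumerate(groups.values()):
        V[:, :, c] = np.einsum("dks,dks->ds", B[:, g, :], CB[:, g, :])
    re_vars = draws.random_variances()
    for c, r in enumerate(draws.lambdas, start=len(groups)):
        V[:, :, c] = re_vars[r]

    total = V.sum(axis=2, keepdims=True)
    shares = np.divide(
        V, total, out=np.full_like(V, np.nan), where=total > 0
    )
    n_neg = int((V[:, :, : len(groups)] < 0).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} negative fixed-component variances (correlated "
            "covariates); reported raw",
            stacklevel=2,
        )
    return VariancePartitionResult(
        components=comp_names,
        variances=V,
        shares=shares,
        species=list(draws.species),
        part=draws.part,
        grid_id=grid_id,
        n_negative_components=n_neg,
    )


def kmeans_profiles(
    grid_habitat_composition: pd.DataFrame,
    k: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster grid cells into habitat profiles by k-means on land-cover
    composition (all categories, not only the model covariates).

    Profiles are named after any category with mean proportion > 0.5,
    otherwise ``heterogeneous`` (disambiguated by an index).
    Returns (labels per cell, profile-mean composition table).
    """
    comp = grid_habitat_composition
    if k > len(comp):
        raise ValueError("k exceeds the number of grid cells")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(comp.to_numpy(dtype=float))
    if len(np.unique(raw)) < k:
        raise ValueError(
            "degenerate clustering: fewer effective clusters than k"
        )
    centers = pd.DataFrame(
        km.cluster_centers_, columns=comp.columns
    )
    names = []
    for _, row in centers.iterrows():
        dominant = row[row > 0.5]
        base = dominant.idxmax() if len(dominant) else "heterogeneous"
        names.append(str(base))
    # disambiguate duplicates deterministically
    seen: dict[str, int] = {}
    final = []
    for nm in names:
        seen[nm] = seen.get(nm, 0) + 1
        final.append(nm if seen[nm] == 1 else f"{nm}_{seen[nm]}")
    labels = pd.Series(
        [final[i] for i in raw], index=comp.index, name="profile"
    )
    centers.index = pd.Index(final, name="profile")
    return labels, centers


def conditional_vp_environmental(
    draws: PosteriorDraws,
    X_grid: DesignMatrix | np.ndarray,
    cell_contexts: pd.Series | np.ndarray,
    groups: dict[str, list[int]] | None = None,
    effort_policy: str = "constant",
    chunk: int = 64,
) -> ContextPartition:
    """Conditional variance partition by environmental context.

    Per context: the grid-restricted partition. Additionally, the total
    fixed-predictor variance is decomposed by the law of total variance
    into cell-count-weighted within-context and between-context parts
    (exact per draw and species). Contexts with fewer than 2 units are
    kept in the decomposition (their within-variance is 0) but skipped in
    the per-context partitions with a warning.
    """
    groups = _groups_from_blocks(draws.blocks, groups)
    X = _grid_matrix(X_grid, draws.blocks, effort_policy)
    ctx = pd.Series(np.asarray(cell_contexts), name="context")
    if len(ctx) != X.shape[0]:
        raise ValueError("cell_contexts must label every grid unit")

    per_context = {}
    for label, members in ctx.groupby(ctx).groups.items():
        sel = np.asarray(members)
        if sel.size < 2:
            warnings.warn(
                f"context {label!r} has < 2 units; per-context partition "
                "skipped",
                stacklevel=2,
            )
            continue
        per_context[str(label)] = variance_partition(
            draws, X[sel], groups=groups, effort_policy="keep",
            grid_id=str(label),
        )

    # law-of-total-variance split of the fixed predictor, streamed in draws
    D, _, S = draws.beta.shape
    n = X.shape[0]
    codes, uniq = pd.factorize(ctx)
    n_ctx = len(uniq)
    M = np.zeros((n_ctx, n))
    M[codes, np.arange(n)] = 1.0
    w = M.sum(axis=1) / n
    within = np.empty((D, S))
    between = np.empty((D, S))
    total = np.empty((D, S))
    for d0 in range(0, D, chunk):
        sl = slice(d0, min(d0 + chunk, D))
        f = np.einsum("nk,dks->dns", X, draws.beta[sl])
        mean_all = f.mean(axis=1)  # (d, S)
        total[sl] = f.var(axis=1)
        gsum = np.einsum("cn,dns->dcs", M, f)
        gmean = gsum / M.sum(axis=1)[None, :, None]
        gsq = np.einsum("cn,dns->dcs", M, f**2)
        gvar = gsq / M.sum(axis=1)[None, :, None] - gmean**2
        within[sl] = np.einsum("c,dcs->ds", w, gvar)
        between[sl] = np.einsum(
            "c,dcs->ds", w, (gmean - mean_all[:, None, :]) ** 2
        )

    re_var = sum(draws.random_variances().values()) if draws.lambdas else (
        np.zeros((D, S))
    )
    return ContextPartition(
        context_of_cell=ctx,
        per_context=per_context,
        within_fixed=within,
        between=between,
        total_fixed=total,
        re_variance=np.asarray(re_var),
        species=list(draws.species),
        context_sizes={str(u): int((codes == i).sum()) for i, u in
                       enumerate(uniq)},
    )


def conditional_vp_functional(
    vp: VariancePartitionResult,
    trait_groups: pd.Series,
) -> dict[str, dict]:
    """Pool share draws over species sharing a trait group.

    For each group, the (habitat share, climate share) pairs of all member
    species and draws are pooled — the joint posterior summarised in the
    functional-context figures — together with marginal quantiles.
    Empty groups are skipped with a warning.
    """
    out: dict[str, dict] = {}
    sp_index = {s: i for i, s in enumerate(vp.species)}
    for group, members in trait_groups.groupby(trait_groups).groups.items():
        idx = [sp_index[s] for s in members if s in sp_index]
        if not idx:
            warnings.warn(f"trait group {group!r} has no modelled species",
                          stacklevel=2)
            continue
        pooled = vp.shares[:, idx, :].reshape(-1, len(vp.components))
        q = np.quantile(pooled, [0.025, 0.5, 0.975], axis=0)
        out[str(group)] = {
            "species": [s for s in members if s in sp_index],
            "pooled_shares": pooled,
            "components": list(vp.components),
            "quantiles": pd.DataFrame(
                q, index=["q2.5", "median", "q97.5"], columns=vp.components
            ),
        }
    return out


def dominant_driver_counts(
    vp: VariancePartitionResult,
    driver: str = "habitat",
    against: str = "climate",
) -> dict:
    """Number of species per draw for which one driver's share exceeds the
    other's; summarised by the posterior median and 95% interval."""
    a = vp.component_share(driver)
    b = vp.component_share(against)
    counts = (a > b).sum(axis=1)
    lo, med, hi = np.quantile(counts, [0.025, 0.5, 0.975])
    return {
        "counts": counts,
        "median": float(med),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "n_species": len(vp.species),
    }
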