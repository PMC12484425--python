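"""Bayesian hurdle joint species distribution model.

Two independently fitted parts share one sampler core:

* occurrence (PA): multivariate probit via truncated-normal data
  augmentation, residual variance fixed at 1;
* abundance given presence (AB): Gaussian model of log counts restricted
  to units where the species is present, per-species residual variance.

Species coefficient columns share a trait-structured prior
``B_.j ~ N(Gamma t_j, Omega)`` and latent-factor random effects per level
(site, year, zone): the contribution of level r to unit i, species j is
``eta_{r, level(i)} . Lambda_{r, ., j}`` with standard-normal factor
scores. The per-species random-effect variance of level r is the sum of
squared loadings, which is what the variance partitioning consumes.

All full conditionals are conjugate; the Gibbs cycle is
z | ... -> B | ... -> (Gamma, Omega) | ... -> (eta, Lambda) | ... -> sigma.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import DesignMatrix

logger = logging.getLogger(__name__)

_Z_CLIP = 40.0


@dataclass
class ModelSpec:
    """Sampler and prior settings for one model part.

    Parameters
    ----------
    n_factors
        Latent factors per random level; a level absent from the mapping
        (or with 0 factors) contributes no random effect.
    tau_gamma
        Prior SD of trait-effect entries (rows of Gamma ~ N(0, tau^2 I)).
    nu, psi_scale
        Inverse-Wishart prior on Omega: dof ``nu`` (default p + 3) and
        scale matrix ``psi_scale * I``.
    tau_lambda
        Prior SD of first-factor loadings; the prior variance halves for
        each successive factor, ordering factors by importance.
    sigma_a, sigma_b
        Inverse-Gamma prior on per-species residual variances (AB part).
    sample_trait_prior
        When False, Gamma is fixed at 0 and Omega at ``omega_fixed``
        (Gaussian debug / conjugate-oracle mode).
    """

    n_factors: Mapping[str, int] = field(
        default_factory=lambda: {"site": 2, "year": 1, "zone": 1}
    )
    tau_gamma: float = 2.0
    nu: float | None = None
    psi_scale: float = 0.5
    tau_lambda: float = 1.0
    sigma_a: float = 2.0
    sigma_b: float = 1.0
    n_chains: int = 2
    n_iter: int = 2000
    burnin: int | None = None  # default n_iter // 2
    thin: int = 2
    seed: int = 0
    sample_trait_prior: bool = True
    omega_fixed: np.ndarray | None = None

    def resolved(self, p: int) -> "ModelSpec":
        out = ModelSpec(**{**self.__dict__})
        if out.nu is None:
            out.nu = p + 3
        if out.burnin is None:
            out.burnin = out.n_iter // 2
        if out.nu <= p + 1:
            raise ValueError("Inverse-Wishart dof must exceed p + 1")
        for name in ("tau_gamma", "psi_scale", "tau_lambda", "sigma_a", "sigma_b"):
            if getattr(out, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return out


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for one model part.

    Arrays are stacked over chains: ``beta`` is (draws, p, S), ``gamma``
    (draws, p, q), ``omega`` (draws, p, p), per-level loadings
    (draws, k_r, S) and factor scores (draws, L_r, k_r); ``sigma``
    (draws, S) for the AB part, None for PA.
    """

    part: str
    beta: np.ndarray
    gamma: np.ndarray
    omega: np.ndarray
    lambdas: dict[str, np.ndarray]
    etas: dict[str, np.ndarray]
    sigma: np.ndarray | None
    colnames: list[str]
    blocks: dict[str, list[int]]
    species: list
    level_values: dict[str, list]
    n_chains: int = 1
    rhat_beta: float | None = None
    n_z_clipped: int = 0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def random_variances(self) -> dict[str, np.ndarray]:
        """Per-level random-effect variance per draw and species:
        sum of squared loadings (rotation-invariant)."""
        return {r: (lam**2).sum(axis=1) for r, lam in self.lambdas.items()}

    def to_netcdf(self, path: str | Path) -> None:
        import xarray as xr

        data = {
            "beta": (("draw", "covariate", "species"), self.beta),
            "gamma": (("draw", "covariate", "trait"), self.gamma),
            "omega": (("draw", "covariate", "covariate2"), self.omega),
        }
        if self.sigma is not None:
            data["sigma"] = (("draw", "species"), self.sigma)
        for r, lam in self.lambdas.items():
            data[f"lambda_{r}"] = ((f"factor_{r}", "draw", "species"),
                                   np.moveaxis(lam, 1, 0))
            data[f"eta_{r}"] = ((f"level_{r}", "draw", f"factor_{r}"),
                                np.moveaxis(self.etas[r], 1, 0))
        ds = xr.Dataset(
            data,
            coords={
                "covariate": self.colnames,
                "covariate2": self.colnames,
                "species": [str(s) for s in self.species],
            },
            attrs={
                "part": self.part,
                "n_chains": self.n_chains,
                "blocks": str(self.blocks),
                "levels": ";".join(
                    f"{r}:{','.join(str(v) for v in vals)}"
                    for r, vals in self.level_values.items()
                ),
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "PosteriorDraws":
        import ast

        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        lambdas, etas, level_values = {}, {}, {}
        levels_attr = ds.attrs.get("levels", "")
        if levels_attr:
            for entry in levels_attr.split(";"):
                r, vals = entry.split(":", 1)
                level_values[r] = vals.split(",") if vals else []
        for name in ds.data_vars:
            if name.startswith("lambda_"):
                r = name[len("lambda_"):]
                lambdas[r] = np.moveaxis(ds[name].values, 0, 1)
                etas[r] = np.moveaxis(ds[f"eta_{r}"].values, 0, 1)
        return cls(
            part=ds.attrs["part"],
            beta=ds["beta"].values,
            gamma=ds["gamma"].values,
            omega=ds["omega"].values,
            lambdas=lambdas,
            etas=etas,
            sigma=ds["sigma"].values if "sigma" in ds else None,
            colnames=[str(c) for c in ds["covariate"].values],
            blocks=ast.literal_eval(ds.attrs["blocks"]),
            species=[str(s) for s in ds["species"].values],
            level_values=level_values,
            n_chains=int(ds.attrs.get("n_chains", 1)),
        )


# ---------------------------------------------------------------------------
# sampler internals


def _truncated_normal(mu: np.ndarray, positive: np.ndarray, rng) -> np.ndarray:
    """Draw z ~ N(mu, 1) truncated to z > 0 where positive else z <= 0,
    by inverse-CDF; numerically safe in the tails via clipping."""
    u = rng.uniform(size=mu.shape)
    lo = special.ndtr(-mu)  # P(z <= 0)
    q = np.where(positive, lo + u * (1.0 - lo), u * lo)
    q = np.clip(q, 1e-16, 1.0 - 1e-16)
    return mu + special.ndtri(q)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, n_draws) scalar trace."""
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return np.nan
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _gibbs_chain(
    Y: np.ndarray,
    mask: np.ndarray,
    X: np.ndarray,
    T: np.ndarray,
    spec: ModelSpec,
    level_index: Mapping[str, np.ndarray],
    response: str,
    rng: np.random.Generator,
    sample_sigma: bool,
):
    """One chain of the blocked Gibbs sampler.

    Y: (n, S) binary (probit) or continuous working response (gaussian).
    mask: (n, S) bool of units entering species' likelihoods.
    level_index: per level, (n,) int array of level membership.
    """
    n, p = X.shape
    S = Y.shape[1]
    q = T.shape[1]
    probit = response == "probit"
    W = mask.astype(float)
    n_obs = W.sum(axis=0)  # per species

    levels = {
        r: idx
        for r, idx in level_index.items()
        if spec.n_factors.get(r, 0) > 0
    }
    n_levels = {r: int(idx.max()) + 1 for r, idx in levels.items()}
    kfac = {r: spec.n_factors[r] for r in levels}
    tau2_lam = {
        r: spec.tau_lambda**2 * 0.5 ** np.arange(kfac[r]) for r in levels
    }
    # level-membership indicator matrices for fast group sums
    memb = {}
    cnt_lvl = {}
    for r, idx in levels.items():
        M = np.zeros((n_levels[r], n))
        M[idx, np.arange(n)] = 1.0
        memb[r] = M
        cnt_lvl[r] = M @ W  # (L, S) observations per level x species

    # per-species Gram matrices (masked for the AB part)
    if probit:
        XtX = np.broadcast_to(X.T @ X, (S, p, p))
    else:
        XtX = np.einsum("ik,ij,il->jkl", X, W, X)

    # --- initial state
    if probit:
        z = np.where(Y > 0, 0.7, -0.7)
    else:
        z = np.where(mask, Y, 0.0)
    B = np.linalg.solve(
        XtX + 1e-3 * np.eye(p)[None],
        np.einsum("ik,ij->jk", X, W * z)[:, :, None],
    )[:, :, 0].T  # (p, S)
    G = np.zeros((p, q))
    omega = spec.omega_fixed if not spec.sample_trait_prior else np.eye(p)
    if omega is None:
        raise ValueError("omega_fixed required when trait prior is disabled")
    sigma2 = np.ones(S)
    Lam = {r: rng.normal(0, 0.1, size=(kfac[r], S)) for r in levels}
    Eta = {r: np.zeros((n_levels[r], kfac[r])) for r in levels}
    re_parts = {r: Eta[r][levels[r]] @ Lam[r] for r in levels}

    TtT = T.T @ T
    n_kept = (spec.n_iter - spec.burnin) // spec.thin
    out = {
        "beta": np.empty((n_kept, p, S)),
        "gamma": np.empty((n_kept, p, q)),
        "omega": np.empty((n_kept, p, p)),
        "sigma": np.empty((n_kept, S)),
        "lambdas": {r: np.empty((n_kept, kfac[r], S)) for r in levels},
        "etas": {r: np.empty((n_kept, n_levels[r], kfac[r])) for r in levels},
    }
    n_clipped = 0
    kept = 0

    for it in range(spec.n_iter):
        re_total = sum(re_parts.values()) if levels else np.zeros((n, S))

        # 1. latent probit response
        if probit:
            mu = X @ B + re_total
            z = _truncated_normal(mu, Y > 0, rng)
            over = np.abs(z) > _Z_CLIP
            if over.any():
                n_clipped += int(over.sum())
                z = np.clip(z, -_Z_CLIP, _Z_CLIP)

        # 2. species coefficient columns, conjugate normal
        omega_inv = np.linalg.inv(omega)
        resid = z - re_total
        prior_mean = G @ T.T  # (p, S)
        for j in range(S):
            prec = XtX[j] / sigma2[j] + omega_inv
            rhs = X.T @ (W[:, j] * resid[:, j]) / sigma2[j] + omega_inv @ (
                prior_mean[:, j]
            )
            cf = np.linalg.cholesky(prec)
            mean_j = np.linalg.solve(prec, rhs)
            B[:, j] = mean_j + np.linalg.solve(cf.T, rng.normal(size=p))

        # 3. trait effects and coefficient residual covariance
        if spec.sample_trait_prior:
            A = np.kron(TtT, omega_inv) + np.eye(p * q) / spec.tau_gamma**2
            rhs = (omega_inv @ B @ T).reshape(-1, order="F")
            cf = np.linalg.cholesky(A)
            gvec = np.linalg.solve(A, rhs) + np.linalg.solve(
                cf.T, rng.normal(size=p * q)
            )
            G = gvec.reshape((p, q), order="F")
            E = B - G @ T.T
            scale = spec.psi_scale * np.eye(p) + E @ E.T
            omega = np.atleast_2d(
                stats.invwishart.rvs(
                    df=spec.nu + S, scale=scale, random_state=rng
                )
            )

        # 4. factor scores and loadings per level
        for r, idx in levels.items():
            other = sum(v for rr, v in re_parts.items() if rr != r) if len(
                levels
            ) > 1 else 0.0
            E_r = z - X @ B - other
            k = kfac[r]
            lam = Lam[r]
            inv_s2 = 1.0 / sigma2
            # factor scores: batched k x k systems over levels
            L = n_levels[r]
            sumWE = memb[r] @ (W * E_r)
            cnt = cnt_lvl[r]
            prec = np.eye(k)[None] + np.einsum(
                "lj,kj,mj->lkm", cnt * inv_s2, lam, lam
            )
            rhs = (lam * inv_s2) @ sumWE.T  # (k, L)
            cov = np.linalg.inv(prec)
            mean = np.einsum("lkm,ml->lk", cov, rhs)
            cf = np.linalg.cholesky(cov)
            Eta[r] = mean + np.einsum(
                "lkm,lm->lk", cf, rng.normal(size=(L, k))
            )
            # loadings: batched k x k systems over species
            H = Eta[r][idx]  # (n, k)
            HtWH = np.einsum("ik,ij,il->jkl", H, W, H)
            HtWE = np.einsum("ik,ij->jk", H, W * E_r)
            prec = np.diag(1.0 / tau2_lam[r])[None] + HtWH * inv_s2[:, None, None]
            cov = np.linalg.inv(prec)
            mean = np.einsum("jkl,jl->jk", cov, HtWE * inv_s2[:, None])
            cf = np.linalg.cholesky(cov)
            Lam[r] = (
                mean + np.einsum("jkl,jl->jk", cf, rng.normal(size=(S, k)))
            ).T
            re_parts[r] = Eta[r][idx] @ Lam[r]

        # 5. residual variances (AB part only; fixed at 1 elsewhere)
        if sample_sigma:
            re_total = sum(re_parts.values()) if levels else 0.0
            E_fin = z - X @ B - re_total
            ssr = (W * E_fin**2).sum(axis=0)
            shape = spec.sigma_a + 0.5 * n_obs
            rate = spec.sigma_b + 0.5 * ssr
            sigma2 = rate / rng.gamma(shape=shape, scale=1.0, size=S)

        if it >= spec.burnin and (it - spec.burnin) % spec.thin == 0:
            out["beta"][kept] = B
            out["gamma"][kept] = G
            out["omega"][kept] = omega
            out["sigma"][kept] = np.sqrt(sigma2)
            for r in levels:
                out["lambdas"][r][kept] = Lam[r]
                out["etas"][r][kept] = Eta[r]
            kept += 1

    out["n_clipped"] = n_clipped
    return out


def _fit(
    Y: np.ndarray,
    mask: np.ndarray,
    X: DesignMatrix | np.ndarray,
    traits: pd.DataFrame | np.ndarray,
    spec: ModelSpec,
    levels: Mapping[str, np.ndarray] | None,
    response: str,
    part: str,
    species: list,
    level_values: dict[str, list] | None,
) -> PosteriorDraws:
    if isinstance(X, DesignMatrix):
        Xarr, colnames, blocks = X.X, X.colnames, X.blocks
    else:
        Xarr = np.asarray(X, dtype=float)
        colnames = [f"x{i}" for i in range(Xarr.shape[1])]
        blocks = {"all": list(range(Xarr.shape[1]))}
    T = (
        traits.to_numpy(dtype=float)
        if isinstance(traits, pd.DataFrame)
        else np.asarray(traits, dtype=float)
    )
    if T.shape[0] != Y.shape[1]:
        raise ValueError("trait table must have one row per species")
    if not np.isfinite(Xarr).all():
        raise ValueError("design matrix contains non-finite values")
    levels = {
        r: np.asarray(v, dtype=int) for r, v in (levels or {}).items()
    }
    rspec = spec.resolved(Xarr.shape[1])

    sample_sigma = response == "gaussian" and part == "AB"
    rngs = _spawn_rngs(rspec.seed, rspec.n_chains)
    chains = [
        _gibbs_chain(
            Y, mask, Xarr, T, rspec, levels, response, rng, sample_sigma
        )
        for rng in rngs
    ]

    def cat(key):
        return np.concatenate([c[key] for c in chains], axis=0)

    lambdas = {
        r: np.concatenate([c["lambdas"][r] for c in chains], axis=0)
        for r in chains[0]["lambdas"]
    }
    etas = {
        r: np.concatenate([c["etas"][r] for c in chains], axis=0)
        for r in chains[0]["etas"]
    }
    beta = cat("beta")

    # convergence diagnostic on a random 5% of coefficient traces (logged)
    rhat = np.nan
    if rspec.n_chains > 1:
        p, S = beta.shape[1:]
        rng = np.random.default_rng(rspec.seed + 10_007)
        n_pick = max(1, int(0.05 * p * S))
        flat = [c["beta"].reshape(c["beta"].shape[0], -1) for c in chains]
        picks = rng.choice(p * S, size=n_pick, replace=False)
        rhats = [
            _split_rhat(np.stack([f[:, i] for f in flat])) for i in picks
        ]
        rhat = float(np.nanmax(rhats))
        if rhat > 1.1:
            logger.warning("max split-R-hat %.3f > 1.1 (%s part)", rhat, part)

    n_clipped = sum(c["n_clipped"] for c in chains)
    if n_clipped:
        logger.info("clipped %d latent values beyond |z| = 40", n_clipped)

    if level_values is None:
        level_values = {
            r: list(range(int(levels[r].max()) + 1)) for r in lambdas
        }
    return PosteriorDraws(
        part=part,
        beta=beta,
        gamma=cat("gamma"),
        omega=cat("omega"),
        lambdas=lambdas,
        etas=etas,
        sigma=cat("sigma") if response == "gaussian" and part == "AB" else None,
        colnames=colnames,
        blocks=blocks,
        species=list(species),
        level_values=level_values,
        n_chains=rspec.n_chains,
        rhat_beta=rhat,
        n_z_clipped=n_clipped,
    )


def fit_pa(
    Y_presence,
    X: DesignMatrix | np.ndarray,
    traits,
    spec: ModelSpec,
    levels: Mapping[str, np.ndarray] | None = None,
    species: list | None = None,
    level_values: dict[str, list] | None = None,
    gaussian_response: bool = False,
) -> PosteriorDraws:
    """Fit the occurrence (probit) part.

    ``Y_presence`` is (n_units, n_species) binary. With
    ``gaussian_response=True`` the latent response is taken as observed
    (Y continuous, residual variance 1) — a debug mode whose posterior is
    available in closed form for conjugate-oracle checks.
    """
    Y = np.asarray(Y_presence, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not gaussian_response and not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("presence-absence response must be binary")
    mask = np.ones_like(Y, dtype=bool)
    if species is None:
        species = [f"sp{j}" for j in range(Y.shape[1])]
    return _fit(
        Y,
        mask,
        X,
        traits,
        spec,
        levels,
        "gaussian" if gaussian_response else "probit",
        "PA",
        species,
        level_values,
    )


def fit_ab(
    Y_counts,
    X: DesignMatrix | np.ndarray,
    traits,
    spec: ModelSpec,
    levels: Mapping[str, np.ndarray] | None = None,
    species: list | None = None,
    level_values: dict[str, list] | None = None,
) -> PosteriorDraws:
    """Fit the abundance-given-presence part.

    The response is the natural log of counts; units where a species is
    absent contribute nothing to that species' likelihood.
    """
    C = np.asarray(Y_counts, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if (C < 0).any():
        raise ValueError("counts must be non-negative")
    mask = C > 0
    n_pos = mask.sum(axis=0)
    few = np.flatnonzero(n_pos < 5)
    if few.size:
        warnings.warn(
            f"{few.size} species with < 5 positive units; expect wide "
            "abundance posteriors",
            stacklevel=2,
        )
    Y = np.zeros_like(C)
    Y[mask] = np.log(C[mask])
    if species is None:
        species = [f"sp{j}" for j in range(C.shape[1])]
    return _fit(
        Y, mask, X, traits, spec, levels, "gaussian", "AB", species,
        level_values,
    )


# ---------------------------------------------------------------------------
# prediction and evaluation


def _re_predictor(
    draws: PosteriorDraws,
    d_slice: slice,
    n_new: int,
    levels_new: Mapping[str, np.ndarray] | None,
    re_mode: str,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Random-effect contribution (d, n_new, S) for a slice of draws.

    Units mapped to an observed level (index >= 0) use its posterior
    factor scores (partial pooling); unobserved levels get zero scores
    under ``marginal_zero`` or fresh standard-normal scores under
    ``sample_new``.
    """
    nd = draws.beta[d_slice].shape[0]
    S = draws.beta.shape[2]
    total = np.zeros((nd, n_new, S))
    for r, lam in draws.lambdas.items():
        lam_d = lam[d_slice]  # (d, k, S)
        k = lam_d.shape[1]
        idx = None if levels_new is None else levels_new.get(r)
        if idx is None:
            idx = np.full(n_new, -1, dtype=int)
        else:
            idx = np.asarray(idx, dtype=int)
        eta_new = np.zeros((nd, n_new, k))
        obs = idx >= 0
        if obs.any():
            eta_new[:, obs, :] = draws.etas[r][d_slice][:, idx[obs], :]
        if re_mode == "sample_new" and (~obs).any():
            if rng is None:
                raise ValueError("sample_new mode requires an rng")
            eta_new[:, ~obs, :] = rng.normal(size=(nd, int((~obs).sum()), k))
        total += np.einsum("dnk,dks->dns", eta_new, lam_d)
    return total


def predict(
    draws_pa: PosteriorDraws | None,
    draws_ab: PosteriorDraws | None,
    X_new: DesignMatrix | np.ndarray,
    re_mode: str = "marginal_zero",
    levels_new: Mapping[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    d_slice: slice = slice(None),
) -> dict[str, np.ndarray]:
    """Per-draw predictions on new units.

    Returns occurrence probability ``p = Phi(L_PA)``, conditional
    abundance mean ``m = exp(L_AB + sigma^2/2)`` and the unconditional
    expectation ``p * m``, each (draws, n_units, S) for whichever parts
    are supplied. ``d_slice`` restricts the posterior draws used (for
    streaming over large grids).
    """
    if re_mode not in ("marginal_zero", "sample_new"):
        raise ValueError("re_mode must be marginal_zero or sample_new")
    Xarr = X_new.X if isinstance(X_new, DesignMatrix) else np.asarray(X_new)
    n_new = Xarr.shape[0]
    out: dict[str, np.ndarray] = {}
    if draws_pa is not None:
        L = np.einsum("nk,dks->dns", Xarr, draws_pa.beta[d_slice])
        L += _re_predictor(draws_pa, d_slice, n_new, levels_new, re_mode, rng)
        out["p"] = special.ndtr(L)
    if draws_ab is not None:
        L = np.einsum("nk,dks->dns", Xarr, draws_ab.beta[d_slice])
        L += _re_predictor(draws_ab, d_slice, n_new, levels_new, re_mode, rng)
        sig = (
            draws_ab.sigma[d_slice]
            if draws_ab.sigma is not None
            else np.zeros((L.shape[0], L.shape[2]))
        )
        out["m"] = np.exp(L + 0.5 * sig[:, None, :] ** 2)
    if "p" in out and "m" in out:
        out["expected_abundance"] = out["p"] * out["m"]
    return out


def tjur_r2(p: np.ndarray, y: np.ndarray) -> float:
    """Mean predicted probability among presences minus among absences."""
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        return float("nan")
    return float(p[y].mean() - p[~y].mean())


def auc(p: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney concordance with 0.5 credit for ties."""
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(p)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(
    predictions: dict[str, np.ndarray],
    counts: np.ndarray,
) -> pd.DataFrame:
    """Per-species fit metrics.

    PA: Tjur R^2 and AUC of posterior-mean occurrence probabilities.
    AB: squared Pearson correlation of observed vs predicted log counts
    on positive units. Species with single-class truth get NaN.
    """
    counts = np.asarray(counts, dtype=float)
    y = counts > 0
    S = counts.shape[1]
    rows = []
    p_mean = predictions["p"].mean(axis=0) if "p" in predictions else None
    m_mean = predictions["m"].mean(axis=0) if "m" in predictions else None
    for j in range(S):
        row = {"species": j}
        if p_mean is not None:
            row["tjur_r2"] = tjur_r2(p_mean[:, j], y[:, j])
            row["auc"] = auc(p_mean[:, j], y[:, j])
        if m_mean is not None:
            pos = y[:, j]
            if pos.sum() >= 3 and np.std(np.log(counts[pos, j])) > 0:
                r = np.corrcoef(
                    np.log(counts[pos, j]), np.log(m_mean[pos, j])
                )[0, 1]
                row["r2_log"] = float(r**2)
            else:
                row["r2_log"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def response_curves(
    draws: PosteriorDraws,
    covariate: str,
    grid_of_values: np.ndarray,
    observed_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Posterior-mean response along one covariate, others at their means.

    Returns one row per species with the curve and a shape label:
    ``U_shaped`` iff the quadratic coefficient's posterior mean is
    positive and the interior minimum lies inside the observed range;
    ``unimodal`` symmetrically for a negative quadratic with an interior
    peak; otherwise ``monotone`` (always monotone for linear-only terms).
    """
    g = np.asarray(grid_of_values, dtype=float)
    if observed_range is None:
        observed_range = (float(g.min()), float(g.max()))
    bmean = draws.beta_mean()
    i_lin = draws.colnames.index(covariate)
    quad_name = covariate + "_sq"
    i_quad = (
        draws.colnames.index(quad_name) if quad_name in draws.colnames else None
    )
    rows = []
    for j, sp in enumerate(draws.species):
        b1 = bmean[i_lin, j]
        curve = b1 * g
        shape = "monotone"
        if i_quad is not None:
            b2 = bmean[i_quad, j]
            curve = curve + b2 * g**2
            if b2 != 0:
                x_star = -b1 / (2 * b2)
                inside = observed_range[0] < x_star < observed_range[1]
                if b2 > 0 and inside:
                    shape = "U_shaped"
                elif b2 < 0 and inside:
                    shape = "unimodal"
        rows.append({"species": sp, "shape": shape, "curve": curve})
    return pd.DataFrame(rows)


def holdout_validate(
    counts: np.ndarray,
    X: DesignMatrix,
    traits,
    spec: ModelSpec,
    levels: Mapping[str, np.ndarray],
    split_seed: int,
    holdout_frac: float = 0.2,
    species: list | None = None,
) -> dict[str, pd.DataFrame]:
    """Explanatory vs predictive metrics under a site-stratified holdout.

    Within each site, ``holdout_frac`` of its trap-years are held out (so
    every site keeps training data and its random effect stays partially
    pooled); the model is refitted on the training units and evaluated on
    both partitions. ``holdout_frac=0`` makes the predictive metrics equal
    the explanatory ones by construction.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    site = np.asarray(levels["site"], dtype=int)
    rng = np.random.default_rng(split_seed)
    test = np.zeros(n, dtype=bool)
    for s in np.unique(site):
        members = np.flatnonzero(site == s)
        n_hold = int(round(holdout_frac * members.size))
        n_hold = min(n_hold, members.size - 1)
        if n_hold > 0:
            test[rng.choice(members, size=n_hold, replace=False)] = True
    train = ~test

    Xtr = DesignMatrix(
        X=X.X[train], colnames=X.colnames, blocks=X.blocks, stats=X.stats
    )
    lv_tr = {r: np.asarray(v)[train] for r, v in levels.items()}
    pa = fit_pa(
        (counts[train] > 0).astype(float), Xtr, traits, spec, lv_tr,
        species=species,
    )
    ab = fit_ab(counts[train], Xtr, traits, spec, lv_tr, species=species)

    def _metrics(sel):
        pred = predict(
            pa, ab, X.X[sel],
            levels_new={r: np.asarray(v)[sel] for r, v in levels.items()},
        )
        return evaluate(pred, counts[sel])

    explanatory = _metrics(train)
    predictive = _metrics(test) if test.any() else explanatory.copy()
    return {
        "explanatory": explanatory,
        "predictive": predictive,
        "test_mask": test,
    }
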