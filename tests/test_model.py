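"""Gibbs sampler against conjugate, maximum-likelihood and construction
oracles; prediction and evaluation metrics."""
import numpy as np
import pandas as pd
import pytest

from hurdlevp.model import (
    ModelSpec,
    PosteriorDraws,
    auc,
    evaluate,
    fit_ab,
    fit_pa,
    holdout_validate,
    predict,
    response_curves,
    tjur_r2,
)

ONE = np.ones((1, 1))


def test_gaussian_debug_mode_matches_conjugate_posterior(rng):
    n, p = 400, 4
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n)
    omega = 4.0 * np.eye(p)
    spec = ModelSpec(
        n_factors={}, sample_trait_prior=False, omega_fixed=omega,
        n_chains=2, n_iter=1200, thin=1, seed=7,
    )
    d = fit_pa(y[:, None], X, ONE, spec, gaussian_response=True)
    closed = np.linalg.solve(X.T @ X + np.linalg.inv(omega), X.T @ y)
    est = d.beta.mean(axis=0)[:, 0]
    # batch-means Monte-Carlo SE
    batches = d.beta[:, :, 0].reshape(24, -1, p).mean(axis=1)
    mcse = batches.std(axis=0, ddof=1) / np.sqrt(batches.shape[0])
    assert np.all(np.abs(est - closed) < 3 * np.maximum(mcse, 1e-4))


def test_probit_fit_matches_ml_oracle(rng):
    import statsmodels.api as sm

    n = 1200
    X = rng.normal(size=(n, 2))
    beta = np.array([0.8, -0.5])
    y = (X @ beta + rng.normal(size=n) > 0).astype(float)
    spec = ModelSpec(n_factors={}, n_chains=2, n_iter=800, thin=1, seed=3)
    d = fit_pa(y[:, None], X, ONE, spec)
    ml = np.asarray(sm.Probit(y, X).fit(disp=0).params)
    assert np.all(np.abs(d.beta.mean(axis=0)[:, 0] - ml) < 0.15)


def test_all_zero_species_shifts_intercept_negative(rng):
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = np.zeros((n, 1))
    spec = ModelSpec(n_factors={}, n_chains=1, n_iter=600, seed=5)
    d = fit_pa(y, X, ONE, spec)
    assert d.beta.mean(axis=0)[0, 0] < 0.0  # prior mean is 0


def test_ab_sigma_recovered(rng):
    n = 1000
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    logc = X @ np.array([2.0, 0.5]) + rng.normal(size=n) * 0.5
    counts = np.exp(logc)  # all positive
    spec = ModelSpec(n_factors={}, n_chains=2, n_iter=800, seed=5)
    d = fit_ab(counts[:, None], X, ONE, spec)
    assert abs(d.sigma.mean() - 0.5) < 0.05


def test_ab_constant_response_concentrates_at_intercept(rng):
    n = 300
    X = np.ones((n, 1))
    counts = np.full((n, 1), 7.0)
    spec = ModelSpec(n_factors={}, n_chains=1, n_iter=800, seed=5)
    d = fit_ab(counts, X, ONE, spec)
    assert d.beta.mean(axis=0)[0, 0] == pytest.approx(np.log(7), abs=0.05)


def test_ab_likelihood_restricted_to_positive_units(rng):
    """Absent units contribute nothing: fitting on the full unit set with
    zeros is identical to fitting on the positive subset only."""
    n = 300
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    counts = np.where(rng.uniform(size=(n, 1)) < 0.6,
                      np.exp(rng.normal(2.0, 0.5, (n, 1))), 0.0)
    spec = ModelSpec(
        n_factors={}, sample_trait_prior=False, omega_fixed=np.eye(2) * 4,
        n_chains=1, n_iter=400, seed=9,
    )
    d_full = fit_ab(counts, X, ONE, spec)
    pos = counts[:, 0] > 0
    d_pos = fit_ab(counts[pos], X[pos], ONE, spec)
    assert np.allclose(d_full.beta, d_pos.beta)
    assert np.allclose(d_full.sigma, d_pos.sigma)


def test_trait_prior_shrinks_rare_species(rng):
    """With informative traits (strong trait effects, small residual
    coefficient covariance), a species observed at only a handful of
    units borrows strength: its coefficient posterior is strictly tighter
    than under a traits-free fit of the same data."""
    S, n, p = 20, 300, 3
    X = rng.normal(size=(n, p))
    T = np.column_stack([np.ones(S), rng.normal(size=S)])
    gamma = 0.5 * np.array([[0.3, 1.2], [-0.4, 1.0], [0.2, -1.2]])
    B = gamma @ T.T + 0.05 * rng.normal(size=(p, S))
    counts = np.exp(X @ B + 2.0 + rng.normal(size=(n, S)) * 0.5)
    counts[4:, 0] = 0.0  # rare species: 4 positive units only
    spec = ModelSpec(
        n_factors={}, n_chains=2, n_iter=1500, seed=1, psi_scale=0.1
    )
    with pytest.warns(UserWarning):  # few-positives warning is expected
        with_traits = fit_ab(counts, X, T, spec)
        no_traits = fit_ab(counts, X, np.ones((S, 1)), spec)
    sd_with = with_traits.beta.std(axis=0)[:, 0].mean()
    sd_without = no_traits.beta.std(axis=0)[:, 0].mean()
    assert sd_with < 0.7 * sd_without


def test_random_effect_variance_positive_and_stored(small_study):
    counts = small_study.community.counts.to_numpy(float)
    spec = ModelSpec(n_chains=1, n_iter=200, thin=1, seed=2)
    d = fit_pa(
        (counts > 0).astype(float), small_study.X_train,
        small_study.trait_matrix, spec, small_study.levels_train,
    )
    rv = d.random_variances()
    assert set(rv) == {"site", "year", "zone"}
    for arr in rv.values():
        assert (arr >= 0).all()
    assert d.lambdas["site"].shape[1] == 2


def test_predict_null_model_gives_half(rng):
    d = _dummy_draws(rng, beta_value=0.0)
    out = predict(d, None, np.ones((5, 2)))
    assert np.allclose(out["p"], 0.5)


def test_predict_zero_sigma_conditional_mean(rng):
    d = _dummy_draws(rng, beta_value=0.3, part="AB", sigma=0.0)
    X = np.ones((4, 2))
    out = predict(None, d, X)
    assert np.allclose(out["m"], np.exp(X @ d.beta[0]))


def _dummy_draws(rng, beta_value=0.0, part="PA", sigma=None, n_draws=20):
    p, S = 2, 3
    beta = np.full((n_draws, p, S), beta_value)
    return PosteriorDraws(
        part=part,
        beta=beta,
        gamma=np.zeros((n_draws, p, 1)),
        omega=np.tile(np.eye(p), (n_draws, 1, 1)),
        lambdas={},
        etas={},
        sigma=None if sigma is None else np.full((n_draws, S), sigma),
        colnames=["x0", "x1"],
        blocks={"all": [0, 1]},
        species=["a", "b", "c"],
        level_values={},
    )


def test_sample_new_random_effects_add_prediction_variance(rng, small_study):
    counts = small_study.community.counts.to_numpy(float)
    spec = ModelSpec(n_chains=1, n_iter=300, thin=1, seed=2)
    d = fit_pa(
        (counts > 0).astype(float), small_study.X_train,
        small_study.trait_matrix, spec, small_study.levels_train,
    )
    Xn = small_study.X_grid.X[:50]
    p_zero = predict(d, None, Xn, re_mode="marginal_zero")["p"]
    p_new = predict(
        d, None, Xn, re_mode="sample_new", rng=np.random.default_rng(0)
    )["p"]
    assert p_new.var(axis=0).mean() > p_zero.var(axis=0).mean()


def test_tjur_r2_example():
    p = np.array([0.8, 0.6, 0.3, 0.1])
    y = np.array([1, 1, 0, 0])
    assert tjur_r2(p, y) == pytest.approx(0.5)
    assert np.isnan(tjur_r2(p, np.ones(4)))


def brute_force_auc(p, y):
    pos = p[y == 1]
    neg = p[y == 0]
    score = 0.0
    for a in pos:
        for b in neg:
            score += 1.0 if a > b else (0.5 if a == b else 0.0)
    return score / (len(pos) * len(neg))


def test_auc_perfect_and_tied_cases():
    assert auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0
    p = np.array([0.7, 0.4, 0.4, 0.2])
    y = np.array([1, 1, 0, 0])
    assert auc(p, y) == pytest.approx(brute_force_auc(p, y))


def test_auc_matches_pair_enumeration_random(rng):
    for _ in range(10):
        p = rng.choice([0.1, 0.3, 0.5, 0.7], size=12)
        y = rng.integers(0, 2, size=12)
        if y.min() == y.max():
            continue
        assert auc(p, y) == pytest.approx(brute_force_auc(p, y))


def test_evaluate_shapes_and_sentinels(rng):
    pred = {"p": rng.uniform(size=(5, 30, 2))}
    counts = np.zeros((30, 2))
    counts[:, 0] = rng.integers(0, 3, 30)
    counts[:, 1] = 0  # single-class species
    m = evaluate(pred, counts)
    assert np.isnan(m.loc[1, "tjur_r2"]) and np.isnan(m.loc[1, "auc"])


def test_response_curve_shapes(rng):
    p, S = 3, 2
    beta = np.zeros((10, p, S))
    beta[:, 1, 0] = 0.0  # linear coefficient, species 0
    beta[:, 2, 0] = -1.0  # quadratic: unimodal peak at 0
    beta[:, 1, 1] = 0.2
    beta[:, 2, 1] = 1.0  # U-shaped with interior minimum
    d = PosteriorDraws(
        part="PA", beta=beta, gamma=np.zeros((10, p, 1)),
        omega=np.tile(np.eye(p), (10, 1, 1)), lambdas={}, etas={},
        sigma=None, colnames=["clumpiness", "gdd", "gdd_sq"],
        blocks={"all": [0, 1, 2]}, species=["u", "v"], level_values={},
    )
    rc = response_curves(d, "gdd", np.linspace(-2, 2, 21))
    assert rc.set_index("species").loc["u", "shape"] == "unimodal"
    assert rc.set_index("species").loc["v", "shape"] == "U_shaped"
    rc_lin = response_curves(d, "clumpiness", np.linspace(-2, 2, 5))
    assert (rc_lin["shape"] == "monotone").all()


def test_holdout_zero_fraction_equals_explanatory(small_study):
    counts = small_study.community.counts.to_numpy(float)
    spec = ModelSpec(n_chains=1, n_iter=200, thin=2, seed=4)
    res = holdout_validate(
        counts, small_study.X_train, small_study.trait_matrix, spec,
        small_study.levels_train, split_seed=0, holdout_frac=0.0,
    )
    pd.testing.assert_frame_equal(res["explanatory"], res["predictive"])
    assert not res["test_mask"].any()


def test_holdout_split_reproducible_and_explanatory_better(small_study):
    counts = small_study.community.counts.to_numpy(float)
    spec = ModelSpec(n_chains=1, n_iter=400, thin=2, seed=4)
    res1 = holdout_validate(
        counts, small_study.X_train, small_study.trait_matrix, spec,
        small_study.levels_train, split_seed=7, holdout_frac=0.25,
    )
    res2 = holdout_validate(
        counts, small_study.X_train, small_study.trait_matrix, spec,
        small_study.levels_train, split_seed=7, holdout_frac=0.25,
    )
    assert np.array_equal(res1["test_mask"], res2["test_mask"])
    assert (
        res1["explanatory"]["tjur_r2"].mean()
        >= res1["predictive"]["tjur_r2"].mean()
    )


def test_netcdf_round_trip(tmp_path, small_study):
    counts = small_study.community.counts.to_numpy(float)
    spec = ModelSpec(n_chains=1, n_iter=100, thin=1, seed=2)
    d = fit_ab(
        counts, small_study.X_train, small_study.trait_matrix, spec,
        small_study.levels_train, species=list(small_study.traits.index),
    )
    path = tmp_path / "draws.nc"
    d.to_netcdf(path)
    back = PosteriorDraws.from_netcdf(path)
    assert back.part == "AB"
    assert np.allclose(back.beta, d.beta)
    assert np.allclose(back.sigma, d.sigma)
    assert back.species == d.species
    assert back.blocks == d.blocks
    for r in d.lambdas:
        assert np.allclose(back.lambdas[r], d.lambdas[r])


def test_nonbinary_presence_rejected(rng):
    with pytest.raises(ValueError):
        fit_pa(np.array([[0.5]]), np.ones((1, 1)), ONE, ModelSpec())
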