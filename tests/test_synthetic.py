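"""Generators: determinism, stated statistical structure, ground truth."""
import numpy as np
import pytest
from scipy import special

from hurdlevp import synthetic as syn
from hurdlevp.design import BLOCKS, COLUMN_NAMES


def like_adjacency_fraction(cat):
    m = cat[:, :-1] == cat[:, 1:]
    v = cat[:-1, :] == cat[1:, :]
    return (m.sum() + v.sum()) / (m.size + v.size)


def test_landscape_deterministic_and_no_change_case():
    a = syn.generate_landscape(3, 40, 40, n_epochs=3, change_rate=0.0)
    b = syn.generate_landscape(3, 40, 40, n_epochs=3, change_rate=0.0)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.categories, rb.categories)
    assert np.array_equal(a[0].categories, a[2].categories)


def test_landscape_change_rate_bounds_pixel_changes():
    rasters = syn.generate_landscape(4, 64, 64, n_epochs=3, change_rate=0.1)
    for prev, nxt in zip(rasters, rasters[1:]):
        frac = (prev.categories != nxt.categories).mean()
        assert frac <= 0.1 + 1e-12


def test_autocorrelation_scale_increases_like_adjacency():
    big = [
        like_adjacency_fraction(
            syn.generate_landscape(s, 48, 48, autocorr_scale=8.0)[0].categories
        )
        for s in range(10)
    ]
    small = [
        like_adjacency_fraction(
            syn.generate_landscape(s, 48, 48, autocorr_scale=1.0)[0].categories
        )
        for s in range(10)
    ]
    assert np.mean(big) > np.mean(small)


def test_landscape_parameter_validation():
    with pytest.raises(ValueError):
        syn.generate_landscape(0, 16, 64)
    with pytest.raises(ValueError):
        syn.generate_landscape(0, 64, 64, autocorr_scale=0.0)
    with pytest.raises(ValueError):
        syn.generate_landscape(0, 64, 64, change_rate=1.0)


def test_directional_conversion_accumulates_target_class():
    rasters = syn.generate_landscape(
        9, 64, 64, n_epochs=4, change_rate=0.1,
        change_target_class=8, change_directional_frac=1.0,
    )
    fr = [(r.categories == 8).mean() for r in rasters]
    assert fr == sorted(fr) and fr[-1] > fr[0]


def trait_matrix(S, rng):
    import pandas as pd

    from hurdlevp import community as comm

    df = pd.DataFrame(
        {
            "wing_span": rng.uniform(18, 45, S),
            "host_group": rng.choice(comm.HOST_GROUPS, S),
        },
        index=[f"sp{j}" for j in range(S)],
    )
    return comm.encode_traits(df)


def test_parameters_omega_zero_limit(rng):
    T = trait_matrix(6, rng)
    pars = syn.generate_parameters(
        0, T, COLUMN_NAMES, BLOCKS, omega=0
    )
    assert np.allclose(pars.beta, pars.gamma @ T.to_numpy().T)


def test_parameters_zero_factors_and_block_scales(rng):
    T = trait_matrix(6, rng)
    pars = syn.generate_parameters(
        0, T, COLUMN_NAMES, BLOCKS,
        n_factors={"site": 0, "year": 0, "zone": 0},
        effect_scales={"intercept": 0.5, "habitat": 0.4, "climate": 0.0,
                       "effort": 0.2},
    )
    assert pars.lambdas == {}
    clim_rows = BLOCKS["climate"]
    assert np.allclose(pars.beta[clim_rows, :], 0.0)


def test_parameters_reject_indefinite_omega(rng):
    T = trait_matrix(3, rng)
    bad = -np.eye(len(COLUMN_NAMES))
    with pytest.raises(ValueError):
        syn.generate_parameters(0, T, COLUMN_NAMES, BLOCKS, omega=bad)


def test_zero_climate_scale_gives_zero_true_climate_share(rng):
    T = trait_matrix(6, rng)
    pars = syn.generate_parameters(
        0, T, COLUMN_NAMES, BLOCKS,
        effect_scales={"intercept": 0.5, "habitat": 0.4, "climate": 0.0,
                       "effort": 0.2},
    )
    X = rng.normal(size=(200, len(COLUMN_NAMES)))
    vp = syn.true_variance_partition(pars, X)
    assert np.allclose(vp.component_share("climate"), 0.0)
    assert np.allclose(vp.shares.sum(axis=-1), 1.0, atol=1e-10)


def test_simulate_prevalence_half_under_null(rng):
    """With B = 0 and no random effects, presence is a fair coin."""
    S, n, p = 5, 2000, len(COLUMN_NAMES)
    T = trait_matrix(S, rng)
    pars = syn.generate_parameters(
        0, T, COLUMN_NAMES, BLOCKS, omega=0,
        n_factors={},
    )
    pars.beta[:] = 0.0
    X = rng.normal(size=(n, p))
    counts = syn.simulate_community(pars, pars, X, {}, seed=11)
    prev = (counts > 0).mean(axis=0)
    se = np.sqrt(0.25 / n)
    assert np.all(np.abs(prev - 0.5) < 3 * se)


def test_simulate_saturated_predictor_always_present(rng):
    S = 3
    T = trait_matrix(S, rng)
    pars = syn.generate_parameters(0, T, COLUMN_NAMES, BLOCKS, omega=0,
                                   n_factors={})
    pars.beta[:] = 0.0
    pars.beta[0, :] = 8.0  # Phi(8) ~ 1
    X = np.zeros((100, len(COLUMN_NAMES)))
    X[:, 0] = 1.0
    counts = syn.simulate_community(pars, pars, X, {}, seed=2)
    assert (counts > 0).all()
    assert (counts >= 1).all()


def test_simulate_deterministic_under_seed(small_study):
    cfg, seed = small_study.config, small_study.seed
    again = syn.generate_study(cfg, seed=seed)
    assert again.community.counts.equals(small_study.community.counts)
    assert np.array_equal(again.X_grid.X, small_study.X_grid.X)


def test_prevalence_calibration_matches_probit_mean(rng):
    """Mean prevalence across replicate simulations matches Phi of the
    mean predictor within Monte-Carlo error."""
    S, n = 4, 400
    T = trait_matrix(S, rng)
    pars = syn.generate_parameters(1, T, COLUMN_NAMES, BLOCKS, omega=0,
                                   n_factors={})
    pars.beta[:] = 0.0
    pars.beta[0, :] = 0.5
    X = np.zeros((n, len(COLUMN_NAMES)))
    X[:, 0] = 1.0
    prevs = []
    for rep in range(20):
        counts = syn.simulate_community(pars, pars, X, {}, seed=rep)
        prevs.append((counts > 0).mean())
    target = special.ndtr(0.5)
    se = np.sqrt(target * (1 - target) / (20 * n * S))
    assert abs(np.mean(prevs) - target) < 3 * se


def test_study_invariants(small_study):
    st = small_study
    cfg = st.config
    # sampled sites are a subset of grid cells, biased south (zone 0/1)
    assert set(st.site_cells) <= set(st.grid["cell"])
    zones = st.grid.set_index("cell").loc[st.site_cells, "zone"]
    south = (zones <= 1).mean()
    assert south > 0.5
    # positive effort everywhere
    assert (st.community.effort_days >= 1).all()
    # finite design matrices, counts in likelihood support
    assert np.isfinite(st.X_train.X).all()
    assert np.isfinite(st.X_grid.X).all()
    pos = st.community.counts.to_numpy()
    assert (pos[pos > 0] >= 1).all()
    # four zones as latitude bands
    assert set(st.grid["zone"]) == {0, 1, 2, 3}
    assert len(st.grid) == cfg.n_cells
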