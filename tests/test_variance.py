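"""Variance partitioning: additivity identities, context decompositions,
clustering, dominance counts."""
import numpy as np
import pandas as pd
import pytest

from hurdlevp.model import PosteriorDraws
from hurdlevp.variance import (
    conditional_vp_environmental,
    conditional_vp_functional,
    dominant_driver_counts,
    kmeans_profiles,
    variance_partition,
)


def make_draws(rng, D=30, p=5, S=4, levels=("site",), k=2, beta=None):
    """Small posterior with two fixed groups and optional random levels."""
    beta = rng.normal(size=(D, p, S)) if beta is None else beta
    lambdas = {r: rng.normal(scale=0.5, size=(D, k, S)) for r in levels}
    etas = {r: rng.normal(size=(D, 3, k)) for r in levels}
    return PosteriorDraws(
        part="PA",
        beta=beta,
        gamma=np.zeros((D, p, 1)),
        omega=np.tile(np.eye(p), (D, 1, 1)),
        lambdas=lambdas,
        etas=etas,
        sigma=None,
        colnames=["intercept", "h1", "h2", "c1", "eff"],
        blocks={"intercept": [0], "habitat": [1, 2], "climate": [3],
                "effort": [4]},
        species=[f"sp{j}" for j in range(S)],
        level_values={r: [0, 1, 2] for r in levels},
    )


def test_fixed_components_sum_to_empirical_total_variance(rng):
    """Oracle identity: sum of group variances equals the empirical
    variance of the fixed predictor over the grid, draw by draw."""
    d = make_draws(rng)
    X = rng.normal(size=(200, 5))
    X[:, 0] = 1.0
    vp = variance_partition(d, X, effort_policy="constant")
    Xc = X.copy()
    Xc[:, 4] = Xc[:, 4].mean()
    f = np.einsum("nk,dks->dns", Xc, d.beta)
    total_emp = f.var(axis=1)  # (D, S), ddof=0
    hab = vp.variances[:, :, vp.components.index("habitat")]
    cli = vp.variances[:, :, vp.components.index("climate")]
    assert np.allclose(hab + cli, total_emp, atol=1e-10)


def test_orthogonal_columns_shares_proportional_to_beta_sq_var(rng):
    D, S = 10, 3
    n = 400
    X = np.column_stack(
        [np.ones(n), rng.normal(0, 1.0, n), rng.normal(0, 2.0, n),
         rng.normal(0, 0.5, n), np.ones(n)]
    )
    d = make_draws(rng, D=D, S=S, levels=())
    vp = variance_partition(d, X)
    for c, cols in (("habitat", [1, 2]), ("climate", [3])):
        V = vp.variances[:, :, vp.components.index(c)]
        direct = np.einsum(
            "nk,dks->dns", X[:, cols], d.beta[:, cols, :]
        ).var(axis=1)
        # symmetric covariance split: V_g = direct + cross terms
        cross = np.einsum(
            "dks,dks->ds",
            d.beta[:, cols, :],
            np.einsum(
                "kl,dls->dks",
                np.cov(X, rowvar=False, ddof=0)[np.ix_(cols, [1, 2, 3])],
                d.beta[:, [1, 2, 3], :],
            ),
        ) - direct
        assert np.allclose(V, direct + cross, atol=1e-10)


def test_zero_climate_coefficients_give_zero_climate_share(rng):
    d = make_draws(rng)
    d.beta[:, 3, :] = 0.0
    X = rng.normal(size=(100, 5))
    vp = variance_partition(d, X)
    assert np.allclose(vp.component_share("climate"), 0.0, atol=1e-12)
    others = [i for i, c in enumerate(vp.components) if c != "climate"]
    assert np.allclose(vp.shares[:, :, others].sum(axis=-1), 1.0)


def test_shares_sum_to_one_and_re_variance_is_sum_sq_loadings(rng):
    d = make_draws(rng, levels=("site", "year"))
    X = rng.normal(size=(150, 5))
    vp = variance_partition(d, X)
    assert np.allclose(vp.shares.sum(axis=-1), 1.0, atol=1e-8)
    v_site = vp.variances[:, :, vp.components.index("site")]
    assert np.allclose(v_site, (d.lambdas["site"] ** 2).sum(axis=1))


def test_effort_held_constant_contributes_nothing(rng):
    d = make_draws(rng)
    X = rng.normal(size=(100, 5))
    X[:, 4] = rng.normal(size=100) * 5  # strongly varying effort
    vp_const = variance_partition(d, X, effort_policy="constant")
    X2 = X.copy()
    X2[:, 4] = 0.0
    vp_zero = variance_partition(d, X2, effort_policy="keep")
    assert np.allclose(vp_const.variances, vp_zero.variances)


def test_translation_invariance_of_shares(rng):
    d = make_draws(rng)
    X = rng.normal(size=(100, 5))
    vp1 = variance_partition(d, X)
    X2 = X + np.array([0.0, 5.0, -2.0, 7.0, 0.0])
    vp2 = variance_partition(d, X2)
    assert np.allclose(vp1.shares, vp2.shares, atol=1e-10)


def test_groups_must_partition_columns(rng):
    d = make_draws(rng)
    X = rng.normal(size=(50, 5))
    with pytest.raises(ValueError):
        variance_partition(d, X, groups={"habitat": [1, 2]})  # misses col 3
    with pytest.raises(ValueError):
        variance_partition(d, X, groups={"a": [1, 2], "b": [2, 3]})


def test_kmeans_recovers_separated_blobs(rng):
    from sklearn.metrics import adjusted_rand_score

    centers = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    truth = rng.integers(0, 3, 300)
    comp = centers[truth] + rng.normal(0, 0.01, (300, 3))
    labels, profiles = kmeans_profiles(
        pd.DataFrame(comp, columns=["forest", "water", "agriculture"]),
        k=3, seed=0,
    )
    assert adjusted_rand_score(truth, pd.factorize(labels)[0]) == 1.0
    assert set(labels.unique()) == {"forest", "water", "agriculture"}


def test_kmeans_heterogeneous_naming_and_determinism(rng):
    comp = pd.DataFrame(
        rng.dirichlet(np.ones(4) * 5, size=100),
        columns=["a", "b", "c", "d"],
    )
    l1, _ = kmeans_profiles(comp, k=2, seed=3)
    l2, _ = kmeans_profiles(comp, k=2, seed=3)
    assert l1.equals(l2)
    assert all(lab.startswith("heterogeneous") for lab in l1.unique())


def test_kmeans_degenerate_inputs_error():
    comp = pd.DataFrame(np.ones((20, 3)) / 3, columns=list("abc"))
    with pytest.raises(ValueError):
        kmeans_profiles(comp, k=3)
    with pytest.raises(ValueError):
        kmeans_profiles(comp.iloc[:2], k=4)


def test_conditional_vp_law_of_total_variance(rng):
    d = make_draws(rng)
    X = rng.normal(size=(120, 5))
    for labels in (
        rng.integers(0, 4, 120),
        np.zeros(120, dtype=int),
        np.arange(120) % 7,
    ):
        ctx = conditional_vp_environmental(d, X, labels)
        assert np.allclose(
            ctx.within_fixed + ctx.between, ctx.total_fixed, atol=1e-8
        )


def test_single_context_has_zero_between(rng):
    d = make_draws(rng)
    X = rng.normal(size=(80, 5))
    ctx = conditional_vp_environmental(d, X, np.zeros(80, dtype=int))
    assert np.allclose(ctx.between, 0.0, atol=1e-12)
    assert np.allclose(ctx.within_fixed, ctx.total_fixed, atol=1e-10)


def test_identical_context_distributions_have_small_between(rng):
    """Two contexts drawn from the same covariate distribution should show
    a negligible between-context share in expectation."""
    d = make_draws(rng, D=5)
    ratios = []
    for rep in range(20):
        r2 = np.random.default_rng(rep)
        X = r2.normal(size=(300, 5))
        labels = np.repeat([0, 1], 150)
        ctx = conditional_vp_environmental(d, X, labels)
        ratios.append((ctx.between / ctx.total_fixed).mean())
    assert np.mean(ratios) < 0.05


def test_merging_contexts_never_increases_between(rng):
    d = make_draws(rng, D=8)
    X = rng.normal(size=(200, 5))
    X[:100, 1] += 2.0  # make contexts genuinely differ
    fine = np.arange(200) // 50  # 4 contexts
    coarse = fine // 2  # merged pairwise
    b_fine = conditional_vp_environmental(d, X, fine).between
    b_coarse = conditional_vp_environmental(d, X, coarse).between
    assert np.all(b_coarse <= b_fine + 1e-10)


def test_small_context_warns_but_keeps_identity(rng):
    d = make_draws(rng)
    X = rng.normal(size=(41, 5))
    labels = np.array([0] * 40 + [1])  # singleton context
    with pytest.warns(UserWarning):
        ctx = conditional_vp_environmental(d, X, labels)
    assert "1" not in ctx.per_context
    assert np.allclose(
        ctx.within_fixed + ctx.between, ctx.total_fixed, atol=1e-8
    )


def test_functional_pooling_single_and_identical_species(rng):
    beta = rng.normal(size=(40, 5, 4))
    beta[:, :, 3] = beta[:, :, 2]  # two identical-parameter species
    d = make_draws(rng, D=40, beta=beta, levels=())
    X = rng.normal(size=(100, 5))
    vp = variance_partition(d, X)
    groups = pd.Series(
        ["solo", "pair", "pair2", "pair2"], index=vp.species
    )
    pooled = conditional_vp_functional(vp, groups)
    # single-species group: pooled draws identical to that species' draws
    solo = pooled["solo"]["pooled_shares"]
    assert np.allclose(solo, vp.shares[:, 0, :])
    # identical species: pooled distribution equals the single species'
    from scipy.stats import ks_2samp

    pair = pooled["pair2"]["pooled_shares"][:, 0]
    single = vp.shares[:, 2, 0]
    assert ks_2samp(pair, single).pvalue > 0.01
    # shares still sum to 1 within each pooled row
    assert np.allclose(solo.sum(axis=1), 1.0)
    with pytest.warns(UserWarning):
        conditional_vp_functional(
            vp, pd.Series(["ghost"], index=["not_a_species"])
        )


def test_dominant_driver_counts(rng):
    d = make_draws(rng)
    d.beta[:, 3, :] = 0.0  # no climate effect at all
    X = rng.normal(size=(100, 5))
    vp = variance_partition(d, X)
    dom = dominant_driver_counts(vp)
    assert np.all(dom["counts"] == len(vp.species))
    assert dom["median"] == len(vp.species)
    # counts can never exceed S
    d2 = make_draws(rng)
    vp2 = variance_partition(d2, X)
    assert np.all(dominant_driver_counts(vp2)["counts"] <= len(vp2.species))


def test_block_symmetry_of_dominance(rng):
    """Exchanging the habitat and climate blocks mirrors the dominance
    count around S/2 across replicate parameter draws."""
    n, S = 150, 6
    counts_a, counts_b = [], []
    for rep in range(20):
        r = np.random.default_rng(rep)
        X = r.normal(size=(n, 4))
        beta = r.normal(size=(1, 4, S))
        common = dict(
            part="PA", gamma=np.zeros((1, 4, 1)),
            omega=np.tile(np.eye(4), (1, 1, 1)), lambdas={}, etas={},
            sigma=None, colnames=list("abcd"),
            species=[f"s{j}" for j in range(S)], level_values={},
        )
        blocks_a = {"intercept": [], "habitat": [0, 1], "climate": [2, 3],
                    "effort": []}
        blocks_b = {"intercept": [], "habitat": [2, 3], "climate": [0, 1],
                    "effort": []}
        da = PosteriorDraws(beta=beta, blocks=blocks_a, **common)
        db = PosteriorDraws(beta=beta, blocks=blocks_b, **common)
        counts_a.append(
            dominant_driver_counts(variance_partition(da, X))["median"]
        )
        counts_b.append(
            dominant_driver_counts(variance_partition(db, X))["median"]
        )
    # swapping the blocks complements the count: a + b = S exactly
    assert np.allclose(np.array(counts_a) + np.array(counts_b), S)
    assert abs(np.mean(counts_a) - S / 2) < 1.0
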