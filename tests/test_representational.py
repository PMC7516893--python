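"""Representational heterogeneity: categorical reductions, Gaussian closed
forms against blind quadrature, pooling, and decomposition invariants."""

import math

import numpy as np
import pytest

from renyihet import (
    CategoricalPosteriorSet,
    GaussianComponentSet,
    ValidationError,
    categorical_point_heterogeneity,
    categorical_rrh,
    continuous_point_heterogeneity,
    continuous_rrh,
    gaussian_renyi,
    gaussian_within,
    nonparametric_pooled,
    parametric_pool_gaussian,
    renyi_heterogeneity,
)

from conftest import gaussian_renyi_quadrature, random_psd

SQRT_2PIE = math.sqrt(2 * math.pi * math.e)


def test_categorical_point_heterogeneity():
    assert categorical_point_heterogeneity([0, 1, 0], 2) == 1.0
    assert categorical_point_heterogeneity([0.25] * 4, 3) == pytest.approx(4.0)
    assert categorical_point_heterogeneity([0.5, 0.25, 0.25], 1) == pytest.approx(
        2 ** 1.5, rel=1e-12
    )


@pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0, math.inf])
def test_categorical_rrh_deterministic_posteriors_recover_hill_numbers(rng, q):
    """One-hot posteriors with uniform weights: between = Pi_q of the label
    frequencies (the classical biodiversity/equality computation)."""
    N, nz = 30, 4
    labels = rng.integers(0, nz, N)
    F = np.zeros((N, nz))
    F[np.arange(N), labels] = 1.0
    d = categorical_rrh(F, q)
    counts = np.bincount(labels, minlength=nz) / N
    assert d.within == pytest.approx(1.0, abs=1e-12)
    assert d.between == pytest.approx(renyi_heterogeneity(counts, q), rel=1e-10)


def test_categorical_rrh_uniform_posteriors_have_between_one():
    F = np.full((6, 3), 1 / 3)
    for q in [0.5, 1.0, 2.0]:
        d = categorical_rrh(F, q)
        assert d.pooled == pytest.approx(3.0, rel=1e-12)
        assert d.between == pytest.approx(1.0, rel=1e-12)


def test_categorical_rrh_two_disjoint_points():
    d = categorical_rrh(CategoricalPosteriorSet([[1, 0], [0, 1]]), 2)
    assert d.between == pytest.approx(2.0)


def test_gaussian_renyi_known_values():
    assert gaussian_renyi(np.eye(2), 1) == pytest.approx(2 * math.pi * math.e, rel=1e-12)
    assert gaussian_renyi(np.eye(1), math.inf) == pytest.approx(
        math.sqrt(2 * math.pi), rel=1e-12
    )
    assert gaussian_renyi(np.eye(1), 2) == pytest.approx(math.sqrt(4 * math.pi), rel=1e-12)
    with pytest.raises(ValueError):
        gaussian_renyi(np.eye(2), 0)


def test_gaussian_renyi_scaling_homogeneity(rng):
    S = random_psd(rng, 3)
    c = 1.7
    for q in [0.5, 1.0, 2.0, math.inf]:
        assert gaussian_renyi(c ** 2 * S, q) == pytest.approx(
            c ** 3 * gaussian_renyi(S, q), rel=1e-10
        )


def test_gaussian_renyi_singular_covariance_warns(caplog):
    with caplog.at_level("WARNING"):
        assert gaussian_renyi(np.zeros((2, 2)), 2) == 0.0


@pytest.mark.parametrize("nz", [1, 2])
@pytest.mark.parametrize("q, tol", [(0.5, 1e-6), (1.0, 1e-6), (2.0, 1e-6),
                                    (5.0, 1e-6), (1000.0, 1e-3)])
def test_gaussian_renyi_matches_quadrature(rng, nz, q, tol):
    for _ in range(3):
        S = random_psd(rng, nz)
        assert gaussian_renyi(S, q) == pytest.approx(
            gaussian_renyi_quadrature(S, q), rel=tol
        )


def test_gaussian_renyi_infinite_q_is_large_q_limit(rng):
    """The q=inf row is the q->infinity limit of the general expression."""
    S = random_psd(rng, 2)
    assert gaussian_renyi(S, math.inf) == pytest.approx(
        gaussian_renyi(S, 1e8), rel=1e-6
    )


def test_parametric_pooling_identity_and_two_point():
    S = np.array([[2.0, 0.3], [0.3, 1.0]])
    g = GaussianComponentSet([[0.5, -1.0]], S)
    pooled = parametric_pool_gaussian(g)
    np.testing.assert_allclose(pooled.mu_star, [0.5, -1.0])
    np.testing.assert_allclose(pooled.Sigma_star, S)

    g2 = GaussianComponentSet(
        [[-1.0], [1.0]], np.zeros((2, 1, 1)), [0.5, 0.5]
    )
    pooled2 = parametric_pool_gaussian(g2)
    assert pooled2.mu_star[0] == pytest.approx(0.0)
    assert pooled2.Sigma_star[0, 0] == pytest.approx(1.0)


def test_parametric_pooling_matches_monte_carlo_covariance(rng):
    g = GaussianComponentSet(
        rng.normal(size=(4, 2)) * 2.0,
        np.stack([random_psd(rng, 2) for _ in range(4)]),
        rng.dirichlet(np.full(4, 5.0)),
    )
    pooled = parametric_pool_gaussian(g)
    z = g.sample(100_000, np.random.default_rng(1))
    np.testing.assert_allclose(z.mean(axis=0), pooled.mu_star, atol=0.05)
    np.testing.assert_allclose(np.cov(z.T), pooled.Sigma_star, rtol=0.02, atol=0.05)


def test_gaussian_within_single_component_equals_renyi(rng):
    S = random_psd(rng, 2)
    g = GaussianComponentSet([[0.0, 0.0]], S)
    for q in [0.5, 1.0, 2.0, math.inf]:
        assert gaussian_within(g, q) == pytest.approx(gaussian_renyi(S, q), rel=1e-10)
    with pytest.raises(ValueError):
        gaussian_within(g, 0)


def test_gaussian_within_identical_covariances(rng):
    S = random_psd(rng, 2)
    g = GaussianComponentSet(rng.normal(size=(5, 2)), np.stack([S] * 5))
    for q in [0.5, 1.0, 2.0, math.inf]:
        assert gaussian_within(g, q) == pytest.approx(gaussian_renyi(S, q), rel=1e-10)


def _within_quadrature(g, q):
    """Oracle: weighted power-sum of per-component quadrature integrals."""
    logints = []
    for S in g.Sigma:
        pi = gaussian_renyi_quadrature(S, q)
        logints.append((1.0 - q) * math.log(pi))  # log int f^q
    logints = np.array(logints)
    wq = g.w ** q
    num = (wq * np.exp(logints)).sum()
    return (num / wq.sum()) ** (1.0 / (1.0 - q))


@pytest.mark.parametrize("q", [0.5, 2.0, 5.0])
def test_gaussian_within_matches_quadrature_oracle(rng, q):
    g = GaussianComponentSet(
        [[0.0], [0.0]],
        np.array([[[1.0]], [[4.0]]]),
        [0.5, 0.5],
    )
    assert gaussian_within(g, q) == pytest.approx(_within_quadrature(g, q), rel=1e-6)
    g2 = GaussianComponentSet(
        rng.normal(size=(3, 2)),
        np.stack([random_psd(rng, 2) for _ in range(3)]),
        rng.dirichlet(np.full(3, 3.0)),
    )
    assert gaussian_within(g2, q) == pytest.approx(_within_quadrature(g2, q), rel=1e-6)


def test_gaussian_within_infinite_q_as_large_q_limit(rng):
    g = GaussianComponentSet(
        rng.normal(size=(3, 1)),
        rng.uniform(0.5, 2.0, size=(3, 1, 1)),
        rng.dirichlet(np.full(3, 2.0)),
    )
    assert gaussian_within(g, math.inf) == pytest.approx(
        gaussian_within(g, 2000.0), rel=5e-3
    )


def test_continuous_point_heterogeneity_uniform_and_normal():
    L = 2.5
    for q in [0.5, 1.0, 3.0]:
        val = continuous_point_heterogeneity(
            lambda z: 1.0 / L if 0 <= z[0] <= L else 0.0, [(0.0, L)], q
        )
        assert val == pytest.approx(L, rel=1e-6)
    normal = lambda z: math.exp(-0.5 * z[0] ** 2) / math.sqrt(2 * math.pi)
    assert continuous_point_heterogeneity(normal, [(-10, 10)], 1) == pytest.approx(
        SQRT_2PIE, rel=1e-8
    )
    assert continuous_point_heterogeneity(normal, [(-10, 10)], 2) == pytest.approx(
        math.sqrt(4 * math.pi), rel=1e-8
    )


def test_nonparametric_pooled_identical_components(rng):
    S = random_psd(rng, 1)
    g = GaussianComponentSet(np.zeros((3, 1)), np.stack([S] * 3))
    for q in [0.5, 1.0, 2.0]:
        assert nonparametric_pooled(g, q) == pytest.approx(
            gaussian_renyi(S, q), rel=1e-7
        )


def test_nonparametric_pooled_well_separated_doubles():
    g = GaussianComponentSet([[-10.0], [10.0]], np.ones((2, 1, 1)), [0.5, 0.5])
    assert nonparametric_pooled(g, 2) == pytest.approx(
        2 * math.sqrt(4 * math.pi), rel=1e-6
    )


def test_nonparametric_mc_agrees_with_quadrature(rng):
    g = GaussianComponentSet(
        [[-1.0], [2.0]], np.array([[[1.0]], [[0.5]]]), [0.4, 0.6]
    )
    for q in [1.0, 2.0]:
        quad = nonparametric_pooled(g, q, method="quadrature")
        mc = nonparametric_pooled(g, q, method="mc", n_samples=200_000, seed=7)
        assert mc == pytest.approx(quad, rel=0.02)


def test_continuous_rrh_identical_components_between_one(rng):
    S = random_psd(rng, 2)
    g = GaussianComponentSet(np.zeros((4, 2)), np.stack([S] * 4))
    for pooling in ["parametric", "nonparametric"]:
        d = continuous_rrh(g, 2, pooling=pooling)
        assert d.between == pytest.approx(1.0, rel=1e-6)
        assert d.pooled == pytest.approx(d.within * d.between, rel=1e-9)


def test_continuous_rrh_replication_to_n():
    """Three well-separated same-shape clusters: effectively 3 observations."""
    mu = np.array([[-6.0, 0.0], [6.0, 0.0], [0.0, 10.0]])
    g = GaussianComponentSet(mu, np.stack([0.25 * np.eye(2)] * 3))
    d = continuous_rrh(g, 1, pooling="nonparametric")
    assert d.between == pytest.approx(3.0, rel=1e-4)


def test_affine_equivariance_under_rotation(rng):
    theta = 0.7
    R = np.array([[math.cos(theta), -math.sin(theta)],
                  [math.sin(theta), math.cos(theta)]])
    mu = rng.normal(size=(3, 2))
    Sigma = np.stack([random_psd(rng, 2) for _ in range(3)])
    g = GaussianComponentSet(mu, Sigma)
    g_rot = GaussianComponentSet(mu @ R.T, np.stack([R @ S @ R.T for S in Sigma]))
    for q in [0.5, 1.0, 2.0]:
        a, b = continuous_rrh(g, q), continuous_rrh(g_rot, q)
        assert a.pooled == pytest.approx(b.pooled, rel=1e-9)
        assert a.within == pytest.approx(b.within, rel=1e-9)
        assert a.between == pytest.approx(b.between, rel=1e-9)


def test_component_set_validation_and_promotion():
    # diagonal variance rows are promoted to full covariances
    g = GaussianComponentSet(
        [[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]], [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    )
    assert g.Sigma.shape == (3, 2, 2)
    assert g.Sigma[1, 0, 0] == 3.0 and g.Sigma[1, 0, 1] == 0.0
    g2 = GaussianComponentSet.from_logvar([[0.0]], [[math.log(2.0)]])
    assert g2.Sigma[0, 0, 0] == pytest.approx(2.0)
    with pytest.raises(ValidationError):
        GaussianComponentSet([[0.0, 0.0]], -np.eye(2))
    with pytest.raises(ValidationError):
        GaussianComponentSet([[0.0]], np.eye(1), [0.7, 0.3])


def test_subset_renormalizes_weights(rng):
    g = GaussianComponentSet(
        rng.normal(size=(5, 1)), np.ones((5, 1, 1)), rng.dirichlet(np.full(5, 2.0))
    )
    sub = g.subset([0, 2, 4])
    assert sub.N == 3
    assert sub.w.sum() == pytest.approx(1.0)
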