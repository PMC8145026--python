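"""The MM estimator: update operators against transcription oracles, the
GMM/FCM/k-means equivalences, monotone descent, and the failure-handling
policies (empty clusters, degenerate covariance scales)."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from paretoclust import (
    ClusterParams,
    ConvergenceError,
    DegenerateScaleError,
    EmptyClusterError,
    Hyperparams,
    MembershipMatrix,
    assign,
    fcm_reference,
    fit,
    init_params,
    make_hyperparams,
    mse_centers,
    responsibilities,
    update_centers,
    update_covariances,
    update_proportions,
)
from conftest import random_theta


def monotone(trace, slack=1e-10):
    trace = np.asarray(trace)
    return np.all(np.diff(trace) <= slack * (1.0 + np.abs(trace[:-1])))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_deterministic_and_valid(blobs):
    X, _ = blobs
    a = init_params(X, 2)
    b = init_params(X, 2)
    assert np.array_equal(a.centers, b.centers)
    assert np.array_equal(a.covariances, b.covariances)
    assert a.proportions.sum() == pytest.approx(1.0)


def test_init_recovers_blob_means(blobs):
    X, _ = blobs
    theta = init_params(X, 2)
    got = np.sort(theta.centers[:, 0])
    # blob SE is 1/sqrt(200) ~ 0.07; centers within 3 SE of (+-5, 0)
    assert abs(got[0] + 5.0) < 0.25 and abs(got[1] - 5.0) < 0.25


def test_init_n_equals_k():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
    theta = init_params(X, 3)
    assert np.allclose(np.sort(theta.centers, axis=0), np.sort(X, axis=0))
    assert np.allclose(theta.proportions, 1.0 / 3.0)


def test_init_k_larger_than_n():
    with pytest.raises(ValueError):
        init_params(np.zeros((3, 2)), 4)


def test_init_trims_extreme_outliers(rng):
    X = np.vstack([rng.normal([0, 0], 1, (150, 2)), rng.normal([8, 8], 1, (150, 2)),
                   [[500.0, -400.0], [450.0, -380.0]]])
    theta = init_params(X, 2)
    assert np.max(np.abs(theta.centers)) < 20.0  # no component seeded on the outliers


# ---------------------------------------------------------------------------
# responsibilities
# ---------------------------------------------------------------------------

def test_responsibilities_symmetry():
    theta = ClusterParams.isotropic([[1.0, 0.0], [-1.0, 0.0]])
    Q = responsibilities(np.array([[0.0, 3.0]]), theta, 0.5, 1.0)
    assert np.allclose(Q.values, 0.5)


def test_responsibilities_match_transcription(rng):
    X = rng.normal(size=(10, 2))
    theta = random_theta(rng, K=3)
    tau, beta = 0.8, 0.7
    Q = responsibilities(X, theta, tau, beta).values
    for i, x in enumerate(X):
        w = np.array([
            theta.proportions[k] * np.linalg.det(theta.covariances[k]) ** -0.5
            * (1 + tau * beta * (x - theta.centers[k]) @ np.linalg.inv(theta.covariances[k])
               @ (x - theta.centers[k])) ** (-1 / beta)
            for k in range(3)])
        assert np.allclose(Q[i], w / w.sum(), rtol=1e-10)


def test_responsibilities_tau_inf_match_fcm_membership(rng):
    """In the tau = inf branch with beta = m - 1, q is Bezdek's row-stochastic
    membership, and the row-normalized q^{1+beta} matches the row-normalized
    u-weights of the classic update."""
    m = 2.0
    beta = m - 1.0
    X = rng.normal(size=(12, 2))
    centers = rng.normal(size=(3, 2)) * 2
    theta = ClusterParams.isotropic(centers)
    q = responsibilities(X, theta, math.inf, beta).values
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    u_bez = d2 ** (-1 / (m - 1))
    u_bez /= u_bez.sum(axis=1, keepdims=True)
    assert np.allclose(q, u_bez, atol=1e-10)
    # Eq-style u weights: u_ik = [sum_l (d_ik^2 / d_il^2)^{1/(m-1)}]^{-m}
    u_w = np.array([[sum((d2[i, k] / d2[i, l]) ** (1 / (m - 1)) for l in range(3)) ** -m
                     for k in range(3)] for i in range(12)])
    qm = q ** (1 + beta)
    assert np.allclose(qm / qm.sum(1, keepdims=True), u_w / u_w.sum(1, keepdims=True),
                       atol=1e-6)


def test_membership_matrix_validation():
    with pytest.raises(ValueError):
        MembershipMatrix(np.array([[0.5, 0.4]]))
    with pytest.raises(ValueError):
        MembershipMatrix(np.array([[1.2, -0.2]]))


# ---------------------------------------------------------------------------
# update operators
# ---------------------------------------------------------------------------

def test_update_centers_uniform_q_gives_grand_mean(rng):
    X = rng.normal(size=(20, 3))
    Q = np.full((20, 4), 0.25)
    for beta in [0.0, 0.5, 1.0]:
        assert np.allclose(update_centers(X, Q, beta), X.mean(axis=0))


def test_update_centers_matches_squared_weights(rng):
    X = rng.normal(size=(15, 2))
    Q = rng.dirichlet(np.ones(3), size=15)
    got = update_centers(X, Q, 1.0)
    want = (Q.T**2 @ X) / (Q**2).sum(axis=0)[:, None]
    assert np.allclose(got, want, rtol=1e-12)


def test_update_centers_empty_cluster():
    Q = np.column_stack([np.ones(5), np.zeros(5)])
    with pytest.raises(EmptyClusterError):
        update_centers(np.random.default_rng(0).normal(size=(5, 2)), Q, 0.5)


def test_update_covariances_gmm_reduction(rng):
    """beta=0, tau=1/2 with uniform one-cluster weights gives the plain
    (biased) sample covariance when the ridge is disabled."""
    X = rng.normal(size=(50, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]])
    Q = np.ones((50, 1))
    got = update_covariances(X, Q, X.mean(0, keepdims=True), 0.5, 0.0, ridge_alpha=1.0)
    want = np.cov(X, rowvar=False, ddof=0)
    assert np.allclose(got[0], want, rtol=1e-10)


def test_update_covariances_degenerate_scale():
    X = np.random.default_rng(0).normal(size=(10, 2))
    Q = np.full((10, 2), 0.5)
    with pytest.raises(DegenerateScaleError):
        update_covariances(X, Q, np.zeros((2, 2)), 0.5, 1.0)  # tau*(2-2) = 0


def test_update_covariances_matches_scaled_scatter(rng):
    X = rng.normal(size=(12, 2))
    Q = rng.dirichlet(np.ones(2), size=12)
    centers = rng.normal(size=(2, 2))
    tau, beta = 0.5, 0.5
    got = update_covariances(X, Q, centers, tau, beta, ridge_alpha=1.0)
    coef = tau * (2 - 2 * beta)  # = 0.5
    for k in range(2):
        w = Q[:, k] ** (1 + beta)
        diff = X - centers[k]
        want = coef * (w[:, None] * diff).T @ diff / w.sum()
        assert np.allclose(got[k], want, rtol=1e-10)


def test_update_proportions_beta_zero_is_column_means(rng):
    X = rng.normal(size=(20, 2))
    Q = rng.dirichlet(np.ones(3), size=20)
    theta = random_theta(rng, K=3)
    assert np.allclose(update_proportions(X, Q, theta, 0.5, 0.0), Q.mean(axis=0))


def test_update_proportions_symmetric_configuration():
    X = np.array([[1.0, 0.0], [-1.0, 0.0], [2.0, 1.0], [-2.0, -1.0]])
    theta = ClusterParams.isotropic([[1.5, 0.5], [-1.5, -0.5]])
    Q = responsibilities(X, theta, 0.5, 1.0)
    pi = update_proportions(X, Q, theta, 0.5, 1.0)
    assert np.allclose(pi, 0.5, atol=1e-12)


def test_update_proportions_matches_transcription(rng):
    X = rng.normal(size=(10, 2))
    theta = random_theta(rng, K=2)
    tau, beta = 0.6, 1.0
    Q = responsibilities(X, theta, tau, beta).values
    got = update_proportions(X, Q, theta, tau, beta)
    w = np.zeros((10, 2))
    for i, x in enumerate(X):
        for k in range(2):
            m = (x - theta.centers[k]) @ np.linalg.inv(theta.covariances[k]) @ (x - theta.centers[k])
            w[i, k] = (np.linalg.det(theta.covariances[k]) ** -0.5
                       * (1 + tau * beta * m) ** (-1 / beta))
    t = ((Q ** (1 + beta)) * w ** -beta).sum(axis=0) ** (1 / (1 + beta))
    assert np.allclose(got, t / t.sum(), rtol=1e-8)


def test_assign_argmax_and_ties():
    Q = np.array([[0.7, 0.3], [0.5, 0.5], [0.2, 0.8]])
    assert assign(Q).tolist() == [1, 1, 2]
    R = np.random.default_rng(1).dirichlet(np.ones(4), size=30)
    assert np.array_equal(assign(R), R.argmax(axis=1) + 1)


# ---------------------------------------------------------------------------
# fit: closed forms, equivalences, descent, robustness
# ---------------------------------------------------------------------------

def test_fit_k1_closed_form(rng):
    X = rng.normal(size=(40, 2)) @ np.array([[1.5, 0.2], [0.2, 0.7]])
    hyper = Hyperparams(tau=0.5, beta=0.0, ridge_alpha=0.95)
    res = fit(X, 1, hyper)
    assert np.allclose(res.params.centers[0], X.mean(axis=0), atol=1e-10)
    raw = np.cov(X, rowvar=False, ddof=0)
    want = 0.95 * raw + 0.05 * raw.diagonal().max() * np.eye(2)
    assert np.allclose(res.params.covariances[0], want, atol=1e-8)


def test_fit_recovers_separated_blobs(blobs):
    X, truth = blobs
    res = fit(X, 2, Hyperparams(tau=0.5, beta=0.5))
    centers = res.params.centers[np.argsort(res.params.centers[:, 0])]
    assert np.allclose(centers, [[-5, 0], [5, 0]], atol=0.5)
    purity = max(np.mean(res.labels == truth), np.mean(res.labels == 3 - truth))
    assert purity >= 0.95
    assert monotone(res.energy_trace)


def test_fit_gmm_sweep_equals_textbook_em(rng):
    """One beta=0, tau=1/2 sweep (without ridge) is exactly one EM step for a
    Gaussian mixture."""
    X = rng.normal(size=(30, 2)) * 2
    theta = random_theta(rng, K=3)
    Q = responsibilities(X, theta, 0.5, 0.0).values
    resp = np.column_stack([
        theta.proportions[k] * multivariate_normal.pdf(X, theta.centers[k], theta.covariances[k])
        for k in range(3)])
    resp /= resp.sum(axis=1, keepdims=True)
    assert np.allclose(Q, resp, atol=1e-10)
    mu = update_centers(X, Q, 0.0)
    assert np.allclose(mu, (resp.T @ X) / resp.sum(0)[:, None], atol=1e-10)
    cov = update_covariances(X, Q, mu, 0.5, 0.0, ridge_alpha=1.0)
    for k in range(3):
        diff = X - mu[k]
        want = (resp[:, k, None] * diff).T @ diff / resp[:, k].sum()
        assert np.allclose(cov[k], want, atol=1e-10)
    pi = update_proportions(X, Q, ClusterParams(mu, cov, theta.proportions), 0.5, 0.0)
    assert np.allclose(pi, resp.mean(axis=0), atol=1e-12)


def test_fit_fuzzy_mode_matches_classic_fcm(rng):
    X = np.vstack([rng.normal([3, 0], 1, (60, 2)), rng.normal([-3, 0], 1, (60, 2))])
    centers0 = np.array([[1.0, 0.5], [-1.0, -0.5]])
    init = ClusterParams.isotropic(centers0)
    res = fit(X, 2, make_hyperparams("fuzzy", m=2.0), init=init)
    fcm_centers, fcm_u = fcm_reference(X, 2, 2.0, centers0)
    assert mse_centers(res.params.centers, fcm_centers) < 1e-6
    assert np.allclose(fcm_u.sum(axis=1), 1.0)
    assert monotone(res.energy_trace)


def test_fit_kmeans_mode_is_lloyd(rng):
    X = rng.normal(size=(50, 2)) * 3
    centers = X[:3].copy()
    init = ClusterParams.isotropic(centers)
    # hand-rolled Lloyd iteration
    lloyd = centers.copy()
    for _ in range(40):
        lab = ((X[:, None, :] - lloyd[None, :, :]) ** 2).sum(-1).argmin(1)
        new = np.vstack([X[lab == k].mean(0) if np.any(lab == k) else lloyd[k]
                         for k in range(3)])
        if np.allclose(new, lloyd):
            break
        lloyd = new
    res = fit(X, 3, make_hyperparams("kmeans"), init=init)
    assert np.allclose(np.sort(res.params.centers, 0), np.sort(lloyd, 0), atol=1e-8)
    assert monotone(res.energy_trace)


def test_fit_permutation_equivariance(rng):
    X = rng.normal(size=(60, 2))
    hyper = Hyperparams(tau=0.5, beta=0.5, max_iter=30)
    init = init_params(X, 3)
    res1 = fit(X, 3, hyper, init=init)
    perm = rng.permutation(60)
    res2 = fit(X[perm], 3, hyper, init=init)
    assert np.allclose(res1.params.centers, res2.params.centers, atol=1e-9)
    assert np.array_equal(res1.labels[perm], res2.labels)
    # permuting the initial component order permutes the estimate identically
    order = np.array([2, 0, 1])
    init_p = ClusterParams(init.centers[order], init.covariances[order],
                           init.proportions[order])
    res3 = fit(X, 3, hyper, init=init_p)
    assert np.allclose(res3.params.centers, res1.params.centers[order], atol=1e-9)


def test_fit_monotone_descent_random_instances(rng):
    """Exact-MM fits (no ridge when Sigma is estimated) always descend."""
    for trial in range(10):
        X = rng.normal(size=(80, 2)) * (1 + trial % 3)
        hyper = Hyperparams(
            tau=[0.3, 0.5, 1.0][trial % 3],
            beta=[0.0, 0.4, 0.8][(trial + 1) % 3],
            estimate_cov=trial % 2 == 0,
            estimate_pi=True,
            ridge_alpha=1.0,
            max_iter=40,
        )
        idx = rng.choice(80, 3, replace=False)
        init = ClusterParams.isotropic(X[idx])
        res = fit(X, 3, hyper, init=init)
        assert monotone(res.energy_trace), f"trial {trial}: {res.energy_trace}"


def test_fit_reseeds_component_stranded_far_away(rng):
    # the exponential (beta = 0) branch underflows for a center stranded far
    # from every point, emptying the component; the fitter must re-seed it
    X = rng.normal(size=(100, 2))
    init = ClusterParams.isotropic(np.array([[0.0, 0.0], [1e3, 1e3]]))
    res = fit(X, 2, Hyperparams(tau=0.5, beta=0.0, estimate_cov=False,
                                estimate_pi=False), init=init)
    assert res.n_reseeds >= 1
    assert np.max(np.abs(res.params.centers)) < 10.0


def test_fit_degenerate_data_raises_convergence_error():
    X = np.zeros((20, 2))
    with pytest.raises((ConvergenceError, EmptyClusterError)):
        fit(X, 2, Hyperparams(tau=0.5, beta=0.5))


def test_fit_guards():
    X = np.random.default_rng(0).normal(size=(20, 2))
    with pytest.raises(DegenerateScaleError):
        fit(X, 2, Hyperparams(tau=0.5, beta=1.0, estimate_cov=True))
    with pytest.raises(ValueError):
        fit(X, 2, Hyperparams(tau=math.inf, beta=1.0, estimate_cov=True,
                              estimate_pi=False))
    with pytest.raises(ValueError):
        fit(X, 25, Hyperparams())


def test_fcm_reference_near_hard_at_small_m(blobs):
    X, truth = blobs
    centers0 = np.array([[2.0, 0.0], [-2.0, 0.0]])
    centers, u = fcm_reference(X, 2, 1.05, centers0)
    hard = u.argmax(axis=1) + 1
    km_lab = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1).argmin(1) + 1
    assert np.mean(hard == km_lab) > 0.99  # memberships are nearly 0/1
    assert np.allclose(np.sort(centers[:, 0]), [-5, 5], atol=0.5)


def test_make_hyperparams_presets():
    assert make_hyperparams("gmm").beta == 0.0 and make_hyperparams("gmm").tau == 0.5
    fz = make_hyperparams("fuzzy", m=3.0)
    assert math.isinf(fz.tau) and fz.beta == 2.0 and not fz.estimate_cov
    km = make_hyperparams("kmeans")
    assert math.isinf(km.tau) and km.beta == 0.0
    assert make_hyperparams("rose", tau=2.0).tau == 2.0
    with pytest.raises(ValueError):
        make_hyperparams("gmm", beta=1.0)
    with pytest.raises(ValueError):
        make_hyperparams("unknown")
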