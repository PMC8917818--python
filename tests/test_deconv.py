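"""Deconvolution tests: population measure construction, block-system Gram
oracles, NNLS optimality, round-trip inversion, regularization behavior, and
credible bands."""

import numpy as np
import pytest

from transdermal import (
    ModelParameters,
    NoiseModel,
    ParameterDomain,
    PopulationMeasure,
    PosteriorChain,
    RegularizationWeights,
    assemble_system,
    build_population_measure,
    build_population_system,
    compute_filter,
    credible_band,
    deconvolve,
    fit_posterior,
    posterior_surface,
    simulate_tac,
    tune_regularization,
)
from transdermal.deconv import _time_basis_matrix, resimulate_tac
from transdermal.synthetic import EpisodeDesign, generate_brac, generate_episode

TAU = 1.0 / 12.0


@pytest.fixture(scope="module")
def single_peak():
    design = EpisodeDesign(peak_brac=0.3, pattern="single", total_hours=8.0)
    times, brac = generate_brac(design)
    return times, brac


@pytest.fixture(scope="module")
def point_system(single_peak):
    q = ModelParameters(0.8, 1.1)
    times, brac = single_peak
    K = len(brac) - 1
    filt = compute_filter(assemble_system(q, 8, TAU), K)
    tac = simulate_tac(filt, brac)
    measure = PopulationMeasure.point_mass(q.q1, q.q2)
    system = build_population_system(measure, n=8, m=K, tau=TAU, K_steps=K)
    return q, brac, tac, system


def test_measure_weights_normalized_and_point_mass():
    dom = ParameterDomain(0.5, 1.5, 0.5, 1.5)
    draws = np.full((200, 2), [0.7, 0.9])
    chain = PosteriorChain(draws=draws, burn_in=0, acceptance_rate=0.3, seed=0, n=8)
    measure = build_population_measure(chain, 5, 5, dom)
    assert measure.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.count_nonzero(measure.weights) == 1
    i, j = measure.cell_index(0.7, 0.9)
    assert measure.weights[i, j] == 1.0
    with pytest.raises(ValueError):
        PopulationMeasure(domain=dom, weights=np.full((2, 2), 0.3))
    with pytest.raises(ValueError):
        build_population_measure(
            PosteriorChain(draws=np.empty((0, 2)), burn_in=0, acceptance_rate=0.2, seed=0, n=8),
            5, 5, dom,
        )


def test_measure_from_chain_and_surface_agree(prior, q_unit, noise25, small_cohort):
    """Two independent discretizations of the same posterior -- the MCMC draw
    histogram and cell quadrature of the grid-normalized surface -- agree in
    total variation within 0.05."""
    chain = fit_posterior(prior, small_cohort, noise25, n=8, n_draws=10100, burn_in=100, seed=3)
    surface = posterior_surface(prior, small_cohort, noise25, n=8, m1=200, m2=200)
    from_chain = build_population_measure(chain, 10, 10, prior.domain)
    from_surface = build_population_measure(surface, 10, 10, prior.domain)
    assert from_chain.total_variation(from_surface) < 0.05


def test_derivative_gram_annihilates_constants():
    measure = PopulationMeasure.point_mass(1.0, 1.0)
    system = build_population_system(
        measure, n=4, m=12, tau=TAU, K_steps=24, zero_start=False
    )
    const = np.ones(system.n_coeffs)
    assert const @ system.Q2 @ const == pytest.approx(0.0, abs=1e-10)
    assert const @ system.Q1 @ const > 0.0


def test_value_gram_matches_dense_quadrature():
    """u^T Q1 u equals the dense quadrature of the measure-weighted integral
    of u(t, q)^2 for random coefficients."""
    dom = ParameterDomain(0.5, 1.5, 0.5, 1.5)
    weights = np.array([[0.25, 0.0], [0.25, 0.5]])
    measure = PopulationMeasure(domain=dom, weights=weights)
    K, m = 24, 8
    system = build_population_system(measure, n=4, m=m, tau=TAU, K_steps=K)
    rng = np.random.default_rng(2)
    c = rng.random(system.n_coeffs)
    T = K * TAU
    tq = np.linspace(0.0, T, 40001)
    Z = _time_basis_matrix(tq, m, T)[:, 1:]
    total = 0.0
    for idx, w in enumerate(system.cell_weights):
        u_cell = Z @ c[idx * system.n_basis : (idx + 1) * system.n_basis]
        total += w * np.trapezoid(u_cell**2, tq)
    assert c @ system.Q1 @ c == pytest.approx(total, rel=1e-8)


def test_zero_tac_deconvolves_to_zero(point_system):
    _, _, _, system = point_system
    result = deconvolve(np.zeros(system.K_steps + 1), system, RegularizationWeights(1.0, 1.0))
    assert np.all(result.mean_curve == 0.0)
    assert np.all(result.band_lower == 0.0)
    assert np.all(result.band_upper == 0.0)


def test_round_trip_inversion_noise_free(point_system):
    """Noise-free TAC from a known single-peak BrAC under a point-mass
    measure is inverted within 5% relative L2 error at tiny regularization."""
    _, brac, tac, system = point_system
    result = deconvolve(tac, system, RegularizationWeights(1e-8, 1e-8))
    err = np.linalg.norm(result.mean_curve - brac) / np.linalg.norm(brac)
    assert err < 0.05
    assert result.mean_curve.min() >= 0.0


def test_solution_satisfies_kkt_conditions(point_system):
    """The NNLS solution satisfies first-order optimality: the gradient of the
    stacked objective is zero on free coordinates and nonnegative on the
    active (zero) set."""
    _, _, tac, system = point_system
    weights = RegularizationWeights(1e-3, 1e-2)
    noisy = tac + np.random.default_rng(9).normal(0, 0.01, len(tac))
    noisy[0] = 0.0
    result = deconvolve(noisy, system, weights)
    R = weights.r1 * system.Q1 + weights.r2 * system.Q2 + 1e-12 * np.eye(system.n_coeffs)
    L = np.linalg.cholesky(R)
    A = np.vstack([system.H, L.T])
    b = np.concatenate([noisy[1:], np.zeros(system.n_coeffs)])
    U = result.coefficients.ravel()
    g = A.T @ (A @ U - b)
    active = U <= 1e-12
    scale = np.linalg.norm(A.T @ b)
    if active.any():
        assert g[active].min() > -1e-6 * scale
    assert np.abs(g[~active]).max() < 1e-6 * scale


def test_stronger_smoothing_reduces_total_variation(point_system):
    """Increasing the derivative weight r2 a hundredfold yields a mean curve
    with smaller discrete total variation."""
    _, _, tac, system = point_system
    noisy = tac + np.random.default_rng(4).normal(0, 0.02, len(tac))
    noisy[0] = 0.0
    tv = {}
    for r2 in (1e-3, 1e-1):
        res = deconvolve(noisy, system, RegularizationWeights(1e-6, r2))
        tv[r2] = np.abs(np.diff(res.mean_curve)).sum()
    assert tv[1e-1] < tv[1e-3]


def test_degenerate_measure_equals_single_parameter_solution(point_system):
    """Deconvolution under a point-mass measure coincides with an
    independently assembled single-parameter regularized NNLS solve."""
    from scipy.optimize import nnls as scipy_nnls
    from transdermal.forward import spline_mass_matrix, spline_stiffness_matrix

    q, _, tac, system = point_system
    K = system.K_steps
    weights = RegularizationWeights(1e-4, 1e-3)
    result = deconvolve(tac, system, weights)

    # Manual single-q assembly with the identical discretization choices.
    h = compute_filter(assemble_system(q, 8, TAU), K).h
    G = np.zeros((K, K))
    for k in range(K):
        G[k, : k + 1] = h[k::-1]
    T = K * TAU
    Z_in = _time_basis_matrix(np.arange(K) * TAU, K, T)[:, 1:]
    G1 = spline_mass_matrix(K, T)[1:, 1:]
    G2 = spline_stiffness_matrix(K, T)[1:, 1:]
    R = weights.r1 * G1 + weights.r2 * G2 + 1e-12 * np.eye(K)
    A = np.vstack([G @ Z_in, np.linalg.cholesky(R).T])
    b = np.concatenate([tac[1:], np.zeros(K)])
    U, _ = scipy_nnls(A, b)
    Z_out = _time_basis_matrix(np.arange(K + 1) * TAU, K, T)[:, 1:]
    np.testing.assert_allclose(result.mean_curve, Z_out @ U, atol=1e-8)


def test_refinement_stability_in_time_discretization(point_system):
    """Mean curves stabilize as the time discretization is refined: the m ->
    2m change is smaller than the m/2 -> m change."""
    q, _, tac, system = point_system
    K = system.K_steps
    noisy = tac + np.random.default_rng(8).normal(0, 0.01, len(tac))
    noisy[0] = 0.0
    measure = PopulationMeasure.point_mass(q.q1, q.q2)
    curves = {}
    for m in (24, 48, 96):
        s = build_population_system(measure, n=8, m=m, tau=TAU, K_steps=K)
        curves[m] = deconvolve(noisy, s, RegularizationWeights(1e-3, 1e-2)).mean_curve
    assert np.linalg.norm(curves[96] - curves[48]) < np.linalg.norm(curves[48] - curves[24])


def test_band_nesting_and_point_mass_collapse(prior, q_unit, noise25, small_cohort):
    chain = fit_posterior(prior, small_cohort, noise25, n=8, n_draws=800, burn_in=100, seed=6)
    test_ep = generate_episode(
        EpisodeDesign(peak_brac=0.4, pattern="steady", total_hours=8.0),
        q_unit, noise25, n=8, seed=17,
    )
    measure = build_population_measure(chain, 20, 20, prior.domain)
    system = build_population_system(measure, n=8, m=48, tau=TAU, K_steps=len(test_ep) - 1)
    result = deconvolve(test_ep.tac, system, RegularizationWeights(1e-3, 1e-2))
    res90 = credible_band(result, chain, level=0.90)
    lo90, hi90 = res90.band_lower.copy(), res90.band_upper.copy()
    res99 = credible_band(result, chain, level=0.99)
    assert np.all(res99.band_lower <= lo90 + 1e-12)
    assert np.all(res99.band_upper >= hi90 - 1e-12)
    assert np.all(lo90 <= res90.mean_curve + 1e-12)
    assert np.all(hi90 >= res90.mean_curve - 1e-12)

    # Point-mass posterior: band collapses onto the single curve.
    pm_chain = PosteriorChain(
        draws=np.tile([0.8, 1.1], (100, 1)), burn_in=0, acceptance_rate=0.4, seed=0, n=8
    )
    pm_measure = PopulationMeasure.point_mass(0.8, 1.1)
    pm_system = build_population_system(pm_measure, n=8, m=48, tau=TAU, K_steps=len(test_ep) - 1)
    pm_result = deconvolve(test_ep.tac, pm_system, RegularizationWeights(1e-3, 1e-2))
    pm_result = credible_band(pm_result, pm_chain, level=0.90)
    np.testing.assert_allclose(pm_result.band_lower, pm_result.mean_curve, atol=1e-12)
    np.testing.assert_allclose(pm_result.band_upper, pm_result.mean_curve, atol=1e-12)


def test_tune_regularization_single_candidate_and_corners(point_system, q_unit):
    q, brac, tac, system = point_system
    times = np.arange(len(tac)) * TAU
    from transdermal import DrinkingEpisode

    noisy = tac + np.random.default_rng(3).normal(0, 0.015, len(tac))
    noisy[0] = 0.0
    episode = DrinkingEpisode("train", times, brac, noisy)

    only = tune_regularization([episode], system, [(0.5, 0.5)])
    assert (only.r1, only.r2) == (0.5, 0.5)

    grid = [(a, b) for a in (1e-4, 1e-2, 1.0) for b in (1e-4, 1e-2, 1.0)]
    best = tune_regularization([episode], system, grid)

    def score(r):
        res = deconvolve(episode.tac, system, RegularizationWeights(*r))
        resim = resimulate_tac(res)
        return float(
            np.sum((res.mean_curve[:-1] - episode.brac[:-1]) ** 2)
            + np.sum((resim[1:] - episode.tac[1:]) ** 2)
        )

    best_score = score((best.r1, best.r2))
    for corner in [(1e-4, 1e-4), (1e-4, 1.0), (1.0, 1e-4), (1.0, 1.0)]:
        assert best_score <= score(corner) + 1e-12

    with pytest.raises(ValueError):
        tune_regularization([episode], system, [])
    with pytest.raises(ValueError):
        tune_regularization([], system, [(1.0, 1.0)])


def test_argument_validation(point_system):
    _, _, tac, system = point_system
    with pytest.raises(ValueError):
        deconvolve(tac[:-5], system, RegularizationWeights(1.0, 1.0))
    with pytest.raises(ValueError):
        RegularizationWeights(0.0, 1.0)
    with pytest.raises(ValueError):
        build_population_system(system.measure, n=8, m=0, tau=TAU, K_steps=10)
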