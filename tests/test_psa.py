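"""Monte Carlo PSA, CEAC, CE plane and net monetary benefit."""

import math

import numpy as np
import pytest
import scipy.stats

from rtcea.psa import (
    PSASample,
    ce_plane_quadrants,
    ceac,
    default_wtp_grid,
    mean_nmb,
    nmb,
    run_psa,
)
from rtcea.reference import distribution_params
from rtcea.uncertainty import DistributionParams


def _toy_params(label, cost_mean, cost_sd, qaly_mean, qaly_sd):
    return DistributionParams.from_moments(label, cost_mean, cost_sd, qaly_mean, qaly_sd)


def _manual_sample(costs, qalys):
    labels = tuple(costs)
    R = len(next(iter(costs.values())))
    return PSASample(
        strategies=labels,
        costs={k: np.asarray(v, float) for k, v in costs.items()},
        qalys={k: np.asarray(v, float) for k, v in qalys.items()},
        n_iterations=R,
        seed=None,
    )


def test_nmb_hand_arithmetic():
    assert nmb(0.5, 10_000, 30_000) == 5_000
    assert nmb(0.7, 123.0, 0.0) == -123.0
    assert nmb(0.4936, 9024.23, 30_000) == pytest.approx(30_000 * 0.4936 - 9024.23)


def test_run_psa_deterministic_and_substream_independent():
    params = distribution_params()
    a = run_psa(params, n_iterations=500, seed=11)
    b = run_psa(params, n_iterations=500, seed=11)
    for s in a.strategies:
        assert np.array_equal(a.costs[s], b.costs[s])
        assert np.array_equal(a.qalys[s], b.qalys[s])
    # dropping a strategy leaves the others' draws untouched
    subset = {k: v for k, v in params.items() if k != "2D"}
    c = run_psa(subset, n_iterations=500, seed=11)
    for s in c.strategies:
        assert np.array_equal(a.costs[s], c.costs[s])


def test_run_psa_single_iteration_and_validation():
    params = distribution_params()
    s = run_psa(params, n_iterations=1, seed=0)
    assert s.n_iterations == 1
    with pytest.raises(ValueError):
        run_psa(params, n_iterations=0)
    with pytest.raises(ValueError):
        run_psa({}, n_iterations=10)


def test_psa_sample_means_match_analytic_moments():
    params = distribution_params()
    R = 100_000
    sample = run_psa(params, n_iterations=R, seed=3)
    for label, p in params.items():
        g = scipy.stats.gamma(a=p.gamma_k, scale=p.gamma_theta)
        b = scipy.stats.beta(p.beta_alpha, p.beta_beta)
        assert sample.costs[label].mean() == pytest.approx(
            g.mean(), abs=3 * g.std() / math.sqrt(R)
        ), label
        assert sample.qalys[label].mean() == pytest.approx(
            b.mean(), abs=3 * b.std() / math.sqrt(R)
        ), label


def test_ceac_probabilities_sum_to_one():
    sample = run_psa(distribution_params(), n_iterations=2_000, seed=5)
    result = ceac(sample)
    total = sum(result.probabilities.values())
    assert np.allclose(total, 1.0)
    assert result.wtp_grid[0] == 0.0 and result.wtp_grid[-1] == 60_000.0


def test_ceac_dominant_strategy_has_probability_one():
    sample = _manual_sample(
        {"a": [100.0] * 50, "b": [200.0] * 50},
        {"a": [0.6] * 50, "b": [0.5] * 50},
    )
    result = ceac(sample, wtp_grid=[0, 10_000, 50_000])
    assert np.all(result.probabilities["a"] == 1.0)
    assert np.all(result.probabilities["b"] == 0.0)


def test_ceac_ties_broken_deterministically():
    sample = _manual_sample(
        {"a": [100.0] * 10, "b": [100.0] * 10},
        {"a": [0.5] * 10, "b": [0.5] * 10},
    )
    result = ceac(sample, wtp_grid=[0, 30_000])
    assert np.all(result.probabilities["a"] == 1.0)  # first label wins ties
    assert np.all(result.probabilities["b"] == 0.0)


def test_ceac_pairwise_matches_closed_form(rng):
    """Two normal-ish NMB clouds: P(NMB_a > NMB_b) has a closed form."""
    R = 100_000
    wtp = 30_000.0
    # constant QALYs, normal costs => NMB difference is normal
    mu_a, mu_b, sd = 1_000.0, 1_200.0, 300.0
    costs_a = rng.normal(mu_a, sd, R)
    costs_b = rng.normal(mu_b, sd, R)
    sample = _manual_sample(
        {"a": costs_a, "b": costs_b},
        {"a": np.full(R, 0.5), "b": np.full(R, 0.5)},
    )
    result = ceac(sample, wtp_grid=[wtp], mode="pairwise", comparator="b")
    expected = scipy.stats.norm.cdf((mu_b - mu_a) / (sd * math.sqrt(2)))
    se = math.sqrt(expected * (1 - expected) / R)
    assert result.probabilities["a"][0] == pytest.approx(expected, abs=3 * se)


def test_ceac_pairwise_monotone_for_more_effective_strategy(rng):
    R = 20_000
    sample = _manual_sample(
        {"rt": rng.normal(1_500, 200, R), "bsc": rng.normal(1_000, 200, R)},
        {"rt": rng.beta(8, 4, R), "bsc": rng.beta(4, 8, R)},
    )
    result = ceac(sample, wtp_grid=np.arange(0, 50_001, 5_000.0),
                  mode="pairwise", comparator="bsc")
    assert np.all(np.diff(result.probabilities["rt"]) >= -1e-12)


def test_ceac_grid_validation():
    sample = _manual_sample({"a": [1.0]}, {"a": [0.5]})
    with pytest.raises(ValueError):
        ceac(sample, wtp_grid=[])
    with pytest.raises(ValueError):
        ceac(sample, wtp_grid=[1000.0, 500.0])
    with pytest.raises(ValueError):
        ceac(sample, wtp_grid=[0.0], mode="pairwise")  # no comparator


def test_monte_carlo_error_across_seeds_within_binomial_ci():
    params = distribution_params()
    R = 20_000
    grid = [20_000.0, 30_000.0, 50_000.0]
    p1 = ceac(run_psa(params, R, seed=1), wtp_grid=grid).probabilities
    p2 = ceac(run_psa(params, R, seed=2), wtp_grid=grid).probabilities
    z = 2.576  # 99%
    for s in p1:
        for a, b in zip(p1[s], p2[s]):
            se = math.sqrt(max(a * (1 - a), 1e-9) / R + max(b * (1 - b), 1e-9) / R)
            assert abs(a - b) <= z * se + 1e-9


def test_ce_plane_constructed_examples():
    R = 40
    comp_cost, comp_qaly = np.full(R, 1_000.0), np.full(R, 0.4)
    sample = _manual_sample(
        {"cheap_better": comp_cost - 100, "same": comp_cost.copy(), "C": comp_cost},
        {"cheap_better": comp_qaly + 0.1, "same": comp_qaly.copy(), "C": comp_qaly},
    )
    summary = ce_plane_quadrants(sample, "C")
    assert summary.fractions["cheap_better"]["SE"] == 1.0
    # identical strategy: both deltas on the boundary, assigned positive side
    assert summary.fractions["same"]["NE"] == 1.0
    for s in summary.fractions:
        assert sum(summary.fractions[s].values()) == pytest.approx(1.0)


def test_ce_plane_fixed_comparator_point():
    sample = _manual_sample(
        {"a": [900.0, 1_100.0]}, {"a": [0.5, 0.3]}
    )
    summary = ce_plane_quadrants(sample, "C", fixed_comparator=(1_000.0, 0.4))
    assert summary.fractions["a"]["SE"] == 0.5
    assert summary.fractions["a"]["NW"] == 0.5


def test_ce_plane_requires_known_comparator():
    sample = _manual_sample({"a": [1.0]}, {"a": [0.5]})
    with pytest.raises(ValueError):
        ce_plane_quadrants(sample, "missing")


def test_mean_nmb_consistent_with_sample_means():
    sample = _manual_sample(
        {"a": [100.0, 300.0]}, {"a": [0.2, 0.4]}
    )
    out = mean_nmb(sample, wtp=1_000.0)
    assert out["a"] == pytest.approx((0.2 * 1000 - 100 + 0.4 * 1000 - 300) / 2)


def test_nmb_affine_switch_point_at_icer():
    """Two deterministic strategies swap NMB ranking exactly at their ICER."""
    sample = _manual_sample(
        {"a": [1_000.0], "b": [2_000.0]}, {"a": [0.30], "b": [0.35]}
    )
    icer = (2_000 - 1_000) / (0.35 - 0.30)  # 20,000
    below = ceac(sample, wtp_grid=[icer - 1.0]).probabilities
    above = ceac(sample, wtp_grid=[icer + 1.0]).probabilities
    assert below["a"][0] == 1.0 and above["b"][0] == 1.0
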