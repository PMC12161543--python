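import math

import mpmath
import numpy as np
import pytest
import scipy.stats

from netroles.analytic import (
    AnalyticPrediction,
    DegreeDistribution,
    FixedPointSolution,
    core_and_root_fractions,
    empirical_distribution,
    er_closed_forms,
    glr,
    poisson_distribution,
    predict,
    predict_nD,
    predict_nDS,
    sf_closed_forms,
    sf_distribution,
    solve_fixed_point,
    upper_incomplete_gamma,
)
from netroles.generators import generate_er
from netroles.graph_io import DirectedGraph
from netroles.matching import build_bipartite, hopcroft_karp
from netroles.roles import classify, role_fractions

from conftest import random_digraph


class TestUpperIncompleteGamma:
    @pytest.mark.parametrize("s", [-3.7, -2.0, -1.5, -0.25, 0.0, 0.5, 3.0])
    @pytest.mark.parametrize("x", [0.05, 0.4, 1.0, 2.5, 6.0])
    def test_against_mpmath(self, s, x):
        ours = upper_incomplete_gamma(s, x)
        ref = float(mpmath.gammainc(s, x, mpmath.inf))
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-14)

    def test_positive_s_at_zero_is_gamma(self):
        assert upper_incomplete_gamma(2.5, 0.0) == pytest.approx(math.gamma(2.5))

    def test_divergent_cases_rejected(self):
        with pytest.raises(ValueError):
            upper_incomplete_gamma(-1.0, 0.0)
        with pytest.raises(ValueError):
            upper_incomplete_gamma(1.0, -0.5)


class TestDistributions:
    def test_empirical_star(self, star_graph):
        d = empirical_distribution(star_graph)
        assert d.p_out[0] == pytest.approx(2 / 3)
        assert d.p_out[2] == pytest.approx(1 / 3)
        assert d.p_in[0] == pytest.approx(1 / 3)
        assert d.p_in[1] == pytest.approx(2 / 3)
        assert d.mean_k == pytest.approx(2 / 3)
        d.validate()

    def test_empirical_cycle_point_mass(self, cycle3):
        d = empirical_distribution(cycle3)
        assert d.p_in.tolist() == [0.0, 1.0]
        assert d.p_out.tolist() == [0.0, 1.0]

    def test_empirical_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            empirical_distribution(DirectedGraph())

    @pytest.mark.parametrize("mean_k", [0.5, 2.0, 8.0])
    def test_poisson_matches_scipy(self, mean_k):
        d = poisson_distribution(mean_k)
        k = np.arange(len(d.p_in))
        ref = scipy.stats.poisson.pmf(k, mean_k)
        assert np.allclose(d.p_in, ref / ref.sum(), atol=1e-12)
        d.validate()

    @pytest.mark.parametrize("gamma", [2.5, 3.0, 4.0])
    @pytest.mark.parametrize("mean_k", [1.0, 4.0])
    def test_sf_normalized(self, mean_k, gamma):
        d = sf_distribution(mean_k, gamma)
        assert d.p_in.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("gamma", [3.0, 4.0])
    def test_sf_mean_close(self, gamma):
        d = sf_distribution(4.0, gamma, k_max=2000)
        mean = float(np.arange(len(d.p_in)) @ d.p_in) / d.p_in.sum()
        assert mean == pytest.approx(4.0, rel=0.01)

    def test_sf_raw_mass_sums_to_one(self):
        # the un-renormalized closed form is itself a probability mass function
        d = sf_distribution(2.0, 3.0, k_max=5000, renormalize=False)
        assert d.p_in.sum() == pytest.approx(1.0, abs=1e-6)

    def test_sf_tail_exponent(self):
        gamma = 3.0
        d = sf_distribution(2.0, gamma, k_max=600, renormalize=False)
        ratio = d.p_in[501] / d.p_in[500]
        assert math.log(ratio) == pytest.approx(gamma * math.log(500 / 501), rel=0.02)

    def test_sf_requires_gamma_above_two(self):
        with pytest.raises(ValueError, match="gamma"):
            sf_distribution(2.0, 2.0)


class TestFixedPoint:
    def test_symmetric_distribution_symmetric_solution(self):
        fp = solve_fixed_point(poisson_distribution(3.0))
        assert fp.alpha_plus == pytest.approx(fp.alpha_minus, abs=1e-10)
        assert fp.beta_plus == pytest.approx(fp.beta_minus, abs=1e-10)
        assert fp.residual < 1e-12

    def test_probabilities_in_unit_interval(self):
        for mean_k in (0.3, 1.0, 2.7, 6.0):
            fp = solve_fixed_point(poisson_distribution(mean_k))
            assert all(0.0 <= v <= 1.0 for v in fp.as_tuple())

    def test_isolated_limit_predicts_all_drivers(self):
        pred, _ = predict(poisson_distribution(1e-6))
        assert pred.n_D > 0.999

    def test_zero_mean_returns_limit_solution(self):
        fp = solve_fixed_point(poisson_distribution(0.0))
        assert fp.as_tuple() == (1.0, 1.0, 0.0, 0.0)

    def test_dense_network_few_drivers(self):
        pred, _ = predict(poisson_distribution(8.0))
        assert pred.n_D < 0.05

    def test_tol_validation(self):
        with pytest.raises(ValueError):
            solve_fixed_point(poisson_distribution(1.0), tol=0.0)

    def test_asymmetric_sides_solved_independently(self):
        # in-degrees concentrated, out-degrees spread: sides must differ
        p_in = np.array([0.0, 1.0])
        p_out = np.array([0.5, 0.0, 0.5])
        d = DegreeDistribution(p_in=p_in, p_out=p_out, mean_k=1.0)
        fp = solve_fixed_point(d)
        assert abs(fp.alpha_plus - fp.alpha_minus) > 1e-3


class TestCoreRootAndPredictions:
    def test_point_mass_at_zero(self):
        d = DegreeDistribution(
            p_in=np.array([1.0]), p_out=np.array([1.0]), mean_k=0.0
        )
        fp = solve_fixed_point(d)
        pred = core_and_root_fractions(d, fp)
        assert pred.nc_plus == pred.nc_minus == pred.n_r == 0.0
        assert predict_nD(pred) == 1.0

    def test_predict_nd_saturation(self):
        assert predict_nD(AnalyticPrediction(0.0, 0.0, 1.0)) == 0.0
        assert predict_nD(AnalyticPrediction(0.0, 0.0, 0.0)) == 1.0

    def test_subcritical_core_vanishes(self):
        # below the core-percolation threshold the analytic core is ~0 ...
        d = poisson_distribution(2.0)
        pred = core_and_root_fractions(d, solve_fixed_point(d))
        assert pred.nc_plus < 1e-3 and pred.nc_minus < 1e-3
        # ... and GLR on an actual ER(10^4, <k>=2) instance confirms it
        g = generate_er(10_000, 20_000, seed=0)
        res = glr(build_bipartite(g))
        assert len(res.core) / (2 * g.N) < 0.01

    def test_supercritical_core_present(self):
        d = poisson_distribution(4.0)
        pred = core_and_root_fractions(d, solve_fixed_point(d))
        assert min(pred.nc_plus, pred.nc_minus) > 0.05

    def test_predict_nds_all_isolated(self):
        d = DegreeDistribution(
            p_in=np.array([1.0]), p_out=np.array([1.0]), mean_k=0.0
        )
        assert predict_nDS(d) == 1.0

    @pytest.mark.parametrize("mean_k", [0.5, 1.0, 2.0, 4.0, 8.0])
    def test_poisson_ds_identity(self, mean_k):
        # generic P(0)/P(1) estimate collapses to exp(-2k)(2k+1)
        got = predict_nDS(poisson_distribution(mean_k))
        assert got == pytest.approx(
            math.exp(-2 * mean_k) * (2 * mean_k + 1), abs=1e-10
        )

    def test_poisson_unit_mean_frozen_value(self):
        assert predict_nDS(poisson_distribution(1.0)) == pytest.approx(
            3 * math.exp(-2), abs=1e-10
        )

    def test_accounting_identity_closes_n_o(self):
        pred, _ = predict(poisson_distribution(2.0))
        assert pred.n_O == pytest.approx(1 - 2 * pred.n_D + pred.n_DS, abs=1e-12)


class TestClosedForms:
    def test_er_zero_mean(self):
        fp = solve_fixed_point(poisson_distribution(0.0))
        n_ds, n_o = er_closed_forms(0.0, fp)
        assert n_ds == 1.0 and n_o == 0.0

    def test_er_unit_mean_frozen_value(self):
        fp = solve_fixed_point(poisson_distribution(1.0))
        n_ds, _ = er_closed_forms(1.0, fp)
        assert n_ds == pytest.approx(3 * math.exp(-2), abs=1e-12)

    def test_er_rejects_asymmetric_fixed_point(self):
        fp = FixedPointSolution(0.2, 0.6, 0.3, 0.3)
        with pytest.raises(ValueError, match="symmetric"):
            er_closed_forms(1.0, fp)

    @pytest.mark.parametrize("gamma", [2.5, 3.0, 4.0])
    @pytest.mark.parametrize("mean_k", [1.0, 2.0, 5.0])
    def test_sf_nds_matches_generic_estimate(self, mean_k, gamma):
        d = sf_distribution(mean_k, gamma, renormalize=False)
        fp = solve_fixed_point(d, check_alternative_init=False)
        n_ds, _ = sf_closed_forms(mean_k, gamma, fp)
        assert n_ds == pytest.approx(predict_nDS(d), abs=1e-10)

    def test_sf_nds_monotone_in_mean_degree(self):
        vals = [sf_closed_forms(k, 3.0, solve_fixed_point(sf_distribution(k, 3.0)))[0]
                for k in (1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_sf_nds_monotone_in_gamma(self):
        vals = [sf_closed_forms(2.0, g, solve_fixed_point(sf_distribution(2.0, g)))[0]
                for g in (2.5, 3.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestGLR:
    def test_star_removes_leaf_and_root(self, star_graph):
        res = glr(build_bipartite(star_graph))
        assert res.matching.size == 1
        assert res.matching.edges == {("x1^l", "x2^r")}
        assert res.roots == {"x1^l"}
        assert res.core == frozenset()

    def test_empty(self):
        res = glr(build_bipartite(DirectedGraph()))
        assert res.matching.size == 0
        assert not res.roots and not res.core

    def test_four_cycle_is_all_core(self):
        g = DirectedGraph([("u", "u"), ("u", "v"), ("v", "u"), ("v", "v")])
        res = glr(build_bipartite(g))
        assert res.matching.size == 0
        assert res.core == {"u^l", "u^r", "v^l", "v^r"}

    def test_matching_bounded_by_maximum(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            g = random_digraph(rng, int(rng.integers(2, 30)), p=0.08)
            rep = build_bipartite(g)
            res = glr(rep)
            hk = hopcroft_karp(rep).size
            assert res.matching.size <= hk
            if not res.core:
                assert res.matching.size == hk

    def test_sparse_er_core_free_glr_is_maximum(self):
        g = generate_er(2000, 2000, seed=1)  # <k>=1, far below threshold
        rep = build_bipartite(g)
        res = glr(rep)
        assert not res.core
        assert res.matching.size == hopcroft_karp(rep).size


def test_theory_matches_simulation_quick():
    # desk-scale version of the ensemble agreement (full scale in acceptance)
    pred, _ = predict(poisson_distribution(1.0))
    sim = np.mean([
        role_fractions(classify(generate_er(5000, 5000, seed=s))).n_D
        for s in range(3)
    ])
    assert sim == pytest.approx(pred.n_D, abs=0.02)
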