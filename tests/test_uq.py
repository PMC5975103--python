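"""Collocation quadrature, Lagrange surrogate, PCM moments, Monte Carlo."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ciuq
from ciuq.errors import DomainError
from ciuq.uq import propagate_pcm

STD = ciuq.UncertainParameter("x", 0.0, 1.0)


def normal_moment(k: int, mu: float, sigma: float) -> float:
    """E[X^k] for X ~ N(mu, sigma^2), by the binomial/double-factorial formula."""
    total = 0.0
    for j in range(k + 1):
        if (k - j) % 2 == 0:
            total += (
                math.comb(k, j)
                * mu**j
                * sigma ** (k - j)
                * (math.factorial(k - j) // (2 ** ((k - j) // 2) * math.factorial((k - j) // 2)))
            )
    return total


class TestHermiteCollocation:
    def test_single_point_is_mean(self):
        p = ciuq.UncertainParameter("d", 27.0, 0.5)
        nodes, w = ciuq.hermite_collocation(p, 1)
        assert nodes.tolist() == [27.0] and w.tolist() == [1.0]

    def test_three_point_rule(self):
        p = ciuq.UncertainParameter("d", 2.0, 3.0)
        nodes, w = ciuq.hermite_collocation(p, 3)
        np.testing.assert_allclose(nodes, [2 - 3 * np.sqrt(3), 2.0, 2 + 3 * np.sqrt(3)], rtol=1e-12)
        np.testing.assert_allclose(w, [1 / 6, 2 / 3, 1 / 6], rtol=1e-12)

    @pytest.mark.parametrize("npoints", range(1, 9))
    def test_weights_sum_to_one(self, npoints):
        _, w = ciuq.hermite_collocation(STD, npoints)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("npoints", [2, 3, 4])
    def test_moment_matching(self, npoints):
        """Quadrature integrates x^k exactly for k <= 2 npoints - 1."""
        p = ciuq.UncertainParameter("d", 1.5, 0.7)
        nodes, w = ciuq.hermite_collocation(p, npoints)
        for k in range(2 * npoints):
            assert np.dot(w, nodes**k) == pytest.approx(
                normal_moment(k, 1.5, 0.7), rel=1e-10, abs=1e-10
            )

    def test_truncated_parameter_rejected(self):
        p = ciuq.UncertainParameter("w", 0.0, 1.0, truncation_sd=3.0)
        with pytest.raises(DomainError, match="Monte Carlo"):
            ciuq.hermite_collocation(p, 3)


class TestTensorPlan:
    def test_two_params_order_2_gives_9_nodes(self):
        plan = ciuq.tensor_plan([STD, STD], 2)
        assert plan.n_nodes == 9

    def test_two_params_order_6_gives_49_nodes(self):
        plan = ciuq.tensor_plan([STD, STD], 6)
        assert plan.n_nodes == 49

    @pytest.mark.parametrize("order", [1, 3, 5])
    def test_one_param_gives_order_plus_one(self, order):
        assert ciuq.tensor_plan([STD], order).n_nodes == order + 1

    @pytest.mark.parametrize("p,order", [(1, 6), (2, 4), (3, 6)])
    def test_tensor_weights_normalized(self, p, order):
        plan = ciuq.tensor_plan([STD] * p, order)
        assert plan.tensor_weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestPCMMoments:
    def test_constant_model(self):
        plan = ciuq.tensor_plan([STD], 3)
        mean, var = ciuq.pcm_moments(np.full(plan.n_nodes, 4.2), plan)
        assert mean == pytest.approx(4.2) and var == pytest.approx(0.0, abs=1e-14)

    def test_linear_model_closed_form(self):
        p = ciuq.UncertainParameter("d", 27.0, 0.5)
        plan = ciuq.tensor_plan([p], 1)
        a, b = 3.0, -2.0
        vals = a * plan.tensor_nodes[:, 0] + b
        mean, var = ciuq.pcm_moments(vals, plan)
        assert mean == pytest.approx(a * 27.0 + b, abs=1e-12)
        assert var == pytest.approx(a**2 * 0.25, rel=1e-12)

    def test_quadratic_model_closed_form(self):
        plan = ciuq.tensor_plan([STD], 2)
        vals = plan.tensor_nodes[:, 0] ** 2
        mean, var = ciuq.pcm_moments(vals, plan)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert var == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("order", range(1, 7))
    def test_quadrature_exactness_up_to_2n_plus_1(self, order):
        """PCM mean of x^k matches the analytic normal moment, k <= 2n+1."""
        p = ciuq.UncertainParameter("x", 0.3, 1.2)
        plan = ciuq.tensor_plan([p], order)
        for k in range(2 * order + 2):
            mean, _ = ciuq.pcm_moments(plan.tensor_nodes[:, 0] ** k, plan)
            exact = normal_moment(k, 0.3, 1.2)
            assert mean == pytest.approx(exact, rel=1e-10, abs=1e-10)

    def test_value_count_mismatch(self):
        plan = ciuq.tensor_plan([STD, STD], 2)
        with pytest.raises(DomainError):
            ciuq.pcm_moments(np.zeros(8), plan)


class TestSurrogate:
    def test_exact_at_nodes(self):
        p1 = ciuq.UncertainParameter("a", 1.0, 2.0)
        p2 = ciuq.UncertainParameter("b", -1.0, 0.5)
        rng = np.random.default_rng(3)

        def model(x):
            return float(np.sin(x[0]) + x[1] ** 2)

        result, surr = propagate_pcm(model, [p1, p2], 3)
        plan = ciuq.tensor_plan([p1, p2], 3)
        for node in plan.tensor_nodes[rng.choice(plan.n_nodes, 5, replace=False)]:
            assert surr["value"](node) == pytest.approx(model(node), rel=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(coeffs=st.lists(st.floats(-3, 3), min_size=1, max_size=4))
    def test_polynomial_exactness(self, coeffs):
        """Degree-<=n polynomials are reproduced everywhere, not just at nodes."""
        order = 3
        p = ciuq.UncertainParameter("x", 0.5, 1.5)

        def model(x):
            return float(np.polyval(coeffs, x[0]))

        _, surr = propagate_pcm(model, [p], order)
        for x in np.linspace(0.5 - 3 * 1.5, 0.5 + 3 * 1.5, 20):
            assert surr["value"]([x]) == pytest.approx(model([x]), rel=1e-9, abs=1e-9)

    def test_extrapolation_warns(self):
        p = ciuq.UncertainParameter("x", 0.0, 1.0)
        _, surr = propagate_pcm(lambda x: float(x[0]), [p], 2)
        with pytest.warns(UserWarning, match="extrapolation"):
            val = surr["value"]([5.0])
        assert val == pytest.approx(5.0, rel=1e-9)


class TestMonteCarlo:
    def test_same_seed_identical(self):
        model = lambda x: {"y": float(x[0] ** 2 + x[1])}
        params = [STD, ciuq.UncertainParameter("z", 1.0, 0.1)]
        a = ciuq.run_mc(model, params, 50, seed=11)
        b = ciuq.run_mc(model, params, 50, seed=11)
        assert a.outputs == b.outputs

    def test_mean_within_clt_bound(self):
        res = ciuq.run_mc(lambda x: float(x[0]), [STD], 10_000, seed=5)
        assert abs(res.mean("value")) < 3 / np.sqrt(10_000)
        assert res.variance("value") == pytest.approx(1.0, rel=0.1)

    def test_truncation_respected(self):
        p = ciuq.UncertainParameter("w", 0.0, 1.0, truncation_sd=3.0)
        res = ciuq.run_mc(lambda x: float(x[0]), [p], 2000, seed=2)
        samples = res.samples["input_w"]
        assert samples.abs().max() <= 3.0

    def test_failed_runs_recorded_and_excluded(self):
        def flaky(x):
            if x[0] > 0.5:
                raise RuntimeError("boom")
            return float(x[0])

        res = ciuq.run_mc(flaky, [STD], 200, seed=9)
        assert res.n_failures > 0
        assert res.n_runs + res.n_failures == 200

    def test_needs_two_runs(self):
        with pytest.raises(DomainError):
            ciuq.run_mc(lambda x: 0.0, [STD], 1, seed=0)

    def test_pcm_mc_consistency_on_smooth_model(self):
        """PCM mean within 3 MC standard errors for a smooth test model."""
        p1 = ciuq.UncertainParameter("a", 0.0, 1.0)
        p2 = ciuq.UncertainParameter("b", 2.0, 0.3)
        model = lambda x: float(np.exp(0.3 * x[0]) + np.sin(x[1]))
        pcm, _ = propagate_pcm(model, [p1, p2], 4)
        mc = ciuq.run_mc(model, [p1, p2], 10_000, seed=17)
        se = mc.sd("value") / np.sqrt(mc.n_runs)
        assert abs(pcm.mean("value") - mc.mean("value")) <= 3 * se
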