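"""Unit tests for the model variants, switches and transformations."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from switchmap.model import (
    DimensionalParameters,
    DimensionlessParameters,
    SwitchSpec,
    ToyParameters,
    FullState,
    hill,
    nondimensionalize,
    reduce_rapid_equilibrium,
    rhs_full,
    rhs_reduced,
    rhs_scaled,
    rhs_toy,
)

HEAVISIDE = SwitchSpec(mode="heaviside")


def dimensional(**over):
    base = dict(alpha_hat=1.0, mu_hat=0.5, k_minus=1.0, k_plus_0=2.0,
                k_plus_delta=4.0, delta_hat=1.0, beta_hat=1.0, gamma_hat=0.5,
                pi_hat=1.0, D_hat=0.2, Theta1=2.0, Theta2=1.0, n=10, nu=10)
    base.update(over)
    return DimensionalParameters(**base)


class TestHill:
    @pytest.mark.parametrize("n", [2, 5, 10, 50])
    def test_half_activation_at_threshold(self, n):
        assert hill(1.7, 1.7, SwitchSpec("finite", n)) == pytest.approx(0.5)

    @pytest.mark.parametrize("spec", [SwitchSpec("finite", 5), HEAVISIDE])
    def test_zero_input(self, spec):
        assert hill(0.0, 1.0, spec) == 0.0

    def test_heaviside_values(self):
        assert hill(2.0, 1.0, HEAVISIDE) == 1.0
        assert hill(0.5, 1.0, HEAVISIDE) == 0.0
        # value at the threshold matches the finite-Hill limit there
        assert hill(1.0, 1.0, HEAVISIDE) == 0.5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill(-0.1, 1.0)
        with pytest.raises(ValueError):
            hill(1.0, 0.0)

    def test_pointwise_monotone_convergence_to_heaviside(self):
        xs = np.array([0.3, 0.8, 1.3, 4.0])
        theta = 1.0
        target = hill(xs, theta, HEAVISIDE)
        errs = np.array([
            np.abs(hill(xs, theta, SwitchSpec("finite", n)) - target)
            for n in np.logspace(0.5, 2.5, 12)
        ])
        assert np.all(np.diff(errs, axis=0) <= 1e-12)
        assert np.all(errs[-1] < 1e-6)


class TestHillProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(x=st.floats(0.0, 1e6), theta=st.floats(1e-3, 1e3),
           n=st.floats(1.5, 60.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_ordered_against_threshold(self, x, theta, n):
        v = hill(x, theta, SwitchSpec("finite", n))
        assert 0.0 <= v <= 1.0
        if x < theta:
            assert v < 0.5
        elif x > theta:
            assert v > 0.5

    @given(x=st.floats(1e-3, 1e3), theta=st.floats(1e-3, 1e3),
           n=st.floats(1.5, 60.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_argument(self, x, theta, n):
        spec = SwitchSpec("finite", n)
        assert hill(x, theta, spec) <= hill(x * 1.01, theta, spec) + 1e-15


class TestNondimensionalize:
    def test_binding_ratios(self):
        p = dimensional(k_plus_0=2.0, k_plus_delta=4.0, k_minus=1.0)
        q = nondimensionalize(p)
        assert p.K0 == 2.0 and p.K == 4.0
        assert q.kappa == pytest.approx(4.0 / 3.0)
        assert q.eta == pytest.approx(2.0)

    def test_mu_group(self):
        p = dimensional(mu_hat=1.0, delta_hat=1.0, k_plus_0=1.0, k_minus=1.0)
        q = nondimensionalize(p)
        assert q.mu == pytest.approx(2.0)   # mu_hat (1 + K0) / delta_hat, K0 = 1

    def test_no_induced_binding(self):
        q = nondimensionalize(dimensional(k_plus_delta=0.0))
        assert q.kappa == 0.0 and q.eta == 0.0

    def test_physical_sets_satisfy_eta_gt_kappa(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = np.exp(rng.uniform(-2, 2, 12))
            p = dimensional(**dict(zip(
                ("alpha_hat", "mu_hat", "k_minus", "k_plus_0", "k_plus_delta",
                 "delta_hat", "beta_hat", "gamma_hat", "pi_hat", "D_hat",
                 "Theta1", "Theta2"), vals)))
            q = nondimensionalize(p)
            assert q.eta > q.kappa

    def test_threshold_groups_roundtrip(self):
        p = dimensional()
        q = nondimensionalize(p)
        scale = p.delta_hat ** 2 / (p.alpha_hat * p.beta_hat * p.K0 * (1 + p.K0))
        assert q.theta1 == pytest.approx(p.Theta1 * scale)
        assert q.theta2 == pytest.approx(p.Theta2 * scale)


class TestRapidEquilibrium:
    def test_no_protein(self):
        p = dimensional()  # K0=2, K=4
        s = FullState(u1=1, u2=0.5, b1=0, b2=0, p1=0, p2=0)
        r = reduce_rapid_equilibrium(s, p)
        assert r.m1 == pytest.approx(3.0)       # u1 (1 + K0)

    def test_saturated_protein(self):
        p = dimensional()
        s = FullState(u1=1, u2=1, b1=0, b2=0, p1=1e9, p2=1e9)
        r = reduce_rapid_equilibrium(s, p)
        assert r.m1 == pytest.approx(7.0, rel=1e-6)   # u1 (1 + K0 + K)

    def test_zero_mrna(self):
        p = dimensional()
        s = FullState(u1=0, u2=0, b1=0, b2=0, p1=1, p2=1)
        assert reduce_rapid_equilibrium(s, p).m1 == 0.0


def scaled_params(**over):
    base = dict(theta1=1.4, theta2=0.9, mu=0.8, gamma=0.2, eta=2.3,
                kappa=2.5, pi=1.2, epsilon=0.1, n=10, nu=10)
    base.update(over)
    return DimensionlessParameters(**base)


class TestScaledRHS:
    def test_origin_production_only(self):
        d = rhs_scaled(np.zeros(4), scaled_params())
        assert np.allclose(d, [1.0, 1.0, 0.0, 0.0])

    def test_cell_swap_equivariance(self):
        rng = np.random.default_rng(1)
        p = scaled_params()
        for _ in range(25):
            y = rng.uniform(0, 3, 4)
            d = rhs_scaled(y, p)
            ds = rhs_scaled(y[[1, 0, 3, 2]], p)
            assert np.allclose(d[[1, 0, 3, 2]], ds)

    def test_heaviside_low_domain_fixed_point(self):
        # with all proteins below both thresholds the affine system has
        # fixed point M = 1/mu, P = 1/(mu pi)
        p = scaled_params(theta1=50.0, theta2=40.0)
        y = np.array([1 / p.mu, 1 / p.mu, 1 / (p.mu * p.pi), 1 / (p.mu * p.pi)])
        assert np.allclose(rhs_scaled(y, p, mode="heaviside"), 0.0, atol=1e-12)


class TestToyRHS:
    def test_heaviside_branch_roots(self):
        p = ToyParameters(b=0.5, theta=1.2, gamma=1.0, n=10)
        assert rhs_toy(p.b / p.gamma, p, HEAVISIDE) == pytest.approx(0.0)
        assert rhs_toy((p.b + 1) / p.gamma, p, HEAVISIDE) == pytest.approx(0.0)

    def test_zero_state(self):
        p = ToyParameters(b=0.7, theta=1.0, gamma=2.0, n=5)
        assert rhs_toy(0.0, p) == pytest.approx(p.b)


class TestModelConsistency:
    """The three model levels describe the same dynamics."""

    def test_full_zero_state(self):
        p = dimensional()
        d = rhs_full(np.zeros(6), p)
        assert np.allclose(d[:2], p.alpha_hat)
        assert np.allclose(d[2:], 0.0)

    def test_full_matches_reduced_in_fast_binding_limit(self):
        slow = dimensional()
        fast = dimensional(k_minus=slow.k_minus * 1e3,
                           k_plus_0=slow.k_plus_0 * 1e3,
                           k_plus_delta=slow.k_plus_delta * 1e3)
        y0 = np.array([0.4, 0.2, 0.1, 0.05, 1.2, 0.3])
        sol = solve_ivp(lambda t, y: rhs_full(y, fast), (0, 400), y0,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        u1, u2, b1, b2, p1, p2 = sol.y[:, -1]
        m = np.array([u1 + b1, u2 + b2, p1, p2])
        res = rhs_reduced(m, slow)
        assert np.max(np.abs(res)) < 5e-3

    def test_reduced_trajectory_maps_onto_scaled_trajectory(self):
        p = dimensional()
        q = nondimensionalize(p)
        K0 = p.K0
        # rescalings: t = delta tau / (1+K0); M = delta m / (alpha (1+K0));
        # P = delta^2 p / (alpha beta K0 (1+K0))
        m_scale = p.delta_hat / (p.alpha_hat * (1 + K0))
        p_scale = p.delta_hat ** 2 / (p.alpha_hat * p.beta_hat * K0 * (1 + K0))
        t_scale = p.delta_hat / (1 + K0)
        y0 = np.array([0.5, 0.1, 0.8, 0.2])
        T = 30.0
        sol_red = solve_ivp(lambda t, y: rhs_reduced(y, p), (0, T / t_scale), y0,
                            method="LSODA", rtol=1e-10, atol=1e-12,
                            t_eval=np.linspace(0, T / t_scale, 7))
        Y0 = np.array([y0[0] * m_scale, y0[1] * m_scale,
                       y0[2] * p_scale, y0[3] * p_scale])
        sol_sc = solve_ivp(lambda t, y: rhs_scaled(y, q), (0, T), Y0,
                           method="LSODA", rtol=1e-10, atol=1e-12,
                           t_eval=np.linspace(0, T, 7))
        mapped = sol_red.y * np.array([[m_scale], [m_scale], [p_scale], [p_scale]])
        assert np.allclose(mapped, sol_sc.y, rtol=1e-5, atol=1e-8)


class TestParameterValidation:
    def test_rejects_equal_thresholds(self):
        with pytest.raises(ValueError):
            scaled_params(theta1=1.0, theta2=1.0)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            scaled_params(mu=0.0)

    def test_rejects_shallow_hill(self):
        with pytest.raises(ValueError):
            ToyParameters(b=1, theta=1, gamma=1, n=1.0)

    def test_json_roundtrip(self, tmp_path):
        q = scaled_params()
        q.to_json(tmp_path / "p.json")
        assert DimensionlessParameters.from_json(tmp_path / "p.json") == q
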