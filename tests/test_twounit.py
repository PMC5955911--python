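"""Fixed points, stability, bifurcations of the reduced 2-unit model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megamap.reduction import ReducedParams, balanced_input_strength
from megamap.twounit import (
    DynamicsType,
    amplification,
    bifurcation_diagram,
    both_active_eigenvalues,
    both_active_stable,
    classify_dynamics,
    detect_hysteresis,
    enumerate_fixed_points,
    g_function,
    integrate_two_unit,
    m_unit_rhs,
    two_unit_rhs,
)

RP_WTA = ReducedParams.balanced(1.2, 5.3, 0.9, q=0.1)  # b_pk_hat = 0.33
RP_COMB = ReducedParams.balanced(1.2, 5.3, 0.9, q=0.3)


def random_valid_params(rng):
    """Random parameter set satisfying all four model constraints."""
    while True:
        theta = rng.uniform(0.5, 0.95)
        w_I_hat = rng.uniform(2.0, 8.0)
        room = w_I_hat * (1.0 - theta)
        w0 = 1.0 + rng.uniform(0.05, 0.95) * room
        b_pk = balanced_input_strength(w0, w_I_hat, theta)
        if not 0.0 < b_pk < 1.0:
            continue
        q = rng.uniform(0.0, 0.98 * room)
        return ReducedParams(w0, q, w_I_hat, theta, b_pk)


class TestRhs:
    def test_origin_without_input_is_fixed(self):
        assert np.allclose(two_unit_rhs(np.zeros(2), RP_WTA, np.zeros(2)), 0.0)

    def test_swap_symmetry(self):
        u = np.array([0.7, -0.2])
        b = np.array([0.3, 0.1])
        lhs = two_unit_rhs(u[::-1], RP_WTA, b[::-1])
        rhs_ = two_unit_rhs(u, RP_WTA, b)[::-1]
        assert np.allclose(lhs, rhs_)

    def test_zero_at_type_iv_fixed_point(self):
        fps = enumerate_fixed_points(RP_COMB, 0.165, 0.165)
        (fp,) = [f for f in fps if f.active == (True, True)]
        du = two_unit_rhs(np.array(fp.u), RP_COMB, np.array([0.165, 0.165]))
        assert np.max(np.abs(du)) < 1e-10


class TestFixedPoints:
    def test_training_input_fixed_point(self):
        # b = (b_pk, 0): the embedded pattern (1, q - w_I_hat(1-theta)) is the
        # unique stable fixed point
        fps = enumerate_fixed_points(RP_WTA, RP_WTA.b_pk_hat, 0.0)
        stable = [f for f in fps if f.stable]
        assert len(stable) == 1
        fp = stable[0]
        assert fp.active == (True, False)
        assert fp.u[0] == pytest.approx(1.0, abs=1e-12)
        assert fp.u[1] == pytest.approx(0.1 - 5.3 * 0.1, abs=1e-12)

    def test_symmetric_combinatorial_fixed_point(self):
        fps = enumerate_fixed_points(RP_COMB, 0.165, 0.165)
        stable = [f for f in fps if f.stable]
        assert len(stable) == 1
        fp = stable[0]
        assert fp.active == (True, True)
        # direct linear solve: u(1 - w0 - q + 2 w_I_hat) = w_I_hat·theta + b
        u_exp = (5.3 * 0.9 + 0.165) / (1.0 - 1.2 - 0.3 + 2 * 5.3)
        assert fp.u[0] == pytest.approx(u_exp, abs=1e-12)
        assert fp.u[1] == pytest.approx(u_exp, abs=1e-12)
        # verified by simulation
        u_fin, ok = integrate_two_unit(
            np.array([0.9, 0.1]), RP_COMB, np.array([0.165, 0.165]), tol=1e-12
        )
        assert ok and np.allclose(u_fin, [u_exp, u_exp], atol=1e-8)

    def test_wta_equal_inputs_bistable(self):
        fps = enumerate_fixed_points(RP_WTA, 0.165, 0.165)
        stable = [f for f in fps if f.stable]
        assert sorted(f.active for f in stable) == [(False, True), (True, False)]
        both = [f for f in fps if f.active == (True, True)]
        assert all(not f.stable for f in both)

    def test_existence_predicates_match_enumeration(self):
        """The closed-form existence conditions for single-unit and
        both-active fixed points agree exactly with the linear case
        analysis over a parameter grid."""
        rp0 = RP_WTA
        b_pk = rp0.b_pk_hat
        qs = np.linspace(0.0, rp0.q_max * 0.98, 50)
        dbs = np.linspace(-b_pk, b_pk, 50)
        for q in qs:
            rp = ReducedParams(1.2, float(q), 5.3, 0.9, b_pk)
            for db in dbs:
                b1, b2 = (b_pk + db) / 2.0, (b_pk - db) / 2.0
                hi, lo = max(b1, b2), min(b1, b2)
                fps = enumerate_fixed_points(rp, b1, b2)
                w0m1 = rp.w0 - 1.0
                gain = rp.w_I_hat - w0m1
                # unit with the stronger input active alone
                ex_strong = q < w0m1 + (hi - lo) * gain / (rp.w_I_hat * rp.theta + hi)
                # unit with the weaker input active alone
                ex_weak = q < w0m1 - (hi - lo) * gain / (rp.w_I_hat * rp.theta + lo)
                # both active (stable branch exists iff w0 - q < 1)
                ex_both = (rp.w0 - rp.q < 1.0) and (
                    q > w0m1 + (hi - lo) * gain / (rp.w_I_hat * rp.theta + hi)
                )
                strong_idx = 0 if b1 >= b2 else 1
                found_strong = any(
                    f.active[strong_idx] and f.n_active == 1 for f in fps
                )
                found_weak = any(
                    f.active[1 - strong_idx] and f.n_active == 1 for f in fps
                )
                found_both_stable = any(
                    f.n_active == 2 and f.stable for f in fps
                )
                if abs(db) > 1e-9:  # skip exact ties of the weak predicate
                    assert found_strong == ex_strong
                    assert found_weak == ex_weak
                assert found_both_stable == ex_both

    def test_single_unit_points_always_stable(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            rp = random_valid_params(rng)
            b1, b2 = rng.uniform(0.0, rp.b_pk_hat, size=2)
            for fp in enumerate_fixed_points(rp, b1, b2):
                if fp.n_active == 1:
                    assert fp.stable
                if fp.n_active == 2 and fp.inh_active:
                    assert fp.stable == (rp.w0 - rp.q < 1.0)
                assert fp.n_active >= 1 or not fp.stable

    def test_both_active_unique_when_it_exists(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            rp = random_valid_params(rng)
            b1, b2 = rng.uniform(0.0, rp.b_pk_hat, size=2)
            both = [
                f for f in enumerate_fixed_points(rp, b1, b2)
                if f.n_active == 2 and f.stable
            ]
            assert len(both) <= 1


class TestModeDichotomy:
    def test_stability_rule(self):
        assert both_active_stable(ReducedParams.balanced(1.2, 5.3, 0.9, 0.3))
        assert not both_active_stable(ReducedParams.balanced(1.2, 5.3, 0.9, 0.1))
        with pytest.raises(ArithmeticError):
            both_active_stable(ReducedParams.balanced(1.2, 5.3, 0.9, 0.2))

    def test_eigenvalues(self):
        lam1, lam2 = both_active_eigenvalues(RP_COMB)
        assert lam1 == pytest.approx((1.2 - 0.3 - 1.0) / 10.0)
        assert lam2 == pytest.approx((1.2 + 0.3 - 2 * 5.3 - 1.0) / 10.0)

    def test_mode_by_simulation_at_random_draws(self):
        """With equal inputs, WTA ⇔ w0 - q > 1: simulation from an asymmetric
        start suppresses one unit iff the constraint holds."""
        rng = np.random.default_rng(11)
        done = 0
        while done < 20:
            rp = random_valid_params(rng)
            if abs(rp.w0 - rp.q - 1.0) < 0.05:
                continue  # skip near-marginal draws (slow transients)
            b = np.full(2, rp.b_pk_hat / 2.0)
            u_fin, ok = integrate_two_unit(np.array([1.0, 0.2]), rp, b, T=6000.0)
            assert ok
            both_active = bool(np.all(u_fin > 0))
            assert both_active == (rp.w0 - rp.q < 1.0)
            done += 1


class TestAmplification:
    def test_zero_difference(self):
        assert amplification(RP_COMB, 0.2, 0.2) == 0.0

    def test_printed_example(self):
        assert amplification(RP_COMB, 0.19, 0.14) == pytest.approx(0.5)

    def test_wta_regime_rejected(self):
        with pytest.raises(ValueError):
            amplification(RP_WTA, 0.2, 0.1)

    def test_matches_enumerated_fixed_point(self):
        rng = np.random.default_rng(13)
        done = 0
        while done < 20:
            rp = random_valid_params(rng)
            if rp.w0 - rp.q >= 1.0:
                continue
            db = rng.uniform(-rp.b_pk_hat, rp.b_pk_hat)
            b1, b2 = (rp.b_pk_hat + db) / 2.0, (rp.b_pk_hat - db) / 2.0
            both = [
                f for f in enumerate_fixed_points(rp, b1, b2)
                if f.n_active == 2 and f.stable
            ]
            if not both:
                continue
            fp = both[0]
            assert fp.u[0] - fp.u[1] == pytest.approx(
                amplification(rp, b1, b2), abs=1e-8
            )
            done += 1


class TestGFunction:
    def test_zero_at_zero_for_any_valid_parameters(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            rp = random_valid_params(rng)
            assert g_function(0.0, rp) == 0.0

    def test_printed_value(self):
        assert g_function(-0.33, RP_WTA) == pytest.approx(-0.3528, abs=1e-4)

    @given(st.floats(-0.32, 0.32), st.floats(-0.32, 0.32))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing(self, x1, x2):
        if abs(x1 - x2) < 1e-12:
            return
        lo, hi = sorted([x1, x2])
        assert g_function(lo, RP_WTA) < g_function(hi, RP_WTA)

    def test_near_linear_slope_as_theta_tends_to_one(self):
        # w0 must stay within 1 + w_I_hat(1-theta) for the balance to hold
        w0, w_I_hat, theta = 1.003, 5.3, 0.999
        rp = ReducedParams.balanced(w0, w_I_hat, theta, q=0.001)
        h = rp.b_pk_hat / 2.0
        slope = (g_function(h, rp) - g_function(-h, rp)) / (2 * h)
        expected = (w_I_hat - (w0 - 1.0)) / (w_I_hat - (w0 - 1.0) / 2.0)
        assert slope == pytest.approx(expected, rel=0.01)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            g_function(0.5, RP_WTA)


class TestClassification:
    @pytest.mark.parametrize(
        "q, db, expected",
        [
            (0.1, 0.0, DynamicsType.III),
            (0.3, 0.0, DynamicsType.IV),
            (0.1, 0.33, DynamicsType.I),
            (0.1, -0.33, DynamicsType.II),
        ],
    )
    def test_examples(self, q, db, expected):
        rp = ReducedParams.balanced(1.2, 5.3, 0.9, q=q)
        assert classify_dynamics(rp, db) is expected

    def test_boundary_is_marginal(self):
        rp = ReducedParams.balanced(1.2, 5.3, 0.9, q=0.2)
        assert classify_dynamics(rp, 0.0) is None

    def test_domain_error(self):
        with pytest.raises(ValueError):
            classify_dynamics(RP_WTA, 0.5)

    def test_hysteresis_matches_type_and_enumeration(self):
        b = RP_WTA.b_pk_hat / 2.0
        assert detect_hysteresis(RP_WTA, b, b)
        assert not detect_hysteresis(RP_COMB, b, b)
        # Type I: unique equilibrium
        rp = ReducedParams.balanced(1.2, 5.3, 0.9, q=0.1)
        assert not detect_hysteresis(rp, rp.b_pk_hat, 0.0)
        # consistency with the number of stable single-unit fixed points
        n_single = sum(
            f.n_active == 1 and f.stable
            for f in enumerate_fixed_points(RP_WTA, b, b)
        )
        assert (n_single == 2) == detect_hysteresis(RP_WTA, b, b)


class TestBifurcationDiagram:
    def test_analytic_regions_ordered(self):
        bd = bifurcation_diagram(RP_WTA, 21, 21, simulate=False)
        df = bd.table.dropna(subset=["type"])
        # Type III at low q, IV at high q, I on the right, II on the left
        assert (
            df[df["type"] == DynamicsType.III]["q"].max()
            < df[df["type"] == DynamicsType.IV]["q"].min()
        )
        assert df[df["type"] == DynamicsType.I]["db"].min() > 0
        assert df[df["type"] == DynamicsType.II]["db"].max() < 0
        # no Type IV below the analytic lower bound of its region
        g_pk = g_function(RP_WTA.b_pk_hat, RP_WTA)
        q_min_iv = (RP_WTA.w0 - 1.0) + g_function(0.0, RP_WTA)
        assert df[df["type"] == DynamicsType.IV]["q"].min() >= q_min_iv
        assert bd.boundary_upper.max() <= (RP_WTA.w0 - 1.0) + g_pk + 1e-12

    def test_small_theta_boundaries_curved(self):
        rp = ReducedParams.balanced(1.1, 1.0, 0.5, q=0.1)
        bd = bifurcation_diagram(rp, 5, 5, simulate=False)
        x, y = bd.boundary_db, bd.boundary_upper
        # compare against the straight line through the endpoints
        line = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        curvature = np.max(np.abs(y - line)) / (y.max() - y.min())
        assert curvature > 0.02

    def test_simulation_agrees_with_analysis(self):
        bd = bifurcation_diagram(RP_WTA, 9, 9, simulate=True)
        assert bd.agreement >= 0.95


class TestMUnit:
    def test_reduces_to_two_unit_model(self):
        rng = np.random.default_rng(19)
        u = rng.normal(size=(5, 2))
        b = rng.uniform(0.0, 0.3, size=(5, 2))
        assert np.allclose(
            m_unit_rhs(u, RP_COMB, b), two_unit_rhs(u, RP_COMB, b), atol=1e-12
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        u = rng.normal(size=4)
        b = rng.uniform(0.0, 0.2, size=4)
        perm = rng.permutation(4)
        assert np.allclose(
            m_unit_rhs(u[perm], RP_COMB, b[perm]),
            m_unit_rhs(u, RP_COMB, b)[perm],
        )

    def test_symmetric_three_input_equilibrium(self):
        # combinatorial-regime parameters with three equal inputs settle on a
        # symmetric all-active state
        rp = RP_COMB
        b = np.full(3, rp.b_pk_hat / 3.0)
        u_fin, ok = integrate_two_unit(
            np.array([0.5, 0.4, 0.6]), rp, b, rhs=m_unit_rhs, tol=1e-10
        )
        assert ok
        assert np.all(u_fin > 0)
        assert np.max(np.abs(u_fin - u_fin.mean())) < 1e-6

    def test_m_lt_2_rejected(self):
        with pytest.raises(ValueError):
            m_unit_rhs(np.array([0.1]), RP_COMB, np.array([0.1]))
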