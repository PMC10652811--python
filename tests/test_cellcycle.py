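"""Multistage cell-cycle chain: structure, solvers, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from cycletrial.cellcycle import (
    CellCycleParams,
    SubphaseState,
    aggregate_phases,
    build_rate_matrix,
    growth_rate,
    initial_state,
    simulate_constant,
    simulate_timevarying,
    stationary_distribution,
)


def brute_force_matrix(m, la, lb, lg, lam_g1s):
    """Independent oracle: explicit enumeration of every transition."""
    n = 3 * m
    a = np.zeros((n, n))
    transitions = []
    for i in range(m - 1):  # within G1
        transitions.append((i, i + 1, la, 1.0))
    transitions.append((m - 1, m, lam_g1s, 1.0))  # G1_m -> S_1
    for i in range(m - 1):  # within S
        transitions.append((m + i, m + i + 1, lb, 1.0))
    transitions.append((2 * m - 1, 2 * m, lb, 1.0))  # S_m -> M_1
    for i in range(m - 1):  # within M
        transitions.append((2 * m + i, 2 * m + i + 1, lg, 1.0))
    transitions.append((n - 1, 0, lg, 2.0))  # division
    for src, dst, rate, mult in transitions:
        a[src, src] -= rate
        a[dst, src] += mult * rate
    return a


class TestRateMatrix:
    def test_m1_smallest_chain(self):
        p = CellCycleParams(m=1, lambda_alpha=1.0, lambda_beta=2.0, lambda_gamma=3.0)
        a = build_rate_matrix(p, 0.7)
        expected = np.array([[-0.7, 0.0, 6.0], [0.7, -2.0, 0.0], [0.0, 2.0, -3.0]])
        np.testing.assert_allclose(a, expected)

    @pytest.mark.parametrize("m", [1, 2, 5, 8])
    def test_column_sums_mass_bookkeeping(self, m):
        p = CellCycleParams(m=m, lambda_alpha=1.3, lambda_beta=2.1, lambda_gamma=3.7)
        a = build_rate_matrix(p, 0.9)
        sums = a.sum(axis=0)
        expected = np.zeros(3 * m)
        expected[-1] = 3.7  # net production from division in the M_m column
        np.testing.assert_allclose(sums, expected, atol=1e-12)

    def test_matches_brute_force_enumeration(self):
        a = build_rate_matrix(
            CellCycleParams(m=2, lambda_alpha=1.1, lambda_beta=2.3, lambda_gamma=3.5), 0.8
        )
        np.testing.assert_allclose(a, brute_force_matrix(2, 1.1, 2.3, 3.5, 0.8))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CellCycleParams(m=0, lambda_alpha=1, lambda_beta=1, lambda_gamma=1)
        with pytest.raises(ValueError):
            CellCycleParams(m=2, lambda_alpha=-1, lambda_beta=1, lambda_gamma=1)
        p = CellCycleParams(m=2, lambda_alpha=1, lambda_beta=1, lambda_gamma=1)
        with pytest.raises(ValueError):
            build_rate_matrix(p, -0.1)


class TestConstantDoseSolver:
    def test_identity_at_t0(self, small_params):
        x0 = initial_state(500.0, "synchronized", small_params, 1.0)
        out = simulate_constant(small_params, x0, 1.0, [0.0])
        np.testing.assert_allclose(out[0].counts, x0.counts)

    def test_log_total_slope_converges_to_dominant_eigenvalue(self, small_params):
        lam = 3.0
        x0 = initial_state(100.0, "synchronized", small_params, lam)
        states = simulate_constant(small_params, x0, lam, [0.0, 40.0, 41.0])
        slope = np.log(states[2].total) - np.log(states[1].total)
        rho = growth_rate(small_params, lam)
        assert slope == pytest.approx(rho, rel=1e-6)

    @pytest.mark.parametrize("m", [1, 2, 8])
    def test_matches_expm_and_adaptive_ode_oracles(self, m, rng):
        rates = rng.uniform(0.1, 5.0, size=4)
        p = CellCycleParams(m=m, lambda_alpha=rates[0], lambda_beta=rates[1],
                            lambda_gamma=rates[2])
        lam = float(rates[3])
        from cycletrial.cellcycle import build_rate_matrix as brm

        a = brm(p, lam)
        x0 = initial_state(200.0, "stationary", p, lam)
        times = np.linspace(0, 4, 9)
        ours = np.array([s.counts for s in simulate_constant(p, x0, lam, times)])
        direct = np.array([expm(a * t) @ x0.counts for t in times])
        sol = solve_ivp(lambda t, x: a @ x, (0, 4), x0.counts, t_eval=times,
                        rtol=1e-12, atol=1e-14, method="DOP853")
        scale = np.maximum(np.abs(direct), 1e-6 * direct.sum(axis=1, keepdims=True))
        assert np.max(np.abs(ours - direct) / scale) < 1e-8
        assert np.max(np.abs(ours - sol.y.T) / scale) < 1e-8

    def test_nonnegative_counts_and_division_growth_rate(self, rng):
        """d(total)/dt equals lambda_gamma * M_m (growth only via division)."""
        for _ in range(5):
            rates = rng.uniform(0.1, 5.0, size=4)
            p = CellCycleParams(m=3, lambda_alpha=rates[0], lambda_beta=rates[1],
                                lambda_gamma=rates[2])
            lam = float(rates[3])
            x0 = initial_state(100.0, "stationary", p, lam)
            h = 1e-5
            t = 1.7
            s = simulate_constant(p, x0, lam, [0.0, t - h, t, t + h])
            assert all((st_.counts >= 0).all() for st_ in s)
            deriv = (s[3].total - s[1].total) / (2 * h)
            expected = rates[2] * s[2].counts[-1]
            assert deriv == pytest.approx(expected, rel=1e-6)

    def test_zero_g1s_rate_absorbs_mass_into_g1(self, small_params):
        x0 = initial_state(100.0, "stationary", small_params, 2.0)
        states = simulate_constant(small_params, x0, 0.0, [0.0, 5.0, 20.0, 60.0])
        traj = aggregate_phases(states, small_params.m)
        s_plus_m = traj.s + traj.g2m
        assert s_plus_m[1] < s_plus_m[0]
        assert s_plus_m[-1] < 1e-6 * traj.total[-1]


class TestTimeVaryingSolver:
    def test_constant_fn_reduces_to_constant_solver(self, small_params):
        x0 = initial_state(300.0, "stationary", small_params, 2.0)
        times = np.linspace(0, 3, 7)
        tv = simulate_timevarying(small_params, x0, lambda t: 2.0, times, step=0.05)
        const = simulate_constant(small_params, x0, 2.0, times)
        for a, b in zip(tv, const):
            np.testing.assert_allclose(a.counts, b.counts, rtol=1e-9, atol=1e-9)

    def test_midpoint_freezing_is_second_order(self, small_params):
        x0 = initial_state(100.0, "synchronized", small_params, 1.0)
        fn = lambda t: 2.0 + 1.5 * np.sin(2 * np.pi * t / 3.0)
        times = [0.0, 10.0]

        def total(step):
            return simulate_timevarying(small_params, x0, fn, times, step=step)[-1].total

        ref = total(0.003125)
        e1 = abs(np.log(total(0.1)) - np.log(ref))
        e2 = abs(np.log(total(0.05)) - np.log(ref))
        assert 3.0 < e1 / e2 < 5.0

    def test_square_wave_matches_segment_composition(self, small_params):
        on, off = 2.5, 0.3
        fn = lambda t: on if t < 1.0 else off
        x0 = initial_state(100.0, "stationary", small_params, on)
        out = simulate_timevarying(small_params, x0, fn, [0.0, 1.0, 2.0], step=0.25)
        seg1 = simulate_constant(small_params, x0, on, [0.0, 1.0])[-1]
        seg2 = simulate_constant(small_params, seg1, off, [1.0, 2.0])[-1]
        np.testing.assert_allclose(out[1].counts, seg1.counts, rtol=1e-9)
        np.testing.assert_allclose(out[2].counts, seg2.counts, rtol=1e-9)

    def test_negative_rate_from_fn_is_contract_violation(self, small_params):
        x0 = initial_state(10.0, "synchronized", small_params, 1.0)
        with pytest.raises(ValueError):
            simulate_timevarying(small_params, x0, lambda t: -1.0, [0.0, 1.0])


class TestAggregationAndInitialState:
    def test_m1_aggregation_is_identity(self):
        p = CellCycleParams(m=1, lambda_alpha=1, lambda_beta=1, lambda_gamma=1)
        s = SubphaseState(np.array([3.0, 4.0, 5.0]), time=0.0)
        traj = aggregate_phases([s], 1)
        assert (traj.g1[0], traj.s[0], traj.g2m[0]) == (3.0, 4.0, 5.0)
        assert traj.total[0] == 12.0

    def test_uniform_ones_m4(self):
        s = SubphaseState(np.ones(12), time=0.0)
        traj = aggregate_phases([s], 4)
        assert (traj.g1[0], traj.s[0], traj.g2m[0]) == (4.0, 4.0, 4.0)
        assert traj.total[0] == 12.0

    def test_random_state_matches_index_ranges(self, rng):
        m = 5
        x = rng.uniform(0, 10, size=3 * m)
        traj = aggregate_phases([SubphaseState(x, 0.0)], m)
        assert traj.g1[0] == pytest.approx(x[:m].sum())
        assert traj.s[0] == pytest.approx(x[m : 2 * m].sum())
        assert traj.g2m[0] == pytest.approx(x[2 * m :].sum())

    def test_synchronized_start(self, small_params):
        s = initial_state(500.0, "synchronized", small_params, 1.0)
        expected = np.zeros(6)
        expected[0] = 500.0
        np.testing.assert_allclose(s.counts, expected)

    def test_stationary_proportions_invariant_under_flow(self, small_params):
        lam = 2.0
        s0 = initial_state(100.0, "stationary", small_params, lam)
        s1 = simulate_constant(small_params, s0, lam, [0.0, 2.0])[-1]
        np.testing.assert_allclose(
            s1.counts / s1.total, s0.counts / s0.total, rtol=1e-8, atol=1e-12
        )
        assert s0.total == pytest.approx(100.0)

    def test_unknown_mode_rejected(self, small_params):
        with pytest.raises(ValueError):
            initial_state(10.0, "banana", small_params, 1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    m=st.integers(1, 6),
    la=st.floats(0.1, 5.0),
    lb=st.floats(0.1, 5.0),
    lg=st.floats(0.1, 5.0),
    lam=st.floats(0.0, 5.0),
)
def test_property_nonnegativity_and_mass(m, la, lb, lg, lam):
    """Counts stay nonnegative and phases always sum to the total."""
    p = CellCycleParams(m=m, lambda_alpha=la, lambda_beta=lb, lambda_gamma=lg)
    x0 = initial_state(50.0, "synchronized", p, lam)
    states = simulate_constant(p, x0, lam, [0.0, 0.7, 2.9])
    traj = aggregate_phases(states, m)
    for s in states:
        assert (s.counts >= 0).all()
    np.testing.assert_allclose(traj.g1 + traj.s + traj.g2m, traj.total, rtol=1e-9)


def test_stationary_distribution_is_perron_vector(small_params):
    v = stationary_distribution(small_params, 2.0)
    assert (v >= 0).all()
    assert v.sum() == pytest.approx(1.0)
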