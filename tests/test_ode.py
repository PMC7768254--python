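"""The ODE-integrated transition probabilities and the exact TKF91 limit."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from geomindel import (
    GGIParams,
    boundary_probs,
    compose_fg,
    count_derivatives,
    counts_to_probs,
    derived_counts,
    expected_transition_count,
    finite_machine,
    occupancy_closed_form,
    solve_transition_probs,
    tkf91_probs,
)

#: the parameter sweep box explored in the study
SWEEP_BOX = dict(lam=(0.01, 1.0), mu=(0.01, 1.0), x=(0.0, 0.7), y=(0.0, 0.65),
                 t=(2**-7, 2.0))


def random_sweep_point(rng: np.random.Generator) -> tuple[GGIParams, float]:
    lo_hi = [SWEEP_BOX[k] for k in ("lam", "mu", "x", "y", "t")]
    lam, mu, x, y, t = (rng.uniform(lo, hi) for lo, hi in lo_hi)
    return GGIParams(lam, mu, x, y), t


def fg_count_derivative(probs, p: GGIParams, h: float = 1e-6) -> np.ndarray:
    """d/d(dt) of the composite machine's expected counts at dt = 0, by a
    second-order finite difference of the path-sum calculus (independent of
    the closed-form ODE right-hand sides)."""
    pairs = [("M", "M"), ("M", "I"), ("I", "M"), ("D", "I")]
    F = probs.machine()

    def counts(dt):
        m = compose_fg(F, p, dt)
        return np.array([expected_transition_count(m, X, Y) for X, Y in pairs])

    e0, e1, e2 = counts(0.0), counts(h), counts(2 * h)
    return (-3 * e0 + 4 * e1 - e2) / (2 * h)


class TestOccupancy:
    def test_zero_time_and_symmetry(self, central_params):
        assert occupancy_closed_form(central_params, 0.0) == (0.0, 0.0)
        si, sd = occupancy_closed_form(central_params, 0.8)
        assert si == sd  # lam = mu, x = y

    def test_known_value(self):
        si, _ = occupancy_closed_form(GGIParams(1, 1, 0.5, 0.5), 0.5)
        assert si == pytest.approx(1.7182818, abs=1e-7)

    def test_matches_direct_ode_integration(self):
        """The closed form solves dS_I/dt = λ(1 + S_I)/(1−x) (rate of new
        events × mean length, each past event's interval growing)."""
        p = GGIParams(0.9, 0.4, 0.35, 0.6)
        grid = np.linspace(0, 2, 21)
        sol = solve_ivp(
            lambda t, s: [p.lam / (1 - p.x) * (1 + s[0]), p.mu / (1 - p.y) * (1 + s[1])],
            (0, 2), [0.0, 0.0], t_eval=grid, rtol=1e-12, atol=1e-14,
        )
        for t, si, sd in zip(sol.t, *sol.y):
            ci, cd = occupancy_closed_form(p, t)
            assert ci == pytest.approx(si, abs=1e-8)
            assert cd == pytest.approx(sd, abs=1e-8)

    def test_small_time_first_order(self):
        p = GGIParams(0.7, 0.4, 0.3, 0.6)
        t = 1e-7
        si, sd = occupancy_closed_form(p, t)
        assert si == pytest.approx(p.lam * t / (1 - p.x), rel=1e-6)
        assert sd == pytest.approx(p.mu * t / (1 - p.y), rel=1e-6)


class TestCountAlgebra:
    def test_boundary_conversion(self, central_params):
        c = derived_counts(0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        pr = counts_to_probs(c, central_params)
        assert (pr.a, pr.b, pr.c, pr.h, pr.q) == (1, 0, 0, 0, 0)
        assert (pr.f, pr.g) == (0.5, 0.5)
        assert (pr.p, pr.r) == (0.5, 0.5)

    def test_direct_ratios_and_row_sums(self, central_params):
        c = derived_counts(0.3, 0.7, 0.2, 0.25, 0.1, 0.6, 0.5)
        assert c.T_MD == pytest.approx(0.1)
        pr = counts_to_probs(c, central_params)
        assert (pr.a, pr.b, pr.c) == pytest.approx((0.7, 0.2, 0.1))
        assert np.allclose(pr.matrix.sum(axis=1), 1.0)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError, match="T_MD"):
            derived_counts(0.1, 0.9, 0.3, 0.0, 0.0, 0.1, 0.1)

    def test_derived_counts_match_count_calculus_for_tkf91(self):
        """Filling the count vector from the four primary counts agrees
        with the full expected-count calculus on the TKF91 machine."""
        lam = mu = 1.0
        t = 0.5
        pr = tkf91_probs(lam, mu, t)
        m = pr.machine()
        ET = {
            (X, Y): expected_transition_count(m, X, Y) for X in "MID" for Y in "MID"
        }
        si, sd = occupancy_closed_form(GGIParams(lam, mu, 0, 0), t)
        c = derived_counts(t, ET["M", "M"], ET["M", "I"], ET["I", "M"], ET["D", "I"], si, sd)
        for X in "MID":
            for Y in "MID":
                assert getattr(c, f"T_{X}{Y}") == pytest.approx(ET[X, Y], abs=1e-9)


class TestDerivatives:
    def test_initial_derivatives(self):
        for p in (GGIParams(1, 1, 0.5, 0.5), GGIParams(0.3, 0.8, 0.0, 0.6)):
            d = count_derivatives(boundary_probs(p), p)
            assert np.allclose(d, [-(p.lam + p.mu), p.lam, p.lam, 0.0], atol=1e-12)

    def test_rhs_matches_composite_machine_finite_difference(self, central_params):
        pr = solve_transition_probs(central_params, 0.5)
        got = count_derivatives(pr, central_params)
        ref = fg_count_derivative(pr, central_params)
        assert np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-8)) < 1e-4

    def test_rhs_matches_finite_difference_across_sweep(self):
        rng = np.random.default_rng(2024)
        for _ in range(4):
            p, t = random_sweep_point(rng)
            pr = solve_transition_probs(p, t)
            got = count_derivatives(pr, p)
            ref = fg_count_derivative(pr, p)
            assert np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-8)) < 1e-4


class TestSolver:
    def test_zero_time_and_frozen_process(self, central_params):
        assert solve_transition_probs(central_params, 0.0) == boundary_probs(central_params)
        frozen = GGIParams(0, 0, 0.3, 0.2)
        assert solve_transition_probs(frozen, 5.0).a == 1.0

    def test_reduces_to_tkf91_for_single_residue_indels(self):
        for lam, mu in [(0.3, 1.0), (2.0, 0.3), (1.0, 1.0)]:
            p = GGIParams(lam, mu, 0, 0)
            for t in (2**-7, 0.5, 2.0):
                h = solve_transition_probs(p, t).matrix
                k = tkf91_probs(lam, mu, t).matrix
                assert np.max(np.abs(h - k)) < 1e-6

    def test_trajectory_stays_on_simplex_with_consistent_occupancy(self):
        p = GGIParams(0.8, 0.5, 0.6, 0.4)
        grid = np.linspace(0.0, 2.0, 41)
        out = solve_transition_probs(p, 2.0, t_eval=grid)
        for tt, pr in zip(grid, out):
            m = pr.matrix
            assert np.all(m >= -1e-10)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-8)
        # occupancies carried by the integration equal the closed form
        for tt, pr in zip(grid, out):
            if tt == 0:
                continue
            si, sd = occupancy_closed_form(p, tt)
            # reconstruct S_I from the ratios: b + T_II + T_DI where
            # T_II = g S_I, T_DI = q S_D  =>  S_I (1-g) = b + q S_D
            lhs = pr.b + pr.q * sd
            assert lhs == pytest.approx(si * (1 - pr.g), abs=1e-8 * (1 + si))

    def test_negative_time_raises(self, central_params):
        with pytest.raises(ValueError):
            solve_transition_probs(central_params, -0.1)


class TestTKF91ClosedForm:
    def test_zero_time(self):
        pr = tkf91_probs(1.0, 2.0, 0.0)
        assert (pr.a, pr.b, pr.c) == (1.0, 0.0, 0.0)

    def test_equal_rates_limit(self):
        lam = 0.8
        t = 0.6
        pr = tkf91_probs(lam, lam, t)
        assert pr.b == pytest.approx(lam * t / (1 + lam * t), rel=1e-12)
        lo = tkf91_probs(lam, lam * (1 - 1e-7), t)
        hi = tkf91_probs(lam, lam * (1 + 1e-7), t)
        assert pr.b == pytest.approx(lo.b, rel=1e-6)
        assert pr.b == pytest.approx(hi.b, rel=1e-6)
        assert pr.q == pytest.approx(lo.q, rel=1e-5)

    def test_deletion_only(self):
        mu, t = 1.3, 0.7
        pr = tkf91_probs(0.0, mu, t)
        assert pr.a == pytest.approx(np.exp(-mu * t))
        assert pr.b == 0.0
        for t2 in (0.1, 1.0, 3.0):
            assert tkf91_probs(0.0, mu, t2).b == 0.0

    def test_rows_are_stochastic(self):
        for lam, mu, t in [(1, 1, 0.5), (0.3, 2, 1.0), (2, 0.3, 0.25), (1, 0, 0.5)]:
            tkf91_probs(lam, mu, t).validate(tol=1e-12)


class TestFiniteMachine:
    def test_interior_block_is_the_three_state_machine(self, central_params):
        pr = solve_transition_probs(central_params, 0.5)
        fm = finite_machine(pr)
        assert np.allclose(fm.Q[:3, :3], pr.matrix)

    def test_zero_time_all_match_path_has_weight_one(self, central_params):
        fm = finite_machine(boundary_probs(central_params))
        names = [n for n, _ in fm.states]
        s, e = names.index("S"), names.index("E")
        assert fm.Q[s, 0] == 1.0   # start -> M
        assert fm.Q[0, 0] == 1.0   # M -> M
        assert fm.Q[0, e] == 1.0   # M -> end
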