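"""Galerkin projection: test functions, weak problems, window selection."""

import numpy as np
import pytest

from slicdd.model_library import LibrarySpec
from slicdd.simulators import TrajectoryDataset
from slicdd.sparse_regression import LibraryMatrix
from slicdd.weakform import (TestFunction as BumpFunction,
                             build_weak_problem_ode,
                             build_weak_problem_pde, select_window_ssim,
                             weak_inner_product, weak_smooth)


def _tf(t_grid, q):
    return BumpFunction.for_grid(t_grid, q)


class TestTestFunction:
    @pytest.mark.parametrize("q", [1.5, 2.0, 3.0, 6.0, 9.5])
    @pytest.mark.parametrize("window", [(0.0, 1.0, 21), (-2.0, 3.0, 57)])
    def test_unit_mass_and_vanishing_ends(self, q, window):
        t1, t2, n = window
        t = np.linspace(t1, t2, n)
        tf = _tf(t, q)
        assert weak_inner_product(np.ones(n), tf, 0, t) == pytest.approx(1.0, abs=1e-10)
        w = tf(t)
        assert w[0] == 0.0 and w[-1] == 0.0
        assert np.all(w >= 0.0)

    def test_derivative_order_capped_by_q(self):
        t = np.linspace(0, 1, 31)
        tf = _tf(t, 2.0)
        tf(t, 2)
        with pytest.raises(ValueError):
            tf(t, 3)

    def test_window_too_narrow(self):
        with pytest.raises(ValueError):
            BumpFunction.for_grid(np.array([0.0, 1.0]), 3.0)

    def test_quadratic_against_fine_grid_oracle(self):
        """-<t^2 * w'> equals 2c (c the window center) at fine-grid accuracy."""
        c = 1.7
        t = np.linspace(c - 0.5, c + 0.5, 41)
        tf = _tf(t, 4.0)
        val = -weak_inner_product(t**2, tf, 1, t)
        t_fine = np.linspace(c - 0.5, c + 0.5, 4001)
        tf_fine = _tf(t_fine, 4.0)
        oracle = -weak_inner_product(t_fine**2, tf_fine, 1, t_fine)
        assert val == pytest.approx(2.0 * c, rel=1e-5)
        assert oracle == pytest.approx(2.0 * c, rel=1e-9)

    def test_reflection_symmetry(self):
        t = np.linspace(-1, 1, 51)
        tf = _tf(t, 3.0)
        f = np.cosh(t)  # even about the window center
        assert weak_inner_product(f, tf, 0, t) == pytest.approx(
            weak_inner_product(f[::-1], tf, 0, t), rel=1e-12)

    @pytest.mark.parametrize("q, rel", [(2.0, 5e-4), (4.0, 1e-6), (7.0, 1e-9)])
    def test_integration_by_parts_identity(self, q, rel):
        """-<f w'> equals <f'>_w for smooth noiseless f; the quadrature
        error shrinks rapidly as the bump gets smoother (larger q)."""
        t = np.linspace(0.2, 1.8, 161)
        f = np.sin(3.0 * t) + 0.5 * t**2
        fprime = 3.0 * np.cos(3.0 * t) + t
        tf = _tf(t, q)
        lhs = -weak_inner_product(f, tf, 1, t)
        rhs = weak_inner_product(fprime, tf, 0, t)
        assert lhs == pytest.approx(rhs, rel=rel, abs=1e-9)


def _ode_dataset(x, dt, names=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    t = np.arange(x.shape[0]) * dt
    return TrajectoryDataset(states=x, time_grid=t,
                             variable_names=names or ["x"][: x.shape[1]])


class TestWeakProblemODE:
    def test_exponential_growth_rate_recovered(self):
        a, dt = 0.7, 0.01
        x = np.exp(a * np.arange(800) * dt)
        data = _ode_dataset(x, dt)
        lib = LibraryMatrix(x[:, None], ["x"])
        prob = build_weak_problem_ode(data, window_size=41, library=lib)
        slope = np.linalg.lstsq(prob.theta_weak.values, prob.y_weak.values,
                                rcond=None)[0][0, 0]
        assert slope == pytest.approx(a, rel=1e-3)

    def test_constant_signal_gives_zero_targets(self):
        x = np.full(300, 2.5)
        data = _ode_dataset(x, 0.01)
        lib = LibraryMatrix(np.column_stack([np.ones(300), x]), ["1", "x"])
        prob = build_weak_problem_ode(data, window_size=31, library=lib)
        assert np.allclose(prob.y_weak.values, 0.0, atol=1e-12)

    def test_windows_respect_segment_boundaries(self):
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(5, 6, 50)])
        data = TrajectoryDataset(states=x[:, None], time_grid=np.tile(np.arange(50) * 0.1, 2),
                                 segment_boundaries=[0, 50], variable_names=["x"])
        lib = LibraryMatrix(x[:, None], ["x"])
        prob = build_weak_problem_ode(data, window_size=21, stride=10, library=lib)
        per_seg = (50 - 21) // 10 + 1
        assert prob.theta_weak.n == 2 * per_seg

    def test_non_uniform_grid_rejected(self):
        t = np.cumsum(np.random.default_rng(0).uniform(0.5, 1.5, 100)) * 0.01
        data = TrajectoryDataset(states=np.sin(t)[:, None], time_grid=t,
                                 variable_names=["x"])
        with pytest.raises(ValueError):
            build_weak_problem_ode(data, window_size=21,
                                   library=LibraryMatrix(np.sin(t)[:, None], ["x"]))

    def test_coefficient_error_refines_at_second_order_or_better(self):
        """The recovered rate of a noiseless linear system converges as the
        grid refines (observed order >= 2)."""
        a = -0.9
        errs = []
        for n in (400, 800):
            dt = 8.0 / n
            x = np.exp(a * np.arange(n) * dt)
            data = _ode_dataset(x, dt)
            lib = LibraryMatrix(x[:, None], ["x"])
            prob = build_weak_problem_ode(data, window_size=n // 20, library=lib, q=3.0)
            c = np.linalg.lstsq(prob.theta_weak.values, prob.y_weak.values, rcond=None)[0]
            errs.append(abs(c[0, 0] - a))
        assert errs[1] < errs[0] / 4.0


class TestWeakProblemPDE:
    def _field(self, f):
        x = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        t = np.linspace(0, 1, 40)
        u = np.broadcast_to(f(x), (t.size, x.size)).copy()
        return TrajectoryDataset(states=u, time_grid=t, space_grid=x,
                                 variable_names=["u"])

    def test_second_derivative_moved_onto_test_function(self, ):
        """For u = sin(x), <u_xx>_w = <u * w_xx> = -<u>_w."""
        data = self._field(np.sin)
        spec = LibrarySpec("pde", max_poly_order=1, max_derivative_order=2,
                           convective=False, include_constant=False)
        prob = build_weak_problem_pde(data, spec, window_sizes=(9, 33))
        labels = prob.theta_weak.term_labels
        u_col = prob.theta_weak.values[:, labels.index("u")]
        uxx_col = prob.theta_weak.values[:, labels.index("dxx(u)")]
        assert np.allclose(uxx_col, -u_col, rtol=1e-3, atol=1e-8)

    def test_constant_field_derivative_columns_vanish(self):
        data = self._field(lambda x: np.full_like(x, 3.0))
        spec = LibrarySpec("pde", max_poly_order=1, max_derivative_order=4,
                           convective=True, include_constant=True)
        prob = build_weak_problem_pde(data, spec, window_sizes=(9, 21))
        labels = prob.theta_weak.term_labels
        for lab in labels:
            col = prob.theta_weak.values[:, labels.index(lab)]
            if lab.startswith("d") or "*dx(" in lab:
                # quadrature floor grows with the derivative order on w
                tol = 1e-8 if lab.count("x") <= 3 else 2e-3
                assert np.allclose(col, 0.0, atol=tol), lab
        assert np.allclose(prob.y_weak.values, 0.0, atol=1e-12)

    def test_convective_column_matches_analytic_form(self):
        """0.5 d(u^2)/dx for u = sin x equals sin x cos x, checked in weak form."""
        data = self._field(np.sin)
        spec = LibrarySpec("pde", max_poly_order=1, max_derivative_order=1,
                           convective=True, include_constant=False)
        prob = build_weak_problem_pde(data, spec, window_sizes=(9, 33))
        labels = prob.theta_weak.term_labels
        conv = prob.theta_weak.values[:, labels.index("u*dx(u)")]
        # oracle: order-0 projection of sin*cos over the same windows, built
        # from a half-harmonic helper field
        data2 = self._field(lambda x: np.sin(x) * np.cos(x))
        spec2 = LibrarySpec("pde", max_poly_order=1, max_derivative_order=1,
                            convective=False, include_constant=False)
        prob2 = build_weak_problem_pde(data2, spec2, window_sizes=(9, 33))
        oracle = prob2.theta_weak.values[:, prob2.theta_weak.term_labels.index("u")]
        assert np.allclose(conv, oracle, rtol=1e-3, atol=1e-8)

    def test_derivative_order_beyond_q_rejected(self):
        data = self._field(np.sin)
        spec = LibrarySpec("pde", max_derivative_order=4)
        with pytest.raises(ValueError):
            build_weak_problem_pde(data, spec, window_sizes=(9, 21), q=3.0)


class TestWindowSelection:
    def test_smooth_signal_takes_widest_window(self):
        t = np.linspace(0, 4 * np.pi, 2000)
        sig = np.sin(0.5 * t)
        assert select_window_ssim(sig, [5, 11, 21]) == 21

    def test_white_noise_falls_back_to_smallest(self, rng):
        sig = rng.normal(size=2000)
        assert select_window_ssim(sig, [5, 11, 21]) == 5

    def test_sharp_feature_limits_window(self, rng):
        # the signal's structure is a train of 15-sample-wide pulses: wide
        # windows flatten them, so the chosen window is shorter than a pulse
        t = np.linspace(0, 1, 1200)
        sig = 0.05 * np.sin(2 * np.pi * t)
        for start in range(50, 1150, 100):
            sig[start:start + 15] += 1.0
        chosen = select_window_ssim(sig, [5, 11, 31, 101, 301])
        assert chosen < 15

    def test_max_mode_returns_ssim_argmax(self, rng):
        sig = np.sin(np.linspace(0, 3, 500)) + 0.3 * rng.normal(size=500)
        out = select_window_ssim(sig, [5, 11, 21], mode="max")
        assert out in (5, 11, 21)

    def test_oversized_candidate_rejected(self):
        with pytest.raises(ValueError):
            select_window_ssim(np.zeros(10), [5, 20])

    def test_weak_smooth_preserves_constant(self):
        out = weak_smooth(np.full(100, 1.3), 11)
        assert np.allclose(out, 1.3, atol=1e-12)
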