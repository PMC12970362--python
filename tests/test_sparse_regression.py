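"""Pseudoinverse fitting and the adaptive threshold-pruning loop."""

import itertools

import numpy as np
import pytest

from slicdd.criteria import comparison_criterion
from slicdd.sparse_regression import (LibraryMatrix, TargetMatrix, auto_prune,
                                      candidate_thresholds, fit_pseudoinverse)


def _lib(values):
    values = np.asarray(values, dtype=float)
    return LibraryMatrix(values, [f"t{i}" for i in range(values.shape[1])])


def _tgt(values):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return TargetMatrix(values, [f"y{i}" for i in range(values.shape[1])])


def exhaustive_best_support(theta, y_col, criterion):
    """Independent oracle: criterion minimization over all 2^l supports."""
    l = theta.shape[1]
    n = theta.shape[0]
    best, best_score = None, np.inf
    for bits in itertools.product([False, True], repeat=l):
        active = np.array(bits)
        xi = np.zeros(l)
        if active.any():
            xi[active] = np.linalg.lstsq(theta[:, active], y_col, rcond=None)[0]
        mse = float(np.mean((y_col - theta @ xi) ** 2))
        k = int((xi != 0).sum()) + 1
        gram = None
        if criterion == "kic":
            act = xi != 0
            if act.any():
                sign, logdet = np.linalg.slogdet(theta[:, act].T @ theta[:, act])
                gram = logdet if sign > 0 else np.inf
            else:
                gram = 0.0
        score = comparison_criterion(criterion, mse, k, n, gram_logdet=gram)
        if score < best_score:
            best, best_score = xi != 0, score
    return best, best_score


class TestFitPseudoinverse:
    def test_orthonormal_consistent_system(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        y = q @ np.array([3.0, -1.0])
        model = fit_pseudoinverse(_lib(q), _tgt(y))
        assert np.allclose(model.coefficients[:, 0], [3.0, -1.0], atol=1e-12)

    def test_rank_deficient_gives_min_norm_solution(self, rng):
        a = rng.normal(size=(20, 3))
        theta = np.column_stack([a, a[:, 0]])  # duplicated column
        y = a @ np.array([1.0, 2.0, -1.0])
        model = fit_pseudoinverse(_lib(theta), _tgt(y))
        xi = model.coefficients[:, 0]
        oracle = np.linalg.pinv(theta) @ y  # dense SVD pseudoinverse
        assert np.allclose(xi, oracle, atol=1e-10)
        resid = np.linalg.norm(y - theta @ xi)
        assert resid == pytest.approx(np.linalg.norm(y - theta @ oracle), abs=1e-10)

    def test_all_false_support_is_null_model(self, rng):
        theta = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = fit_pseudoinverse(_lib(theta), _tgt(y),
                                  support=np.zeros((3, 1), dtype=bool))
        assert np.all(model.coefficients == 0.0)

    def test_row_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fit_pseudoinverse(_lib(rng.normal(size=(10, 2))),
                              _tgt(rng.normal(size=8)))


class TestCandidateThresholds:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0.5, -2.0, 0.0], [0.5, 2.0]),
            ([1.0, 1.0, -1.0], [1.0]),
            ([0.0, 0.0], []),
        ],
    )
    def test_sorted_deduplicated_magnitudes(self, column, expected):
        theta = np.eye(len(column))
        model = fit_pseudoinverse(_lib(theta), _tgt(np.asarray(column)))
        assert candidate_thresholds(model, 0).tolist() == expected


class TestAutoPrune:
    def _sparse_problem(self, seed, n=60, l=8, nnz=3, noise=0.0):
        rng = np.random.default_rng(seed)
        theta = rng.normal(size=(n, l))
        xi = np.zeros(l)
        idx = rng.choice(l, size=nnz, replace=False)
        xi[idx] = rng.uniform(0.5, 2.0, size=nnz) * rng.choice([-1, 1], size=nnz)
        y = theta @ xi + noise * rng.normal(size=n)
        return theta, xi, y

    def test_noiseless_recovery_matches_exhaustive_oracle(self):
        theta, xi_true, y = self._sparse_problem(seed=7)
        model, scores = auto_prune(_lib(theta), _tgt(y), criterion="slic")
        got = model.coefficients[:, 0]
        assert np.array_equal(got != 0, xi_true != 0)
        assert np.allclose(got, xi_true, atol=1e-8)
        oracle_support, _ = exhaustive_best_support(theta, y, "slic")
        assert np.array_equal(got != 0, oracle_support)

    def test_non_finite_input_rejected(self):
        theta = np.ones((4, 2))
        theta[0, 0] = np.nan
        with pytest.raises(ValueError):
            auto_prune(_lib(theta), _tgt(np.ones(4)))

    def test_monotone_improvement_and_variance_link(self):
        """Accepted scores never increase, and the length-scaling criterion
        orders candidate models exactly like the variance proxy mse*k."""
        theta, _, y = self._sparse_problem(seed=3, noise=0.3)
        trace = []
        model, (score,) = auto_prune(_lib(theta), _tgt(y), criterion="slic",
                                     _trace=trace)
        assert len(trace) > 2
        running = np.inf
        accepted = []
        for xi, s in trace:
            if s.score < running:
                running = s.score
                accepted.append(s.score)
        assert accepted == sorted(accepted, reverse=True)
        assert score.score == pytest.approx(min(s.score for _, s in trace))
        slic_order = np.argsort([s.score for _, s in trace], kind="stable")
        var_order = np.argsort([s.mse * s.k for _, s in trace], kind="stable")
        assert np.array_equal(slic_order, var_order)

    def test_tie_keeps_first_encountered_model(self):
        """With strict-inequality acceptance, an equally scored later
        candidate does not displace the incumbent."""
        c = np.linspace(1.0, 2.0, 12)
        theta = np.column_stack([c, 2.0 * c])  # col1 = 2*col0, both fit y exactly
        y = c.copy()
        trace = []
        model, (score,) = auto_prune(_lib(theta), _tgt(y), criterion="slic",
                                     _trace=trace)
        best = min(s.score for _, s in trace)
        first_best = next(xi for xi, s in trace if s.score == best)
        assert np.array_equal(model.coefficients[:, 0] != 0, first_best != 0)

    def test_pure_noise_selects_sparse_model(self):
        """On patternless targets the selected model is at most one term, at
        least as often as the exhaustive optimum is that sparse."""
        auto_sparse = exh_sparse = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            theta = rng.normal(size=(50, 6))
            y = rng.normal(size=50)
            model, _ = auto_prune(_lib(theta), _tgt(y), criterion="slic")
            auto_sparse += int((model.coefficients[:, 0] != 0).sum() <= 1)
            oracle_support, _ = exhaustive_best_support(theta, y, "slic")
            exh_sparse += int(oracle_support.sum() <= 1)
        assert auto_sparse >= exh_sparse

    def test_pruning_never_grows_support(self):
        theta, _, y = self._sparse_problem(seed=11, noise=0.5)
        full = fit_pseudoinverse(_lib(theta), _tgt(y))
        model, _ = auto_prune(_lib(theta), _tgt(y), criterion="bic")
        assert np.all(model.support <= full.support)

    def test_normalize_columns_back_transforms(self):
        theta, xi_true, y = self._sparse_problem(seed=5)
        theta_scaled = theta * np.array([1.0, 100.0, 0.01, 1, 1, 1, 1, 1])
        xi_scaled = xi_true / np.array([1.0, 100.0, 0.01, 1, 1, 1, 1, 1])
        y2 = theta_scaled @ xi_scaled
        model, _ = auto_prune(_lib(theta_scaled), _tgt(y2), criterion="slic",
                              normalize_columns=True)
        assert np.allclose(model.coefficients[:, 0], xi_scaled, atol=1e-8)

    def test_pooled_mode_scores_targets_jointly(self):
        theta, xi_true, y = self._sparse_problem(seed=9)
        y2 = np.column_stack([y, theta @ (2 * xi_true)])
        model, scores = auto_prune(_lib(theta), _tgt(y2), criterion="slic", pooled=True)
        assert model.coefficients.shape == (8, 2)
        assert len(scores) == 2
        assert np.allclose(model.coefficients[:, 1], 2 * xi_true, atol=1e-7)
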