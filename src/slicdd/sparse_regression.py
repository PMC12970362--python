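"""Auto-pruning hard-threshold sparse regression.

Solves ``Y = Theta(X) Xi`` for a sparse coefficient matrix ``Xi`` with an L0
penalty, without a user-supplied threshold.  Candidate thresholds are read off
the fitted coefficients themselves: the algorithm fits the full model by
pseudoinverse, collects the absolute values of its nonzero coefficients as the
threshold ladder, and for each threshold prunes the smaller coefficients,
refits the survivors, and keeps the pruned model whenever it strictly improves
the chosen information criterion.  The ladder is regenerated from the current
best model and the sweep repeated (up to ``max_outer_iters`` times) until the
selected support stops changing.

Each target column is pruned and scored independently by default; a pooled
mode sums the per-column scores and prunes the whole coefficient matrix
jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .criteria import comparison_criterion, ScoredModel

__all__ = [
    "LibraryMatrix",
    "TargetMatrix",
    "SparseModel",
    "fit_pseudoinverse",
    "candidate_thresholds",
    "auto_prune",
]


@dataclass
class LibraryMatrix:
    """Design matrix of candidate terms Theta(X): n observations x l terms."""

    values: np.ndarray
    term_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("library values must be a 2-D matrix")
        n, l = self.values.shape
        if n < 1 or l < 1:
            raise ValueError("library must have at least one row and one column")
        if len(self.term_labels) != l:
            raise ValueError("term_labels length must equal the number of columns")
        if len(set(self.term_labels)) != l:
            raise ValueError("term labels must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_terms(self) -> int:
        return self.values.shape[1]


@dataclass
class TargetMatrix:
    """Regression targets Y: n observations x p targets."""

    values: np.ndarray
    target_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if len(self.target_labels) != self.values.shape[1]:
            raise ValueError("target_labels length must equal the number of targets")

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]


@dataclass
class SparseModel:
    """Sparse coefficient matrix Xi (l terms x p targets) with its support."""

    coefficients: np.ndarray
    support: np.ndarray
    threshold_used: float = 0.0
    regularization: str = "L0"
    term_labels: list[str] = field(default_factory=list)
    target_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        if self.coefficients.shape != self.support.shape:
            raise ValueError("coefficients and support must have equal shapes")
        if np.any(self.coefficients[~self.support] != 0.0):
            raise ValueError("coefficients must be exactly zero off-support")
        if self.threshold_used < 0:
            raise ValueError("threshold_used must be nonnegative")

    def coefficient(self, term: str, target: str | int = 0) -> float:
        """Look up a coefficient by term label (and target label or index)."""
        i = self.term_labels.index(term)
        j = target if isinstance(target, int) else self.target_labels.index(target)
        return float(self.coefficients[i, j])


def _lstsq_on_support(theta: np.ndarray, y_col: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Min-norm least squares restricted to the active columns; zeros elsewhere."""
    xi = np.zeros(theta.shape[1])
    if active.any():
        sol, *_ = np.linalg.lstsq(theta[:, active], y_col, rcond=None)
        xi[active] = sol
    return xi


def fit_pseudoinverse(
    theta: LibraryMatrix,
    y: TargetMatrix,
    support: np.ndarray | None = None,
) -> SparseModel:
    """Least-squares fit via the singular-value pseudoinverse.

    When ``support`` (boolean l x p) is given, each target column is fitted on
    its active library columns only; inactive entries are exactly zero.  An
    all-false support column yields the all-zero (null) model for that target.
    """
    th, yv = theta.values, y.values
    if th.shape[0] != yv.shape[0]:
        raise ValueError("library and targets must have the same number of rows")
    l, p = th.shape[1], yv.shape[1]
    if support is None:
        support = np.ones((l, p), dtype=bool)
    support = np.asarray(support, dtype=bool)
    if support.shape != (l, p):
        raise ValueError(f"support must have shape {(l, p)}, got {support.shape}")
    coef = np.zeros((l, p))
    for j in range(p):
        coef[:, j] = _lstsq_on_support(th, yv[:, j], support[:, j])
    eff_support = coef != 0.0
    return SparseModel(
        coefficients=coef,
        support=eff_support,
        term_labels=list(theta.term_labels),
        target_labels=list(y.target_labels),
    )


def candidate_thresholds(model: SparseModel, target_index: int) -> np.ndarray:
    """Sorted, de-duplicated absolute values of the nonzero coefficients."""
    col = model.coefficients[:, target_index]
    return np.unique(np.abs(col[col != 0.0]))


def _column_score(
    theta: np.ndarray,
    y_col: np.ndarray,
    xi: np.ndarray,
    criterion: str,
) -> ScoredModel:
    n = theta.shape[0]
    resid = y_col - theta @ xi
    mse = float(np.mean(resid**2))
    active = xi != 0.0
    k = int(active.sum()) + 1  # + the unknown noise strength
    gram_logdet = None
    if criterion == "kic":
        if active.any():
            tha = theta[:, active]
            sign, logdet = np.linalg.slogdet(tha.T @ tha)
            gram_logdet = logdet if sign > 0 else np.inf
        else:
            gram_logdet = 0.0
    value = comparison_criterion(criterion, mse, k, n, gram_logdet=gram_logdet)
    return ScoredModel(n=n, k=k, mse=mse, score=value, criterion_name=criterion)


def _prune_column(
    theta: np.ndarray,
    y_col: np.ndarray,
    criterion: str,
    max_outer_iters: int,
    trace: list | None = None,
) -> tuple[np.ndarray, ScoredModel]:
    """Algorithm: full pseudoinverse fit, then threshold-sweep pruning."""
    xi = _lstsq_on_support(theta, y_col, np.ones(theta.shape[1], dtype=bool))
    best = xi
    best_score = _column_score(theta, y_col, xi, criterion)
    if trace is not None:
        trace.append((best.copy(), best_score))
    for _ in range(max_outer_iters):
        lams = np.unique(np.abs(best[best != 0.0]))
        accepted = False
        for lam in lams:
            keep = np.abs(best) >= lam  # prune strictly-smaller terms
            keep &= best != 0.0
            if np.array_equal(keep, best != 0.0):
                continue  # identical support cannot strictly improve
            xi_new = _lstsq_on_support(theta, y_col, keep)
            new_score = _column_score(theta, y_col, xi_new, criterion)
            if trace is not None:
                trace.append((xi_new.copy(), new_score))
            if new_score.score < best_score.score:
                best, best_score = xi_new, new_score
                accepted = True
        if not accepted:
            break
    return best, best_score


def _pooled_prune(
    theta: np.ndarray,
    yv: np.ndarray,
    criterion: str,
    max_outer_iters: int,
) -> tuple[np.ndarray, list[ScoredModel]]:
    """Joint pruning of the full coefficient matrix; score = sum over columns."""
    l, p = theta.shape[1], yv.shape[1]

    def refit(keep: np.ndarray) -> np.ndarray:
        coef = np.zeros((l, p))
        for j in range(p):
            coef[:, j] = _lstsq_on_support(theta, yv[:, j], keep[:, j])
        return coef

    def total(coef: np.ndarray) -> tuple[float, list[ScoredModel]]:
        scores = [_column_score(theta, yv[:, j], coef[:, j], criterion) for j in range(p)]
        return sum(s.score for s in scores), scores

    best = refit(np.ones((l, p), dtype=bool))
    best_total, best_scores = total(best)
    for _ in range(max_outer_iters):
        lams = np.unique(np.abs(best[best != 0.0]))
        accepted = False
        for lam in lams:
            keep = (np.abs(best) >= lam) & (best != 0.0)
            if np.array_equal(keep, best != 0.0):
                continue
            coef_new = refit(keep)
            new_total, new_scores = total(coef_new)
            if new_total < best_total:
                best, best_total, best_scores = coef_new, new_total, new_scores
                accepted = True
        if not accepted:
            break
    return best, best_scores


def auto_prune(
    theta: LibraryMatrix,
    y: TargetMatrix,
    criterion: str = "slic",
    max_outer_iters: int = 10,
    pooled: bool = False,
    normalize_columns: bool = False,
    _trace: list | None = None,
) -> tuple[SparseModel, list[ScoredModel]]:
    """Fit a sparse model by adaptive threshold pruning under a criterion.

    Parameters
    ----------
    theta, y :
        Library and target matrices with matching row counts.
    criterion : str
        Criterion name (``slic`` by default; see :mod:`slicdd.criteria`).
    max_outer_iters : int
        Maximum number of regenerate-thresholds-and-sweep rounds; each round
        stops the loop early if no pruned model was accepted.
    pooled : bool
        Score targets jointly (summed criterion) instead of independently.
    normalize_columns : bool
        Rescale library columns to unit RMS before fitting so the threshold
        ladder compares normalized coefficient magnitudes; coefficients are
        transformed back before being returned.

    Returns
    -------
    (SparseModel, list of ScoredModel) — one score per target column.
    """
    th, yv = theta.values, y.values
    if th.shape[0] != yv.shape[0]:
        raise ValueError("library and targets must have the same number of rows")
    if not (np.all(np.isfinite(th)) and np.all(np.isfinite(yv))):
        raise ValueError("library and target matrices must be finite")

    scale = np.ones(th.shape[1])
    if normalize_columns:
        scale = np.sqrt(np.mean(th**2, axis=0))
        scale[scale == 0.0] = 1.0
        th = th / scale

    if pooled:
        coef, scores = _pooled_prune(th, yv, criterion, max_outer_iters)
    else:
        cols, scores = [], []
        for j in range(yv.shape[1]):
            xi, sc = _prune_column(th, yv[:, j], criterion, max_outer_iters, trace=_trace)
            cols.append(xi)
            scores.append(sc)
        coef = np.column_stack(cols)

    coef = coef / scale[:, None]
    model = SparseModel(
        coefficients=coef,
        support=coef != 0.0,
        term_labels=list(theta.term_labels),
        target_labels=list(y.target_labels),
    )
    return model, scores
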