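"""Information criteria for sparse model selection.

All criteria share the Gaussian-likelihood form ``IC = n*log(mse) + s(n, k)``,
where ``n`` is the number of observations, ``mse`` the mean-squared residual of
the fitted model, and ``k`` the model complexity.  The complexity convention
used throughout this package counts the number of nonzero coefficients of the
scored target column *plus one* for the unknown noise strength, and the same
convention is applied to every criterion so comparisons are fair.

The headline criterion is the sample-length-scaling logarithmic information
criterion (SLIC),

    SLIC(mse, k, n) = n * log(mse * k),

whose complexity penalty grows linearly with the sample length.  Classical
criteria (AIC, BIC, ...) have penalties that become negligible relative to the
``n*log(mse)`` fidelity term as ``n`` grows, which biases them towards dense,
overfit models on long records; SLIC keeps the fit/sparsity trade-off invariant
to how much data was collected.  Minimizing SLIC is equivalent to minimizing
the model-variance proxy ``mse * k / n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScoredModel",
    "slic",
    "comparison_criterion",
    "score",
    "CRITERIA",
]

#: Names accepted by :func:`comparison_criterion` and :func:`score`.
CRITERIA = ("slic", "aic", "aicc", "hqic", "bic", "kic", "bc")

#: Floor applied to the mean-squared error before taking logarithms, so that
#: exact (zero-residual) fits receive a very negative but finite score while
#: the ``k`` factor inside SLIC's log still orders them sparsest-first.
MSE_FLOOR = 1e-300


@dataclass(frozen=True)
class ScoredModel:
    """A model's score under one information criterion.

    Attributes
    ----------
    n : int
        Number of observations the model was fitted to.
    k : int
        Model complexity: nonzero coefficients of the scored target column
        plus one for the unknown noise strength (so ``k >= 1`` always).
    mse : float
        Mean-squared residual of the fit.
    score : float
        Criterion value (dimensionless; lower is better).
    criterion_name : str
        One of :data:`CRITERIA`.
    """

    n: int
    k: int
    mse: float
    score: float
    criterion_name: str

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"model complexity k must be >= 1, got {self.k}")
        if self.mse < 0:
            raise ValueError(f"mse must be nonnegative, got {self.mse}")


def _check_args(k: float, n: float) -> None:
    if n < 1:
        raise ValueError(f"sample length n must be >= 1, got {n}")
    if k < 1:
        raise ValueError(f"model complexity k must be >= 1, got {k}")


def slic(mse: float, k: float, n: float) -> float:
    """Sample-length-scaling logarithmic information criterion.

    ``n * log(mse * k)`` with the natural logarithm.  ``mse`` is floored at
    :data:`MSE_FLOOR` so an exact fit scores very negative but finite.

    ``k`` is accepted as a real number (not just an integer) because the
    criterion is symmetric in its two arguments, ``slic(a, b, n) ==
    slic(b, a, n)``; integer complexities are the only values produced by the
    fitting code.
    """
    if mse < 0:
        raise ValueError(f"mse must be nonnegative, got {mse}")
    _check_args(k, n)
    return n * math.log(max(mse, MSE_FLOOR) * k)


def _harmonic(k: int) -> float:
    return sum(1.0 / i for i in range(1, k + 1))


def comparison_criterion(
    name: str,
    mse: float,
    k: int,
    n: int,
    gram_logdet: float | None = None,
) -> float:
    """Evaluate one of the comparison information criteria.

    Parameters
    ----------
    name : str
        One of ``aic``, ``aicc``, ``hqic``, ``bic``, ``kic``, ``bc`` (``slic``
        is also accepted and dispatches to :func:`slic`).
    mse, k, n :
        Mean-squared error, complexity (nonzero coefficients + 1 for the noise
        strength) and sample length.
    gram_logdet : float, optional
        ``log|Theta_a^T Theta_a|`` over the active library columns; required
        for ``kic`` only.  The number of active columns is ``k - 1``.

    Notes
    -----
    * AICc returns ``+inf`` when ``n - k - 1 <= 0`` (model inadmissible).
    * KIC uses ``log|Theta^T Theta / mse| = gram_logdet - (k-1)*log(mse)``.
    * BC's penalty is ``n^(1/3)`` times the k-th harmonic number.
    """
    if mse < 0:
        raise ValueError(f"mse must be nonnegative, got {mse}")
    _check_args(k, n)
    name = name.lower()
    logmse = math.log(max(mse, MSE_FLOOR))
    fit = n * logmse
    if name == "slic":
        return slic(mse, k, n)
    if name == "aic":
        return fit + 2.0 * k
    if name == "aicc":
        if n - k - 1 <= 0:
            return math.inf
        return fit + 2.0 * n * k / (n - k - 1)
    if name == "hqic":
        return fit + k * math.log(math.log(n))
    if name == "bic":
        return fit + k * math.log(n)
    if name == "kic":
        if gram_logdet is None:
            raise ValueError("kic requires gram_logdet of the active columns")
        if not math.isfinite(gram_logdet):
            return math.inf
        k_active = k - 1
        return fit - k * math.log(2.0 * math.pi) + gram_logdet - k_active * logmse
    if name == "bc":
        return fit + n ** (1.0 / 3.0) * _harmonic(k)
    raise ValueError(f"unknown criterion {name!r}; expected one of {CRITERIA}")


def score(
    name: str,
    mse: float,
    k: int,
    n: int,
    gram_logdet: float | None = None,
) -> ScoredModel:
    """Score a model under the named criterion and wrap the result."""
    value = comparison_criterion(name, mse, k, n, gram_logdet=gram_logdet)
    return ScoredModel(n=int(n), k=int(k), mse=float(mse), score=value, criterion_name=name.lower())
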