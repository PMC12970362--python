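"""Weak-form (Galerkin-projected) regression problems.

Instead of differentiating noisy data, the dynamics are multiplied by a
compactly supported polynomial test function

    w(t) = C_q * (t2 - t)^q * (t - t1)^q,      t in [t1, t2],

and integrated by parts, which moves every derivative onto the analytically
differentiable ``w``.  For an ODE ``x' = Theta(x) Xi`` the projected problem
over one window is ``-<x * w'> = <Theta(x)>_w Xi``; sliding the window along
the record and stacking the rows yields the regression problem handed to the
sparse solver.  For PDEs the test function is a separable product of one bump
per dimension and each spatial derivative of order ``b`` contributes a factor
``(-1)^b`` with the derivative applied to the spatial bump.

``C_q`` is fixed by trapezoidal quadrature on the window's sample grid so
that ``<1>_w = 1`` exactly in floating point; the same constant scales every
derivative of ``w``.  An SSIM-based selector picks the largest integration
window that does not visibly distort the signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.metrics import structural_similarity

from .model_library import LibrarySpec, build_pointwise_library, pde_term_specs, _spatial_derivative
from .sparse_regression import LibraryMatrix, TargetMatrix
from .simulators import TrajectoryDataset

__all__ = [
    "TestFunction",
    "WeakFormProblem",
    "weak_inner_product",
    "build_weak_problem_ode",
    "build_weak_problem_pde",
    "select_window_ssim",
]

logger = logging.getLogger(__name__)


def _bump_derivative(s: np.ndarray, q: float, order: int) -> np.ndarray:
    """d^order/ds^order of g(s) = s^q (1-s)^q on [0, 1] (Leibniz expansion)."""
    out = np.zeros_like(s)
    for a in range(order + 1):
        fall1 = math.prod(q - i for i in range(a))            # q falling a
        fall2 = math.prod(q - i for i in range(order - a))    # q falling (order-a)
        sign = (-1.0) ** (order - a)
        with np.errstate(invalid="ignore"):
            term = (math.comb(order, a) * fall1 * fall2 * sign
                    * s ** (q - a) * (1.0 - s) ** (q - order + a))
        out += np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0)
    return out


@dataclass
class TestFunction:
    """Polynomial bump ``C_q (t2-t)^q (t-t1)^q`` on ``[t1, t2]``.

    ``normalization`` (``C_q``) is chosen so the trapezoidal quadrature of the
    bump over the window's uniform sample grid equals one.
    """

    q: float
    t1: float
    t2: float
    normalization: float = 1.0

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("q must be positive")
        if not self.t1 < self.t2:
            raise ValueError("window endpoints must satisfy t1 < t2")

    @classmethod
    def for_grid(cls, t_window: np.ndarray, q: float) -> "TestFunction":
        """Build a normalized test function on a uniform sample window."""
        t_window = np.asarray(t_window, dtype=float)
        if t_window.size < 3:
            raise ValueError("window must contain at least 3 samples")
        tf = cls(q=q, t1=float(t_window[0]), t2=float(t_window[-1]))
        raw = tf._raw(t_window, 0)
        tf.normalization = 1.0 / np.trapezoid(raw, t_window)
        return tf

    def _raw(self, t: np.ndarray, order: int) -> np.ndarray:
        length = self.t2 - self.t1
        s = (np.asarray(t, dtype=float) - self.t1) / length
        return length ** (2.0 * self.q - order) * _bump_derivative(s, self.q, order)

    def __call__(self, t: np.ndarray, order: int = 0) -> np.ndarray:
        """Evaluate d^order w / dt^order at times ``t``."""
        if order > math.floor(self.q):
            raise ValueError(f"derivative order {order} exceeds floor(q)={math.floor(self.q)}")
        return self.normalization * self._raw(t, order)


@dataclass
class WeakFormProblem:
    """Stacked weak-form library and targets, one row per window placement."""

    theta_weak: LibraryMatrix
    y_weak: TargetMatrix
    window_size: int | tuple[int, ...]
    stride: int | tuple[int, ...]

    def __post_init__(self) -> None:
        if self.theta_weak.values.shape[0] != self.y_weak.values.shape[0]:
            raise ValueError("weak library and targets must have equal row counts")


def weak_inner_product(
    f: np.ndarray,
    tf: TestFunction,
    derivative_order_on_w: int = 0,
    t_grid: np.ndarray | None = None,
) -> float:
    """Trapezoidal quadrature of ``f`` against a derivative of the bump.

    ``f`` must be sampled on a uniform grid spanning ``[t1, t2]`` (pass the
    grid explicitly, or it is reconstructed from the endpoints).  Sign
    conventions from integration by parts are the caller's responsibility
    (e.g. first-order targets use ``-<x * w'>``).
    """
    f = np.asarray(f, dtype=float)
    if f.size < 3:
        raise ValueError("window must contain at least 3 samples")
    if t_grid is None:
        t_grid = np.linspace(tf.t1, tf.t2, f.size)
    w = tf(t_grid, derivative_order_on_w)
    return float(np.trapezoid(f * w, t_grid))


def _trapezoid_weights(n: int, dt: float) -> np.ndarray:
    w = np.full(n, dt)
    w[0] = w[-1] = 0.5 * dt
    return w


def _window_weights(window_size: int, dt: float, q: float, orders: list[int],
                    refine: int = 32):
    """Quadrature weights: analytic bump derivatives against hat functions.

    The inner product ``<f * w^(b)>`` treats the sampled ``f`` as piecewise
    linear (trapezoidal in ``f``), but the known polynomial ``w^(b)`` — which
    oscillates strongly for high derivative orders — is integrated against
    each linear hat on a ``refine``-times finer grid.  Sampling ``w^(b)``
    only at the data points would leak large quadrature errors into the
    high-derivative library columns.  All orders share the normalization
    that makes the order-0 weights sum to one.
    """
    n = window_size
    length = (n - 1) * dt
    tf = TestFunction(q=q, t1=0.0, t2=length)
    n_fine = (n - 1) * refine + 1
    t_fine = np.linspace(0.0, length, n_fine)
    raw0 = tf._raw(t_fine, 0)
    norm = 1.0 / np.trapezoid(raw0, t_fine)
    idx = np.arange(n_fine)
    out = {}
    for order in orders:
        if order > math.floor(q):
            raise ValueError(f"derivative order {order} exceeds floor(q)={math.floor(q)}")
        g = norm * tf._raw(t_fine, order)
        w = np.zeros(n)
        for i in range(n):
            phi = np.clip(1.0 - np.abs(idx - i * refine) / refine, 0.0, None)
            w[i] = np.trapezoid(g * phi, t_fine)
        out[order] = w
    return out


def build_weak_problem_ode(
    data: TrajectoryDataset,
    library_spec: LibrarySpec | None = None,
    window_size: int = 41,
    stride: int | None = None,
    q: float | None = None,
    target_indices: list[int] | None = None,
    states: np.ndarray | None = None,
    library: LibraryMatrix | None = None,
) -> WeakFormProblem:
    """Galerkin-project an ODE discovery problem.

    One row per window placement, windows never straddling segment
    boundaries: the target row is ``-<x_i * w'>`` per state variable, the
    library row is ``<theta_j(X)>_w`` per candidate term.  ``states``
    overrides ``data.states`` (e.g. when a velocity column was appended by
    finite differences) and ``library`` may supply a pre-built pointwise
    library matrix instead of a spec.
    """
    t = data.time_grid
    for a, b in data.segments():
        if b - a >= 2:
            steps = np.diff(t[a:b])
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
                raise ValueError("time grid must be uniform within each segment")
    if states is None:
        states = data.states
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if library is None:
        if library_spec is None:
            library_spec = LibrarySpec(kind="polynomial")
        names = data.variable_names or None
        library = build_pointwise_library(states, library_spec, names=names)
    theta = library.values
    if stride is None:
        stride = max(1, window_size // 2)
    if q is None:
        q = 3.0  # max(3, highest transferred derivative order 1 + 2)
    dt = data.dt
    wts = _window_weights(window_size, dt, q, [0, 1])
    if target_indices is None:
        target_indices = list(range(states.shape[1]))

    theta_rows, y_rows = [], []
    for a, b in data.segments():
        seg_len = b - a
        if seg_len < window_size:
            continue
        starts = a + np.arange(0, seg_len - window_size + 1, stride)
        idx = starts[:, None] + np.arange(window_size)[None, :]
        theta_rows.append(np.einsum("t,ptl->pl", wts[0], theta[idx]))
        y_rows.append(-np.einsum("t,pti->pi", wts[1], states[idx][:, :, target_indices]))
    if not theta_rows:
        raise ValueError("no window placement fits inside any trajectory segment")
    names = data.variable_names or [f"x{i}" for i in range(states.shape[1])]
    y_labels = [f"d({names[i]})/dt" for i in target_indices]
    return WeakFormProblem(
        theta_weak=LibraryMatrix(np.vstack(theta_rows), list(library.term_labels)),
        y_weak=TargetMatrix(np.vstack(y_rows), y_labels),
        window_size=window_size,
        stride=stride,
    )


def build_weak_problem_pde(
    data: TrajectoryDataset,
    library_spec: LibrarySpec | None = None,
    window_sizes: tuple[int, int] = (17, 33),
    stride: tuple[int, int] | None = None,
    q: float | None = None,
) -> WeakFormProblem:
    """Galerkin-project a PDE discovery problem (one time + one space dim).

    The test function is ``w(t, x) = w_t(t) * w_x(x)``; each spatial
    derivative of order ``b`` on a library term in conservative form is moved
    onto ``w_x`` with sign ``(-1)^b``, and the time-derivative target becomes
    ``-<u * w_t' * w_x>``.  Integration is 2-D trapezoidal.
    """
    if data.space_grid is None:
        raise ValueError("dataset has no spatial grid")
    fields = data.states
    if fields.ndim == 2:
        fields = fields[None]
    n_fields, nt, nx = fields.shape
    if library_spec is None:
        library_spec = LibrarySpec(kind="pde")
    if q is None:
        q = float(max(3, library_spec.max_derivative_order + 2))
    if library_spec.max_derivative_order > math.floor(q):
        raise ValueError("spatial derivative order exceeds floor(q)")
    wt_size, wx_size = window_sizes
    if stride is None:
        stride = (max(1, wt_size // 2), max(1, wx_size // 2))
    st_t, st_x = stride
    dt, dx = data.dt, data.dx
    wt = _window_weights(wt_size, dt, q, [0, 1])
    orders = list(range(library_spec.max_derivative_order + 1))
    wx = _window_weights(wx_size, dx, q, orders)

    terms = pde_term_specs(library_spec, n_fields, data.variable_names or None)
    derivs = {}
    if library_spec.full_products:
        for f in range(n_fields):
            for b in range(1, library_spec.max_derivative_order + 1):
                derivs[(f, b)] = _spatial_derivative(fields[f], dx, b)

    def project(arr2d: np.ndarray, w_time: np.ndarray, w_space: np.ndarray) -> np.ndarray:
        view = sliding_window_view(arr2d, (wt_size, wx_size))[::st_t, ::st_x]
        return np.einsum("a,b,ijab->ij", w_time, w_space, view).ravel()

    cols, labels = [], []
    for exp, f, b, conv, label in terms:
        if conv:
            cols.append(-0.5 * project(fields[f] ** 2, wt[0], wx[1]))
        elif b and sum(exp) == 0:
            cols.append((-1.0) ** b * project(fields[f], wt[0], wx[b]))
        elif b:  # full-product term: pointwise derivative, order-0 projection
            base = np.ones((nt, nx))
            for g, e in enumerate(exp):
                if e:
                    base = base * fields[g] ** e
            cols.append(project(base * derivs[(f, b)], wt[0], wx[0]))
        else:
            base = np.ones((nt, nx))
            for g, e in enumerate(exp):
                if e:
                    base = base * fields[g] ** e
            cols.append(project(base, wt[0], wx[0]))
        labels.append(label)

    names = data.variable_names or ([f"u{i}" for i in range(n_fields)] if n_fields > 1 else ["u"])
    y_cols = [-project(fields[f], wt[1], wx[0]) for f in range(n_fields)]
    y_labels = [f"d({names[f]})/dt" for f in range(n_fields)]
    return WeakFormProblem(
        theta_weak=LibraryMatrix(np.column_stack(cols), labels),
        y_weak=TargetMatrix(np.column_stack(y_cols), y_labels),
        window_size=window_sizes,
        stride=stride,
    )


def weak_smooth(signal: np.ndarray, window_size: int, q: float = 3.0) -> np.ndarray:
    """Order-0 weak projection of a signal, resampled to the original grid.

    This is the moving weighted average implied by the test-function window
    (reflective boundary handling); used by the SSIM window selector.
    """
    signal = np.asarray(signal, dtype=float)
    wts = _window_weights(window_size, 1.0, q, [0])[0]
    pad = window_size // 2
    padded = np.pad(signal, pad, mode="reflect")
    sm = np.convolve(padded, wts[::-1], mode="valid")
    return sm[: signal.size]


def select_window_ssim(
    signal: np.ndarray,
    candidate_window_sizes: list[int],
    q: float = 3.0,
    ssim_floor: float = 0.95,
    mode: str = "threshold",
) -> int:
    """Pick an integration window that minimally distorts the signal.

    For each candidate size, the signal is compared (via the structural
    similarity index) with its order-0 weak projection.  In ``threshold``
    mode the largest candidate with SSIM >= ``ssim_floor`` wins — the widest
    window that still preserves the signal's structure; ``max`` mode returns
    the SSIM-maximizing candidate.  If nothing passes the floor the smallest
    candidate is returned with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    cands = sorted(int(c) for c in candidate_window_sizes)
    if any(c >= signal.size for c in cands):
        raise ValueError("candidate windows must be smaller than the signal")
    rng_val = float(np.ptp(signal))
    if rng_val == 0.0:
        return cands[-1]
    ssims = []
    for c in cands:
        sm = weak_smooth(signal, c, q)
        ssims.append(structural_similarity(signal, sm, data_range=rng_val))
    if mode == "max":
        return cands[int(np.argmax(ssims))]
    passing = [c for c, s in zip(cands, ssims) if s >= ssim_floor]
    if passing:
        return passing[-1]
    logger.warning("no candidate window reached SSIM >= %.3f; using the smallest (%d)",
                   ssim_floor, cands[0])
    return cands[0]
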