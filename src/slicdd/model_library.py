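"""Candidate-term library construction.

Four families of libraries are supported:

* ``polynomial`` — all monomials of the state variables up to a total degree,
  in graded-lexicographic order;
* ``fourier`` — ``{1, sin(h*x), cos(h*x)}`` per state variable up to a maximum
  harmonic;
* ``pde`` — state-variable powers, single spatial derivatives, and a
  nonlinear convective term ``u*du/dx = 0.5*d(u^2)/dx`` (kept in conservative
  form so the weak formulation can move the derivative onto the test
  function);
* ``kernel`` — aggregation-kernel components in a pair of cluster indices
  ``(i, j)`` and a fractal dimension ``df``.

A 4th-order central-difference helper estimates velocities when the library
must contain nonlinear functions of a derivative of the observed signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .sparse_regression import LibraryMatrix

__all__ = [
    "LibrarySpec",
    "polynomial_library",
    "fourier_library",
    "pde_library",
    "pde_term_specs",
    "finite_difference_states",
    "kernel_component_library",
    "build_pointwise_library",
]


@dataclass
class LibrarySpec:
    """Declarative description of a candidate-term library."""

    kind: str = "polynomial"  # polynomial | fourier | pde | kernel
    max_poly_order: int = 3
    include_constant: bool = True
    max_derivative_order: int = 4
    fourier_order: int = 5
    convective: bool = True
    full_products: bool = False  # pde: include u^a * d^b u products, a,b >= 1

    def __post_init__(self) -> None:
        if self.kind not in ("polynomial", "fourier", "pde", "kernel"):
            raise ValueError(f"unknown library kind {self.kind!r}")
        if min(self.max_poly_order, self.max_derivative_order, self.fourier_order) < 0:
            raise ValueError("library orders must be nonnegative")


# ---------------------------------------------------------------------------
# polynomial / fourier libraries (ODE state variables)
# ---------------------------------------------------------------------------

def _monomial_exponents(m: int, max_order: int, include_constant: bool):
    """Exponent tuples of total degree <= max_order, graded-lex order."""
    exps = []
    lo = 0 if include_constant else 1
    for deg in range(lo, max_order + 1):
        combos = sorted(
            {tuple(np.bincount(c, minlength=m)) for c in
             combinations_with_replacement(range(m), deg)},
            reverse=True,
        )
        exps.extend([tuple(int(e) for e in c) for c in combos])
    return exps


def _monomial_label(exp, names) -> str:
    if sum(exp) == 0:
        return "1"
    parts = []
    for e, nm in zip(exp, names):
        if e == 1:
            parts.append(nm)
        elif e > 1:
            parts.append(f"{nm}^{e}")
    return "*".join(parts)


def polynomial_library(
    states: np.ndarray,
    max_order: int = 3,
    include_constant: bool = True,
    names: list[str] | None = None,
) -> LibraryMatrix:
    """All monomials of total degree <= ``max_order`` in the state variables."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[1] == 0:
        raise ValueError("need at least one state variable")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    n, m = states.shape
    if names is None:
        names = [f"x{i}" for i in range(m)] if m > 2 else ["x", "v"][:m]
    exps = _monomial_exponents(m, max_order, include_constant)
    cols = [np.prod(states**np.array(e), axis=1) for e in exps]
    labels = [_monomial_label(e, names) for e in exps]
    return LibraryMatrix(np.column_stack(cols), labels)


def fourier_library(
    states: np.ndarray,
    max_harmonic: int = 5,
    names: list[str] | None = None,
) -> LibraryMatrix:
    """``{1, sin(h*x), cos(h*x)}``, ``h = 1..max_harmonic``, per variable."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if max_harmonic < 1:
        raise ValueError("max_harmonic must be >= 1")
    n, m = states.shape
    if names is None:
        names = [f"x{i}" for i in range(m)] if m > 1 else ["x"]
    cols = [np.ones(n)]
    labels = ["1"]
    for v in range(m):
        for h in range(1, max_harmonic + 1):
            cols.append(np.sin(h * states[:, v]))
            labels.append(f"sin({h}{names[v]})" if h > 1 else f"sin({names[v]})")
            cols.append(np.cos(h * states[:, v]))
            labels.append(f"cos({h}{names[v]})" if h > 1 else f"cos({names[v]})")
    return LibraryMatrix(np.column_stack(cols), labels)


def build_pointwise_library(
    states: np.ndarray,
    spec: LibrarySpec,
    names: list[str] | None = None,
) -> LibraryMatrix:
    """Evaluate a polynomial or Fourier spec on sampled state variables."""
    if spec.kind == "polynomial":
        return polynomial_library(states, spec.max_poly_order, spec.include_constant, names)
    if spec.kind == "fourier":
        return fourier_library(states, spec.fourier_order, names)
    raise ValueError(f"spec kind {spec.kind!r} is not a pointwise state library")


# ---------------------------------------------------------------------------
# PDE library
# ---------------------------------------------------------------------------

def pde_term_specs(spec: LibrarySpec, n_fields: int = 1, names: list[str] | None = None):
    """Enumerate PDE library terms as ``(poly_exponents, field, deriv_order,
    convective, label)`` tuples.

    ``poly_exponents`` is a tuple of powers (one per field) for pure
    polynomial terms (``deriv_order`` 0); derivative terms carry the field
    index they differentiate.  Convective terms are ``0.5 * d(u^2)/dx`` per
    field.  By default the library is the union of these three groups; with
    ``full_products`` every product of a monomial with a single derivative is
    included as well.
    """
    if names is None:
        names = ["u"] if n_fields == 1 else [f"u{i}" for i in range(n_fields)]
    terms = []
    for exp in _monomial_exponents(n_fields, spec.max_poly_order, spec.include_constant):
        terms.append((exp, None, 0, False, _monomial_label(exp, names)))
    zero = tuple([0] * n_fields)
    for f in range(n_fields):
        for b in range(1, spec.max_derivative_order + 1):
            terms.append((zero, f, b, False, f"d{'x'*b}({names[f]})"))
    if spec.convective:
        for f in range(n_fields):
            terms.append((zero, f, 1, True, f"{names[f]}*dx({names[f]})"))
    if spec.full_products:
        for exp in _monomial_exponents(n_fields, spec.max_poly_order, False):
            for f in range(n_fields):
                for b in range(1, spec.max_derivative_order + 1):
                    lab = f"{_monomial_label(exp, names)}*d{'x'*b}({names[f]})"
                    terms.append((exp, f, b, False, lab))
    return terms


def _spatial_derivative(u: np.ndarray, dx: float, order: int) -> np.ndarray:
    """Central-difference spatial derivative along the last axis."""
    if u.shape[-1] < 2 * order + 1:
        raise ValueError(f"grid too small for derivative order {order}")
    out = u
    for _ in range(order):
        out = np.gradient(out, dx, axis=-1, edge_order=2)
    return out


def pde_library(
    fields: np.ndarray,
    dx: float,
    max_derivative_order: int = 4,
    max_poly_order: int = 3,
    convective: bool = True,
    include_constant: bool = True,
    names: list[str] | None = None,
    full_products: bool = False,
) -> LibraryMatrix:
    """Pointwise (strong-form) PDE library from field snapshots.

    ``fields`` has shape ``(nt, nx)`` for one field or ``(n_fields, nt, nx)``.
    Spatial derivatives are estimated by central differences; each library
    column is flattened to one value per space-time sample.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim == 2:
        fields = fields[None]
    n_fields = fields.shape[0]
    spec = LibrarySpec(
        kind="pde",
        max_poly_order=max_poly_order,
        include_constant=include_constant,
        max_derivative_order=max_derivative_order,
        convective=convective,
        full_products=full_products,
    )
    derivs = {}
    for f in range(n_fields):
        for b in range(1, max_derivative_order + 1):
            derivs[(f, b)] = _spatial_derivative(fields[f], dx, b)
    cols, labels = [], []
    for exp, f, b, conv, label in pde_term_specs(spec, n_fields, names):
        if conv:
            col = 0.5 * _spatial_derivative(fields[f] ** 2, dx, 1)
        else:
            col = np.ones_like(fields[0])
            for g, e in enumerate(exp):
                if e:
                    col = col * fields[g] ** e
            if b:
                col = col * derivs[(f, b)]
        cols.append(col.ravel())
        labels.append(label)
    return LibraryMatrix(np.column_stack(cols), labels)


# ---------------------------------------------------------------------------
# finite-difference state augmentation
# ---------------------------------------------------------------------------

def finite_difference_states(x: np.ndarray, dt: float) -> tuple[np.ndarray, slice]:
    """4th-order central-difference derivative of a uniformly sampled signal.

    Uses the interior stencil ``(-f[i+2] + 8 f[i+1] - 8 f[i-1] + f[i-2]) /
    (12 dt)``; the two samples at each boundary (where the stencil does not
    fit) are trimmed.  Returns the interior derivative and the slice of the
    original samples it aligns with.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples for the 4th-order stencil")
    d = (-x[4:] + 8.0 * x[3:-1] - 8.0 * x[1:-3] + x[:-4]) / (12.0 * dt)
    return d, slice(2, n - 2)


# ---------------------------------------------------------------------------
# aggregation-kernel component library
# ---------------------------------------------------------------------------

# Component list in the pair indices (i, j) and fractal dimension df.  The
# grouping of the two mixed third-order items is read as (i^2 j)^(1/df) and
# (i j^2)^(1/df).  Alternative readings that were considered and rejected:
#   i^2 * j^(1/df)      -- breaks the homogeneity shared by every other term
#   i * j^(2/df)        -- same objection
# Every third-order term appears a second time multiplied by the prefactor
# |i^(1/df) - j^(1/df)| (shear-like kernels vanish for equal-size clusters).


def kernel_component_library(
    i: np.ndarray,
    j: np.ndarray,
    df: float,
) -> LibraryMatrix:
    """Kernel-component basis evaluated at cluster-index pairs ``(i, j)``.

    ``df`` is the fractal dimension of the aggregates and must lie in the
    physical range [1.5, 3].  Callers wanting a symmetric regression target
    should evaluate on a pair list already concatenated with its swapped
    counterpart.
    """
    if not 1.5 <= df <= 3.0:
        raise ValueError(f"fractal dimension df={df} outside the physical range [1.5, 3]")
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    if i.shape != j.shape:
        raise ValueError("index arrays must have equal shapes")
    if np.any(i < 1) or np.any(j < 1):
        raise ValueError("cluster indices must be >= 1")
    e = 1.0 / df
    pref = np.abs(i**e - j**e)
    cols = [
        (np.ones_like(i), "1"),
        (i**e, "i^(1/df)"),
        (j**e, "j^(1/df)"),
        ((i / j) ** e, "(i/j)^(1/df)"),
        ((j / i) ** e, "(j/i)^(1/df)"),
        ((i**2 * j) ** e, "(i^2*j)^(1/df)"),
        ((i * j**2) ** e, "(i*j^2)^(1/df)"),
        (j ** (3.0 * e), "j^(3/df)"),
        (pref * i ** (3.0 * e), "|i^(1/df)-j^(1/df)|*i^(3/df)"),
        (pref * (i**2 * j) ** e, "|i^(1/df)-j^(1/df)|*(i^2*j)^(1/df)"),
        (pref * (i * j**2) ** e, "|i^(1/df)-j^(1/df)|*(i*j^2)^(1/df)"),
        (pref * j ** (3.0 * e), "|i^(1/df)-j^(1/df)|*j^(3/df)"),
    ]
    values = np.column_stack([c for c, _ in cols])
    labels = [lab for _, lab in cols]
    return LibraryMatrix(values, labels)
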