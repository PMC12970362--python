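"""Finite-size Smoluchowski aggregation and kernel discovery.

The truncated coagulation equations for cluster concentrations ``n_k`` are

    dn_k/dt = 1/2 * sum_{i+j=k} K_ij n_i n_j  -  n_k * sum_j K_kj n_j,

with a symmetric, nonnegative kernel ``K_ij`` giving the rate at which an
i-mer and a j-mer merge.  Formation into sizes above the truncation ``kmax``
is dropped; destruction of tracked sizes by such events is retained.

Kernel discovery proceeds in two stages.  First the kernel values over the
(i, j) grid are estimated from the cluster time series by minimizing the L2
misfit between simulated and observed trajectories (a collocation estimate —
the dynamics are linear in the kernel entries — provides the starting point,
then a bounded trajectory-matching least-squares refines it).  Second, the
estimated kernel values, concatenated with their index-swapped mirror to
encourage symmetry, become the target of a sparse regression over a library
of physical kernel components in ``(i, j)`` and the fractal dimension ``df``;
sparse regression at fixed ``df`` alternates with a bounded simulated-
annealing update of ``df`` in [1.5, 3] until ``df`` converges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, nnls

from .model_library import kernel_component_library
from .sparse_regression import SparseModel, TargetMatrix, auto_prune

__all__ = [
    "ClusterTimeseries",
    "KernelEstimate",
    "KernelModel",
    "simulate_smoluchowski",
    "synthetic_cluster_data",
    "estimate_kernel",
    "discover_kernel",
    "constant_kernel_closed_form",
]


@dataclass
class ClusterTimeseries:
    """Concentrations ``n_k(t)``: rows = time points, columns = k-mers (k>=1)."""

    counts: np.ndarray
    time_grid: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] < 2:
            raise ValueError("counts must be (T, kmax) with kmax >= 2")
        if np.any(self.counts < -1e-12):
            raise ValueError("cluster counts must be nonnegative")

    @property
    def kmax(self) -> int:
        return self.counts.shape[1]


@dataclass
class KernelEstimate:
    """Kernel values estimated on the upper-triangular (i, j) grid."""

    i_idx: np.ndarray
    j_idx: np.ndarray
    values: np.ndarray
    converged: bool = True

    def symmetrized(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pairs concatenated with the index-swapped mirror (regression target)."""
        i = np.concatenate([self.i_idx, self.j_idx])
        j = np.concatenate([self.j_idx, self.i_idx])
        v = np.concatenate([self.values, self.values])
        return i, j, v


@dataclass
class KernelModel:
    """Discovered kernel: sparse component coefficients + fractal dimension."""

    component_coefficients: SparseModel
    df: float
    kernel_values: np.ndarray
    score: float = np.nan
    criterion_name: str = "slic"
    converged: bool = True
    restarts_tried: int = 1

    @property
    def active_components(self) -> list[str]:
        c = self.component_coefficients
        return [lab for lab, on in zip(c.term_labels, c.support[:, 0]) if on]


def _rhs_factory(kernel: np.ndarray, kmax: int):
    sizes = np.arange(1, kmax + 1)
    sum_idx = (sizes[:, None] + sizes[None, :]).ravel()

    def rhs(t, n):
        outer = kernel * np.outer(n, n)
        gain = 0.5 * np.bincount(sum_idx, weights=outer.ravel(),
                                 minlength=2 * kmax + 2)[1:kmax + 1]
        loss = n * (kernel @ n)
        return gain - loss

    return rhs


def simulate_smoluchowski(
    kernel_values: np.ndarray,
    initial_counts: np.ndarray,
    time_grid: np.ndarray,
    kmax: int | None = None,
) -> ClusterTimeseries:
    """Integrate the truncated coagulation equations on ``time_grid``."""
    kernel = np.asarray(kernel_values, dtype=float)
    n0 = np.asarray(initial_counts, dtype=float)
    if kmax is None:
        kmax = n0.size
    if kernel.shape != (kmax, kmax):
        raise ValueError(f"kernel must be ({kmax}, {kmax})")
    if np.any(kernel < 0):
        raise ValueError("kernel entries must be nonnegative")
    if not np.allclose(kernel, kernel.T):
        raise ValueError("kernel must be symmetric")
    if np.any(n0 < 0):
        raise ValueError("initial counts must be nonnegative")
    t = np.asarray(time_grid, dtype=float)
    sol = solve_ivp(_rhs_factory(kernel, kmax), (t[0], t[-1]), n0, t_eval=t,
                    method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"coagulation integration failed: {sol.message}")
    return ClusterTimeseries(counts=np.clip(sol.y.T, 0.0, None), time_grid=t)


def constant_kernel_closed_form(
    k0: float, n_total: float, k: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Classical monodisperse-start solution for a constant kernel.

    ``n_k(t) = N0 (t/tau)^(k-1) / (1 + t/tau)^(k+1)`` with ``tau = 2/(K0 N0)``.
    Returns an array of shape ``(len(t), len(k))``.
    """
    tau = 2.0 / (k0 * n_total)
    s = (np.asarray(t, dtype=float) / tau)[:, None]
    kk = np.asarray(k, dtype=float)[None, :]
    return n_total * s ** (kk - 1.0) / (1.0 + s) ** (kk + 1.0)


# ---------------------------------------------------------------------------
# kernel estimation from data
# ---------------------------------------------------------------------------

def _upper_pairs(k_fit: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(k_fit)
    return iu + 1, ju + 1  # 1-based cluster sizes


def _pairs_to_matrix(values: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray,
                     kmax: int) -> np.ndarray:
    kernel = np.zeros((kmax, kmax))
    kernel[i_idx - 1, j_idx - 1] = values
    kernel[j_idx - 1, i_idx - 1] = values
    return kernel


def _collocation_design(data: ClusterTimeseries, i_idx, j_idx):
    """Design matrix of dn/dt against the kernel parameters (linear system)."""
    counts, t = data.counts, data.time_grid
    kmax = data.kmax
    dndt = np.gradient(counts, t, axis=0)
    n_par = i_idx.size
    rows = counts.shape[0] * kmax
    design = np.zeros((rows, n_par))
    for p, (ip, jp) in enumerate(zip(i_idx, j_idx)):
        contrib = np.zeros((counts.shape[0], kmax))
        prod = counts[:, ip - 1] * counts[:, jp - 1]
        gain = prod if ip != jp else 0.5 * prod
        if ip + jp <= kmax:
            contrib[:, ip + jp - 1] += gain
        contrib[:, ip - 1] -= counts[:, ip - 1] * counts[:, jp - 1]
        if jp != ip:
            contrib[:, jp - 1] -= counts[:, jp - 1] * counts[:, ip - 1]
        design[:, p] = contrib.ravel()
    return design, dndt.ravel()


def synthetic_cluster_data(
    kernel: str = "constant",
    k0: float = 0.8,
    df: float = 2.0,
    amplitude: float = 0.4,
    kmax: int = 6,
    t_max: float = 3.0,
    n_times: int = 31,
    n_initial_conditions: int = 4,
    seed: int = 0,
) -> tuple[list[ClusterTimeseries], np.ndarray]:
    """Generate a seeded ensemble of cluster-count trajectories.

    Emulates repeated aggregation experiments started from different initial
    size distributions (a monodisperse run plus seeded random mixtures), all
    governed by one kernel: ``constant`` (``K_ij = k0``) or ``shear`` — the
    size-ratio kernel ``amplitude * ((i/j)^(1/df) + (j/i)^(1/df))``.  Returns
    the trajectory list and the true kernel matrix.  Distinct initial
    compositions probe independent flux combinations, which is what makes
    the pairwise kernel identifiable from the ensemble.
    """
    sizes = np.arange(1, kmax + 1, dtype=float)
    if kernel == "constant":
        kern = np.full((kmax, kmax), k0)
    elif kernel == "shear":
        ii, jj = np.meshgrid(sizes, sizes, indexing="ij")
        kern = amplitude * ((ii / jj) ** (1.0 / df) + (jj / ii) ** (1.0 / df))
    else:
        raise ValueError(f"unknown kernel kind {kernel!r}")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_times)
    geometric = np.exp(-np.arange(kmax) / 2.0)
    binary = np.zeros(kmax)
    binary[0] = binary[kmax // 2] = 0.5
    panel = [np.eye(kmax)[0] * 1.0,          # monodisperse
             np.full(kmax, 1.0 / kmax),      # uniform
             geometric / geometric.sum(),    # geometric decay
             binary]                         # two-component mix
    ics = panel[:n_initial_conditions]
    for _ in range(n_initial_conditions - len(ics)):
        ics.append(rng.dirichlet(np.ones(kmax)))
    runs = [simulate_smoluchowski(kern, n0, t, kmax) for n0 in ics]
    return runs, kern


def _as_runs(data) -> list[ClusterTimeseries]:
    return list(data) if isinstance(data, (list, tuple)) else [data]


def estimate_kernel(
    data,
    kmax: int | None = None,
    k_fit: int | None = None,
    max_nfev: int = 300,
    ridge: float = 1e-8,
) -> KernelEstimate:
    """Estimate kernel values by trajectory matching.

    ``data`` is a single :class:`ClusterTimeseries` or a list of runs from
    different initial conditions (strongly recommended: one run explores a
    single path through composition space and leaves many pairwise rates
    nearly unidentifiable).  The upper triangle of ``K`` up to ``k_fit``
    (default: all tracked sizes) is parameterized and mirrored; a
    nonnegative collocation solve (the coagulation dynamics are linear in
    the kernel) initializes a bounded least-squares minimization of the L2
    trajectory misfit.  A light ridge penalty pulls entries the data cannot
    constrain to zero instead of letting them wander.  Non-convergence is
    flagged on the returned estimate rather than raised.
    """
    runs = _as_runs(data)
    if any(r.time_grid.size < 3 for r in runs):
        raise ValueError("need at least 3 time points per run")
    if kmax is None:
        kmax = runs[0].kmax
    if k_fit is None:
        k_fit = kmax
    i_idx, j_idx = _upper_pairs(k_fit)
    n_par = i_idx.size
    blocks = [_collocation_design(r, i_idx, j_idx) for r in runs]
    design = np.vstack([b[0] for b in blocks])
    target = np.concatenate([b[1] for b in blocks])
    col_scale = max(float(np.abs(design).max()), 1e-30)
    design_r = np.vstack([design, np.sqrt(ridge) * col_scale * np.eye(n_par)])
    target_r = np.concatenate([target, np.zeros(n_par)])
    x0, _ = nnls(design_r, target_r)

    scale = max(max(float(np.abs(r.counts).max()) for r in runs), 1e-30)
    n_obs = sum(r.counts.size for r in runs)

    def residual(params):
        kernel = _pairs_to_matrix(params, i_idx, j_idx, kmax)
        out = []
        for r in runs:
            try:
                sim = simulate_smoluchowski(kernel, r.counts[0], r.time_grid, kmax)
            except RuntimeError:
                return np.full(n_obs + n_par, 1e6)
            out.append(((sim.counts - r.counts) / scale).ravel())
        out.append(np.sqrt(ridge) * params)
        return np.concatenate(out)

    res = least_squares(residual, np.clip(x0, 0.0, None),
                        bounds=(0.0, np.inf), max_nfev=max_nfev,
                        x_scale="jac", method="trf")
    return KernelEstimate(i_idx=i_idx, j_idx=j_idx, values=res.x,
                          converged=bool(res.status > 0))


# ---------------------------------------------------------------------------
# alternating sparse-regression / fractal-dimension discovery
# ---------------------------------------------------------------------------

def _anneal_df(loss, df0: float, rng: np.random.Generator,
               n_evals: int = 200, t0: float = 1.0, cooling: float = 0.97,
               step: float = 0.4) -> float:
    """Bounded simulated annealing on df in [1.5, 3] with geometric cooling."""
    df, cur = df0, loss(df0)
    best_df, best = df, cur
    temp = t0
    for _ in range(n_evals):
        cand = float(np.clip(df + step * rng.normal(), 1.5, 3.0))
        val = loss(cand)
        if val < cur or rng.random() < np.exp(-(val - cur) / max(temp, 1e-12)):
            df, cur = cand, val
            if val < best:
                best_df, best = cand, val
        temp *= cooling
    return best_df


def discover_kernel(
    data: ClusterTimeseries,
    criterion: str = "slic",
    n_alternations: int = 50,
    restarts: int = 3,
    seed: int = 0,
    k_fit: int | None = None,
    estimate: KernelEstimate | None = None,
    df_tol: float = 1e-4,
) -> KernelModel:
    """Discover the functional form of the aggregation kernel.

    Alternates (a) auto-pruning sparse regression of the estimated kernel
    values onto the kernel-component library at fixed ``df`` with (b) a
    bounded simulated-annealing update of ``df`` minimizing
    ``||K_est - Theta(i, j; df) Xi||^2`` with the regressed coefficients
    held fixed; stops early once ``df`` moves less than ``df_tol``.  The
    whole procedure is restarted from ``restarts`` random initial ``df``
    values and the restart with the best criterion score is returned.
    """
    rng = np.random.default_rng(seed)
    runs = _as_runs(data)
    if estimate is None:
        estimate = estimate_kernel(runs, k_fit=k_fit)
    i_sym, j_sym, k_target = estimate.symmetrized()
    y = TargetMatrix(k_target[:, None], ["K_est"])

    best: KernelModel | None = None
    any_converged = False
    for _ in range(restarts):
        df = float(rng.uniform(1.5, 3.0))
        model, scores = None, None
        for _ in range(n_alternations):
            lib = kernel_component_library(i_sym, j_sym, df)
            model, scores = auto_prune(lib, y, criterion=criterion)
            support = model.support[:, 0]

            # Profile the coefficients over the selected support inside the
            # df loss: holding them at the fixed-df values would pin the loss
            # minimum to the current df and stall the alternation.
            def loss(d, support=support):
                cols = kernel_component_library(i_sym, j_sym, d).values[:, support]
                if cols.size == 0:
                    return float(np.sum(k_target**2))
                coef, *_ = np.linalg.lstsq(cols, k_target, rcond=None)
                return float(np.sum((k_target - cols @ coef) ** 2))

            df_new = _anneal_df(loss, df, rng)
            if abs(df_new - df) < df_tol:
                df = df_new
                break
            df = df_new
        any_converged = True
        kmax = runs[0].kmax
        ii, jj = np.meshgrid(np.arange(1, kmax + 1), np.arange(1, kmax + 1),
                             indexing="ij")
        kv = (kernel_component_library(ii.ravel(), jj.ravel(), df).values
              @ model.coefficients[:, 0]).reshape(kmax, kmax)
        cand = KernelModel(component_coefficients=model, df=df,
                           kernel_values=kv, score=scores[0].score,
                           criterion_name=criterion,
                           converged=estimate.converged)
        if best is None or cand.score < best.score:
            best = cand
    if not any_converged or best is None:
        raise RuntimeError("all kernel-discovery restarts failed to converge")
    best.restarts_tried = restarts
    return best
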