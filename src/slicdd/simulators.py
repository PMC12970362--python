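"""Benchmark ODE/PDE simulators and the Gaussian measurement-noise model.

Six ordinary systems (Lorenz, Rössler, Lotka–Volterra, a Brusselator-type
nonlinear system, Van der Pol, nonlinear pendulum) are integrated with a
high-order adaptive Runge–Kutta method sampled on a fixed grid (time step 0.01,
except 0.001 for Lorenz, Rössler and the Brusselator-type system).  For each
system three initial conditions are drawn from a documented box near the
system's interesting regime and the resulting trajectories are concatenated;
segment boundaries are recorded so that downstream sliding windows never
straddle two trajectories.

Four PDE benchmarks (Burgers, Korteweg–de Vries, Kuramoto–Sivashinsky, the
nonlinear Schrödinger equation) are solved by Fourier collocation with an
exponential time-differencing RK4 stepper (split-step Fourier for NLS) and
resampled onto fixed output grids.

Measurement noise is zero-mean Gaussian, independent per variable, with
standard deviation ``(percent/100) * std(clean variable)``; the clean copy is
retained so classification metrics can be evaluated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TrajectoryDataset",
    "ODE_SYSTEMS",
    "PDE_SYSTEMS",
    "true_rhs_coefficients",
    "simulate_ode",
    "simulate_pde",
    "simulate_duffing_free_decay",
    "add_noise",
]


@dataclass
class TrajectoryDataset:
    """Sampled states of one simulated system.

    For ODEs ``states`` is ``(n, m)`` over a uniform ``time_grid`` and may
    concatenate several initial-condition segments (``segment_boundaries``
    holds the start index of each segment).  For PDEs ``states`` is
    ``(nt, nx)`` (one field) or ``(n_fields, nt, nx)`` and ``space_grid``
    holds the spatial axis.  ``clean_states`` is the noise-free copy.
    """

    states: np.ndarray
    time_grid: np.ndarray
    segment_boundaries: list[int] = field(default_factory=lambda: [0])
    space_grid: np.ndarray | None = None
    noise_percent: float = 0.0
    noise_sigma_per_variable: np.ndarray | None = None
    seed: int | None = None
    system: str = ""
    variable_names: list[str] = field(default_factory=list)
    clean_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.clean_states is None:
            self.clean_states = self.states.copy()

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    @property
    def dx(self) -> float:
        return float(self.space_grid[1] - self.space_grid[0])

    def segments(self):
        """Yield (start, stop) index pairs for each trajectory segment."""
        bounds = list(self.segment_boundaries) + [self.states.shape[0]]
        for a, b in zip(bounds[:-1], bounds[1:]):
            yield a, b


# ---------------------------------------------------------------------------
# ODE benchmark systems
# ---------------------------------------------------------------------------

def _lorenz(t, s):
    x, y, z = s
    return [10.0 * (y - x), x * (28.0 - z) - y, x * y - (8.0 / 3.0) * z]


def _rossler(t, s):
    x, y, z = s
    return [-y - z, x + 0.2 * y, 0.5 + z * (x - 5.7)]


def _lotka_volterra(t, s):
    x, y = s
    return [x - 0.05 * x * y, 0.05 * x * y - y]


def _nonlinear_system(t, s):  # Brusselator-type (a=1, b=3)
    x, y = s
    return [1.0 - 4.0 * x + x**2 * y, 3.0 * x - x**2 * y]


def _van_der_pol(t, s):
    x, v = s
    return [v, -x + 0.81 * x**2 * v]


def _pendulum(t, s):
    x, v = s
    return [v, -4.0 * np.sin(x)]


#: name -> (rhs, dt, timespan, initial-condition box, variable names)
ODE_SYSTEMS = {
    "lorenz": (_lorenz, 0.001, (0.0, 10.0),
               [(-10.0, 10.0), (-10.0, 10.0), (10.0, 30.0)], ["x", "y", "z"]),
    "rossler": (_rossler, 0.001, (0.0, 10.0),
                [(-5.0, 5.0), (-5.0, 5.0), (0.0, 2.0)], ["x", "y", "z"]),
    "lotka_volterra": (_lotka_volterra, 0.01, (0.0, 20.0),
                       [(10.0, 30.0), (10.0, 30.0)], ["x", "y"]),
    "nonlinear_system": (_nonlinear_system, 0.001, (0.0, 10.0),
                         [(0.5, 2.0), (1.0, 4.0)], ["x", "y"]),
    # The cubic velocity coupling feeds energy in, so amplitudes grow; the
    # initial box is kept small enough that trajectories stay finite over the
    # 30-time-unit record.
    "van_der_pol": (_van_der_pol, 0.01, (0.0, 30.0),
                    [(-0.2, 0.2), (-0.2, 0.2)], ["x", "v"]),
    # Below-separatrix energies only (separatrix energy is 8 for v''=-4 sin x).
    "pendulum": (_pendulum, 0.01, (0.0, 20.0),
                 [(-1.5, 1.5), (-1.0, 1.0)], ["x", "v"]),
}


def true_rhs_coefficients(name: str, term_labels: list[str]) -> np.ndarray:
    """Ground-truth coefficient matrix of a benchmark ODE in library coordinates.

    Returns an ``(l, p)`` matrix aligned with ``term_labels`` (one column per
    state-variable derivative; for the pendulum, one column for the velocity
    equation, the only one representable in its Fourier library).
    """
    truth = {
        "lorenz": [{"y": 10.0, "x": -10.0},
                   {"x": 28.0, "x*z": -1.0, "y": -1.0},
                   {"x*y": 1.0, "z": -8.0 / 3.0}],
        "rossler": [{"y": -1.0, "z": -1.0},
                    {"x": 1.0, "y": 0.2},
                    {"1": 0.5, "x*z": 1.0, "z": -5.7}],
        "lotka_volterra": [{"x": 1.0, "x*y": -0.05},
                           {"x*y": 0.05, "y": -1.0}],
        "nonlinear_system": [{"1": 1.0, "x": -4.0, "x^2*y": 1.0},
                             {"x": 3.0, "x^2*y": -1.0}],
        "van_der_pol": [{"v": 1.0},
                        {"x": -1.0, "x^2*v": 0.81}],
        "pendulum": [{"sin(x)": -4.0}],
    }[name]
    xi = np.zeros((len(term_labels), len(truth)))
    for j, eq in enumerate(truth):
        for lab, c in eq.items():
            xi[term_labels.index(lab), j] = c
    return xi


def simulate_ode(
    name: str,
    timespan: tuple[float, float] | None = None,
    dt: float | None = None,
    n_initial_conditions: int = 3,
    seed: int = 0,
) -> TrajectoryDataset:
    """Integrate a named benchmark ODE from seeded random initial conditions.

    Uses RK45 with tight tolerances, sampled on the system's fixed grid; the
    ``n_initial_conditions`` trajectory segments are concatenated.
    """
    if name not in ODE_SYSTEMS:
        raise ValueError(f"unknown ODE system {name!r}; choose from {sorted(ODE_SYSTEMS)}")
    rhs, dt_default, span_default, box, names = ODE_SYSTEMS[name]
    dt = dt_default if dt is None else dt
    timespan = span_default if timespan is None else timespan
    rng = np.random.default_rng(seed)
    t_eval = np.arange(timespan[0], timespan[1] + 0.5 * dt, dt)
    segments, bounds, pos = [], [], 0
    for _ in range(n_initial_conditions):
        ic = [rng.uniform(lo, hi) for lo, hi in box]
        sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), ic, t_eval=t_eval,
                        method="RK45", rtol=1e-12, atol=1e-14)
        if not sol.success:
            raise RuntimeError(f"integration of {name} failed: {sol.message}")
        segments.append(sol.y.T)
        bounds.append(pos)
        pos += len(t_eval)
    states = np.vstack(segments)
    time_grid = np.concatenate([t_eval] * n_initial_conditions)
    return TrajectoryDataset(states=states, time_grid=time_grid,
                             segment_boundaries=bounds, seed=seed,
                             system=name, variable_names=list(names))


def simulate_duffing_free_decay(
    omega0: float = 7.802,
    damping_ratio: float = 0.072 / 7.802,
    beta: float = 0.351,
    x0: float = 3.5,
    v0: float = 0.0,
    timespan: tuple[float, float] = (0.0, 30.0),
    dt: float = 0.01,
) -> TrajectoryDataset:
    """Unforced Duffing oscillator ``x'' = -w0^2 x - 2 zeta w0 x' + beta x^3``."""

    def rhs(t, s):
        x, v = s
        return [v, -(omega0**2) * x - 2.0 * damping_ratio * omega0 * v + beta * x**3]

    t_eval = np.arange(timespan[0], timespan[1] + 0.5 * dt, dt)
    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), [x0, v0], t_eval=t_eval,
                    method="RK45", rtol=1e-12, atol=1e-14)
    return TrajectoryDataset(states=sol.y.T, time_grid=t_eval, system="duffing",
                             variable_names=["x", "v"])


# ---------------------------------------------------------------------------
# PDE benchmark systems (Fourier collocation + ETDRK4 / split-step)
# ---------------------------------------------------------------------------

def _etdrk4(u0, L, nonlin, dt, n_steps, store_every, blowup=1e6):
    """Exponential time-differencing RK4 on Fourier coefficients.

    ``L`` is the diagonal linear operator in Fourier space, ``nonlin`` maps
    Fourier coefficients to the Fourier transform of the nonlinear term.
    Returns the stored physical-space snapshots.
    """
    v = np.fft.fft(u0)
    E = np.exp(dt * L)
    E2 = np.exp(dt * L / 2.0)
    m = 32  # contour points for the phi-function averages
    r = np.exp(1j * np.pi * (np.arange(1, m + 1) - 0.5) / m)
    LR = dt * L[:, None] + r[None, :]
    Q = dt * np.real(np.mean((np.exp(LR / 2.0) - 1.0) / LR, axis=1))
    f1 = dt * np.real(np.mean((-4.0 - LR + np.exp(LR) * (4.0 - 3.0 * LR + LR**2)) / LR**3, axis=1))
    f2 = dt * np.real(np.mean((2.0 + LR + np.exp(LR) * (-2.0 + LR)) / LR**3, axis=1))
    f3 = dt * np.real(np.mean((-4.0 - 3.0 * LR - LR**2 + np.exp(LR) * (4.0 - LR)) / LR**3, axis=1))
    out = [u0.copy()]
    for step in range(1, n_steps + 1):
        Nv = nonlin(v)
        a = E2 * v + Q * Nv
        Na = nonlin(a)
        b = E2 * v + Q * Na
        Nb = nonlin(b)
        c = E2 * a + Q * (2.0 * Nb - Nv)
        Nc = nonlin(c)
        v = E * v + Nv * f1 + 2.0 * (Na + Nb) * f2 + Nc * f3
        if step % store_every == 0:
            u = np.real(np.fft.ifft(v))
            if not np.all(np.isfinite(u)) or np.max(np.abs(u)) > blowup:
                raise RuntimeError("PDE integration blew up (unstable configuration)")
            out.append(u)
    return np.array(out)


def _pde_burgers():
    nx, nt = 256, 101
    x = np.linspace(-8.0, 8.0, nx, endpoint=False)
    t = np.linspace(0.0, 10.0, nt)
    u0 = np.exp(-((x + 2.0) ** 2))
    k = 2.0 * np.pi * np.fft.fftfreq(nx, d=x[1] - x[0])
    L = -0.1 * k**2  # diffusive sign: the stabilizing 0.1*u_xx

    def nonlin(v):
        u = np.real(np.fft.ifft(v))
        return -0.5j * k * np.fft.fft(u * u)

    n_sub = 20
    dt = (t[1] - t[0]) / n_sub
    u = _etdrk4(u0, L, nonlin, dt, n_sub * (nt - 1), n_sub)
    return u, t, x


def _pde_kdv():
    # u_t = -6 u u_x - u_xxx; two-soliton initial condition.
    nx, nt = 512, 201
    x = np.linspace(-20.0, 20.0, nx, endpoint=False)
    t = np.linspace(0.0, 4.0, nt)
    u0 = (2.0 * 1.0**2 / np.cosh(1.0 * (x + 12.0)) ** 2
          + 2.0 * 0.7**2 / np.cosh(0.7 * (x + 2.0)) ** 2)
    k = 2.0 * np.pi * np.fft.fftfreq(nx, d=x[1] - x[0])
    L = 1j * k**3  # from -u_xxx

    def nonlin(v):
        u = np.real(np.fft.ifft(v))
        return -3.0j * k * np.fft.fft(u * u)  # -6 u u_x = -3 (u^2)_x

    n_sub = 200
    dt = (t[1] - t[0]) / n_sub
    u = _etdrk4(u0, L, nonlin, dt, n_sub * (nt - 1), n_sub)
    return u, t, x


def _pde_kuramoto_sivashinsky():
    # u_t = -u u_x - u_xx - u_xxxx on [0, 32 pi]; 300 stored times, dt 0.5.
    nx, nt = 256, 300
    length = 32.0 * np.pi
    x = np.linspace(0.0, length, nx, endpoint=False)
    t = np.arange(nt) * 0.5
    u0 = np.cos(x / 16.0) * (1.0 + np.sin(x / 16.0))
    k = 2.0 * np.pi * np.fft.fftfreq(nx, d=x[1] - x[0])
    L = k**2 - k**4

    def nonlin(v):
        u = np.real(np.fft.ifft(v))
        return -0.5j * k * np.fft.fft(u * u)

    n_sub = 2
    dt = 0.5 / n_sub
    u = _etdrk4(u0, L, nonlin, dt, n_sub * (nt - 1), n_sub)
    return u, t, x


def _pde_nls():
    # i psi_t = -0.5 psi_xx - |psi|^2 psi, Gaussian start, split-step Fourier.
    nx, nt = 512, 501
    x = np.linspace(-5.0, 5.0, nx, endpoint=False)
    t = np.linspace(0.0, np.pi, nt)
    psi = 2.0 * np.exp(-(x**2)).astype(complex)
    k = 2.0 * np.pi * np.fft.fftfreq(nx, d=x[1] - x[0])
    n_sub = 10
    dt = (t[1] - t[0]) / n_sub
    lin_half = np.exp(-0.25j * k**2 * dt)  # half step of psi_t = (i/2) psi_xx
    out = [psi.copy()]
    for it in range(nt - 1):
        for _ in range(n_sub):
            psi = np.fft.ifft(lin_half * np.fft.fft(psi))
            psi = psi * np.exp(1j * np.abs(psi) ** 2 * dt)
            psi = np.fft.ifft(lin_half * np.fft.fft(psi))
        out.append(psi.copy())
    psi_t = np.array(out)
    fields = np.stack([psi_t.real, psi_t.imag])  # (2, nt, nx)
    return fields, t, x


PDE_SYSTEMS = {
    "burgers": _pde_burgers,
    "kdv": _pde_kdv,
    "kuramoto_sivashinsky": _pde_kuramoto_sivashinsky,
    "nls": _pde_nls,
}


def simulate_pde(name: str) -> TrajectoryDataset:
    """Simulate a named benchmark PDE on its fixed space-time output grid."""
    if name not in PDE_SYSTEMS:
        raise ValueError(f"unknown PDE system {name!r}; choose from {sorted(PDE_SYSTEMS)}")
    u, t, x = PDE_SYSTEMS[name]()
    names = ["u"] if u.ndim == 2 else ["u", "v"]
    return TrajectoryDataset(states=u, time_grid=t, space_grid=x,
                             system=name, variable_names=names)


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def add_noise(data: TrajectoryDataset, noise_percent: float, seed: int = 0) -> TrajectoryDataset:
    """Add zero-mean Gaussian noise, sigma = (percent/100)*std per variable.

    For field data the standard deviation is taken over the whole field per
    field variable.  The clean states are carried along unchanged.
    """
    if noise_percent < 0:
        raise ValueError("noise percent must be nonnegative")
    clean = data.clean_states
    if noise_percent == 0:
        noisy = clean.copy()
        sigma = np.zeros(clean.shape[-1] if clean.ndim == 2 else clean.shape[0])
    else:
        rng = np.random.default_rng(seed)
        if clean.ndim == 2 and data.space_grid is None:  # ODE: columns are variables
            sigma = (noise_percent / 100.0) * clean.std(axis=0)
            noisy = clean + rng.normal(size=clean.shape) * sigma
        else:  # field data: one sigma per field
            f = clean if clean.ndim == 3 else clean[None]
            sigma = (noise_percent / 100.0) * f.std(axis=(1, 2))
            noisy = f + rng.normal(size=f.shape) * sigma[:, None, None]
            if clean.ndim == 2:
                noisy = noisy[0]
    return TrajectoryDataset(
        states=noisy, time_grid=data.time_grid,
        segment_boundaries=list(data.segment_boundaries),
        space_grid=data.space_grid, noise_percent=noise_percent,
        noise_sigma_per_variable=np.asarray(sigma), seed=seed,
        system=data.system, variable_names=list(data.variable_names),
        clean_states=clean.copy(),
    )
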