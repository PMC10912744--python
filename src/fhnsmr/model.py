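"""Delay-coupled stochastic FitzHugh-Nagumo network integrator.

The network obeys, for each neuron i = 1..N,

    eps * dx_i/dt = x_i - x_i^3/3 - y_i + g * sum_j J_ij (x_j(t - tau) - x_i(t))
        dy_i/dt = x_i + a + A * sin(2*pi*t / Te) + D * xi_i(t)

with xi_i Gaussian white noise, <xi_i(t) xi_j(t')> = delta_ij * delta(t - t').
Integration is explicit Euler-Maruyama on the fast/slow pair; the delayed
coupling uses a ring buffer of past membrane potentials, with the history
before t = 0 pinned to the initial condition x_i(0) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "SimControl",
    "Trajectory",
    "fhn_drift",
    "mean_field",
    "simulate",
]

#: relative tolerance for snapping tau onto the dt grid
_TAU_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the delayed FHN network.

    ``noise_convention`` selects the discrete noise amplitude per Euler step:
    ``"amplitude"`` uses D*sqrt(dt) (the noise term read literally as an
    amplitude D multiplying unit-intensity white noise), ``"intensity"`` uses
    sqrt(2*D*dt) (D read as the diffusion intensity of the Wiener increment).
    """

    eps: float = 0.01
    a: float = 1.1
    A: float = 0.14
    Te: float = 14.0
    g: float = 0.01
    D: float = 0.0
    tau: float = 0.0
    noise_convention: str = "amplitude"

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.Te <= 0:
            raise ValueError(f"Te must be positive, got {self.Te}")
        if self.D < 0:
            raise ValueError(f"noise intensity D must be >= 0, got {self.D}")
        if self.tau < 0:
            raise ValueError(f"delay tau must be >= 0, got {self.tau}")
        if self.noise_convention not in ("amplitude", "intensity"):
            raise ValueError(
                "noise_convention must be 'amplitude' or 'intensity', "
                f"got {self.noise_convention!r}"
            )

    @property
    def sigma_per_sqrt_dt(self) -> float:
        """Noise prefactor s such that the Euler step adds s*sqrt(dt)*eta."""
        if self.noise_convention == "amplitude":
            return self.D
        return math.sqrt(2.0 * self.D)


@dataclass(frozen=True)
class SimControl:
    """Numerical controls for one realization."""

    t_total: float = 500.0
    t_transient: float = 100.0
    dt: float = 0.001
    seed: int = 0
    record_stride: int = 10
    record_raster: bool = False
    record_y: bool = False
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.t_transient < self.t_total:
            raise ValueError(
                f"t_transient ({self.t_transient}) must be < t_total ({self.t_total})"
            )
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class Trajectory:
    """Recorded output of one realization.

    The mean field X(t) is stored at full dt resolution; the optional
    per-neuron raster is subsampled by ``record_stride``.
    """

    t: np.ndarray
    X: np.ndarray
    dt: float
    raster: np.ndarray | None = None
    raster_t: np.ndarray | None = None
    raster_y: np.ndarray | None = None
    params: ModelParams | None = None
    control: SimControl | None = None

    def __post_init__(self) -> None:
        if self.t.shape != self.X.shape:
            raise ValueError("time grid and mean field must have equal length")


def fhn_drift(
    x: np.ndarray,
    y: np.ndarray,
    x_delayed: np.ndarray,
    t: float,
    model: ModelParams,
    J: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic drift of the coupled FHN equations (noise excluded).

    Pure function of its arguments; used both as the reference for the
    integrator kernel and directly in tests of fixed points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_delayed = np.asarray(x_delayed, dtype=float)
    if not (x.shape == y.shape == x_delayed.shape):
        raise ValueError("state vectors must share a common shape")
    J = np.asarray(J, dtype=float)
    if J.shape != (x.size, x.size):
        raise ValueError(
            f"adjacency shape {J.shape} does not match state length {x.size}"
        )
    degree = J.sum(axis=1)
    coupling = model.g * (J @ x_delayed - degree * x)
    dx = (x - x**3 / 3.0 - y + coupling) / model.eps
    dy = x + model.a + model.A * math.sin(2.0 * math.pi * t / model.Te)
    return dx, dy


def mean_field(raster: np.ndarray) -> np.ndarray:
    """Arithmetic mean over neurons at each time point.

    ``raster`` has shape (n_neurons, n_times); returns length n_times.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.size == 0:
        raise ValueError("raster must be non-empty")
    if raster.ndim != 2:
        raise ValueError("raster must be 2-D (neurons x time)")
    return raster.mean(axis=0)


@njit(cache=True)
def _euler_chunk(
    x, y, hist, J, degree, drive, noise, X_out, raster, raster_y, stride,
    step0, tau_steps, dt, inv_eps, g,
):  # pragma: no cover - exercised through simulate()
    n_sub, N = noise.shape
    record = raster.shape[0] > 0
    record_y = raster_y.shape[0] > 0
    for s in range(n_sub):
        step = step0 + s
        if tau_steps > 0:
            m = step % tau_steps
            xd = hist[m]
        else:
            xd = x
        # record the *pre-update* state so sample 0 is the initial value
        acc = 0.0
        for i in range(N):
            acc += x[i]
        X_out[step] = acc / N
        if record and step % stride == 0:
            r = step // stride
            for i in range(N):
                raster[r, i] = x[i]
        if record_y and step % stride == 0:
            r = step // stride
            for i in range(N):
                raster_y[r, i] = y[i]
        # coupling must use the delayed state *before* the history slot is
        # overwritten with the current one (xd aliases hist[m])
        coup = np.dot(J, xd)
        if tau_steps > 0:
            for i in range(N):
                hist[m, i] = x[i]
        d = drive[s]
        for i in range(N):
            xi = x[i]
            dx = (xi - xi * xi * xi / 3.0 - y[i] + g * (coup[i] - degree[i] * xi)) * inv_eps
            y[i] = y[i] + dt * (xi + d) + noise[s, i]
            x[i] = xi + dt * dx


def _resolve_tau_steps(tau: float, dt: float) -> int:
    steps = tau / dt
    rounded = round(steps)
    if abs(steps - rounded) > _TAU_TOL * max(1.0, abs(steps)):
        raise ValueError(
            f"tau={tau} is not an integer multiple of dt={dt} "
            f"(off by {abs(steps - rounded)} steps)"
        )
    return int(rounded)


def simulate(J: np.ndarray, model: ModelParams, control: SimControl) -> Trajectory:
    """Integrate one realization and return the recorded trajectory.

    Explicit Euler-Maruyama: x advances by dt*dx with dx from the drift;
    y advances by dt*dy plus an independent N(0,1) increment per neuron per
    step scaled by ``model.sigma_per_sqrt_dt * sqrt(dt)``.  Identical inputs
    (including seeds) yield bit-identical trajectories.  The transient
    ``t < t_transient`` is discarded from the returned arrays.
    """
    J = np.ascontiguousarray(np.asarray(J, dtype=np.float64))
    N = J.shape[0]
    if J.shape != (N, N):
        raise ValueError("adjacency must be square")
    dt = control.dt
    n_steps = int(round(control.t_total / dt))
    tau_steps = _resolve_tau_steps(model.tau, dt)
    degree = J.sum(axis=1)

    x = np.full(N, control.x0, dtype=np.float64)
    y = np.full(N, control.y0, dtype=np.float64)
    hist = np.full((max(tau_steps, 1), N), control.x0, dtype=np.float64)
    X = np.empty(n_steps, dtype=np.float64)

    sigma = model.sigma_per_sqrt_dt * math.sqrt(dt)
    rng = np.random.default_rng(control.seed)

    stride = control.record_stride
    n_rec = -(-n_steps // stride)  # ceil
    raster = (
        np.empty((n_rec, N), dtype=np.float64)
        if control.record_raster
        else np.empty((0, N), dtype=np.float64)
    )
    raster_y = (
        np.empty((n_rec, N), dtype=np.float64)
        if control.record_y
        else np.empty((0, N), dtype=np.float64)
    )

    chunk = 20_000
    inv_eps = 1.0 / model.eps
    two_pi_over_Te = 2.0 * math.pi / model.Te
    step0 = 0
    while step0 < n_steps:
        n_sub = min(chunk, n_steps - step0)
        t_sub = (step0 + np.arange(n_sub)) * dt
        drive = model.a + model.A * np.sin(two_pi_over_Te * t_sub)
        if sigma > 0.0:
            noise = sigma * rng.standard_normal((n_sub, N))
        else:
            noise = np.zeros((n_sub, N))
        _euler_chunk(
            x, y, hist, J, degree, drive, noise, X, raster, raster_y, stride,
            step0, tau_steps, dt, inv_eps, model.g,
        )
        if not np.isfinite(x).all() or not np.isfinite(y).all():
            bad_t = step0 * dt
            raise FloatingPointError(
                f"non-finite state after t={bad_t:.3f} "
                f"(D={model.D}, g={model.g}, dt={dt}); integration aborted"
            )
        step0 += n_sub

    t = np.arange(n_steps) * dt
    keep = t >= control.t_transient
    traj = Trajectory(
        t=t[keep],
        X=X[keep],
        dt=dt,
        params=model,
        control=control,
    )
    if control.record_raster or control.record_y:
        rt = np.arange(n_rec) * (dt * stride)
        rkeep = rt >= control.t_transient
        if control.record_raster:
            traj.raster = raster[rkeep].T.copy()
        if control.record_y:
            traj.raster_y = raster_y[rkeep].T.copy()
        traj.raster_t = rt[rkeep]
    return traj
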