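"""Resonance-curve protocols: parameter sweeps and extrema detection.

A sweep runs the full pipeline (simulate -> mean-field spike detection ->
ISI accumulation -> ordinal complexity, optionally spectral SNR) at every
value of a control parameter (noise intensity D, delay tau, rewiring p,
degree k, size N, or coupling g) and locates the local maxima/minima of the
resulting complexity curve.  Stochastic resonance shows up as local maxima
of the statistical complexity C at optimal noise levels; delay-induced
multiresonance as maxima at delays commensurate with the drive period.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from fhnsmr.model import ModelParams, SimControl, Trajectory, simulate
from fhnsmr.network import NetworkParams, build_ws_adjacency
from fhnsmr.ordinal import ComplexitySummary, complexity_of_isi
from fhnsmr.spectral import SNREstimate, estimate_snr
from fhnsmr.spikes import (
    DEFAULT_REFRACTORY,
    DEFAULT_THRESHOLD,
    ISISeries,
    accumulate_isis,
    detect_spikes,
    extract_isis,
)

__all__ = [
    "SweepSpec",
    "ResonanceCurve",
    "IntrinsicPeriodEstimate",
    "derive_seed",
    "run_condition",
    "sweep",
    "find_local_extrema",
    "estimate_intrinsic_period",
    "predicted_resonance_count",
    "export_raster",
    "load_raster",
    "default_noise_grid",
    "default_delay_grid",
]

_MODEL_CONTROLS = ("D", "tau", "g")
_NETWORK_CONTROLS = ("p", "k", "N")


def derive_seed(base_seed: int, *components) -> int:
    """Stable sub-stream seed from a base seed and arbitrary labels.

    Uses SHA-256 of the component reprs, so adding grid points or
    realizations never changes the seeds of existing conditions.
    """
    key = "|".join([str(int(base_seed))] + [repr(c) for c in components])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SweepSpec:
    """One resonance-curve protocol."""

    control: str
    values: tuple[float, ...]
    net: NetworkParams = NetworkParams()
    model: ModelParams = ModelParams()
    sim: SimControl = SimControl()
    L_target: int = 2000
    d: int = 3
    threshold: float = DEFAULT_THRESHOLD
    refractory: float = DEFAULT_REFRACTORY
    max_realizations: int = 200
    reps_snr: int = 0
    prominence: float = 0.05
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in _MODEL_CONTROLS + _NETWORK_CONTROLS:
            raise ValueError(f"unknown control parameter {self.control!r}")
        vals = tuple(self.values)
        if len(vals) != len(set(vals)) or list(vals) != sorted(vals):
            raise ValueError("control values must be sorted and distinct")
        if self.L_target < self.d:
            raise ValueError("L_target must be >= d")


@dataclass
class ResonanceCurve:
    """Sweep result: one row per control value plus detected extrema."""

    control: str
    table: pd.DataFrame
    maxima: np.ndarray
    minima: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.table[self.control].to_numpy()


@dataclass
class IntrinsicPeriodEstimate:
    """Modal mean-field ISI with the periodic signal switched off."""

    T0: float
    D_used: float
    n_isi: int


def _isi_recipe(
    J: np.ndarray,
    model: ModelParams,
    control: SimControl,
    threshold: float,
    refractory: float,
    seed_for: Callable[[int], int],
) -> Callable[[int], np.ndarray]:
    def make_intervals(r: int) -> np.ndarray:
        ctrl = replace(control, seed=seed_for(r))
        traj = simulate(J, model, ctrl)
        train = detect_spikes(
            traj.X, traj.dt, t0=traj.t[0], threshold=threshold, refractory=refractory
        )
        return extract_isis(train)

    return make_intervals


def run_condition(
    J: np.ndarray,
    model: ModelParams,
    control: SimControl,
    L_target: int,
    d: int = 3,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    max_realizations: int = 200,
    seed_for: Callable[[int], int] | None = None,
) -> tuple[ComplexitySummary, ISISeries]:
    """Full pipeline at one parameter point.

    Runs independent realizations (seeds from ``seed_for``, defaulting to the
    control seed plus the realization index) until ``L_target`` mean-field
    ISIs are collected, then evaluates the ordinal complexity.  A condition
    that never reaches the target is returned under the no-firing convention.
    """
    if seed_for is None:
        base = control.seed
        seed_for = lambda r: derive_seed(base, "realization", r)
    recipe = _isi_recipe(J, model, control, threshold, refractory, seed_for)
    series = accumulate_isis(recipe, L_target, max_realizations=max_realizations)
    summary = complexity_of_isi(series, d=d)
    return summary, series


def sweep(spec: SweepSpec) -> ResonanceCurve:
    """Run the pipeline over the control grid and detect curve extrema.

    Conditions are seeded independently (seed = hash of base seed, control
    value and realization index), so results do not depend on execution
    order and extending the grid never changes existing points.
    """
    if spec.control in _MODEL_CONTROLS:
        J_fixed = build_ws_adjacency(spec.net)
    rows = []
    for v in spec.values:
        if spec.control in _MODEL_CONTROLS:
            J = J_fixed
            model_v = replace(spec.model, **{spec.control: v})
        else:
            net_v = replace(spec.net, **{spec.control: int(v) if spec.control != "p" else v})
            J = build_ws_adjacency(net_v)
            model_v = spec.model
        seed_for = lambda r, v=v: derive_seed(spec.base_seed, spec.control, v, r)
        summary, series = run_condition(
            J,
            model_v,
            spec.sim,
            spec.L_target,
            d=spec.d,
            threshold=spec.threshold,
            refractory=spec.refractory,
            max_realizations=spec.max_realizations,
            seed_for=seed_for,
        )
        row = {
            spec.control: v,
            "C": summary.C,
            "H": summary.H,
            "S": summary.S,
            "Q": summary.Q,
            "n_isi": len(series),
            "misi_mean": float(series.intervals.mean()) if len(series) else np.nan,
            "no_firing": summary.no_firing,
        }
        if spec.reps_snr > 0:
            fields = []
            for r in range(spec.reps_snr):
                ctrl = replace(
                    spec.sim, seed=derive_seed(spec.base_seed, "snr", spec.control, v, r)
                )
                fields.append(simulate(J, model_v, ctrl).X)
            est = estimate_snr(fields, spec.sim.dt, fe=1.0 / model_v.Te)
            row["snr"] = est.snr
        rows.append(row)
    table = pd.DataFrame(rows)
    vals = table[spec.control].to_numpy()
    if len(vals) >= 3:
        imax, imin = find_local_extrema(table["C"].to_numpy(), prominence=spec.prominence)
    else:
        imax = imin = np.empty(0, dtype=int)
    return ResonanceCurve(
        control=spec.control, table=table, maxima=vals[imax], minima=vals[imin]
    )


def find_local_extrema(
    curve: np.ndarray, prominence: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima of a sampled curve.

    A maximum must be strictly greater than both neighbours and rise at
    least ``prominence`` times the curve's total range above the higher of
    its two flanking valleys; minima are symmetric.  Endpoints are never
    extrema; a flat curve has none.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise ValueError("need at least 3 points to detect extrema")
    rng = float(curve.max() - curve.min())
    if rng == 0.0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    thr = prominence * rng

    def _peaks(v: np.ndarray) -> np.ndarray:
        idx, _ = find_peaks(v, prominence=thr if thr > 0 else None)
        strict = [i for i in idx if v[i] > v[i - 1] and v[i] > v[i + 1]]
        return np.asarray(strict, dtype=int)

    return _peaks(curve), _peaks(-curve)


def modal_isi(intervals: np.ndarray, bin_width: float = 0.1) -> float:
    """Centre of the modal histogram bin of an interval sample."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        raise ValueError("no intervals")
    edges = np.arange(0.0, intervals.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(intervals, bins=edges)
    m = int(np.argmax(counts))
    return float((edges[m] + edges[m + 1]) / 2.0)


def estimate_intrinsic_period(
    J: np.ndarray,
    model: ModelParams,
    control: SimControl,
    L_target: int = 1000,
    bin_width: float = 0.1,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    max_realizations: int = 200,
) -> IntrinsicPeriodEstimate:
    """Intrinsic firing period T0: modal mean-field ISI with the drive off.

    T0 is the coherence-resonance time scale of the noisy network; the drive
    amplitude must be exactly zero.  Raises if no firing occurs (raise D).
    """
    if model.A != 0.0:
        raise ValueError("intrinsic period requires the signal off (A = 0)")
    base = control.seed
    _, series = run_condition(
        J,
        model,
        control,
        L_target,
        threshold=threshold,
        refractory=refractory,
        max_realizations=max_realizations,
        seed_for=lambda r: derive_seed(base, "T0", r),
    )
    if len(series) == 0:
        raise RuntimeError(
            f"no mean-field firing at D={model.D}; increase the noise intensity"
        )
    return IntrinsicPeriodEstimate(
        T0=modal_isi(series.intervals, bin_width), D_used=model.D, n_isi=len(series)
    )


def predicted_resonance_count(Te: float, T0: float) -> int:
    """Number of noise-induced resonances predicted by the period ratio.

    The noise can induce m stochastic resonances when the drive period Te
    falls inside (m*T0, (m+1)*T0); the boundary Te = m*T0 resolves to m.
    """
    if Te <= 0 or T0 <= 0:
        raise ValueError("Te and T0 must be positive")
    return int(np.floor(Te / T0))


def export_raster(traj: Trajectory, path) -> None:
    """Write the per-neuron raster as TSV with a time header row."""
    if traj.raster is None:
        raise ValueError("trajectory has no recorded raster")
    header = "time\t" + "\t".join(f"{t:.10g}" for t in traj.raster_t)
    lines = [header]
    for i, row in enumerate(traj.raster):
        lines.append(f"x{i}\t" + "\t".join(f"{v:.10g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_raster(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a raster TSV; returns (times, neurons x time matrix)."""
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        times = np.asarray([float(v) for v in header[1:]])
        rows = [
            [float(v) for v in line.strip().split("\t")[1:]]
            for line in fh
            if line.strip()
        ]
    return times, np.asarray(rows)


def default_noise_grid() -> np.ndarray:
    """25 geometric points over [5e-4, 0.2] plus the landmark intensities."""
    grid = np.geomspace(5e-4, 0.2, 25)
    extras = np.array([0.001, 0.02, 0.04, 0.065, 0.08, 0.14])
    return np.unique(np.round(np.concatenate([grid, extras]), 12))


def default_delay_grid(step: float = 2.0, tau_max: float = 100.0) -> np.ndarray:
    """Delay grid 0, step, ..., tau_max (contains the drive-period multiples)."""
    return np.arange(0.0, tau_max + step / 2, step)
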