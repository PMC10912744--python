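"""Spike detection on the mean field and inter-spike-interval extraction.

A firing of the mean field X(t) is registered at each upward crossing of a
threshold (default 0.0, midway between the FHN rest state near -1 and the
spike peak near +2), subject to a refractory period (default 1.0 time units,
safely below the intrinsic firing period ~3.45 so genuine consecutive spikes
are never merged).  The interval sequence between contiguous firings is the
MISI series {T_s} analysed by the ordinal-complexity stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ISISeries",
    "detect_spikes",
    "extract_isis",
    "accumulate_isis",
    "spikes_per_period",
]

DEFAULT_THRESHOLD = 0.0
DEFAULT_REFRACTORY = 1.0


@dataclass
class ISISeries:
    """Sequence of inter-spike intervals with per-realization provenance.

    ``boundaries[r]`` is the number of intervals contributed by realization
    r; intervals are never differenced across realization boundaries.
    ``no_firing`` marks a series that fell short of its requested length
    (including the fully empty case) and is treated downstream by the
    no-firing convention (complexity 0, entropy 1).
    """

    intervals: np.ndarray
    boundaries: list[int] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    no_firing: bool = False

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size and not (self.intervals > 0).all():
            raise ValueError("all inter-spike intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals.size)


def detect_spikes(
    series: np.ndarray,
    dt: float,
    t0: float = 0.0,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> np.ndarray:
    """Spike times of a regularly sampled series (upward threshold crossings).

    A spike is registered at sample i when series[i-1] < threshold <= series[i]
    and the previous accepted spike lies at least ``refractory`` time units
    earlier.  Returns the (possibly empty) strictly increasing array of spike
    times ``t0 + i*dt``.
    """
    series = np.asarray(series, dtype=float)
    if series.size and not np.isfinite(series).all():
        raise ValueError("series contains non-finite values")
    if refractory < 0:
        raise ValueError("refractory must be >= 0")
    if series.size < 2:
        return np.empty(0)
    up = np.flatnonzero((series[:-1] < threshold) & (series[1:] >= threshold)) + 1
    if up.size == 0:
        return np.empty(0)
    times = t0 + up * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def extract_isis(train: np.ndarray) -> np.ndarray:
    """Successive differences of a (sorted, strictly increasing) spike train."""
    train = np.asarray(train, dtype=float)
    if train.size < 2:
        return np.empty(0)
    return np.diff(train)


def accumulate_isis(
    make_intervals: Callable[[int], np.ndarray],
    L_target: int,
    max_realizations: int = 200,
) -> ISISeries:
    """Concatenate ISIs from independent realizations up to a target length.

    ``make_intervals(r)`` must return the interval array of realization
    r = 0, 1, ...; realizations are run until at least ``L_target`` intervals
    are collected, then the tail is truncated to exactly ``L_target``.  No
    interval ever spans two realizations.  If ``max_realizations`` is reached
    first, the short series is returned with ``no_firing`` set.
    """
    if L_target < 1:
        raise ValueError("L_target must be >= 1")
    parts: list[np.ndarray] = []
    boundaries: list[int] = []
    seeds: list[int] = []
    total = 0
    r = 0
    while total < L_target and r < max_realizations:
        isi = np.asarray(make_intervals(r), dtype=float)
        parts.append(isi)
        boundaries.append(int(isi.size))
        seeds.append(r)
        total += isi.size
        r += 1
    intervals = np.concatenate(parts) if parts else np.empty(0)
    if total >= L_target:
        intervals = intervals[:L_target]
        # trim the last boundary to the truncated tail
        excess = total - L_target
        boundaries[-1] -= excess
        return ISISeries(intervals, boundaries, seeds, no_firing=False)
    return ISISeries(intervals, boundaries, seeds, no_firing=True)


def spikes_per_period(
    train: np.ndarray, Te: float, t_start: float | None = None
) -> tuple[np.ndarray, dict[int, int], int]:
    """Spike counts in consecutive windows of length Te, plus the modal count.

    Time is partitioned into windows [t_start + m*Te, t_start + (m+1)*Te);
    ``t_start`` defaults to the first spike time.  Returns (per-window counts,
    histogram of counts, modal count).  The train must span at least two
    windows.  Ties in the histogram resolve to the smaller count.
    """
    train = np.asarray(train, dtype=float)
    if Te <= 0:
        raise ValueError("Te must be positive")
    if train.size == 0:
        raise ValueError("empty spike train")
    if t_start is None:
        t_start = train[0]
    span = train[-1] - t_start
    n_windows = int(np.floor(span / Te))
    if n_windows < 2:
        raise ValueError(
            f"train spans {span:.3g} time units, need at least 2 periods of {Te}"
        )
    idx = np.floor((train - t_start) / Te).astype(int)
    idx = idx[(idx >= 0) & (idx < n_windows)]
    counts = np.bincount(idx, minlength=n_windows)
    hist_vals = np.bincount(counts)
    mode = int(np.argmax(hist_vals))  # argmax takes the first (= smallest) on ties
    histogram = {c: int(n) for c, n in enumerate(hist_vals) if n > 0}
    return counts, histogram, mode


def save_isi(path, series: ISISeries) -> None:
    """Persist intervals as single-column text; provenance in a sidecar JSON."""
    import json

    np.savetxt(path, series.intervals, fmt="%.10g")
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "boundaries": series.boundaries,
                "seeds": series.seeds,
                "no_firing": series.no_firing,
            },
            fh,
        )


def load_isi(path) -> ISISeries:
    """Read a single-column interval file (sidecar JSON optional)."""
    import json
    import os

    intervals = np.loadtxt(path, ndmin=1)
    sidecar = str(path) + ".json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        return ISISeries(
            intervals,
            boundaries=list(meta.get("boundaries", [])),
            seeds=list(meta.get("seeds", [])),
            no_firing=bool(meta.get("no_firing", False)),
        )
    return ISISeries(intervals, boundaries=[int(intervals.size)])
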