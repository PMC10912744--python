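"""Synthetic inter-spike-interval generators.

These surrogates emulate the statistical structure the ordinal-complexity
stage is meant to discriminate: cyclic period-k firing patterns (k intervals
repeating within one drive period, each perturbed by truncated-Gaussian
jitter) versus structureless i.i.d. interval sequences.  They make the
analysis stages testable without running the network simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SurrogateSpec", "generate_periodic_isi", "generate_iid_isi"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Specification of a periodic-pattern ISI surrogate.

    ``pattern`` lists the k base intervals of one firing cycle (for a
    period-k firing class within a drive period Te they sum to Te);
    ``jitter_sd`` is the standard deviation of the Gaussian perturbation on
    each interval, truncated so intervals stay positive.
    """

    pattern: tuple[float, ...]
    jitter_sd: float = 0.0
    L: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pattern) == 0:
            raise ValueError("pattern must contain at least one interval")
        if any(b <= 0 for b in self.pattern):
            raise ValueError("base intervals must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.L < 1:
            raise ValueError("L must be >= 1")


def _truncated_normal(
    base: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """base + N(0, sd) resampled (per element) until strictly positive."""
    out = base + sd * rng.standard_normal(base.size)
    bad = out <= 0
    while bad.any():
        out[bad] = base[bad] + sd * rng.standard_normal(int(bad.sum()))
        bad = out <= 0
    return out


def generate_periodic_isi(spec: SurrogateSpec) -> np.ndarray:
    """Cyclic repetition of the base pattern with i.i.d. truncated jitter."""
    rng = np.random.default_rng(spec.seed)
    base = np.resize(np.asarray(spec.pattern, dtype=float), spec.L)
    if spec.jitter_sd == 0.0:
        return base
    return _truncated_normal(base, spec.jitter_sd, rng)


def generate_iid_isi(mean: float, sd: float, L: int, seed: int = 0) -> np.ndarray:
    """i.i.d. truncated-Gaussian positive intervals (the structureless null)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    return _truncated_normal(np.full(L, float(mean)), sd, rng)
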