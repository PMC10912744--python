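"""Bandt-Pompe ordinal patterns and the statistical complexity measure.

A window of d consecutive values maps to the permutation that sorts it
ascending (ties broken by temporal order).  Sliding the window over a series
of length L yields a probability distribution P over the d! permutations,

    p(pi) = #{windows of type pi} / (L - d + 1).

From P the quantifiers are

    S[P]   = -sum_i p_i ln p_i                    (Shannon entropy, nats)
    H[P]   = S[P] / ln(d!)                        (normalized Shannon entropy)
    J[P,Pe]= S[(P+Pe)/2] - S[P]/2 - S[Pe]/2       (Jensen-Shannon divergence
                                                   to the uniform Pe)
    Q[P]   = Q0 * J[P,Pe]                         (disequilibrium; Q0 scales
                                                   the delta-vs-uniform case
                                                   to exactly 1)
    C[P]   = H[P] * Q[P]                          (statistical complexity)

C vanishes for both a perfectly ordered series (H=0) and a fully random one
(Q=0) and peaks for structured-but-nontrivial dynamics, which is what makes
it a resonance detector on inter-spike-interval series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrdinalDistribution",
    "ComplexitySummary",
    "ordinal_pattern",
    "pattern_distribution",
    "shannon_entropy",
    "nse",
    "jensen_shannon",
    "disequilibrium",
    "scm",
    "complexity_of_isi",
    "lexicographic_permutations",
]

_NORM_TOL = 1e-9


@dataclass
class OrdinalDistribution:
    """Probabilities over the d! permutations, in lexicographic order of pi."""

    d: int
    probs: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        M = math.factorial(self.d)
        if self.probs.size != M:
            raise ValueError(f"expected {M} probabilities for d={self.d}")
        if (self.probs < -_NORM_TOL).any():
            raise ValueError("negative pattern probability")
        if abs(self.probs.sum() - 1.0) > 1e-12 * M + 1e-12:
            raise ValueError("pattern probabilities must sum to 1")

    @property
    def M(self) -> int:
        return math.factorial(self.d)


@dataclass
class ComplexitySummary:
    """Entropy/complexity quantifiers of one ordinal distribution."""

    S: float
    H: float
    Q: float
    C: float
    no_firing: bool = False
    L: int = 0
    d: int = 3


def ordinal_pattern(window) -> tuple[int, ...]:
    """Permutation placing the window's elements in ascending order.

    Equal values keep their temporal order (stable sort), e.g.
    (1.1, 3.5, 2.3) -> (0, 2, 1).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be a 1-D sequence of length >= 2")
    return tuple(int(i) for i in np.argsort(window, kind="stable"))


def lexicographic_permutations(d: int) -> list[tuple[int, ...]]:
    """All permutations of (0..d-1) in lexicographic order."""
    from itertools import permutations

    return list(permutations(range(d)))


def _lehmer_rank(perms: np.ndarray, d: int) -> np.ndarray:
    """Lexicographic rank of each permutation row (factorial number system)."""
    n = perms.shape[0]
    rank = np.zeros(n, dtype=np.int64)
    fact = [math.factorial(d - 1 - i) for i in range(d)]
    for i in range(d):
        smaller = np.zeros(n, dtype=np.int64)
        for j in range(i):
            smaller += perms[:, j] < perms[:, i]
        rank += (perms[:, i] - smaller) * fact[i]
    return rank


def pattern_distribution(series, d: int = 3) -> OrdinalDistribution:
    """Ordinal-pattern probability distribution of a series.

    Slides a length-d window with stride 1 over the L - d + 1 positions and
    normalizes the pattern counts by that window count.
    """
    if not 2 <= d <= 7:
        raise ValueError(f"embedding dimension d must be in 2..7, got {d}")
    x = np.asarray(getattr(series, "intervals", series), dtype=float)
    L = x.size
    if L < d:
        raise ValueError(f"series length {L} is shorter than d={d}")
    M = math.factorial(d)
    if L < 100 * M:
        warnings.warn(
            f"series length L={L} is small for d={d} (recommended L >> d! = {M})",
            stacklevel=2,
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, d)
    perms = np.argsort(windows, axis=1, kind="stable")
    ranks = _lehmer_rank(perms, d)
    counts = np.bincount(ranks, minlength=M)
    n_windows = L - d + 1
    return OrdinalDistribution(d=d, probs=counts / n_windows, n_windows=n_windows)


def _check_distribution(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if (P < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(P.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"distribution not normalized (sum={P.sum()!r})")
    return P


def shannon_entropy(P) -> float:
    """Shannon entropy -sum p ln p in nats, with the convention 0 ln 0 = 0."""
    P = _check_distribution(np.asarray(getattr(P, "probs", P), dtype=float))
    nz = P[P > 0]
    return float(-(nz * np.log(nz)).sum())


def nse(P) -> float:
    """Normalized Shannon entropy H = S[P] / ln M, in [0, 1]."""
    P = np.asarray(getattr(P, "probs", P), dtype=float)
    return shannon_entropy(P) / math.log(P.size)


def jensen_shannon(P, Pe=None) -> float:
    """Jensen-Shannon divergence between P and the uniform reference Pe."""
    P = np.asarray(getattr(P, "probs", P), dtype=float)
    M = P.size
    if Pe is None:
        Pe = np.full(M, 1.0 / M)
    Pe = np.asarray(Pe, dtype=float)
    if Pe.size != M:
        raise ValueError("P and Pe must have the same number of categories")
    return (
        shannon_entropy((P + Pe) / 2.0)
        - shannon_entropy(P) / 2.0
        - shannon_entropy(Pe) / 2.0
    )


def _q0(M: int) -> float:
    """Normalizer making the delta-vs-uniform divergence equal exactly 1."""
    return -2.0 / (
        ((M + 1.0) / M) * math.log(M + 1.0) - 2.0 * math.log(2.0 * M) + math.log(M)
    )


def disequilibrium(P) -> float:
    """Normalized Jensen-Shannon distance Q = Q0 * J[P, Pe] in [0, 1]."""
    P = np.asarray(getattr(P, "probs", P), dtype=float)
    return _q0(P.size) * jensen_shannon(P)


def scm(P, d: int | None = None, L: int = 0) -> ComplexitySummary:
    """Statistical complexity C = H * Q with all intermediate quantifiers."""
    probs = np.asarray(getattr(P, "probs", P), dtype=float)
    if d is None:
        d = getattr(P, "d", 3)
    S = shannon_entropy(probs)
    H = S / math.log(probs.size)
    Q = disequilibrium(probs)
    return ComplexitySummary(S=S, H=H, Q=Q, C=H * Q, no_firing=False, L=L, d=d)


def no_firing_summary(d: int = 3) -> ComplexitySummary:
    """The convention for silent conditions: complexity 0, entropy 1."""
    M = math.factorial(d)
    return ComplexitySummary(S=math.log(M), H=1.0, Q=0.0, C=0.0, no_firing=True, L=0, d=d)


def complexity_of_isi(series, d: int = 3) -> ComplexitySummary:
    """Full pipeline on an ISI series, honouring the no-firing convention.

    Empty or flagged series (or series with fewer than d intervals) yield
    (C, H) = (0, 1) with ``no_firing`` set; otherwise the result of
    ``scm(pattern_distribution(series, d))``.
    """
    intervals = np.asarray(getattr(series, "intervals", series), dtype=float)
    flagged = bool(getattr(series, "no_firing", False))
    if flagged or intervals.size < d:
        return no_firing_summary(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = pattern_distribution(intervals, d)
    return scm(dist, d=d, L=intervals.size)
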