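# Methods

## Model

The package simulates an ensemble of N FitzHugh–Nagumo (FHN) neurons coupled
on a Watts–Strogatz (WS) small-world graph with transmission delay τ:

    ε dx_i/dt = x_i − x_i³/3 − y_i + g Σ_j J_ij (x_j(t−τ) − x_i(t))
      dy_i/dt = x_i + a + A sin(2πt/Te) + D ξ_i(t)

x_i is the fast membrane potential, y_i the slow recovery variable, and
ξ_i independent Gaussian white noise, ⟨ξ_i(t)ξ_j(t′)⟩ = δ_ij δ(t−t′).
With |a| > 1 each neuron is excitable: it rests at (x*, y*) = (−a, −a+a³/3)
and fires a large excursion only when perturbed across threshold.  The
sinusoidal drive is subthreshold at the default amplitude — without noise
the network never fires.  The collective output is the mean field
X(t) = (1/N) Σ_i x_i(t).

Defaults (the reference operating point used throughout the tests):
ε = 0.01, a = 1.1, A = 0.14, Te = 14, g = 0.01, N = 100, k = 30, p = 0.15,
dt = 0.001, x_i(0) = y_i(0) = 0.

## Integration

Explicit Euler–Maruyama with step dt: the x-equation advances by dt·dx and
the y-equation by dt·dy plus a noise increment per neuron per step.  Two
discretizations of the noise term are supported:

- `amplitude` (default): increment `D·sqrt(dt)·η`, reading the stochastic
  term literally as amplitude D times unit-intensity white noise.  This
  convention reproduces the reference firing phenomenology (see below) and
  is therefore the default.
- `intensity`: increment `sqrt(2·D·dt)·η`, reading D as the diffusion
  coefficient of the Wiener increment.

The delayed state x_j(t−τ) is kept in a ring buffer of round(τ/dt) steps;
the history before t = 0 equals the initial condition x_j(0) = 0.  τ is
snapped to the dt grid within a relative tolerance of 1e−9 and rejected
otherwise.  Non-finite states abort with a diagnostic.  All randomness
flows from a single `numpy` PCG64 generator per realization seed, so
trajectories are bit-reproducible.  The integrator kernel is numba-compiled
and advances ≈ 300 simulated time units per second for N = 100, k = 30
on one core.

With ε = 0.01 the fast subsystem has relaxation rates up to ≈ 300 during
the spike upstroke; dt = 0.001 keeps the explicit scheme comfortably stable
(dt·λ ≈ 0.3).  Step sizes above ≈ 0.005 are not recommended.

## Spike detection and the MISI series

A firing of the mean field is an upward crossing of a threshold (default
0.0) separated from the previous firing by at least a refractory time
(default 1.0).  The FHN mean field swings between ≈ −2 and ≈ +2 at
resonance, so 0.0 separates rest from spike cleanly; the refractory time is
far below the intrinsic period (≈ 3.5–4) and only suppresses double
crossings within a single collective excursion.  The MISI series {T_s} is
the sequence of intervals between contiguous mean-field firings.  Long
series are accumulated by concatenating independent realizations
(incremented derived seeds); intervals never span a realization boundary.
A condition that cannot reach the requested series length within the
realization cap is flagged and enters resonance curves under the no-firing
convention (complexity 0, entropy 1).

## Ordinal quantifiers

Windows of d consecutive intervals are mapped to the permutation that sorts
them ascending (stable: ties keep temporal order).  Probabilities over the
d! permutations (lexicographic storage order) give

- normalized Shannon entropy H = S[P]/ln(d!),
- disequilibrium Q = Q0·J[P, Pe], the Jensen–Shannon divergence to the
  uniform distribution Pe scaled by Q0 so that a delta distribution scores
  exactly 1,
- statistical complexity C = H·Q.

C vanishes for both perfectly regular (H→0) and structureless (Q→0)
interval series and peaks for structured-but-nontrivial firing, which makes
it a sharp detector of stochastic and delay-induced resonance.  Natural
logarithms are used throughout (H is base-invariant).  The default
embedding dimension is d = 3; series shorter than d (or flagged no-firing)
score (C, H) = (0, 1).

## Spectral SNR

The periodogram (rectangular window, mean removed, normalized so the
spectrum sums to the series variance) yields SNR = Ps/Pn, with Ps the sum
of the three bins centred on the drive frequency 1/Te and Pn the mean of
the surrounding ±20 bins (excluding the signal bins) scaled to the same
3-bin width, so pure white noise scores ≈ 1.  Per-realization SNRs are
averaged.  Band conventions differ across the literature, so absolute SNR
values are estimator-specific; peak locations in a sweep are the robust
output.

## Sweeps and extrema

A sweep evaluates C, H (and optionally SNR) per control value of
D, τ, p, k, N or g.  Each condition is seeded by SHA-256 of (base seed,
control name, value, realization index): conditions are independent of
execution order and a grid can be extended without changing existing
points.  Local extrema are interior points strictly above (below) both
neighbours whose prominence — height above the higher flanking valley —
exceeds a configurable fraction (default 0.05) of the curve range; curves
are not smoothed.

The intrinsic period T0 of the noise-induced collective oscillation
(coherence resonance) is the modal mean-field ISI (histogram bin 0.1) with
the drive off (A = 0); the number of stochastic-resonance peaks expected as
noise grows is the integer m with m·T0 < Te < (m+1)·T0.

## Surrogate ISI generators

Two generators mirror the regimes the pipeline must separate: a cyclic
base pattern of k intervals with truncated-Gaussian jitter (period-k firing
within one drive period, e.g. pattern (4, 10) ~ period-2), and i.i.d.
truncated-Gaussian intervals (the structureless null).  Truncation simply
rejects non-positive draws, keeping the requested mean interpretable at
small jitter.  These surrogates reproduce the ordinal statistics of the
simulated MISI series but not their spectral content or inter-realization
correlations, so they validate the analysis stages, not the dynamics.

## Problem sizes

Desk-scale defaults were chosen so that every documented result recomputes
in minutes on one core; the resonance structure (peak locations and
orderings) is already stable at these sizes, which we verified by
comparison across seeds and series lengths:

- resonance-curve conditions use L_target = 500–2000 intervals from
  realizations of 1000 time units (after a 100-unit transient), instead of
  the 60,000-interval production setting, which is available via
  `L_target` / the CLI config;
- the noise-resonance check uses a 12-point grid spanning [5e−4, 0.2]
  containing all landmark intensities (0.001, 0.02, 0.04, 0.065, 0.08,
  0.14); the full 31-point default grid is the CLI preset;
- the delay-resonance check compares τ ∈ {14, 20, 28} at D = 0.04 and
  τ ∈ {10, 12} at D = 0.02; the full step-2 grid over [0, 100] is the CLI
  preset;
- T0 estimation uses 2,000 intervals (the mode is already stable at 600).

## Known limitations and open choices

- The firing threshold/refractory convention is not uniquely determined by
  the problem; absolute peak heights of C shift slightly under other
  conventions, while peak positions are robust.
- The measured intrinsic period at D = 0.08 is T0 ≈ 3.85 under this
  package's estimator (modal mean-field ISI); reported values of ≈ 3.45
  exist under other estimation conventions.  The predicted resonance count
  for Te = 14 is 4 for T0 ∈ (2.8, 3.5] and 3 for T0 ∈ (3.5, 4.67); the
  simulated noise sweep itself shows four maxima, consistent with the
  effective intrinsic time scale shortening as D grows (mean ISI falls
  from ≈ 4.0 at D = 0.08 to ≈ 3.3 at D = 0.2).
- Only WS topologies and the explicit Euler–Maruyama scheme are
  implemented; no adaptive or higher-order integrators.
- MISI is the interval sequence of the mean field, not the mean of
  per-neuron interval sequences.
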