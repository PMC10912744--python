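# fhnsmr

Stochastic multiresonance in delay-coupled FitzHugh–Nagumo networks,
quantified by ordinal statistical complexity.

## What this package is for

Excitable neurons can exploit noise: a periodic input too weak to trigger
any spike on its own ("subthreshold") becomes detectable when an optimal
amount of noise — or an optimal transmission delay — locks the network's
firing to the signal (stochastic resonance, SR; several optima:
multiresonance, SMR).  This package provides the complete computational
pipeline to study that effect in a small-world network of
FitzHugh–Nagumo (FHN) neurons:

1. **Simulate** N delay-coupled, noise-driven FHN neurons on a
   Watts–Strogatz graph,

       ε ẋᵢ = xᵢ − xᵢ³/3 − yᵢ + g Σⱼ Jᵢⱼ (xⱼ(t−τ) − xᵢ(t))
         ẏᵢ = xᵢ + a + A sin(2πt/Tₑ) + D ξᵢ(t)

   (explicit Euler–Maruyama, dt = 0.001, zero initial conditions), and
   record the mean field X(t) = (1/N) Σᵢ xᵢ(t).
2. **Extract** the inter-spike intervals of the mean field (the MISI
   series {T_s}).
3. **Quantify** the interval structure with the Bandt–Pompe ordinal
   methodology: normalized Shannon entropy H = S[P]/ln d!, disequilibrium
   Q = Q₀·J[P, Pₑ] (Jensen–Shannon distance to the uniform distribution),
   and the statistical complexity measure C = H·Q, plus a periodogram
   signal-to-noise ratio at the drive frequency.
4. **Sweep** noise intensity D, delay τ, or network parameters (p, k, N, g)
   and locate resonances as local maxima of C.

C vanishes both for perfectly regular and for structureless interval
series and peaks for structured firing, which makes it a sharper resonance
detector than SNR at strong noise.  At the reference operating point
(ε=0.01, a=1.1, A=0.14, Tₑ=14, g=0.01, N=100, k=30, p=0.15) the noise
sweep shows *quadruple* SR — complexity maxima at D ≈ 0.001, 0.04, 0.08
and 0.14, where the network fires 1, 2, 3 and 4 collective spikes per
drive period — and with moderate noise the delay sweep peaks at the
multiples τ = nTₑ.

## Worked example

The ordinal machinery on a six-interval series:

```python
>>> from fhnsmr import pattern_distribution, scm
>>> dist = pattern_distribution([1.1, 3.5, 2.3, 4.7, 1.8, 5.6], d=3)
>>> dist.probs            # lexicographic: 012, 021, 102, 120, 201, 210
array([0.  , 0.25, 0.5 , 0.  , 0.25, 0.  ])
>>> res = scm(dist)
>>> round(res.H, 4), round(res.Q, 4), round(res.C, 4)
(0.5803, 0.4963, 0.288)
```

The four length-3 windows map to the patterns (0,2,1), (1,0,2), (2,0,1),
(1,0,2), so pattern (1,0,2) has probability 2/4 and the entropy is
S = 1.5·ln 2 ≈ 1.0397 nats; H is that relative to ln 6, Q the normalized
distance from uniformity, and C their product.

The same numbers from the shell:

```sh
$ fhnsmr surrogate --kind periodic --pattern 4,10 --jitter 0.35 -L 10000 -o isi.txt
$ fhnsmr analyze-isi isi.txt
L,d,S,H,Q,C,no_firing
10000,3,1.386..,0.7737,0.2915,0.2255,0
```

A jittered period-2 firing surrogate (two spikes per 14-unit drive period)
scores C ≈ 0.23, while an i.i.d. interval series of the same mean and
spread scores C ≈ 0.000 — the discrimination the resonance curves rest on.

Running the physics end to end (noise resonance curve on a reduced grid;
minutes, not hours):

```python
from fhnsmr import (NetworkParams, ModelParams, SimControl,
                    SweepSpec, sweep)
spec = SweepSpec(
    control="D",
    values=(0.0005, 0.001, 0.002, 0.005, 0.01, 0.02,
            0.04, 0.065, 0.08, 0.11, 0.14, 0.2),
    net=NetworkParams(N=100, k=30, p=0.15, seed=1),
    model=ModelParams(),
    sim=SimControl(t_total=1100.0, t_transient=100.0, dt=0.001),
    L_target=500, max_realizations=8, base_seed=1,
)
curve = sweep(spec)
print(curve.maxima)        # -> [0.001 0.04  0.08  0.14]
```

exactly the four resonant noise intensities.  The CLI subcommands
`sweep-noise`, `sweep-delay` and `sweep-param` run the same protocols from
a flat JSON config and write curve/extrema CSVs plus a run manifest.

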