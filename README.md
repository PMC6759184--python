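# clockloops

Models and analysis tools for **transient dissociation of the circadian
clock's interlocked feedback loops**. Dual-reporter recordings of the
mammalian clock show that *Per1* and *Bmal1* rhythms can drift apart for
days after jet-lag, light pulses, or slice preparation, before re-locking.
`clockloops` is for chronobiologists and modelers who want to ask: can that
dissociation live inside a single cell, and what coupling strengths and
light inputs are consistent with it?

The package provides four tiers, from data to mechanism:

* **`clockloops.surrogate`** — in-silico dual-channel (Bmal1/Per1)
  time-lapse movies under two null hypotheses: H0(1), both reporters
  oscillate with different periods in *every* cell; H0(2), two disjoint
  cell populations each carry one reporter. Cosine cells, Gaussian blobs,
  3 attenuated tissue layers, Gaussian camera noise.
* **`clockloops.rhythms`** — Hodrick-Prescott detrending
  (λ = 0.05·(24 h/Δt)⁴), Lomb-Scargle periods on [4, 48] h, harmonic fits
  y(t) = a·cos(2πt/τ) + b·sin(2πt/τ) with A = √(a²+b²), φ = arctan2(b, a),
  acrophases, pixel-wise period maps, bivariate KDE cluster counting, and
  robust Student's-t period-histogram fits.
* **`clockloops.phase_model` / `clockloops.poincare`** — the conceptual
  tier: two coupled phase oscillators
  θ̇_P = ω_P + K_R sin(θ_R−θ_P−β) + Z(t), θ̇_R = ω_R + K_P sin(θ_P−θ_R+β),
  with closed-form locking theory (Δθ* = arcsin(Δω/K_Σ) − β for
  |Δω| < K_Σ), isoclines of constant phase difference, jet-lag fitting and
  pulse-relaxation dynamics; plus the amplitude-aware version as
  mean-field-coupled Poincaré oscillators (self-sustained or damped
  Bmal-Rev).
* **`clockloops.dde`** — the mechanistic tier: delay differential equations
  for Per auto-inhibition and the interlocked three-gene
  Per/Bmal1/RevErb circuit, with LD-cycle entrainment, jet-lag, light-pulse
  and phase-response-curve protocols (numba-jitted method of steps).

`clockloops.workbench` orchestrates reproducible experiments (YAML specs,
seeded runs, hashed configs) and generates the synthetic fixtures; a thin
`clockloops` CLI wraps the main drivers.

## Worked example

The two-loop phase model with the optimal free-running parameters —
τ_P = 24.38 h, τ_R = 24.68 h, symmetric coupling K = 0.043 rad/h,
β = 0.7π — phase-locks because |ω_P − ω_R|/(K_P+K_R) ≈ 0.036 < 1:

```bash
$ clockloops phase locked
{
 "tau_star_h": 24.52908275580921,
 "delta_star_rad": -2.162684458461805,
 "delta_star_pi": -0.6884023490030994
}
```

Both loops run at a common period of 24.53 h with the Per loop locked
≈ 0.69π rad (~8.4 h) *behind* the Bmal-Rev loop — the near-antiphasic
Per1/Bmal1 relation seen in tissue. After a 6 h phase advance of the
light cycle the loops transiently dissociate; the Per loop, which
receives the light input, re-entrains first:

```python
>>> from clockloops import workbench
>>> workbench.make_jetlag_reference()
   day  shift_per_h  shift_bmal_h
0   -1     0.000000      0.000000
1    2     3.576685      1.997795
2    3     4.411252      3.229754
3    4     4.964312      4.144878
4   12     5.970136      5.944539
```

By day 2 the Per loop has advanced 3.6 of the 6 h, the Bmal-Rev loop only
2.0 h; by day 12 both have completed the shift and the loops are locked
again. The same ordering — Per first, Bmal1/RevErb lagging by a degree set
by the inter-loop coupling — emerges from the mechanistic three-gene DDE
circuit (`dde.simulate_jetlag_dde`), where the coupling is the biochemical
constant c_R of Per's repression of RevErb transcription.

On the imaging side, generating the reference surrogate movies and counting
the modes of the bivariate (Bmal1, Per1) pixel-period density
(`workbench.run_experiment`, driver `surrogate-compare`) yields **2**
clusters when both reporters share every cell and **4** clusters for two
disjoint populations — the fingerprint that lets dual-reporter recordings
discriminate the two scenarios.

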