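# Methods

`clockloops` studies how the two principal feedback loops of the cellular
circadian clock — the light-sensitive Per loop and the light-insensitive
Bmal-Rev loop — can transiently dissociate after perturbations of the light
schedule, and how such dissociation would look in dual-reporter imaging.
This note documents the models, their parameters, the numerical choices, and
what the synthetic data do and do not emulate.

## Two-oscillator phase model

Each loop is reduced to a single phase variable:

    dθ_P/dt = ω_P + K_R sin(θ_R − θ_P − β) + Z(t)
    dθ_R/dt = ω_R + K_P sin(θ_P − θ_R + β)

with ω_j = 2π/τ_j, coupling rates K_P, K_R (rad/h) and a coupling offset β
(rad) that selects the locked phase difference. Light acts only on the Per
loop, by default as Z(t) = z·sin(2πt/T − θ_P + φ₀). The free-running phase
difference Δθ = θ_P − θ_R obeys dΔθ/dt = Δω − (K_P+K_R)·sin(Δθ+β); the loops
phase-lock iff |Δω| < K_P + K_R, at

    ω* = (K_P ω_P + K_R ω_R)/(K_P + K_R),
    Δθ* = arcsin(Δω/(K_P+K_R)) − β.

Defaults are the optimal free-running fit: τ_P = 24.38 h, τ_R = 24.68 h,
symmetric K = 0.043 rad/h, β = 0.7π, giving Δθ* = −0.688π and τ* = 24.529 h.
`isocline` inverts the symmetric locked-state relation to produce (K, τ_P,
τ_R) triples of constant Δθ*; note that at β = 0.7π the exact target −0.7π
degenerates to zero detuning, so scans use the locked value of the optimal
set (−0.688π) as their default target. Asymmetric coupling is parameterized
as K_R = pK, K_P = (1−p)K at fixed total K.

Jet-lag protocols entrain the pair to the sinusoidal Zeitgeber (T = 24 h),
advance the Zeitgeber phase by the stated shift at the shift day, and report
each loop's acrophase advance per cycle relative to its entrained phase
(advances positive, converging to the imposed shift). Entrainment is
accepted when the pre-shift acrophase drift is below 0.05 h per cycle over
the last six cycles. The light-pulse analysis integrates the reduced Δθ
equation from Δθ* plus an offset (hours converted to radians via ω*); the
re-adaptation time is the first time the residual stays within 10% of the
initial offset. Offsets beyond the unstable fixed point relax the long way
around the circle and are flagged as such.

The synthetic jet-lag reference (`workbench.make_jetlag_reference`) is
generated by this model at documented truth parameters (K = 0.05, z = 0.05,
β = 0.7π, τ* = 24.53 h, 6 h advance) and sampled at days {−1, 2, 3, 4, 12},
the classic re-entrainment sampling design. It stands in for digitized
experimental curves, which are not distributed; fitness scans
(`rss_fitness`) accept any user CSV in the same schema.

## Coupled Poincaré oscillators

To check that the phase-only reduction is not doing the work, the same two
loops are modeled as mean-field-coupled Poincaré oscillators:

    dz_j/dt = (λ_j (A_j − r_j) + i·2π/τ_j) z_j + K e^{iφ} (z_P + z_R),

j ∈ {P, R}, r_j = |z_j|, integrated in Cartesian coordinates, with the
Zeitgeber added to dx_P/dt. Defaults λ = 0.1 h⁻¹, A = 1, φ = π. Setting
A_R = 0 yields a damped Bmal-Rev loop. The mean field includes the
oscillator's own state, exactly as written; `include_self=False` is
available because the wording of a "mean field" is ambiguous. In the
weak-coupling limit the pair reduces to the phase model with β = π and
K_P = K_R = K, a correspondence verified in the tests to < 0.05 rad.

For (K, z) fitness scans the period detuning at each K is calibrated by
root-finding on the *simulated* locked phase difference (symmetric detuning
τ_P = τ*−d, τ_R = τ*+d), because amplitude dynamics shift the locked phase
away from the weak-coupling formula at moderate K; the weak-coupling rule
remains available (`calibrate=False`). A grid cell counts as a good fit when
the mean squared error against the reference shift curves is below 0.5 h²
per sample (0.71 h RMS on shifts up to 6 h), a threshold fixed once for the
self-sustained/damped region comparison.

## Three-gene delay circuit

The mechanistic model condenses translation and post-translational steps
into explicit delays. Per auto-inhibition alone,

    dP/dt = (v_P/(k_P + P(t−T_P)))² − d_P P + Z(t),

already oscillates in the circadian band. The full circuit interlocks it
with the Bmal-Rev loop (Bmal1 activates RevErb via its delayed E-box
activity; RevErb represses Bmal1; Per represses RevErb transcription):

    dP/dt = (v_P/(k_P+P_d))²·((c_P + b_P B_d)/(c_P + B_d))² − d_P P + Z(t)
    dB/dt = (v_B/(k_B+R_d))² − d_B B
    dR/dt = ((v_R + b_R B_d)/(k_R + B_d))³·(c_R/(P_d + c_R))³ − d_R R

with X_d the delayed states. Nominal constants: d = (0.25, 0.26, 0.29) h⁻¹,
v = (1, 0.9, 0.6), k = (0.1, 0.05, 0.9), c_P = 0.1, c_R = 35, b_P = 1,
b_R = 8, delays T_P = 8.333 h, T_R = 1.52 h, T_B = 3.652 h; Hill exponents
reflect known binding-site counts and are fixed. c_R is the inter-loop
coupling: larger c_R weakens Per's repression of RevErb and slows every
Bmal-Rev response to light. With b_P = 1 the Bmal1→Per factor is identically
one, so the circuit is a one-way chain — exactly why Per responds to light
first and Bmal1/RevErb follow only through the loop. The repression term is
implemented as (c_R/(P_d+c_R))³, the reading under which larger c_R means
weaker coupling.

The free-running period of the nominal set is an emergent quantity
(measured by the package at ≈ 24.3 h, comfortably inside the 20–28 h band);
entrained under a square LD 12:12 Zeitgeber of z = 0.21 the model peaks Per
and RevErb around midday and Bmal1 in the morning. Light pulses are
rectangular additive inputs on a chosen variable (P or R), by default 9 h
long, timed relative to the last free-running Per acrophase.

Numerics: method of steps with fixed-step classical Runge-Kutta (default
h = 0.01 h, matching the output sampling) and cubic Hermite interpolation of
the stored past; constant history on [−max delay, 0]. The default history is
**half** the delay-free steady state — the steady state itself is an exact
fixed point of the DDE and would never leave it. Square-wave switching times
align with the step grid for the default protocols; pulse onsets are snapped
to the grid (≤ 0.01 h error). Halving the step changes the free-running
period estimate by < 10⁻³ h (tested). Phase shifts are measured by matching
each pulsed/shifted acrophase to the nearest unperturbed one, advances
positive, asymptotes taken over the last five recorded cycles;
`reentrainment_time` reports the first cycle after which the shift stays
within 10% of its target (floor 0.25 h, so near-zero targets are not held
to an impossible relative band).

## Surrogate dual-reporter movies

The generator emulates dual-channel (Bmal1/Per1) time-lapse recordings under
two null hypotheses: H0(1), every cell carries both reporters with distinct
periods (23 h / 24 h); H0(2), two disjoint half-populations each carrying
one reporter. Cells are placed uniformly on the unit square (positions drawn
independently of the hypothesis, so layouts are comparable), each emitting
I/2·(1 + cos(2πt/τ + φ)) with i.i.d. uniform initial phases (a common-phase
option exists). Each of the M = 3 layers is an independent draw of N = 150
cells; layers superimpose with weights 1, 0.5, 0.25. Cells render as
Gaussian blobs of σ_G = 0.0132 field widths (≈1.7 px on the default
128×128 grid), truncated at ±4σ (< 10⁻⁴ mass lost); i.i.d. Gaussian
observation noise (σ_n = 1) is added per pixel, frame and channel after
superposition. Movies default to 12 days sampled hourly (289 frames).

One convention deserves emphasis: the stated parameters fix the cell's
*shape* but not its rendered brightness relative to the noise (that scale
hides inside the kernel normalization, i.e. the camera gain). The package
makes it explicit as `kernel_gain`, the peak brightness of a unit-intensity
cell in noise-σ units, default 10. This default places covered pixels in
the clearly rhythmic regime — oscillations visible over the noise in a
single-pixel trace — while empty pixels remain noise-dominated, the regime
dual-reporter recordings actually show. At much lower gain, period detection
becomes a coin flip across blob rims and deep layers and both hypotheses
blur into the same four-mode density; at much higher gain the blobs tile the
field and the empty-pixel population disappears. Conclusions drawn from the
cluster analysis therefore presuppose a moderate per-cell signal-to-noise,
which is a statement about the imaging regime, not about the hypotheses.

The movies are idealized in ways real recordings are not: no photon
(Poisson) noise, no baseline drift or decaying luminescence, no spectral
spillover between channels, cosine waveforms with fixed per-channel periods,
and no SCN geometry. Passing the hypothesis test on these movies shows the
*analysis pipeline* discriminates the two null hypotheses in this idealized
regime; it does not by itself certify performance on experimental movies.

## Rhythm analysis

Time series are detrended with a Hodrick-Prescott filter using
λ = 0.05·(24 h/Δt)⁴ (λ = 16 588.8 at hourly sampling; high-pass with ~100 h
cutoff, leaving circadian components untouched). Periods come from the
Lomb-Scargle periodogram evaluated on 2000 log-spaced periods in [4, 48] h —
enough to separate 23 h from 24 h on 12-day records. Pixel-wise maps
factorize the HP penalty system once and solve for all pixels, and evaluate
the periodogram as matrix products against precomputed (τ-corrected)
cosine/sine bases; both paths are tested to agree with the reference
single-series implementations. Empty pixels produce short dominant periods
(white-noise argmax concentrates near the 4 h edge of the log grid), which
is what makes the "non-circadian" cluster sit near small periods; pixels
with dominant period below 20 h are labeled non-rhythmic where a binary call
is needed.

Bivariate cluster counting runs a Gaussian KDE (Scott's bandwidth) over the
paired per-pixel (Bmal1, Per1) periods on a 200×200 grid and counts local
maxima above 5% of the global maximum separated by more than 2 h. These
constants mirror what a reader counts by eye in a contour plot; they are
exposed in `AnalysisConfig`.

Acrophases are local maxima above the series mean, at least half a dominant
period apart, refined by a least-squares parabola over ±20% of a period
(unbiased for symmetric waves, robust to observation noise) and discarded
within half a period of either record boundary. Instantaneous periods are
first differences of acrophase times. Period histograms are summarized by a
maximum-likelihood Student's-t fit started from median/MAD so that heavy
outliers do not capture the likelihood search.

## Harness and reproducibility

All randomness derives from a single master seed via `numpy` seed
sequences, with deterministic child streams per layer and channel;
identical configurations reproduce bit-identical movies and experiment
payloads (logs carry the timestamps instead). Experiment drivers embed the
resolved configuration hash and seed in their JSON outputs. ODEs integrate
with an adaptive Runge-Kutta at rtol 10⁻⁸ / atol 10⁻¹⁰ (10⁻¹⁰/10⁻¹² where a
10⁻⁶-rad comparison is the point), sampled at 0.01 h by default; analyses
that only need acrophases sample at 0.05 h.

Problem sizes used by the shipped tests and the acceptance script — e.g.
five seeds per hypothesis for the cluster majority vote, 7×7 and 5×5
(K, z) grids, eight-phase PRCs, and 20–30 entrainment cycles — are the
package's default study sizes; all are arguments that can be scaled up.

## Known limitations

* The original experimental movies and the digitized jet-lag curves are not
  distributed; all fitness scans here target self-generated references, so
  the numerical optimum of the original study (K ≈ 0.043, z ≈ 0.051) and
  the experimental period-histogram locations (23.87 h / 23.40 h) are not
  reproduced, by design.
* The five-group-gene clock model is out of scope; the mechanistic tier
  stops at the three-gene circuit.
* PRCs and re-entrainment times are measured from acrophase matching; for
  pulses that nearly split the phase (shift ≈ ±τ/2) the advance/delay sign
  convention is decided by the nearest-match rule.
* The phase model's Zeitgeber enters as a phase-coupling term; amplitude
  effects of light are represented only in the Poincaré and gene-circuit
  tiers.
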