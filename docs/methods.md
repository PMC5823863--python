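# Methods

## Scope

`micropk` quantifies local ligand concentrations near live-cell membranes
from fluorescence correlation spectroscopy (FCS), estimates membrane-phase
concentrations and receptor binding kinetics, and propagates the measured
near-membrane concentration into a corrected ("true") binding affinity.
Every input can be generated synthetically by physically motivated,
seeded simulators, so each analysis stage is testable against known ground
truth.

## FCS model and conventions

The detection profile is the standard 3D Gaussian
W(r) = exp(−2(x²+y²)/w₀² − 2z²/z₀²). The fitted model for the normalized
autocorrelation G(τ) is a sum of diffusing components (one free 3D species;
for membrane reads one 3D plus one or two 2D species) with amplitude 1/N,
fractions φᵢ, a fitted offset G∞ (drift guard, can be fixed to 0), and the
usual decay laws g₃D and g₂D. Conventions that matter:

* **Effective volume.** Default V_eff = π^(3/2)·w₀²·z₀ (the Gaussian
  convention; 0.223 fL at w₀ = 0.2 µm, z₀ = 1 µm). A `cylinder` convention
  (π·w₀²·2z₀ = 0.251 fL, the "~0.25 fL" figure usually quoted for this
  geometry) is provided; every calibration result records which was used.
* **Dwell time and diffusion.** τ_D = w₀²/4D. Calibration inverts this for
  a reference dye of known D (Cy5, D = 3.16×10⁻¹⁰ m²/s): a 31.65 µs dye
  dwell time gives w₀ = 0.200 µm. The ligand's aqueous dwell time
  (~140 µs) is fixed in membrane fits, mirroring same-day solution
  calibration practice.
* **Brightness is detected counts-per-molecule (cpm).** All brightness
  values are referenced to the detected mean rate per particle in V_eff,
  i.e. cpm = ⟨rate⟩/N, not to the profile-peak emission rate. The two
  differ by the profile shape factor γ (γ₃D = 2^(−3/2), γ₂D = 1/2), and —
  crucially — the ACF amplitude algebra weights species by cpm. Using the
  peak convention, a measured 2D/3D cpm ratio would overstate the true
  amplitude ratio by √2 and the two-species inversion below would need a
  √2-adjusted ratio, contradicting the single measured correction factor
  (9.1) the workflow is built around. The simulator therefore interprets
  its `brightness_eps`/`brightness_ratio` inputs as cpm quantities and
  converts to peak rates internally (peak = cpm/γ).
* **Two-species brightness correction.** An equal-brightness fit of a
  membrane read reports apparent (N_app, φ₂D). Physically
  Gᵢ(0) = Nᵢqᵢ²/(Σ Nⱼqⱼ)² with qᵢ the species cpm; with r = q₂D/q₃D the
  closed-form inversion is
  N₃D = φ₃D·N_app/(φ₃D + φ₂D/r)², N₂D = (φ₂D/r²)·N_app/(φ₃D + φ₂D/r)².
  r = 1 returns the uncorrected split; a pure species is returned
  unchanged (normalization cancels brightness). For the 3-component model
  both 2D species share the single r. The corrected N₂D is referenced to a
  cylinder π·w₀²·h with h = 5 nm (bilayer height) to give the
  membrane-phase concentration.

## Correlator

* Brute-force estimator: G(kΔ) at every integer lag with *symmetric*
  normalization — the lag-k product mean divided by (mean of first n−k
  bins)·(mean of last n−k bins) — which removes first-order drift bias.
  This is the reference implementation and the oracle in tests.
* Multi-tau estimator: m (default 16) linear lags at native resolution,
  then m/2 lags per level with pairwise bin coarsening, lag spacing
  doubling per level, default depth reaching τ_max ≈ duration/10. The same
  normalization is applied per level, so level-0 lags agree with the
  brute-force estimator to float precision. Coarsening block-averages the
  signal; since every coarse-level lag is ≥ m/2+1 coarse bins, the
  triangular-averaging bias is second order (≲3% of the local curvature)
  and no deconvolution is applied. Lag 0 (shot noise) is never reported.
  Per-lag SDs come from splitting the trace into 10 segments and taking
  the SE across segment ACFs.

## Fitting

Nonlinear fits use bounded trust-region least squares
(`scipy.optimize.least_squares`); lmfit is not a dependency. Particle
numbers and dwell times are searched in log space; dwell times get ≥5
log-spaced multi-starts (the best-RSS start wins). Default bounds:
N ∈ (10⁻⁴, 10⁴), τ_D ∈ (1 µs, 10 s), S ∈ (2, 10). Standard errors come
from the Gauss–Newton curvature at the optimum scaled by residual
variance. Non-convergence and active bounds are flagged on the result,
never silently dropped. Membrane model choice (one vs two 2D components)
is by AICc with a parsimony margin: ΔAICc < 2 prefers the simpler model.

Binding kinetics: saturation data are fitted as specific binding
B_max·L/(K_d+L) (flagged poorly constrained when SE(K_d)/K_d > 1); the
global association fit shares k_on and k_off across ≥2 ligand
concentrations with free per-curve plateaus. Starting rates come from
per-curve log-linear late-phase slopes regressed against concentration,
backed by a multi-start grid. A single concentration is rejected: with a
free amplitude, k_ob = k_on·L + k_off cannot be decomposed from one curve.

## Synthetic data: what is emulated

* **Traces.** Brownian dynamics of point emitters in a periodic box
  (half-widths 4w₀ laterally, 4z₀ axially by default), per-axis step SD
  √(2DΔt), per-bin Poisson photon counts on the summed Gaussian-profile
  emission rates plus background. Membrane simulations add 2D diffusers
  confined to z = 0 with their own D and brightness. No triplet blinking,
  photobleaching, detector dead time or afterpulsing — deliberately
  matching the analysis model's assumptions, so a green recovery test
  establishes estimator correctness, not robustness to photophysics.
* **Particle number is deterministic.** The box holds
  round(C·N_A·V_box) particles (round(σ·A_box) on the membrane plane).
  The closed periodic box has no particle reservoir, so a per-seed Poisson
  count draw would merely freeze in a ±1/√N between-replicate offset
  (CV ≈ 21% at 1.8 nM) and make the generator's concentration claim
  inexact; the deterministic count states the concentration exactly, which
  is what recovery tests should measure against. Number fluctuations
  *inside* the detection volume — the signal FCS lives on — are fully
  present either way.
* **Random streams.** One root `SeedSequence` per call; child streams are
  spawned per particle (and per condition, then per cell, in the gradient
  generator), so enlarging a simulation never reshuffles entities already
  generated. Everything is byte-reproducible from config + seed.
* **Gradients.** Mean concentration
  C(z,t) = c_bulk + (c_near(t) − c_bulk)·exp(−(z−2 µm)/λ) with λ = 15 µm
  by default. The measured profiles show a monotone decline but no
  functional form; the exponential is the simplest monotone choice and λ
  is a knob, not an inference. Near-membrane targets per condition default
  to the measured 2-h values (no cell 5.1, receptor-none 19.2,
  receptor-high 45.7, receptor-high+antagonist 27.1 nM; bulk 1.5 nM).
  Time courses: flat for cell-free reads, linear build-up for
  receptor-absent or antagonist-blocked membranes, saturating exponential
  (default half-time 45 min, the scale suggested by a 17-min residence
  time plus rebinding) for receptor-expressing membranes. Noise is
  mean-one log-normal, CV 0.25 by default (≈ the near-membrane SEM/mean at
  n = 13), independent per cell and reading.
* **Binding plates.** One-site world: K_d = 1.8 nM, k_off = 0.04 min⁻¹,
  k_on = k_off/K_d ≈ 2.22×10⁷ M⁻¹min⁻¹; TR-FRET ratio units (×10,000)
  with B_max = 500, baseline 50, non-specific slope 1 per nM, Gaussian
  noise SD 10 (2% of B_max); association sampled every 30 s for 1 h at
  {0.6, 1.8, 5.4, 16.2} nM, saturation over 0.001–300 nM.

## Statistics

Cell-level values are the replicates (one cell per condition per day).
Profiles report mean ± SEM (SD/√n) per position. One-sample t-tests
against the added concentration accept raw values or printed
(mean, SEM, n) summaries — the routes agree exactly. Two-way ANOVA uses
Type-II sums of squares with interaction (balanced designs from the
generator; unbalanced input is flagged); post-hoc comparisons are Tukey
(all pairs, optionally stratified per distance) and Dunnett (versus a
reference level), with no additional FDR layer. All tests are two-sided
at α = 0.05.

## Numerical notes and limitations

* Trajectories integrate in float32 (positions are wrapped each chunk;
  cumulative error stays ≪ w₀); photon rates accumulate in float64.
* The periodic box makes the simulation a closed system: measured
  amplitudes carry an O(V_eff/V_box) ≈ 1–5% depression relative to the
  open-reservoir model, absorbed by the fitted G∞ and well inside stated
  tolerances; box re-entry slightly truncates the deep ACF tail for slow
  2D species (box crossing time ~1.3 s at D₂D = 5×10⁻¹³ m²/s).
* Membrane 2D particle numbers are small (a few per box at realistic
  surface densities), so per-seed scatter of 2D amplitudes is large;
  recovery contracts are therefore stated on medians over seeds.
* The brightness estimator is cpm (rate/N), not a full photon-counting
  histogram fit; it recovers brightness ratios with the same contract, and
  PCH is out of scope.
* The true-affinity correction is the algebraic substitution
  K_d,true = K_d,app·(L_micro/L_bulk); it inherits the measurement
  uncertainty of L_micro and does not model the gradient mechanistically.
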