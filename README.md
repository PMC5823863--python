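# micropk

Micro-pharmacokinetics: quantifying local drug concentrations at live-cell
membranes with fluorescence correlation spectroscopy (FCS).

Binding affinities are conventionally computed assuming the ligand
concentration at the receptor equals the bulk concentration. Lipophilic
ligands, however, interact with the plasma membrane and with their target
receptors, so the concentration a membrane receptor actually sees
(L<sub>micro</sub>) can be far higher than the added bulk concentration
(L<sub>bulk</sub>). `micropk` implements the full quantification pipeline
for this problem — from photon-count fluctuation traces, through
autocorrelation analysis and confocal-volume calibration, to local
concentrations, membrane-phase estimates, binding kinetics, and the
corrected ("true") affinity

> K<sub>d,true</sub> = K<sub>d,app</sub> · (L<sub>micro</sub> / L<sub>bulk</sub>)

It is aimed at quantitative pharmacologists and single-molecule
spectroscopists who want a tested, scriptable version of this analysis,
together with a physically simulated data generator for validating every
stage.

## The model

FCS records the fluctuating photon count rate of fluorophores diffusing
through a ~0.25 fL confocal volume. The normalized autocorrelation function

G(τ) = ⟨δI(t)·δI(t+τ)⟩ / ⟨I⟩²

of a mixture of diffusing species is

G(τ) = G<sub>∞</sub> + (1/N) Σᵢ φᵢ gᵢ(τ),
 g<sub>3D</sub>(τ) = (1+τ/τ<sub>D</sub>)⁻¹ (1+τ/(S²τ<sub>D</sub>))^(−1/2),
 g<sub>2D</sub>(τ) = (1+τ/τ<sub>D</sub>)⁻¹

with N the mean particle number in the effective volume
V<sub>eff</sub> = π^(3/2) w₀² z₀, dwell time τ<sub>D</sub> = w₀²/4D, and
structure parameter S = z₀/w₀. Calibration against a reference dye of known
D fixes w₀ and S; then C = N/(N<sub>A</sub>·V<sub>eff</sub>) converts the
fitted amplitude to a molar concentration, and membrane reads (one 3D free
component with fixed τ<sub>D</sub>, plus one or two 2D membrane-bound
components) are corrected for the ~9-fold brighter membrane environment
before referencing the bound particle number to a bilayer-height cylinder
π w₀² h.

Receptor binding is characterized by TR-FRET: saturation fits of
B = B<sub>max</sub>L/(K<sub>d</sub>+L) and global association fits of
B(t) = Y<sub>eq</sub>(1−e^(−(k<sub>on</sub>L+k<sub>off</sub>)t)) across
several ligand concentrations.

## Worked example

The core printed quantities, recomputed from their stated inputs
(`micropk demo`):

```
residence half-life at koff = 0.04 /min: 17.3 min (printed as 17 min)
true-affinity correction: fold = 25.4, Kd_true = 45.7 nM
detection volume (cylinder, w0 = 0.2 um, z0 = 1 um): 0.25 fL
near-coverslip 5.1 +/- 0.8 nM vs 1.8 nM: t = 4.125, p = 0.0044
near-coverslip 3.2 +/- 0.4 nM vs 1.8 nM: t = 3.500, p = 0.0100
near-coverslip 3.3 +/- 0.5 nM vs 1.8 nM: t = 3.000, p = 0.0199
```

A ligand residing 17 min on its receptor, local near-membrane
concentrations 25-fold above bulk (hence a corrected K<sub>d</sub> of
~45 nM rather than 1.8 nM), and near-surface concentrations significantly
above the added 1.8 nM are the quantitative story this pipeline tells.

End-to-end, from a simulated photon trace:

```python
from micropk import synthetic, correlator, fcs_models, quantify

cfg = synthetic.SolutionSimConfig(concentration=1.8, duration=8.0, seed=1)
trace = synthetic.simulate_solution_trace(cfg)
acf = correlator.multitau_autocorrelate(trace)
fit = fcs_models.fit_acf(acf, fcs_models.FCSModelSpec.single_3d(1.0, 1e-4, 5.0))
conc = quantify.concentration_from_n(fit.model.total_n, 0.2227e-15)
print(f"{conc:.2f} nM")   # 1.88 nM for this seed (true value 1.8)
```

The `micropk` command-line tool exposes the same pipeline as subcommands
(`simulate`, `correlate`, `fit`, `calibrate`, `quantify`, `kinetics`,
`profile`, `correct`, `demo`), all driven by JSON/YAML configs with JSON
sidecar provenance.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json` runs
the whole pipeline from scratch on seeded synthetic inputs — reference-dye
calibration, solution and membrane reads with fitting and brightness
correction, saturation and global kinetic binding fits, gradient statistics
and the true-affinity correction — printing each stage's recovered
quantities and writing the results file.

See `docs/methods.md` for the model assumptions, simulation design,
numerical choices and known limitations.
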