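"""Synthetic data generation: the pipeline's stated experimental world.

Four generators cover every input the analysis needs:

* Brownian-dynamics photon traces — point emitters diffusing through a 3D
  Gaussian detection profile (optionally plus 2D diffusers confined to the
  membrane plane z = 0), with per-bin Poisson photon statistics.  These are
  the physical stand-in for confocal FCS reads of a fluorescent ligand.
* Noise-free analytic autocorrelation curves (fitting ground truth).
* Distance/time-resolved concentration tables emulating the measured
  near-membrane ligand gradients (an exponential decline from a
  near-membrane value at the 2 um reference height to the bulk value, with
  linear or saturating build-up over incubation time).
* TR-FRET saturation and association plates from a one-site binding model
  (kon = koff/Kd), with total and non-specific series.

Everything is seeded; random streams are split per particle / per cell with
``numpy.random.SeedSequence.spawn`` so enlarging a simulation never
reshuffles the entities already generated.
"""

from __future__ import annotations

import logging
import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .binding import BindingTimeCourse, SaturationDataset
from .correlator import AutocorrelationCurve, IntensityTrace
from .fcs_models import FCSModelSpec, eval_model
from .quantify import AVOGADRO, GAMMA

logger = logging.getLogger(__name__)

__all__ = [
    "SolutionSimConfig",
    "MembraneSimConfig",
    "GradientGeneratorConfig",
    "BindingGeneratorConfig",
    "simulate_solution_trace",
    "simulate_membrane_trace",
    "analytic_acf",
    "generate_gradient_dataset",
    "generate_association_timecourses",
    "generate_saturation_dataset",
]

_MAX_UPDATES = int(1e9)  # particle-bin resource guard
_CHUNK_BINS = 200_000


class SolutionSimConfig(BaseModel):
    """Free-ligand (3D diffusion) trace simulation parameters.

    Defaults describe the standard read: 1.8 nM ligand (the added
    concentration, about 1x Kd), D tuned to a ~140 us dwell time through a
    0.2 um beam waist, a 30-s measurement.
    """

    model_config = ConfigDict(frozen=True)

    concentration: float = 1.8            # nM
    diffusion_coeff: float = 7.142857e-11  # m^2/s  (w0^2 / (4 * 140 us))
    beam_waist_w0: float = 0.2e-6         # m
    axial_radius_z0: float = 1.0e-6       # m
    brightness_eps: float = 30e3          # detected counts/s/molecule (cpm)
    background_rate: float = 0.0          # counts/s
    bin_width: float = 1e-5               # s
    duration: float = 30.0                # s
    box_scale: float = 4.0                # box half-width, multiples of w0 / z0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for name in ("concentration", "diffusion_coeff", "beam_waist_w0",
                     "axial_radius_z0", "brightness_eps", "bin_width", "duration"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("diffusion_coeff", "beam_waist_w0", "axial_radius_z0",
                     "bin_width", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.duration < 1000 * self.bin_width:
            raise ValueError("duration must span at least 1000 bins")
        if self.box_scale < 4:
            raise ValueError("box_scale must be >= 4 (profile negligible at wall)")
        return self


class MembraneSimConfig(SolutionSimConfig):
    """Adds 2D diffusers confined to the membrane plane z = 0."""

    surface_density: float = 2.0e12       # molecules / m^2
    diffusion_coeff_2d: float = 5.0e-13   # m^2/s (tauD_2D = 20 ms at w0 = 0.2 um)
    brightness_ratio: float = 9.1         # 2D-species / 3D-species brightness

    @model_validator(mode="after")
    def _check_membrane(self):
        if self.surface_density < 0:
            raise ValueError("surface_density must be >= 0")
        if not (self.diffusion_coeff_2d > 0 and self.brightness_ratio > 0):
            raise ValueError("diffusion_coeff_2d and brightness_ratio must be positive")
        return self


def _wrap_inplace(x: np.ndarray, span: np.float32) -> None:
    """Periodic wrap of ``x`` into [0, span) in place (floor-multiply form)."""
    f = np.floor(x * np.float32(1.0 / span))
    f *= span
    x -= f


def _accumulate(lam, rng, n_bins, halves, sd_step, inv_sq, eps):
    """Add one particle's emission-rate trajectory to ``lam`` (in place).

    ``halves``: box half-width per axis (2 or 3 axes); ``inv_sq``: the
    Gaussian-profile coefficients 2/w0^2 (lateral) and 2/z0^2 (axial).
    Positions are tracked in float32 relative to the box corner (wrapped
    into [0, 2*half) each chunk), which keeps the cumulative-sum error far
    below the beam waist.
    """
    n_ax = len(halves)
    halves32 = np.asarray(halves, dtype=np.float32)
    spans = 2.0 * halves32
    pos = (rng.uniform(0.0, 1.0, size=n_ax) * spans).astype(np.float32)
    for start in range(0, n_bins, _CHUNK_BINS):
        n = min(_CHUNK_BINS, n_bins - start)
        traj = rng.standard_normal((n_ax, n), dtype=np.float32)
        traj *= sd_step
        traj[:, 0] += pos
        np.cumsum(traj, axis=1, out=traj)
        arg = None
        for ax in range(n_ax):
            row = traj[ax]
            _wrap_inplace(row, spans[ax])
            pos[ax] = row[-1]
            row -= halves32[ax]
            contrib = np.float32(inv_sq[ax]) * np.square(row)
            arg = contrib if arg is None else arg + contrib
        np.negative(arg, out=arg)
        np.exp(arg, out=arg)
        lam[start:start + n] += eps * arg.astype(np.float64)


def _simulate(config: SolutionSimConfig, membrane: bool) -> IntensityTrace:
    n_bins = int(round(config.duration / config.bin_width))
    half = np.array([
        config.box_scale * config.beam_waist_w0,
        config.box_scale * config.beam_waist_w0,
        config.box_scale * config.axial_radius_z0,
    ])
    v_box_l = float(np.prod(2 * half)) * 1e3
    n3d_expected = config.concentration * 1e-9 * AVOGADRO * v_box_l

    root = np.random.SeedSequence(config.seed)
    _ss_reserved, ss_photon, ss_particles = root.spawn(3)
    # the periodic box is a closed system: it holds round(C * N_A * V_box)
    # particles, so the generator states its concentration exactly rather
    # than adding an open-reservoir count draw on top (see docs/methods.md)
    n3d = int(round(n3d_expected)) if config.brightness_eps > 0 else 0

    n2d = 0
    if membrane:
        area = float(4 * half[0] * half[1])
        n2d_expected = config.surface_density * area
        n2d = int(round(n2d_expected)) if config.brightness_eps > 0 else 0

    if config.brightness_eps > 0 and n3d + n2d == 0:
        raise ValueError("zero particles in simulation box; enlarge box or concentration")
    if (n3d + n2d) * n_bins > _MAX_UPDATES:
        raise ValueError(
            f"{(n3d + n2d) * n_bins:.2g} particle-bin updates exceed the "
            f"{_MAX_UPDATES:.0g} resource guard; shorten the trace or shrink the box"
        )

    lam = np.zeros(n_bins)
    sd3 = np.float32(math.sqrt(2 * config.diffusion_coeff * config.bin_width))
    inv3 = (2.0 / config.beam_waist_w0**2, 2.0 / config.beam_waist_w0**2,
            2.0 / config.axial_radius_z0**2)
    streams = ss_particles.spawn(n3d + n2d)
    # brightness_eps is detected counts-per-molecule (mean rate / N_eff);
    # the profile-peak emission rate is cpm / gamma for each geometry
    peak3 = config.brightness_eps / GAMMA["solution_3d"]
    for i in range(n3d):
        _accumulate(lam, np.random.default_rng(streams[i]), n_bins, half, sd3,
                    inv3, peak3)
    if membrane:
        sd2 = np.float32(math.sqrt(2 * config.diffusion_coeff_2d * config.bin_width))
        peak2 = (config.brightness_eps * config.brightness_ratio
                 / GAMMA["membrane_2d"])
        inv2 = (2.0 / config.beam_waist_w0**2, 2.0 / config.beam_waist_w0**2)
        for i in range(n2d):
            _accumulate(lam, np.random.default_rng(streams[n3d + i]), n_bins,
                        half[:2], sd2, inv2, peak2)

    lam *= config.bin_width
    lam += config.background_rate * config.bin_width
    counts = np.random.default_rng(ss_photon).poisson(lam)
    meta = {"config": config.model_dump(), "n_particles_3d": n3d, "seed": config.seed}
    if membrane:
        meta["n_particles_2d"] = n2d
    return IntensityTrace(counts, config.bin_width, meta)


def simulate_solution_trace(config: SolutionSimConfig) -> IntensityTrace:
    """Photon-count trace of freely diffusing 3D emitters.

    Particles follow periodic Brownian steps (per-axis step SD
    sqrt(2 D dt)) in a box of half-widths box_scale * (w0, w0, z0); the
    per-particle emission rate is
    eps_peak * exp(-2(x^2+y^2)/w0^2 - 2 z^2/z0^2) and the detected counts
    per bin are Poisson on the summed rate plus background.  The peak rate
    eps_peak is brightness_eps / gamma_3D, so that brightness_eps is the
    *detected* counts-per-molecule (mean rate / N_eff) — the quantity the
    brightness estimator and the amplitude algebra work with.
    Deterministic given the config seed.
    """
    return _simulate(config, membrane=False)


def simulate_membrane_trace(config: MembraneSimConfig) -> IntensityTrace:
    """As :func:`simulate_solution_trace` plus 2D diffusers on z = 0.

    The membrane-bound species has its own diffusion coefficient and a
    detected brightness of eps * brightness_ratio (peak rate re-referenced
    through the 2D profile factor gamma_2D), emulating the enhanced quantum
    yield of the BODIPY fluorophore in the lipid environment.
    """
    return _simulate(config, membrane=True)


def analytic_acf(model: FCSModelSpec, lags: Sequence[float]) -> AutocorrelationCurve:
    """Exact model ACF on a lag grid — the noise-free fitting oracle."""
    lags = np.asarray(lags, dtype=float)
    return AutocorrelationCurve(lags, eval_model(model, lags),
                                source={"model": "analytic"})


# ---------------------------------------------------------------------------
# gradient measurement tables


CONDITIONS = ("no_cell", "receptor_none", "receptor_high", "receptor_high_ICI")

#: near-membrane (2 um) concentrations per condition after the full 2-h
#: incubation, and the time-course shape each condition follows.  The
#: receptor-present/unblocked condition builds up with a saturating delay
#: (dissociation-limited, t1/2-scale); receptor-absent or antagonist-blocked
#: membranes accumulate linearly; cell-free reads are flat in time.
DEFAULT_C_NEAR = {
    "no_cell": 5.1,
    "receptor_none": 19.2,
    "receptor_high": 45.7,
    "receptor_high_ICI": 27.1,
}
TIME_SHAPE = {
    "no_cell": "constant",
    "receptor_none": "linear",
    "receptor_high": "saturating",
    "receptor_high_ICI": "linear",
}


class GradientGeneratorConfig(BaseModel):
    """Distance/time gradient emulation parameters.

    ``c_near`` applies to the receptor-high condition; other conditions use
    ``condition_c_near`` (all in nM at the 2 um reference height, final
    timepoint).  These mirror the measured values and are emulation knobs,
    not mechanistic ground truth.
    """

    model_config = ConfigDict(frozen=True)

    c_near: float = 45.7                 # nM at 2 um, final time (receptor_high)
    c_bulk: float = 1.5                  # nM far-field
    decay_length: float = 15.0           # um
    distances: tuple[float, ...] = (2, 3, 4, 5, 7, 10, 20, 50, 100, 200)
    timepoints: tuple[float, ...] = (15, 30, 60, 90, 120)  # min
    time_model: Literal["linear", "saturating"] = "saturating"
    time_halflife: float = 45.0          # min, saturating mode
    noise_cv: float = 0.25
    n_cells: int = 13
    conc_floor: float = 0.0              # clip floor, nM
    d_mean: float = 7.142857e-11         # m^2/s, reported diffusion coefficient
    d_cv: float = 0.10
    condition_c_near: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_C_NEAR))
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.c_near >= self.c_bulk > 0:
            raise ValueError("need c_near >= c_bulk > 0")
        if not self.decay_length > 0:
            raise ValueError("decay_length must be positive")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must lie in [0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        return self


def _time_factor(shape: str, t: float, t_final: float, halflife: float) -> float:
    """Fraction of the final near-membrane excess present at time t."""
    if shape == "constant" or t >= t_final:
        return 1.0
    if shape == "linear":
        return t / t_final
    # saturating: exponential approach, normalized to 1 at the final timepoint
    k = math.log(2.0) / halflife
    return (1.0 - math.exp(-k * t)) / (1.0 - math.exp(-k * t_final))


def gradient_true_mean(config: GradientGeneratorConfig, condition: str,
                       distance_um: float, time_min: float) -> float:
    """Noise-free mean concentration C(z, t) for one condition (nM)."""
    c_near_final = (config.c_near if condition == "receptor_high"
                    else config.condition_c_near[condition])
    shape = TIME_SHAPE[condition]
    if config.time_model == "linear" and shape == "saturating":
        shape = "linear"  # global override knob
    f = _time_factor(shape, time_min, max(config.timepoints), config.time_halflife)
    c_near_t = config.c_bulk + (c_near_final - config.c_bulk) * f
    return config.c_bulk + (c_near_t - config.c_bulk) * math.exp(
        -(distance_um - 2.0) / config.decay_length
    )


def generate_gradient_dataset(config: GradientGeneratorConfig) -> pd.DataFrame:
    """Per-cell concentration/diffusion table over condition x distance x time.

    Multiplicative log-normal noise with the configured CV (mean-one), drawn
    independently per cell and reading; per-cell random streams are spawned
    from the root seed so increasing ``n_cells`` leaves earlier cells
    untouched.  Columns: cell_id, condition, distance_um, time_min, conc_nM,
    diff_coeff_m2s.
    """
    root = np.random.SeedSequence(config.seed)
    # one child sequence per condition, then one stream per cell within it:
    # growing n_cells extends each condition's stream list without touching
    # the cells already generated
    condition_seqs = root.spawn(len(config.conditions))
    sig_c = math.sqrt(math.log(1.0 + config.noise_cv**2))
    sig_d = math.sqrt(math.log(1.0 + config.d_cv**2))
    rows = []
    n_clipped = 0
    for ci, condition in enumerate(config.conditions):
        cell_streams = condition_seqs[ci].spawn(config.n_cells)
        for cell in range(config.n_cells):
            rng = np.random.default_rng(cell_streams[cell])
            cell_id = f"{condition}_cell{cell:02d}"
            for t in config.timepoints:
                for z in config.distances:
                    mu = gradient_true_mean(config, condition, z, t)
                    noise = rng.lognormal(-0.5 * sig_c**2, sig_c) if sig_c else 1.0
                    conc = mu * noise
                    if conc < config.conc_floor:
                        conc = config.conc_floor
                        n_clipped += 1
                    dnoise = rng.lognormal(-0.5 * sig_d**2, sig_d) if sig_d else 1.0
                    rows.append((cell_id, condition, float(z), float(t),
                                 conc, config.d_mean * dnoise))
    if n_clipped:
        logger.warning("clipped %d generated concentrations at floor %.3g nM",
                       n_clipped, config.conc_floor)
    return pd.DataFrame(rows, columns=["cell_id", "condition", "distance_um",
                                       "time_min", "conc_nM", "diff_coeff_m2s"])


# ---------------------------------------------------------------------------
# TR-FRET binding plates


class BindingGeneratorConfig(BaseModel):
    """One-site binding world: Kd 1.8 nM, koff 0.04 /min, kon = koff/Kd.

    Signals are in TR-FRET ratio units (665/620 x 10,000).  The association
    design reads every 30 s for an hour at four ligand concentrations
    bracketing Kd; saturation spans 0.001-300 nM.
    """

    model_config = ConfigDict(frozen=True)

    kd: float = 1.8                       # nM
    bmax_signal: float = 500.0            # ratio units
    koff: float = 0.04                    # 1/min
    ligand_concs: tuple[float, ...] = (0.6, 1.8, 5.4, 16.2)  # nM
    times: tuple[float, ...] = tuple(np.arange(0.0, 60.001, 0.5))  # min
    ns_slope: float = 1.0                 # ratio units per nM
    baseline: float = 50.0                # ratio units
    noise_sd: float = 10.0                # ratio units (2% of Bmax)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not (self.kd > 0 and self.koff > 0):
            raise ValueError("kd and koff must be positive")
        if self.noise_sd < 0 or self.ns_slope < 0:
            raise ValueError("noise_sd and ns_slope must be non-negative")
        if len(self.ligand_concs) < 1 or any(c <= 0 for c in self.ligand_concs):
            raise ValueError("ligand concentrations must be positive")
        return self

    @property
    def kon_per_nm(self) -> float:
        """Association rate constant, nM^-1 min^-1 (= koff / Kd)."""
        return self.koff / self.kd


def generate_association_timecourses(
    config: BindingGeneratorConfig,
) -> list[BindingTimeCourse]:
    """Total + non-specific association reads per ligand concentration.

    total(t; L) = baseline + ns_slope*L
                  + bmax * L/(L+Kd) * (1 - exp(-(kon*L + koff) t)) + noise,
    NSB(t; L)  = baseline + ns_slope*L + noise.
    """
    if len(config.ligand_concs) < 2:
        raise ValueError("association design needs >= 2 ligand concentrations")
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.ligand_concs))
    t = np.asarray(config.times, dtype=float)
    out = []
    for ss, conc in zip(streams, config.ligand_concs):
        rng = np.random.default_rng(ss)
        kob = config.kon_per_nm * conc + config.koff
        y_eq = config.bmax_signal * conc / (conc + config.kd)
        ns = config.baseline + config.ns_slope * conc
        total = ns + y_eq * (1.0 - np.exp(-kob * t))
        nsb = np.full_like(t, ns)
        if config.noise_sd:
            total = total + rng.normal(0, config.noise_sd, t.size)
            nsb = nsb + rng.normal(0, config.noise_sd, t.size)
        out.append(BindingTimeCourse(conc, t, total, nsb,
                                     label=f"L={conc:g}nM"))
    return out


def generate_saturation_dataset(
    config: BindingGeneratorConfig,
    concs: Sequence[float] | None = None,
) -> SaturationDataset:
    """Equilibrium total/NSB pairs across a concentration range spanning Kd."""
    if concs is None:
        concs = np.geomspace(0.001, 300.0, 12)
    concs = np.asarray(sorted(concs), dtype=float)
    if not (concs.min() < config.kd < concs.max()):
        raise ValueError("saturation range must span Kd")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ns = config.baseline + config.ns_slope * concs
    total = ns + config.bmax_signal * concs / (concs + config.kd)
    nsb = ns.copy()
    if config.noise_sd:
        total = total + rng.normal(0, config.noise_sd, concs.size)
        nsb = nsb + rng.normal(0, config.noise_sd, concs.size)
    return SaturationDataset(concs, total, nsb)
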