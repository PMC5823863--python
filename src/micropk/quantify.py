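"""From fit parameters to physical quantities.

The confocal detection volume is calibrated from a reference-dye fit
(dwell time + structure parameter) and the dye's literature diffusion
coefficient; particle numbers then convert to molar concentration via the
effective volume, and dwell times to diffusion coefficients via the beam
waist.  Membrane reads additionally need a molecular-brightness correction
(bound ligand is brighter in the lipid environment than in water) before
the membrane-bound particle number is referenced to a thin cylindrical
volume spanning the bilayer.

Unit policy: SI internally (m, s, m^2/s, counts/s); user-facing
concentrations in nM, volumes in litres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .correlator import IntensityTrace
from .fcs_models import FCSFitResult

__all__ = [
    "AVOGADRO",
    "CalibrationResult",
    "BrightnessResult",
    "MembraneEstimate",
    "ConcentrationMeasurement",
    "calibrate_volume",
    "concentration_from_n",
    "particles_from_concentration",
    "diffusion_from_dwell",
    "brightness_cpm",
    "brightness_ratio",
    "correct_two_species_numbers",
    "membrane_concentration",
]

AVOGADRO = 6.02214076e23  # mol^-1

#: detection-profile shape factors (integral W / V_eff): the ratio between
#: the detected counts-per-molecule (mean rate / N_eff) and the profile-peak
#: emission rate.  3D Gaussian: 2^-3/2; 2D Gaussian: 1/2.  All user-facing
#: brightness values in this package are detected-cpm-referenced, which is
#: what the FCS amplitude algebra and PCH-style outputs operate on; GAMMA is
#: used by the simulator to convert a requested cpm into a peak rate.
GAMMA = {"solution_3d": 2.0 ** -1.5, "membrane_2d": 0.5}

Convention = Literal["gaussian", "cylinder"]


def _v_eff_m3(w0: float, z0: float, convention: Convention) -> float:
    if convention == "gaussian":
        return float(np.pi ** 1.5 * w0**2 * z0)
    if convention == "cylinder":
        return float(np.pi * w0**2 * 2 * z0)
    raise ValueError("convention must be 'gaussian' or 'cylinder'")


@dataclass(frozen=True)
class CalibrationResult:
    """Detection-volume geometry from a reference-dye measurement."""

    beam_waist_w0: float        # m
    structure_parameter: float  # z0 / w0
    axial_radius_z0: float      # m
    effective_volume: float     # L
    convention: Convention
    calibration_dye_d: float    # m^2/s
    session: str = ""

    def __post_init__(self):
        if min(self.beam_waist_w0, self.axial_radius_z0, self.effective_volume) <= 0:
            raise ValueError("geometry must be positive")
        if abs(self.axial_radius_z0 - self.structure_parameter * self.beam_waist_w0) \
                > 1e-9 * self.axial_radius_z0:
            raise ValueError("z0 must equal S * w0")


def calibrate_volume(
    dye_fit: FCSFitResult,
    dye_d: float,
    convention: Convention = "gaussian",
    session: str = "",
) -> CalibrationResult:
    """Calibrate w0, z0 and V_eff from a single-3D reference-dye fit.

    w0 = sqrt(4 * D_dye * tauD); z0 = S * w0;
    V_eff = pi^(3/2) w0^2 z0 (gaussian) or pi w0^2 * 2 z0 (cylinder).
    """
    if not dye_fit.converged:
        raise ValueError("calibration fit did not converge")
    comps = dye_fit.model.components
    if len(comps) != 1 or comps[0].kind != "3d":
        raise ValueError("calibration requires a single-3D-component fit")
    if not dye_d > 0:
        raise ValueError("dye diffusion coefficient must be positive")
    tau_d = comps[0].tau_d
    s = dye_fit.model.structure_parameter
    w0 = float(np.sqrt(4.0 * dye_d * tau_d))
    z0 = s * w0
    v_eff_l = _v_eff_m3(w0, z0, convention) * 1e3  # m^3 -> L
    return CalibrationResult(w0, s, z0, v_eff_l, convention, dye_d, session)


def concentration_from_n(n: float, v_eff: float) -> float:
    """Molar concentration (nM) from particle number and effective volume (L)."""
    if n < 0 or v_eff <= 0:
        raise ValueError("need n >= 0 and v_eff > 0")
    return n / (AVOGADRO * v_eff) * 1e9


def particles_from_concentration(c_nm: float, v_eff: float) -> float:
    """Mean particle number in ``v_eff`` litres at ``c_nm`` nM."""
    if c_nm < 0 or v_eff <= 0:
        raise ValueError("need c >= 0 and v_eff > 0")
    return c_nm * 1e-9 * AVOGADRO * v_eff


def diffusion_from_dwell(tau_d: float, w0: float) -> float:
    """Diffusion coefficient D = w0^2 / (4 tauD), in m^2/s."""
    if tau_d <= 0 or w0 <= 0:
        raise ValueError("tau_d and w0 must be positive")
    return w0**2 / (4.0 * tau_d)


@dataclass(frozen=True)
class BrightnessResult:
    """Detected counts per molecule per second (mean rate / fitted N)."""

    cpm: float
    environment: str
    ratio: float | None = None  # this / reference, when paired

    def __post_init__(self):
        if not self.cpm > 0:
            raise ValueError("cpm must be positive")


def brightness_cpm(
    trace: IntensityTrace,
    n: float,
    environment: str = "solution_3d",
    background_rate: float = 0.0,
) -> BrightnessResult:
    """Molecular brightness from mean count rate and fitted particle number.

    cpm = (mean rate - background) / n, with n the particle number fitted
    from the ACF amplitude.  This detected counts-per-molecule is the same
    quantity the FCS amplitude algebra weights species by, so the
    membrane/solution cpm ratio is exactly the r that
    :func:`correct_two_species_numbers` needs.  The environment label is
    recorded so paired estimates state which detection geometry they came
    from.
    """
    if n <= 0:
        raise ValueError("particle number must be positive")
    if environment not in GAMMA:
        raise ValueError(f"environment must be one of {sorted(GAMMA)}")
    cpm = (trace.mean_rate - background_rate) / n
    return BrightnessResult(cpm, environment)


def brightness_ratio(sample: BrightnessResult, reference: BrightnessResult) -> BrightnessResult:
    """Pair a brightness estimate with a reference (ratio = sample/reference)."""
    return BrightnessResult(sample.cpm, sample.environment, sample.cpm / reference.cpm)


def correct_two_species_numbers(
    n_apparent_total: float,
    fraction_2d: float,
    r: float,
) -> tuple[float, float]:
    """Invert the equal-brightness fit for unequal molecular brightness.

    The fitted (apparent) amplitudes assume equal brightness; physically each
    species i with particle number N_i and brightness eps_i contributes

        G_i(0) = N_i eps_i^2 / (sum_j N_j eps_j)^2,

    while the fit reports G_i(0) = phi_i / N_app.  With eps_2D/eps_3D = r
    the closed-form inversion is

        N_3D = phi_3D * N_app / (phi_3D + phi_2D / r)^2
        N_2D = (phi_2D / r^2) * N_app / (phi_3D + phi_2D / r)^2.

    r = 1 returns the uncorrected split exactly; fraction 0 or 1 degenerates
    to the single-species case, where normalization cancels the brightness
    and N equals the apparent number.
    """
    if not 0 <= fraction_2d <= 1:
        raise ValueError("fraction_2d must lie in [0, 1]")
    if r <= 0:
        raise ValueError("brightness ratio must be positive")
    if n_apparent_total < 0:
        raise ValueError("apparent particle number must be non-negative")
    if fraction_2d in (0.0, 1.0):  # single species: amplitude is 1/N regardless of eps
        n2 = n_apparent_total * fraction_2d
        return n_apparent_total - n2, n2
    phi3 = 1.0 - fraction_2d
    denom = (phi3 + fraction_2d / r) ** 2
    n3 = phi3 * n_apparent_total / denom
    n2 = (fraction_2d / r**2) * n_apparent_total / denom
    return n3, n2


@dataclass(frozen=True)
class MembraneEstimate:
    """Membrane-phase concentration from the corrected 2D particle number."""

    n2d_apparent: float
    brightness_ratio: float
    n2d_corrected: float
    cylinder_height: float   # m
    cylinder_volume: float   # L
    conc_membrane: float     # nM


def membrane_concentration(
    n2d_corrected: float,
    w0: float,
    h: float = 5e-9,
    n2d_apparent: float | None = None,
    r: float = 1.0,
) -> MembraneEstimate:
    """Membrane concentration referencing N_2D to a bilayer-height cylinder.

    The cylinder has the beam-waist cross-section and height ``h`` (default
    5 nm, a lipid-bilayer thickness): V = pi w0^2 h, C = N / (N_A V).
    Independent of z0/S — only the lateral beam waist and bilayer height
    enter.
    """
    if min(n2d_corrected, w0, h) < 0 or w0 == 0 or h == 0:
        raise ValueError("n2d_corrected >= 0 and w0, h > 0 required")
    v_cyl_l = float(np.pi * w0**2 * h) * 1e3
    conc = concentration_from_n(n2d_corrected, v_cyl_l)
    return MembraneEstimate(
        n2d_apparent if n2d_apparent is not None else n2d_corrected,
        r, n2d_corrected, h, v_cyl_l, conc,
    )


@dataclass(frozen=True)
class ConcentrationMeasurement:
    """One cell's local concentration / diffusion reading at a position."""

    cell_id: str
    condition: str           # no_cell | receptor_none | receptor_high | receptor_high_ICI
    distance_um: float       # height above membrane (cells) or coverslip (no cell)
    time_min: float
    conc_nm: float
    diff_coeff: float        # m^2/s

    def __post_init__(self):
        if self.distance_um < 0 or self.conc_nm < 0:
            raise ValueError("distance and concentration must be non-negative")
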