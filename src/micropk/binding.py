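"""TR-FRET equilibrium and kinetic ligand-binding analysis.

Receptor occupancy is read out as a time-resolved FRET ratio (acceptor
665 nm over donor 620 nm emission, scaled by 10,000).  Non-specific signal,
measured in the presence of a saturating unlabelled antagonist, is
subtracted from total signal to give specific binding.  Equilibrium
saturation data follow the one-site law B = Bmax L / (Kd + L); association
time courses follow B(t) = Y_eq (1 - exp(-kob t)) with the observed rate
kob = kon L + koff, so a global fit across several ligand concentrations
identifies kon and koff jointly (a single amplitude-free curve cannot
separate them — hence the >= 2 concentration requirement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "BindingTimeCourse",
    "SaturationDataset",
    "SaturationFit",
    "KineticFit",
    "tr_fret_ratio",
    "specific_binding",
    "fit_saturation",
    "fit_association_global",
    "half_life",
]


@dataclass(frozen=True)
class BindingTimeCourse:
    """Total and non-specific TR-FRET ratio reads at one ligand concentration."""

    ligand_conc: float          # nM
    times: np.ndarray           # min, strictly increasing
    ratio_total: np.ndarray
    ratio_nsb: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        tot = np.asarray(self.ratio_total, dtype=float)
        nsb = np.asarray(self.ratio_nsb, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (t.shape == tot.shape == nsb.shape):
            raise ValueError("times, total and NSB must have equal lengths")
        if not self.ligand_conc > 0:
            raise ValueError("ligand_conc must be positive")
        for name, arr in (("times", t), ("ratio_total", tot), ("ratio_nsb", nsb)):
            object.__setattr__(self, name, arr)

    @property
    def specific(self) -> np.ndarray:
        return specific_binding(self.ratio_total, self.ratio_nsb)


@dataclass(frozen=True)
class SaturationDataset:
    """Equilibrium total/NSB reads across a ligand concentration range."""

    ligand_concs: np.ndarray    # nM, strictly increasing
    totals: np.ndarray
    nsbs: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.ligand_concs, dtype=float)
        tot = np.asarray(self.totals, dtype=float)
        nsb = np.asarray(self.nsbs, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if not (c.shape == tot.shape == nsb.shape):
            raise ValueError("concentrations, totals and NSBs must match")
        object.__setattr__(self, "ligand_concs", c)
        object.__setattr__(self, "totals", tot)
        object.__setattr__(self, "nsbs", nsb)

    @property
    def specific(self) -> np.ndarray:
        return specific_binding(self.totals, self.nsbs)


@dataclass(frozen=True)
class SaturationFit:
    kd: float                   # nM
    bmax: float                 # ratio units
    kd_se: float
    bmax_se: float
    converged: bool
    poorly_constrained: bool = False
    message: str = ""


@dataclass(frozen=True)
class KineticFit:
    kon: float                  # M^-1 min^-1
    koff: float                 # min^-1
    kon_se: float
    koff_se: float
    y_eq: Mapping[float, float] = field(default_factory=dict)  # per ligand conc
    converged: bool = True
    message: str = ""

    @property
    def kd_kinetic(self) -> float:
        """Equilibrium Kd from rates: koff / kon, in nM."""
        return self.koff / self.kon * 1e9

    @property
    def t_half(self) -> float:
        """Residence half-life ln2 / koff, in min."""
        return half_life(self.koff)


def tr_fret_ratio(em665, em620) -> np.ndarray | float:
    """TR-FRET ratio: 10,000 x (665 nm emission / 620 nm emission)."""
    em665 = np.asarray(em665, dtype=float)
    em620 = np.asarray(em620, dtype=float)
    if np.any(em620 <= 0):
        raise ValueError("620 nm donor counts must be positive")
    out = 1e4 * em665 / em620
    return out if out.ndim else float(out)


def specific_binding(total, nsb) -> np.ndarray | float:
    """Elementwise total minus non-specific; negatives preserved, not clipped."""
    total = np.asarray(total, dtype=float)
    nsb = np.asarray(nsb, dtype=float)
    if total.shape != nsb.shape:
        raise ValueError("total and NSB series must be aligned")
    out = total - nsb
    return out if out.ndim else float(out)


def fit_saturation(data: SaturationDataset) -> SaturationFit:
    """One-site fit of specific binding: B = Bmax L / (Kd + L).

    Flags the result as poorly constrained when SE(Kd)/Kd > 1 (e.g. all
    concentrations far below Kd).
    """
    if data.ligand_concs.size < 6:
        raise ValueError("saturation fit needs >= 6 concentrations")
    conc, spec = data.ligand_concs, data.specific

    def model(l, bmax, kd):
        return bmax * l / (kd + l)

    p0 = (max(spec.max(), 1e-9), float(np.median(conc)))
    try:
        popt, pcov = curve_fit(model, conc, spec, p0=p0,
                               bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=10000)
    except Exception as e:  # pragma: no cover - pathological input
        return SaturationFit(np.nan, np.nan, np.nan, np.nan, False, message=str(e))
    bmax, kd = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    poorly = bool(not np.isfinite(se[1]) or se[1] / kd > 1)
    return SaturationFit(float(kd), float(bmax), float(se[1]), float(se[0]),
                         True, poorly)


def _initial_rates(datasets: Sequence[BindingTimeCourse]) -> tuple[float, float]:
    """Heuristic kon (nM^-1 min^-1), koff from per-curve single-exponential fits."""
    kobs, concs = [], []
    for d in datasets:
        spec = d.specific
        plateau = float(np.mean(spec[-max(3, spec.size // 10):]))
        if plateau <= 0:
            continue
        # log-linear slope of the approach to plateau over the rising phase
        resid = plateau - spec
        mask = resid > 0.05 * plateau
        if mask.sum() < 3:
            continue
        slope = np.polyfit(d.times[mask], np.log(resid[mask]), 1)[0]
        if slope < 0:
            kobs.append(-slope)
            concs.append(d.ligand_conc)
    if len(kobs) >= 2:
        kon, koff = np.polyfit(concs, kobs, 1)
        if kon > 0 and koff > 0:
            return float(kon), float(koff)
    if kobs:
        return float(min(kobs) / (2 * min(concs))), float(min(kobs) / 2)
    return 0.01, 0.01


def fit_association_global(datasets: Sequence[BindingTimeCourse]) -> KineticFit:
    """Global association fit with shared kon/koff, free per-curve plateaus.

    Fits specific(t; L) = Y_eq(L) (1 - exp(-(kon L + koff) t)) jointly over
    all time courses.  Rates are searched in log space; the heuristic start
    (kob-vs-L regression of per-curve exponential rates) is backed by a
    log-spaced multi-start grid.  Returns kon in M^-1 min^-1.
    """
    datasets = list(datasets)
    concs = sorted({d.ligand_conc for d in datasets})
    if len(concs) < 2:
        raise ValueError(
            "global association fitting needs >= 2 distinct ligand concentrations: "
            "koff is not identifiable from amplitude-free single-curve fits"
        )
    t_all = [d.times for d in datasets]
    y_all = [d.specific for d in datasets]
    n_sets = len(datasets)

    def unpack(x):
        kon, koff = np.exp(x[0]), np.exp(x[1])
        return kon, koff, x[2:]

    def residuals(x):
        kon, koff, yeq = unpack(x)
        res = []
        for d, t, y, a in zip(datasets, t_all, y_all, yeq):
            kob = kon * d.ligand_conc + koff
            res.append(a * (1.0 - np.exp(-kob * t)) - y)
        return np.concatenate(res)

    kon0, koff0 = _initial_rates(datasets)
    yeq0 = [max(float(np.mean(y[-max(3, y.size // 10):])), 1e-6) for y in y_all]
    starts = [(kon0, koff0)]
    starts += [(k, f) for k in (1e-3, 1e-2, 1e-1) for f in (1e-3, 1e-2, 1e-1)]
    best = None
    for kon_s, koff_s in starts:
        x0 = np.concatenate(([np.log(kon_s), np.log(koff_s)], yeq0))
        lo = np.concatenate(([np.log(1e-8), np.log(1e-8)], np.full(n_sets, -np.inf)))
        hi = np.concatenate(([np.log(1e4), np.log(1e4)], np.full(n_sets, np.inf)))
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return KineticFit(np.nan, np.nan, np.nan, np.nan, {}, False,
                          "all starts failed")

    kon_nm, koff, yeq = unpack(best.x)
    dof = sum(y.size for y in y_all) - best.x.size
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac) * (2 * best.cost / max(dof, 1))
        kon_se = float(np.sqrt(max(cov[0, 0], 0)) * kon_nm)
        koff_se = float(np.sqrt(max(cov[1, 1], 0)) * koff)
    except Exception:
        kon_se = koff_se = np.nan
    return KineticFit(
        kon=kon_nm * 1e9,            # nM^-1 min^-1 -> M^-1 min^-1
        koff=float(koff),
        kon_se=kon_se * 1e9,
        koff_se=koff_se,
        y_eq={d.ligand_conc: float(a) for d, a in zip(datasets, yeq)},
        converged=bool(best.status > 0),
        message=str(best.message),
    )


def half_life(koff: float) -> float:
    """Residence half-life t1/2 = ln2 / koff (min for koff in 1/min)."""
    if not koff > 0:
        raise ValueError("koff must be positive")
    return float(np.log(2.0) / koff)
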