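"""FCS diffusion models and weighted least-squares fitting.

The normalized ACF of a mixture of diffusing species, under the
equal-brightness amplitude convention, is

    G(tau) = G_inf + (1/N) * sum_i phi_i * g_i(tau)

with the per-species decay laws for a 3D Gaussian detection volume of
beam waist w0 and structure parameter S = z0/w0:

    g_3D(tau) = (1 + tau/tauD)^-1 * (1 + tau/(S^2 tauD))^-1/2
    g_2D(tau) = (1 + tau/tauD)^-1

N is the (apparent) mean particle number in the effective volume, phi_i
the amplitude fractions (sum to 1), and G_inf an offset guarding against
residual drift.  Unequal molecular brightness between species is *not*
modelled here — exactly as in vendor fitting software, it is corrected
downstream (see :func:`micropk.quantify.correct_two_species_numbers`).

Membrane reads are fitted with one 3D component (free ligand, dwell time
fixed to the same-day solution value) plus one or two 2D components
(membrane-bound ligand); :func:`select_membrane_model` chooses between the
two by AICc.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .correlator import AutocorrelationCurve

__all__ = [
    "FCSComponent",
    "FCSModelSpec",
    "FCSFitResult",
    "eval_model",
    "fit_acf",
    "select_membrane_model",
]

# default parameter bounds when free
BOUNDS = {
    "total_n": (1e-4, 1e4),
    "tau_d": (1e-6, 10.0),
    "structure_parameter": (2.0, 10.0),
    "g_inf": (-0.5, 0.5),
    "fraction": (0.0, 1.0),
}


@dataclass(frozen=True)
class FCSComponent:
    kind: Literal["3d", "2d"]
    tau_d: float            # dwell time, s
    fraction: float = 1.0   # amplitude fraction

    def __post_init__(self):
        if self.kind not in ("3d", "2d"):
            raise ValueError("component kind must be '3d' or '2d'")
        if not self.tau_d > 0:
            raise ValueError("tau_d must be positive")
        if not 0 <= self.fraction <= 1 + 1e-12:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FCSModelSpec:
    """Mixture model: components, total particle number, S, offset."""

    components: tuple[FCSComponent, ...]
    total_n: float
    structure_parameter: float = 5.0
    g_inf: float = 0.0

    def __post_init__(self):
        comps = tuple(self.components)
        if not 1 <= len(comps) <= 3:
            raise ValueError("1 to 3 components supported")
        if abs(sum(c.fraction for c in comps) - 1.0) > 1e-6:
            raise ValueError("component fractions must sum to 1")
        n3d = sum(c.kind == "3d" for c in comps)
        if len(comps) > 1 and n3d != 1:
            raise ValueError("membrane-mode mixtures need exactly one 3D component")
        if not self.total_n > 0:
            raise ValueError("total_n must be positive")
        if not self.structure_parameter > 1:
            raise ValueError("structure parameter must exceed 1")
        object.__setattr__(self, "components", comps)

    @staticmethod
    def single_3d(total_n: float, tau_d: float, structure_parameter: float = 5.0,
                  g_inf: float = 0.0) -> "FCSModelSpec":
        return FCSModelSpec((FCSComponent("3d", tau_d),), total_n,
                            structure_parameter, g_inf)

    @staticmethod
    def single_2d(total_n: float, tau_d: float, g_inf: float = 0.0) -> "FCSModelSpec":
        return FCSModelSpec((FCSComponent("2d", tau_d),), total_n, 5.0, g_inf)

    @staticmethod
    def membrane(total_n: float, tau_3d: float, tau_2d: Sequence[float],
                 fraction_2d: Sequence[float], structure_parameter: float = 5.0,
                 g_inf: float = 0.0) -> "FCSModelSpec":
        """One 3D component plus one or two 2D components."""
        tau_2d = tuple(tau_2d)
        fraction_2d = tuple(fraction_2d)
        if len(tau_2d) != len(fraction_2d) or not 1 <= len(tau_2d) <= 2:
            raise ValueError("need 1 or 2 matched 2D dwell times / fractions")
        f3 = 1.0 - sum(fraction_2d)
        comps = (FCSComponent("3d", tau_3d, f3),) + tuple(
            FCSComponent("2d", t, f) for t, f in zip(tau_2d, fraction_2d)
        )
        return FCSModelSpec(comps, total_n, structure_parameter, g_inf)


def eval_model(model: FCSModelSpec, lag) -> np.ndarray | float:
    """Evaluate G(tau) for the model at scalar or array lag (seconds)."""
    tau = np.asarray(lag, dtype=float)
    s2 = model.structure_parameter**2
    g = np.zeros_like(tau)
    for c in model.components:
        x = tau / c.tau_d
        gi = 1.0 / (1.0 + x)
        if c.kind == "3d":
            gi = gi / np.sqrt(1.0 + x / s2)
        g = g + c.fraction * gi
    out = model.g_inf + g / model.total_n
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FCSFitResult:
    model: FCSModelSpec
    param_se: Mapping[str, float]
    rss: float
    aicc: float
    n_lags: int
    converged: bool
    fixed: Mapping[str, float] = field(default_factory=dict)
    message: str = ""
    at_bounds: tuple[str, ...] = ()

    @property
    def n_free(self) -> int:
        return len(self.param_se)


# ---------------------------------------------------------------------------
# fitting machinery: a flat named-parameter vector over a model template


def _param_names(template: FCSModelSpec) -> list[str]:
    names = ["total_n", "structure_parameter", "g_inf"]
    names += [f"tau_d_{i}" for i in range(len(template.components))]
    # fractions of all but the first component are free; first = 1 - rest
    names += [f"fraction_{i}" for i in range(1, len(template.components))]
    return names


def _build_model(template: FCSModelSpec, values: Mapping[str, float]) -> FCSModelSpec:
    k = len(template.components)
    fracs = [float(values[f"fraction_{i}"]) for i in range(1, k)]
    total = sum(fracs)
    if total > 1.0:  # box-bounded fractions can transiently overshoot; renormalize
        fracs = [f / total for f in fracs]
        total = 1.0
    f0 = 1.0 - total
    comps = []
    for i, c in enumerate(template.components):
        f = f0 if i == 0 else fracs[i - 1]
        comps.append(FCSComponent(c.kind, float(values[f"tau_d_{i}"]), min(max(f, 0.0), 1.0)))
    return FCSModelSpec(tuple(comps), float(values["total_n"]),
                        float(values["structure_parameter"]), float(values["g_inf"]))


def _template_values(template: FCSModelSpec) -> dict[str, float]:
    vals = {
        "total_n": template.total_n,
        "structure_parameter": template.structure_parameter,
        "g_inf": template.g_inf,
    }
    for i, c in enumerate(template.components):
        vals[f"tau_d_{i}"] = c.tau_d
        if i > 0:
            vals[f"fraction_{i}"] = c.fraction
    return vals


def _bound_for(name: str) -> tuple[float, float]:
    if name.startswith("tau_d"):
        return BOUNDS["tau_d"]
    if name.startswith("fraction"):
        return BOUNDS["fraction"]
    return BOUNDS[name]


def _aicc(rss: float, n: int, k: int) -> float:
    # least-squares AICc with Gaussian errors, +2k small-sample correction
    if n <= k + 1 or rss <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_acf(
    acf: AutocorrelationCurve,
    model_template: FCSModelSpec,
    fixed: Mapping[str, float] | Sequence[str] = ("structure_parameter",),
    weights: np.ndarray | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
) -> FCSFitResult:
    """Weighted least-squares fit of a diffusion-model template to an ACF.

    ``fixed`` names parameters held at the template's value (a mapping
    overrides the value).  Parameter names: ``total_n``,
    ``structure_parameter``, ``g_inf``, ``tau_d_<i>`` and ``fraction_<i>``
    for component index i (component 0's fraction is the complement and is
    never free).  Dwell times and total_n are searched in log space with
    >= ``n_starts`` log-spaced dwell-time restarts; the lowest-RSS start
    wins.  Standard errors come from the Gauss-Newton curvature at the
    optimum.  Non-convergence and active bounds are flagged, never silent.
    """
    names = _param_names(model_template)
    values = _template_values(model_template)
    if isinstance(fixed, Mapping):
        fixed_map = {k: float(v) for k, v in fixed.items()}
    else:
        fixed_map = {k: values[k] for k in fixed}
    for k in fixed_map:
        if k not in names:
            raise ValueError(f"unknown fixed parameter {k!r}")
    values.update(fixed_map)
    free = [n for n in names if n not in fixed_map]
    if len(acf) < len(free) + 5:
        raise ValueError("need at least 5 more lags than free parameters")

    lags, g_obs = acf.lags, acf.g_values
    if weights is None:
        w = np.ones_like(g_obs)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != g_obs.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per lag")

    user_bounds = dict(bounds or {})
    log_scale = [n.startswith("tau_d") or n == "total_n" for n in free]

    def pack(vals: Mapping[str, float]) -> np.ndarray:
        return np.array([np.log(vals[n]) if lg else vals[n]
                         for n, lg in zip(free, log_scale)])

    def unpack(x: np.ndarray) -> dict[str, float]:
        out = dict(values)
        for n, lg, xi in zip(free, log_scale, x):
            out[n] = float(np.exp(xi)) if lg else float(xi)
        return out

    lo, hi = [], []
    for n, lg in zip(free, log_scale):
        b = user_bounds.get(n, _bound_for(n))
        lo.append(np.log(b[0]) if lg else b[0])
        hi.append(np.log(b[1]) if lg else b[1])
    lo, hi = np.array(lo), np.array(hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        return w * (eval_model(_build_model(model_template, unpack(x)), lags) - g_obs)

    # multi-start over log-spaced dwell times for the free tau parameters
    free_taus = [n for n in free if n.startswith("tau_d")]
    tau_grid = np.geomspace(max(lags[0], 1e-6), lags[-1], n_starts)
    starts = [dict(values)]
    for combo in itertools.product(tau_grid, repeat=len(free_taus)):
        if len(free_taus) == 2 and combo[0] >= combo[1]:
            continue  # keep 2x2D dwell times ordered to halve the grid
        s = dict(values)
        s.update({n: t for n, t in zip(free_taus, combo)})
        starts.append(s)

    best = None
    for s in starts:
        x0 = np.clip(pack(s), lo, hi)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FCSFitResult(model_template, {}, np.inf, np.inf, len(acf),
                            False, fixed_map, "all starts failed")

    vals = unpack(best.x)
    fitted = _build_model(model_template, vals)
    rss = float(np.sum((eval_model(fitted, lags) - g_obs) ** 2))
    k_free = len(free)
    aicc = _aicc(float(2 * best.cost), len(acf), k_free)

    # SEs from (J^T J)^-1 scaled by residual variance; chain rule for log params
    se: dict[str, float] = {}
    dof = len(acf) - k_free
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * (2 * best.cost / max(dof, 1))
        for i, (n, lg) in enumerate(zip(free, log_scale)):
            s_i = np.sqrt(max(cov[i, i], 0.0))
            se[n] = s_i * vals[n] if lg else s_i
    except Exception:
        se = {n: np.nan for n in free}

    at_bounds = tuple(
        n for n, xi, l, h in zip(free, best.x, lo, hi)
        if xi - l < 1e-8 * max(1, abs(l)) or h - xi < 1e-8 * max(1, abs(h))
    )
    converged = bool(best.status > 0)
    return FCSFitResult(fitted, se, rss, aicc, len(acf), converged,
                        fixed_map, str(best.message), at_bounds)


def select_membrane_model(
    acf: AutocorrelationCurve,
    fixed_tau3d: float,
    structure_parameter: float = 5.0,
    weights: np.ndarray | None = None,
    aicc_margin: float = 2.0,
) -> FCSFitResult:
    """Fit 3D+1x2D and 3D+2x2D membrane models; keep the lower-AICc fit.

    The free-ligand 3D dwell time is fixed to ``fixed_tau3d`` (the same-day
    solution value).  When AICc differs by less than ``aicc_margin`` the
    simpler (single 2D) model is preferred.  If both fits fail, raises with
    both diagnostics attached.
    """
    t1 = FCSModelSpec.membrane(1.0, fixed_tau3d, [10 * fixed_tau3d], [0.5],
                               structure_parameter)
    t2 = FCSModelSpec.membrane(1.0, fixed_tau3d, [10 * fixed_tau3d, 300 * fixed_tau3d],
                               [0.3, 0.3], structure_parameter)
    fixed = {"structure_parameter": structure_parameter, "tau_d_0": fixed_tau3d}
    results = []
    for tpl in (t1, t2):
        try:
            results.append(fit_acf(acf, tpl, fixed=fixed, weights=weights))
        except ValueError as e:
            results.append(FCSFitResult(tpl, {}, np.inf, np.inf, len(acf),
                                        False, fixed, str(e)))
    r1, r2 = results
    if not (r1.converged or r2.converged):
        raise RuntimeError(f"both membrane fits failed: [{r1.message}] / [{r2.message}]")
    if not r2.converged or r1.aicc - r2.aicc < aicc_margin:
        chosen, other = r1, r2
    else:
        chosen, other = r2, r1
    sel = {"selection": "aicc", "aicc_1x2d": r1.aicc, "aicc_2x2d": r2.aicc,
           "margin": aicc_margin}
    return replace(chosen, fixed={**chosen.fixed, **sel})
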