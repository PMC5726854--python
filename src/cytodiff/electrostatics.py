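"""Ionic-strength-dependent binding free energy and its fits.

The probe-ribosome interaction is split into a non-ionic part and an
electrostatic part screened by small ions.  Following the modified
Debye-Hueckel treatment originally applied to thrombin-hirudin binding,
the standard binding free energy at ionic strength I (M) is

    dG_b(I) = dG_nio + dG_io0 * exp(-C1*sqrt(I)) / (1 + C1*sqrt(I)),

with dG_nio the non-ionic contribution, dG_io0 the electrostatic
contribution at zero ionic strength (both J/mol) and C1 (M^-1/2) a
screening parameter.  The dissociation constant follows from
Kd = exp(dG_b / RT) with a 1 M standard state.

Assuming the electrostatic term is linear in the probe's net charge,
dG_io0 = dG_pc * charge, and composing with the two-state effective
diffusion and site-saturation relations yields the effective diffusion
coefficient directly as a function of net charge:

    D_eff(q) = (1 - [site]/([site] + exp(dG_b(q)/RT))) * (D_free - D_bound)
               + D_bound.

Fits are performed in free-energy (log Kd) space, which equalises the
>20x dynamic range of the measured Kd values across ionic strengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

GAS_CONSTANT = 8.314  # J / (K mol)

__all__ = [
    "GAS_CONSTANT",
    "IonicBindingParams",
    "KdPoint",
    "ChargeModelConstants",
    "ChargeModelParams",
    "ChargeModelFit",
    "screening_factor",
    "binding_free_energy",
    "kd_from_dg",
    "dg_from_kd",
    "fit_ionic",
    "deff_of_charge",
    "fit_charge_model",
]


def screening_factor(ionic_strength: float | np.ndarray, c1: float):
    """exp(-C1*sqrt(I)) / (1 + C1*sqrt(I)); equals 1 at I = 0."""
    s = c1 * np.sqrt(ionic_strength)
    return np.exp(-s) / (1.0 + s)


@dataclass(frozen=True)
class IonicBindingParams:
    """Parameters of the screened electrostatic binding model."""

    dg_nio: float             # J/mol
    dg_io0: float             # J/mol
    c1: float                 # M^-1/2
    temperature: float = 293.0
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class KdPoint:
    """A (ionic strength, dissociation constant) observation, both in M."""

    ionic_strength: float
    kd: float

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be non-negative")
        if self.kd <= 0:
            raise ValueError("kd must be positive")


def binding_free_energy(
    ionic_strength: float | np.ndarray, params: IonicBindingParams
):
    """Standard binding free energy (J/mol) at ionic strength I (M)."""
    if np.any(np.asarray(ionic_strength) < 0):
        raise ValueError("ionic_strength must be non-negative")
    return params.dg_nio + params.dg_io0 * screening_factor(
        ionic_strength, params.c1
    )


def kd_from_dg(dg: float, temperature: float = 293.0) -> float:
    """Kd (M, 1 M standard state) from a binding free energy (J/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg / (GAS_CONSTANT * temperature))


def dg_from_kd(kd: float, temperature: float = 293.0) -> float:
    """Binding free energy (J/mol) from Kd (M, 1 M standard state)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT * temperature * math.log(kd)


def _ionic_rss(c1: float, ionic: np.ndarray, dg: np.ndarray):
    """Linear least squares for (dg_nio, dg_io0) at fixed c1."""
    design = np.column_stack([np.ones_like(ionic), screening_factor(ionic, c1)])
    coef, *_ = np.linalg.lstsq(design, dg, rcond=None)
    resid = design @ coef - dg
    return float(resid @ resid), coef


#: deterministic multi-start grid over the screening parameter
_C1_STARTS = (0.5, 1.0, 1.5, 2.0, 3.0)


def fit_ionic(
    points: list[KdPoint] | list[tuple[float, float]],
    temperature: float = 293.0,
) -> IonicBindingParams:
    """Fit (dG_nio, dG_io0, C1) to (I, Kd) observations.

    Residuals are minimised in free-energy space: each Kd is converted to
    dG = RT ln Kd and compared with the screened model.  At fixed C1 the
    problem is linear in the two free energies, so the search reduces to a
    deterministic multi-start 1D optimisation over C1 followed by bounded
    local refinement.  With exactly three distinct points the fit
    interpolates.
    """
    pts = [p if isinstance(p, KdPoint) else KdPoint(*p) for p in points]
    if len(pts) < 3:
        raise ValueError("at least 3 (I, Kd) points are required")
    ionic = np.array([p.ionic_strength for p in pts])
    if np.unique(ionic).size < 3:
        raise ValueError("need at least 3 distinct ionic strengths")
    dg = np.array([dg_from_kd(p.kd, temperature) for p in pts])

    best_c1, best_rss = None, np.inf
    for c1 in _C1_STARTS:
        rss, _ = _ionic_rss(c1, ionic, dg)
        if rss < best_rss:
            best_c1, best_rss = c1, rss

    i = _C1_STARTS.index(best_c1)
    lo = _C1_STARTS[i - 1] if i > 0 else 0.05
    hi = _C1_STARTS[i + 1] if i < len(_C1_STARTS) - 1 else 10.0
    res = minimize_scalar(
        lambda c: _ionic_rss(c, ionic, dg)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    c1 = float(res.x)
    _, coef = _ionic_rss(c1, ionic, dg)
    return IonicBindingParams(
        dg_nio=float(coef[0]), dg_io0=float(coef[1]), c1=c1,
        temperature=temperature,
    )


@dataclass(frozen=True)
class ChargeModelConstants:
    """Fixed quantities of the D_eff(charge) model.

    Concentrations here are in M (the electrostatics boundary converts
    from the uM convention of the binding module).
    """

    d_free: float = 10.0          # um^2/s
    d_bound: float = 0.04         # um^2/s
    site_conc: float = 660e-6     # M
    ionic_strength: float = 0.2   # M
    temperature: float = 293.0    # K

    def __post_init__(self) -> None:
        if self.d_free <= self.d_bound:
            raise ValueError("d_free must exceed d_bound")
        if min(self.site_conc, self.ionic_strength, self.temperature) <= 0:
            raise ValueError("constants must be positive")


@dataclass(frozen=True)
class ChargeModelParams:
    """Free parameters of the D_eff(charge) model plus its constants."""

    dg_nio: float                 # J/mol
    dg_pc: float                  # J/mol per elementary charge
    c1: float                     # M^-1/2
    constants: ChargeModelConstants = field(
        default_factory=ChargeModelConstants
    )


@dataclass(frozen=True)
class ChargeModelFit:
    params: ChargeModelParams
    rss: float                    # in log10(D_eff) space
    boundary: bool                # True when the optimum sits at a bound

    @property
    def charge_slope(self) -> float:
        """Identifiable electrostatic slope dG_pc * s(I, C1), J/mol/charge.

        At a single ionic strength dG_pc and C1 enter the model only
        through this product, so the product — not the pair — is the
        quantity a fit determines.
        """
        c = self.params.constants
        return self.params.dg_pc * float(
            screening_factor(c.ionic_strength, self.params.c1)
        )


def deff_of_charge(
    charge: float | np.ndarray, params: ChargeModelParams
):
    """Effective diffusion coefficient (um^2/s) at a given net charge."""
    c = params.constants
    rt = GAS_CONSTANT * c.temperature
    dg = params.dg_nio + params.dg_pc * np.asarray(charge, dtype=float) * (
        screening_factor(c.ionic_strength, params.c1)
    )
    kd = np.exp(dg / rt)
    f_bound = c.site_conc / (c.site_conc + kd)
    out = (1.0 - f_bound) * (c.d_free - c.d_bound) + c.d_bound
    if np.isscalar(charge):
        return float(out)
    return out


_FIT_BOUNDS = ([-2e5, -2e4, 1e-3], [1e5, 2e4, 50.0])


def fit_charge_model(
    points: list[tuple[float, float]],
    constants: ChargeModelConstants = ChargeModelConstants(),
) -> ChargeModelFit:
    """Fit (dG_nio, dG_pc, C1) to (net charge, D_eff) observations.

    Least squares on log10(D_eff) over a deterministic multi-start grid,
    refined with a trust-region solver.  Requires at least four points.
    """
    if len(points) < 4:
        raise ValueError("at least 4 (charge, D_eff) points are required")
    q = np.array([p[0] for p in points], dtype=float)
    d = np.array([p[1] for p in points], dtype=float)
    if np.any(d <= 0):
        raise ValueError("D_eff values must be positive")
    logd = np.log10(d)

    def residuals(x):
        p = ChargeModelParams(x[0], x[1], x[2], constants)
        return np.log10(deff_of_charge(q, p)) - logd

    best = None
    for c1 in _C1_STARTS:
        for dg_pc in (-2000.0, -1000.0, -500.0):
            for dg_nio in (-20000.0, -10000.0):
                sol = least_squares(
                    residuals, x0=[dg_nio, dg_pc, c1],
                    bounds=_FIT_BOUNDS, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                rss = float(2.0 * sol.cost)
                if best is None or rss < best[0] - 1e-10:
                    best = (rss, sol.x)
    rss, x = best
    at_bound = any(
        math.isclose(x[i], _FIT_BOUNDS[0][i], rel_tol=1e-6)
        or math.isclose(x[i], _FIT_BOUNDS[1][i], rel_tol=1e-6)
        for i in range(3)
    )
    params = ChargeModelParams(float(x[0]), float(x[1]), float(x[2]), constants)
    # a fit driven entirely to the free-diffusion plateau is flagged: the
    # binding parameters are then unidentifiable
    f_bound_max = float(
        np.max(1.0 - (deff_of_charge(q, params) - constants.d_bound)
               / (constants.d_free - constants.d_bound))
    )
    return ChargeModelFit(
        params=params, rss=rss, boundary=at_bound or f_bound_max < 1e-6
    )
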