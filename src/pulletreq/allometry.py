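"""Allometric models linking body-protein mass to live body weight.

Carcass protein (CP, g) and feather protein (FP, g) are each regressed on
live body weight X (g) with four candidate forms:

* linear        Y = b0 + b1*X
* quadratic     Y = b0 + b1*X + b2*X**2
* power         Y = b0 * X**b1
* exponential   Y = b0 * exp(b1*X)

Composing the selected allometry with a fitted growth curve and applying
the chain rule, d(protein)/dt = (d protein/d BW) * (dBW/dt), gives the
analytic daily protein deposition rates PRc(t) and PRf(t) that feed the
factorial requirement model. For a power allometry over a Von Bertalanffy
curve the rate collapses to

    PR(t) = K * exp(-k t) * (1 - b*exp(-k t))**(3*b1 - 1),
    K = b0*b1*3*A**b1*b*k,

and for a quadratic allometry over Von Bertalanffy to the two-term form

    PR(t) = k*exp(-k t) * [3*A*b*b1*u**2 + 6*A**2*b*b2*u**5],  u = 1 - b*exp(-k t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._diagnostics import FitDiagnostics, least_squares_diagnostics
from .growth import GrowthFamily, GrowthParams, growth_rate, predict_bw

__all__ = [
    "AllometricForm",
    "Compartment",
    "AllometricParams",
    "ProteinObservation",
    "AllometricFit",
    "DepositionRates",
    "protein_mass",
    "protein_slope",
    "fit_allometric",
    "select_allometric",
    "deposition_rate",
    "power_vb_leading_constant",
    "quadratic_vb_term_constants",
]


class AllometricForm(str, Enum):
    LINEAR = "linear"
    QUADRATIC = "quadratic"
    POWER = "power"
    EXPONENTIAL = "exponential"


class Compartment(str, Enum):
    CARCASS = "carcass"
    FEATHER = "feather"


@dataclass(frozen=True)
class AllometricParams:
    """Coefficients of one protein~body-weight form.

    ``b2`` is only meaningful for the quadratic form. A quadratic fitted to
    feather protein may predict negative mass at very small body weights;
    no clamping is applied here — downstream requirement computation only
    uses the deposition *rate*, which stays positive over the study range.
    """

    form: AllometricForm
    b0: float
    b1: float
    b2: float | None = None
    target: Compartment | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", AllometricForm(self.form))
        if self.target is not None:
            object.__setattr__(self, "target", Compartment(self.target))
        if self.form is AllometricForm.QUADRATIC:
            if self.b2 is None:
                raise ValueError("quadratic form requires b2")
        elif self.b2 is not None:
            raise ValueError(f"{self.form.value} form takes no b2")
        if self.form is AllometricForm.POWER and not self.b0 > 0:
            raise ValueError("power form requires b0 > 0")


@dataclass(frozen=True)
class ProteinObservation:
    """Total protein (g) of one compartment at a given live body weight (g)."""

    bw: float
    protein_mass: float
    compartment: Compartment
    age_days: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        if not self.bw > 0:
            raise ValueError("body weight must be positive")
        if self.protein_mass < 0:
            raise ValueError("protein mass must be non-negative")


@dataclass(frozen=True)
class AllometricFit:
    params: AllometricParams
    diagnostics: FitDiagnostics


@dataclass(frozen=True)
class DepositionRates:
    """Daily deposition (g/day) of carcass and feather protein at age t."""

    t: float
    pr_c: float
    pr_f: float
    dbw_dt: float


def _check_bw(params: AllometricParams, bw):
    bw = np.asarray(bw, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    return bw


def protein_mass(params: AllometricParams, bw):
    """Closed-form protein mass (g) at live body weight ``bw`` (g)."""
    x = _check_bw(params, bw)
    if params.form is AllometricForm.LINEAR:
        out = params.b0 + params.b1 * x
    elif params.form is AllometricForm.QUADRATIC:
        out = params.b0 + params.b1 * x + params.b2 * x**2
    elif params.form is AllometricForm.POWER:
        out = params.b0 * x**params.b1
    else:
        out = params.b0 * np.exp(params.b1 * x)
    return out if isinstance(bw, np.ndarray) else float(out)


def protein_slope(params: AllometricParams, bw):
    """Analytic d(protein)/d(BW) at live body weight ``bw``."""
    x = _check_bw(params, bw)
    if params.form is AllometricForm.LINEAR:
        out = np.full_like(x, params.b1)
    elif params.form is AllometricForm.QUADRATIC:
        out = params.b1 + 2.0 * params.b2 * x
    elif params.form is AllometricForm.POWER:
        out = params.b0 * params.b1 * x ** (params.b1 - 1.0)
    else:
        out = params.b0 * params.b1 * np.exp(params.b1 * x)
    return out if isinstance(bw, np.ndarray) else float(out)


def fit_allometric(
    observations: Iterable[ProteinObservation],
    form: AllometricForm | str,
) -> AllometricFit:
    """Least-squares fit of one form (linear algebra for the polynomial
    forms, Levenberg-Marquardt for power/exponential)."""
    form = AllometricForm(form)
    obs = sorted(observations, key=lambda o: o.bw)
    x = np.array([o.bw for o in obs], dtype=float)
    y = np.array([o.protein_mass for o in obs], dtype=float)
    n_par = 3 if form is AllometricForm.QUADRATIC else 2
    if x.size <= n_par or x.size < 4:
        raise ValueError(
            f"{form.value} fit needs more than max({n_par}, 3) observations, got {x.size}"
        )
    if x.max() <= x.min():
        raise ValueError("body weights must span a positive range")
    compartments = {o.compartment for o in obs}
    target = compartments.pop() if len(compartments) == 1 else None

    if form in (AllometricForm.LINEAR, AllometricForm.QUADRATIC):
        deg = 1 if form is AllometricForm.LINEAR else 2
        design = np.vander(x, deg + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        if form is AllometricForm.LINEAR:
            params = AllometricParams(form, float(coef[0]), float(coef[1]), target=target)
        else:
            params = AllometricParams(
                form, float(coef[0]), float(coef[1]), float(coef[2]), target=target
            )
        jac = design
        names = ("b0", "b1", "b2")[: deg + 1]
        est = coef
    else:
        if form is AllometricForm.POWER:
            # log-log regression seeds the nonlinear fit
            lb = np.polyfit(np.log(x), np.log(np.maximum(y, 1e-12)), 1)
            p0 = (math.exp(lb[1]), lb[0])

            def f(x_, b0, b1):
                return b0 * x_**b1

            def jacf(x_, b0, b1):
                return np.column_stack([x_**b1, b0 * x_**b1 * np.log(x_)])

        else:
            lb = np.polyfit(x, np.log(np.maximum(y, 1e-12)), 1)
            p0 = (math.exp(lb[1]), lb[0])

            def f(x_, b0, b1):
                return b0 * np.exp(b1 * x_)

            def jacf(x_, b0, b1):
                e = np.exp(b1 * x_)
                return np.column_stack([e, b0 * x_ * e])

        popt, _ = curve_fit(f, x, y, p0=p0, jac=jacf, maxfev=20000)
        params = AllometricParams(form, float(popt[0]), float(popt[1]), target=target)
        jac = jacf(x, *popt)
        names = ("b0", "b1")
        est = popt

    diagnostics = least_squares_diagnostics(
        y, protein_mass(params, x), jac, names, np.asarray(est, dtype=float)
    )
    return AllometricFit(params=params, diagnostics=diagnostics)


def select_allometric(fits: Sequence[AllometricFit]) -> list[AllometricFit]:
    """Rank candidate forms: highest R-squared first, ties by lowest AIC.

    R-squared is compared at 3-decimal precision — the precision at which
    goodness of fit is conventionally reported for these regressions — so
    that practically indistinguishable fits are adjudicated by AIC, which
    penalises the extra quadratic parameter.
    """
    if len(fits) < 2:
        raise ValueError("selection needs at least two fits")
    return sorted(fits, key=lambda f: (-round(f.diagnostics.r2, 3), f.diagnostics.aic))


def deposition_rate(
    growth: GrowthParams,
    carcass: AllometricParams,
    feather: AllometricParams,
    t,
) -> DepositionRates:
    """Analytic protein deposition rates at age ``t`` (days).

    Chain rule on the composed functions: the slope of each allometry is
    evaluated at BW(t) and multiplied by the analytic growth rate.
    """
    bw = predict_bw(growth, t)
    dbw = growth_rate(growth, t)
    pr_c = protein_slope(carcass, bw) * dbw
    pr_f = protein_slope(feather, bw) * dbw
    return DepositionRates(t=float(t), pr_c=float(pr_c), pr_f=float(pr_f), dbw_dt=float(dbw))


def power_vb_leading_constant(growth: GrowthParams, allom: AllometricParams) -> float:
    """Leading constant K = b0*b1*3*A**b1*b*k of the power-over-Von-Bertalanffy
    deposition rate K*exp(-kt)*(1-b*exp(-kt))**(3*b1-1)."""
    if growth.family is not GrowthFamily.VON_BERTALANFFY:
        raise ValueError("closed form requires a von Bertalanffy growth curve")
    if allom.form is not AllometricForm.POWER:
        raise ValueError("closed form requires a power allometry")
    A, b, k = growth.A, growth.b, growth.k
    return allom.b0 * allom.b1 * 3.0 * A**allom.b1 * b * k


def quadratic_vb_term_constants(
    growth: GrowthParams, allom: AllometricParams
) -> tuple[float, float]:
    """Term constants (3*A*b*b1, 6*A**2*b*b2) of the quadratic-over-Von-
    Bertalanffy rate k*exp(-kt)*[c_lin*u**2 + c_quad*u**5], u = 1-b*exp(-kt).

    For a concave feather quadratic (b2 < 0) the second constant is
    negative; its magnitude is what a two-term printed expression reports.
    """
    if growth.family is not GrowthFamily.VON_BERTALANFFY:
        raise ValueError("closed form requires a von Bertalanffy growth curve")
    if allom.form is not AllometricForm.QUADRATIC:
        raise ValueError("closed form requires a quadratic allometry")
    A, b = growth.A, growth.b
    return 3.0 * A * b * allom.b1, 6.0 * A**2 * b * allom.b2
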