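"""Indicator-method apparent digestibility and its age trend.

Acid-insoluble ash (AIA) is an indigestible internal marker: the apparent
digestibility of a nutrient follows from the change of its concentration
relative to AIA between feed and excreta,

    digestibility = 1 - (AIA_feed / AIA_feces) * (nutrient_feces / nutrient_feed),

a dimensionless fraction (negative values are possible with noisy data and
are returned with a warning). Apparent protein digestibility (APD) and a
pooled apparent amino-acid digestibility (AAD) both rise with age as the
digestive tract matures; the age trend is fitted with logarithmic,
exponential and quadratic candidate curves and selected by R-squared
(ties by AIC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._diagnostics import FitDiagnostics, least_squares_diagnostics

__all__ = [
    "NutrientKind",
    "CurveFamily",
    "DigestibilityObservation",
    "DigestibilityCurve",
    "apparent_digestibility",
    "fit_digestibility_curve",
    "select_digestibility_curve",
    "predict_digestibility",
    "logarithmic_curve",
]


class NutrientKind(str, Enum):
    PROTEIN = "protein"
    AMINO_ACID = "amino_acid"


class CurveFamily(str, Enum):
    LOGARITHMIC = "logarithmic"
    EXPONENTIAL = "exponential"
    QUADRATIC = "quadratic"


@dataclass(frozen=True)
class DigestibilityObservation:
    """Feed and fecal concentrations backing one digestibility measurement.

    Concentrations are % of dry matter; feed and feces must use the same
    units for a given nutrient (the ratio form cancels them).
    """

    age_days: float
    aia_feed: float
    aia_feces: float
    nutrient_feed: float
    nutrient_feces: float
    nutrient_kind: NutrientKind = NutrientKind.PROTEIN
    amino_acid: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nutrient_kind", NutrientKind(self.nutrient_kind))
        for fld in ("aia_feed", "aia_feces", "nutrient_feed", "nutrient_feces"):
            if not getattr(self, fld) > 0:
                raise ValueError(f"{fld} must be positive")
        if self.aia_feces < self.aia_feed:
            warnings.warn(
                "AIA concentration lower in feces than in feed: the marker "
                "should concentrate as digestible matter disappears",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DigestibilityCurve:
    """Fitted age trend of apparent digestibility (fractions, not %).

    * logarithmic:  d(t) = c0 + c1 * ln(t)
    * exponential:  d(t) = c0 * exp(c1 * t)
    * quadratic:    d(t) = c0 + c1 * t + c2 * t**2

    Predictions clamp t below 1 day to 1 (the logarithm needs a positive
    age; day-0 rations are evaluated at day 1) and clamp the output to
    [0, 1].
    """

    family: CurveFamily
    coefficients: tuple[float, ...]
    nutrient_kind: NutrientKind
    diagnostics: FitDiagnostics | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", CurveFamily(self.family))
        object.__setattr__(self, "nutrient_kind", NutrientKind(self.nutrient_kind))
        need = 3 if self.family is CurveFamily.QUADRATIC else 2
        if len(self.coefficients) != need:
            raise ValueError(f"{self.family.value} family needs {need} coefficients")


def apparent_digestibility(obs: DigestibilityObservation) -> float:
    """Apparent digestibility fraction of one observation.

    Returns 1 - (AIA_feed/AIA_feces) * (nutrient_feces/nutrient_feed).
    A nutrient:AIA ratio unchanged between feed and feces gives exactly 0;
    negative results (net apparent secretion) are returned with a warning.
    """
    d = 1.0 - (obs.aia_feed / obs.aia_feces) * (obs.nutrient_feces / obs.nutrient_feed)
    if d < 0:
        warnings.warn(
            f"negative apparent digestibility ({d:.4f}) at age {obs.age_days}",
            stacklevel=2,
        )
    return float(d)


def fit_digestibility_curve(
    observations: Iterable[DigestibilityObservation],
    family: CurveFamily | str,
) -> DigestibilityCurve:
    """Least-squares fit of one curve family to observed digestibilities.

    Needs at least four distinct ages; the logarithmic family requires all
    ages >= 1 day at fit time (no clamping of training data).
    """
    family = CurveFamily(family)
    obs = sorted(observations, key=lambda o: o.age_days)
    if not obs:
        raise ValueError("no observations supplied")
    kinds = {o.nutrient_kind for o in obs}
    if len(kinds) > 1:
        raise ValueError("observations mix protein and amino-acid nutrients")
    kind = kinds.pop()
    t = np.array([o.age_days for o in obs], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y = np.array([apparent_digestibility(o) for o in obs], dtype=float)
    n_par = 3 if family is CurveFamily.QUADRATIC else 2
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct ages")
    if family is CurveFamily.LOGARITHMIC and np.any(t < 1):
        raise ValueError("logarithmic family requires ages >= 1 day")

    if family is CurveFamily.LOGARITHMIC:
        design = np.column_stack([np.ones_like(t), np.log(t)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        jac, names = design, ("c0", "c1")
    elif family is CurveFamily.QUADRATIC:
        design = np.vander(t, 3, increasing=True)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        jac, names = design, ("c0", "c1", "c2")
    else:
        slope0, logint0 = np.polyfit(t, np.log(np.maximum(y, 1e-6)), 1)
        coef, _ = curve_fit(
            lambda t_, c0, c1: c0 * np.exp(c1 * t_),
            t,
            y,
            p0=(math.exp(logint0), slope0),
            maxfev=20000,
        )
        e = np.exp(coef[1] * t)
        jac, names = np.column_stack([e, coef[0] * t * e]), ("c0", "c1")

    curve = DigestibilityCurve(family, tuple(float(c) for c in coef), kind)
    y_hat = _raw_predict(curve, t)
    diagnostics = least_squares_diagnostics(y, y_hat, jac, names, np.asarray(coef))
    return DigestibilityCurve(family, curve.coefficients, kind, diagnostics)


def select_digestibility_curve(
    fits: Sequence[DigestibilityCurve],
) -> list[DigestibilityCurve]:
    """Rank fitted curves: highest R-squared first (compared at 3-decimal
    precision, as goodness of fit is reported), ties by lowest AIC."""
    if len(fits) < 2:
        raise ValueError("selection needs at least two fitted curves")
    if any(f.diagnostics is None for f in fits):
        raise ValueError("all curves must carry fit diagnostics")
    return sorted(fits, key=lambda f: (-round(f.diagnostics.r2, 3), f.diagnostics.aic))


def _raw_predict(curve: DigestibilityCurve, t: np.ndarray) -> np.ndarray:
    c = curve.coefficients
    if curve.family is CurveFamily.LOGARITHMIC:
        return c[0] + c[1] * np.log(t)
    if curve.family is CurveFamily.EXPONENTIAL:
        return c[0] * np.exp(c[1] * t)
    return c[0] + c[1] * t + c[2] * t**2


def predict_digestibility(curve: DigestibilityCurve, t) -> float:
    """Predicted digestibility fraction at age ``t`` days.

    Ages below 1 day are clamped to 1 before evaluation (so the day-0
    ration uses the day-1 digestibility) and the output is clamped to
    [0, 1].
    """
    tt = np.maximum(np.asarray(t, dtype=float), 1.0)
    if np.any(np.asarray(t) < 0):
        raise ValueError("age must be non-negative")
    out = np.clip(_raw_predict(curve, tt), 0.0, 1.0)
    return out if isinstance(t, np.ndarray) else float(out)


def logarithmic_curve(
    intercept: float, slope: float, nutrient_kind: NutrientKind | str
) -> DigestibilityCurve:
    """Construct a logarithmic digestibility curve from known coefficients."""
    return DigestibilityCurve(
        CurveFamily.LOGARITHMIC, (float(intercept), float(slope)), NutrientKind(nutrient_kind)
    )
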