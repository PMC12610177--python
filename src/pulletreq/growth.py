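"""Growth-curve models for body weight of growing laying hens.

Three classical sigmoid families are supported, each parameterised by a
mature weight ``A`` (g), a dimensionless shape parameter ``b`` and a growth
rate coefficient ``k`` (per day):

* Gompertz          BW(t) = A * exp(-b * exp(-k t))
* Logistic          BW(t) = A / (1 + b * exp(-k t))
* Von Bertalanffy   BW(t) = A * (1 - b * exp(-k t))**3

All three are strictly increasing in t with asymptote A, and each has a
closed-form inflection point (the age of maximum daily gain):

* Gompertz          t* = ln(b)/k,   BW* = A/e
* Logistic          t* = ln(b)/k,   BW* = A/2
* Von Bertalanffy   t* = ln(3b)/k,  BW* = 8A/27

Fitting is by nonlinear least squares on group-mean body weights, with
asymptotic standard errors from the Jacobian and information-criterion
model selection (AIC, ties broken by BIC then R-squared).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._diagnostics import FitDiagnostics, least_squares_diagnostics

__all__ = [
    "GrowthFamily",
    "GrowthParams",
    "WeightObservation",
    "GrowthFit",
    "predict_bw",
    "growth_rate",
    "inflection",
    "fit_growth",
    "select_model",
]


class GrowthFamily(str, Enum):
    GOMPERTZ = "gompertz"
    LOGISTIC = "logistic"
    VON_BERTALANFFY = "von_bertalanffy"


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one growth-curve family.

    A is the mature body weight in grams, b the dimensionless adjustment
    (shape) parameter and k the growth-rate coefficient per day. For the
    Von Bertalanffy family b must lie in (0, 1) so that BW(0) > 0.
    """

    family: GrowthFamily
    A: float
    b: float
    k: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", GrowthFamily(self.family))
        if not (self.A > 0 and self.b > 0 and self.k > 0):
            raise ValueError("growth parameters A, b, k must all be positive")
        if self.family is GrowthFamily.VON_BERTALANFFY and not self.b < 1:
            raise ValueError(
                "von Bertalanffy shape parameter b must satisfy 0 < b < 1 "
                "so the hatch weight BW(0) is positive"
            )


@dataclass(frozen=True)
class WeightObservation:
    """One group-mean body weight (grams) at a given age (days)."""

    t: float
    bw: float
    group_id: str = "g1"

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("age must be non-negative")
        if not self.bw > 0:
            raise ValueError("body weight must be positive")


@dataclass(frozen=True)
class GrowthFit:
    """A fitted growth curve plus diagnostics and inflection analytics."""

    params: GrowthParams
    diagnostics: FitDiagnostics
    inflection_time: float
    inflection_weight: float
    # identity of the fitted data, used to refuse cross-data-set comparisons
    observations: tuple[tuple[float, float], ...]


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be non-negative")
    return t


def predict_bw(params: GrowthParams, t):
    """Body weight (g) at age ``t`` days; accepts scalars or arrays."""
    tt = _check_t(t)
    e = np.exp(-params.k * tt)
    if params.family is GrowthFamily.GOMPERTZ:
        out = params.A * np.exp(-params.b * e)
    elif params.family is GrowthFamily.LOGISTIC:
        out = params.A / (1.0 + params.b * e)
    else:
        out = params.A * (1.0 - params.b * e) ** 3
    return out if isinstance(t, np.ndarray) else float(out)


def growth_rate(params: GrowthParams, t):
    """Analytic daily gain dBW/dt (g/day) at age ``t`` days."""
    tt = _check_t(t)
    A, b, k = params.A, params.b, params.k
    e = np.exp(-k * tt)
    if params.family is GrowthFamily.GOMPERTZ:
        out = A * b * k * e * np.exp(-b * e)
    elif params.family is GrowthFamily.LOGISTIC:
        out = A * b * k * e / (1.0 + b * e) ** 2
    else:
        out = 3.0 * A * b * k * e * (1.0 - b * e) ** 2
    return out if isinstance(t, np.ndarray) else float(out)


def inflection(params: GrowthParams) -> tuple[float, float]:
    """Closed-form inflection point (age in days, weight in grams).

    Raises ``ValueError`` for a Von Bertalanffy curve with b <= 1/3, which
    has no inflection at positive age.
    """
    A, b, k = params.A, params.b, params.k
    if params.family is GrowthFamily.GOMPERTZ:
        return math.log(b) / k, A / math.e
    if params.family is GrowthFamily.LOGISTIC:
        return math.log(b) / k, A / 2.0
    if b <= 1.0 / 3.0:
        raise ValueError(
            "von Bertalanffy curve with b <= 1/3 has no inflection at "
            "positive age (ln(3b)/k <= 0)"
        )
    return math.log(3.0 * b) / k, 8.0 * A / 27.0


def _start_values(family: GrowthFamily, t: np.ndarray, bw: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting values: A from the data range, k = 0.03, b
    solved from the model at the earliest observation."""
    A0 = 1.1 * float(bw.max())
    k0 = 0.03
    i0 = int(np.argmin(t))
    t0, w0 = float(t[i0]), float(bw[i0])
    ratio = min(w0 / A0, 1.0 - 1e-9)
    grow = math.exp(k0 * t0)
    if family is GrowthFamily.GOMPERTZ:
        b0 = -math.log(ratio) * grow
    elif family is GrowthFamily.LOGISTIC:
        b0 = (1.0 / ratio - 1.0) * grow
    else:
        b0 = (1.0 - ratio ** (1.0 / 3.0)) * grow
        b0 = min(max(b0, 1e-6), 1.0 - 1e-6)
    return A0, max(b0, 1e-6), k0


def _model_and_jacobian(family: GrowthFamily):
    def f(t, A, b, k):
        return predict_bw(GrowthParams(family, A, b, k), t)

    def jac(t, A, b, k):
        t = np.asarray(t, dtype=float)
        e = np.exp(-k * t)
        if family is GrowthFamily.GOMPERTZ:
            core = np.exp(-b * e)
            dA = core
            db = -A * e * core
            dk = A * b * t * e * core
        elif family is GrowthFamily.LOGISTIC:
            den = (1.0 + b * e) ** 2
            dA = 1.0 / (1.0 + b * e)
            db = -A * e / den
            dk = A * b * t * e / den
        else:
            u = 1.0 - b * e
            dA = u**3
            db = -3.0 * A * e * u**2
            dk = 3.0 * A * b * t * e * u**2
        return np.column_stack([dA, db, dk])

    return f, jac


def fit_growth(
    observations: Iterable[WeightObservation],
    family: GrowthFamily | str,
) -> GrowthFit:
    """Fit one growth family to group-mean body weights.

    Each group-age mean is one observation with equal weight. Requires at
    least four distinct ages. Convergence failures are reported together
    with the starting values used.
    """
    family = GrowthFamily(family)
    obs = sorted(observations, key=lambda o: (o.t, o.group_id))
    if not obs:
        raise ValueError("no observations supplied")
    t = np.array([o.t for o in obs], dtype=float)
    bw = np.array([o.bw for o in obs], dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError(
            "growth fitting needs at least 4 distinct ages "
            f"(got {len(np.unique(t))}): the 3-parameter curve is underdetermined"
        )

    f, jac = _model_and_jacobian(family)
    p0 = _start_values(family, t, bw)
    upper_b = 1.0 if family is GrowthFamily.VON_BERTALANFFY else np.inf
    try:
        popt, _ = curve_fit(
            f,
            t,
            bw,
            p0=p0,
            jac=jac,
            bounds=([0.0, 0.0, 0.0], [np.inf, upper_b, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - scipy message pass-through
        raise RuntimeError(
            f"{family.value} fit did not converge from starting values "
            f"A={p0[0]:.3f}, b={p0[1]:.4f}, k={p0[2]:.4f}: {err}"
        ) from err

    params = GrowthParams(family, *map(float, popt))
    diagnostics = least_squares_diagnostics(
        bw, f(t, *popt), jac(t, *popt), ("A", "b", "k"), popt
    )
    t_star, w_star = inflection(params)
    return GrowthFit(
        params=params,
        diagnostics=diagnostics,
        inflection_time=t_star,
        inflection_weight=w_star,
        observations=tuple((float(o.t), float(o.bw)) for o in obs),
    )


def select_model(fits: Sequence[GrowthFit]) -> list[GrowthFit]:
    """Rank fits of the same observations by AIC (ties: BIC, then R2 desc).

    Fits on differing observation sets are rejected: information criteria
    are only comparable on identical data.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    ref = fits[0].observations
    if any(f.observations != ref for f in fits[1:]):
        raise ValueError("fits were made on differing observation sets")
    return sorted(
        fits,
        key=lambda f: (f.diagnostics.aic, f.diagnostics.bic, -f.diagnostics.r2),
    )
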