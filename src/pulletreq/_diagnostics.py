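"""Shared least-squares fit diagnostics.

All regression modules (growth, allometry, digestibility) report the same
diagnostic block: R-squared, residual RMSE, Gaussian-likelihood AIC/BIC, and
per-parameter asymptotic standard errors with t-based 95% confidence
intervals computed from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ParamEstimate", "FitDiagnostics", "least_squares_diagnostics"]


@dataclass(frozen=True)
class ParamEstimate:
    """Point estimate of one regression parameter with asymptotic uncertainty."""

    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def ci_length(self) -> float:
        return self.ci_high - self.ci_low


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary for a least-squares regression.

    ``rmse`` is the root-mean-square error of the residuals, sqrt(RSS/n).
    AIC and BIC use the Gaussian-likelihood form for least squares,
    AIC = n*ln(RSS/n) + 2*(p+1) and BIC = n*ln(RSS/n) + (p+1)*ln(n),
    counting the residual variance as an extra parameter. These serve model
    comparison on a common data set, not absolute value matching.
    """

    r2: float
    rmse: float
    aic: float
    bic: float
    n_obs: int
    params: tuple[ParamEstimate, ...]

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.n_params

    def param(self, name: str) -> ParamEstimate:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)


def least_squares_diagnostics(
    y: np.ndarray,
    y_hat: np.ndarray,
    jacobian: np.ndarray,
    names: tuple[str, ...],
    estimates: np.ndarray,
    ci_level: float = 0.95,
) -> FitDiagnostics:
    """Assemble :class:`FitDiagnostics` at a least-squares optimum.

    Parameters
    ----------
    y, y_hat
        Observed and fitted response values.
    jacobian
        n x p Jacobian of the model prediction w.r.t. the parameters,
        evaluated at the optimum.
    names, estimates
        Parameter names and point estimates, in Jacobian column order.
    ci_level
        Two-sided confidence level for the parameter intervals (t-quantile
        with n - p degrees of freedom).

    Raises
    ------
    np.linalg.LinAlgError
        If the Jacobian is numerically singular (unidentifiable fit).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    jacobian = np.asarray(jacobian, dtype=float)
    n = y.size
    p = len(names)
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")

    resid = y - y_hat
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else np.nan)
    rmse = float(np.sqrt(rss / n))

    # Guard the log for perfect (noise-free) fits.
    rss_floor = max(rss, np.finfo(float).tiny)
    aic = n * np.log(rss_floor / n) + 2 * (p + 1)
    bic = n * np.log(rss_floor / n) + (p + 1) * np.log(n)

    jtj = jacobian.T @ jacobian
    cond = np.linalg.cond(jtj)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            "singular Jacobian at the optimum: parameters are not jointly "
            "identifiable from these observations"
        )
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(jtj)
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))

    tq = stats.t.ppf(0.5 + ci_level / 2.0, df=n - p)
    params = []
    for name, est, se in zip(names, estimates, ses, strict=True):
        if se > 0:
            pval = 2.0 * stats.t.sf(abs(est / se), df=n - p)
        else:
            pval = 0.0
        params.append(
            ParamEstimate(
                name=name,
                estimate=float(est),
                se=float(se),
                ci_low=float(est - tq * se),
                ci_high=float(est + tq * se),
                p_value=float(pval),
            )
        )
    return FitDiagnostics(
        r2=float(r2),
        rmse=rmse,
        aic=float(aic),
        bic=float(bic),
        n_obs=int(n),
        params=tuple(params),
    )
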