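"""Binomial dose-response fitting, model selection and LC estimation.

Three two-parameter families with lower asymptote 0 and upper asymptote
1 are supported, in the parameterisation where ``e`` carries dose units
and ``b`` is a (signed) slope on the log-dose axis:

- ``LL2``  log-logistic:  f(x) = 1 / (1 + exp(b (ln x − ln e)))
- ``W1_2`` Weibull type 1: f(x) = exp(−exp(b (ln x − ln e)))
- ``W2_2`` Weibull type 2: f(x) = 1 − exp(−exp(b (ln x − ln e)))

For LL2 with an increasing response (b < 0), ``e`` is exactly the LC50.
Parameters maximise the binomial log-likelihood of the pooled per-dose
kill counts; fitting is deterministic via a fixed multi-start grid and
Nelder-Mead polish.  Goodness of fit is the deviance against the
saturated binomial model referred to χ² with ``#groups − 2`` degrees of
freedom, and model selection keeps the family with the highest
goodness-of-fit p-value (ties broken by log-likelihood).  Lethal doses
invert the fitted curve in closed form; confidence intervals use the
delta method on the log-dose scale.

Zero-dose controls are excluded (log-dose undefined) and no control
pre-correction is applied: the models are fitted to raw observed
mortality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "DoseGroup",
    "DoseResponseFit",
    "LCEstimate",
    "SeparationError",
    "FitError",
    "predict",
    "fit_model",
    "goodness_of_fit",
    "select_model",
    "lethal_dose",
]

FAMILIES = ("LL2", "W1_2", "W2_2")

_PCLIP = 1e-12


class SeparationError(ValueError):
    """Every dose group is all-dead or all-alive; the slope is unbounded."""


class FitError(RuntimeError):
    """The optimiser failed to produce a finite maximum."""


@dataclass(frozen=True)
class DoseGroup:
    """Pooled binomial response at one positive dose."""

    dose: float
    n: int
    dead: int

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive (controls are excluded from fits)")
        if not 0 <= self.dead <= self.n:
            raise ValueError(f"dead={self.dead} outside [0, n={self.n}]")


@dataclass
class DoseResponseFit:
    family: str
    b: float
    e: float
    log_likelihood: float
    gof_statistic: float = float("nan")
    gof_df: int = 0
    gof_p: float = float("nan")
    cov_log: np.ndarray | None = field(default=None, repr=False)
    groups: tuple[DoseGroup, ...] = field(default=(), repr=False)


@dataclass
class LCEstimate:
    level: float
    dose: float
    ci_low: float
    ci_high: float
    se_log: float = float("nan")


def _predict_z(family: str, z: np.ndarray) -> np.ndarray:
    z = np.clip(z, -700.0, 700.0)
    if family == "LL2":
        return special.expit(-z)
    if family == "W1_2":
        return np.exp(-np.exp(z))
    if family == "W2_2":
        return -np.expm1(-np.exp(z))
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def predict(family: str, b: float, e: float, x) -> np.ndarray:
    """Predicted mortality at dose ``x`` under the given family."""
    if e <= 0:
        raise ValueError("location parameter e must be positive")
    x = np.asarray(x, dtype=float)
    return _predict_z(family, b * (np.log(x) - np.log(e)))


def _loglik(family: str, b: float, loge: float, dose, n, dead) -> float:
    p = np.clip(_predict_z(family, b * (np.log(dose) - loge)), _PCLIP, 1 - _PCLIP)
    return float(np.sum(dead * np.log(p) + (n - dead) * np.log1p(-p)))


def _saturated_loglik(n, dead) -> float:
    p = dead / n
    return float(np.sum(special.xlogy(dead, p) + special.xlogy(n - dead, 1.0 - p)))


def _unpack(groups):
    groups = tuple(groups)
    dose = np.array([g.dose for g in groups], dtype=float)
    n = np.array([g.n for g in groups], dtype=float)
    dead = np.array([g.dead for g in groups], dtype=float)
    return groups, dose, n, dead


def fit_model(groups, family: str) -> DoseResponseFit:
    """Maximum-likelihood fit of one family to pooled dose groups.

    Deterministic: Nelder-Mead from every point of a fixed start grid
    (slopes ±0.25, ±1, ±4 restricted to the sign consistent with the
    empirical dose trend; log-location spanning the dose range), the
    best converged optimum kept.
    """
    groups, dose, n, dead = _unpack(groups)
    if len(groups) < 3:
        raise ValueError("need at least 3 dose groups to fit a 2-parameter model")
    partial = (dead > 0) & (dead < n)
    if not partial.any():
        raise SeparationError(
            "every larva responded identically at every dose; the dose range "
            "brackets no part of the response curve — widen the dose range"
        )

    loge_lo, loge_hi = np.log(dose.min()), np.log(dose.max())
    loge_starts = np.linspace(loge_lo, loge_hi, 5)
    b_starts = [-4.0, -1.0, -0.25, 0.25, 1.0, 4.0]
    # keep starts whose slope sign matches the empirical dose trend
    # (LL2 and W1_2 increase with dose for b < 0, W2_2 for b > 0)
    trend = np.corrcoef(np.log(dose), dead / n)[0, 1]
    if np.isfinite(trend) and trend != 0:
        want = -np.sign(trend) if family in ("LL2", "W1_2") else np.sign(trend)
        b_starts = [b for b in b_starts if np.sign(b) == want]

    def nll(theta):
        return -_loglik(family, theta[0], theta[1], dose, n, dead)

    best = None
    for b0, l0 in itertools.product(b_starts, loge_starts):
        res = optimize.minimize(
            nll,
            x0=np.array([b0, l0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"no start converged for family {family}")

    b_hat, loge_hat = best.x
    cov = _cov_log(family, b_hat, loge_hat, dose, n, dead)
    fit = DoseResponseFit(
        family=family,
        b=float(b_hat),
        e=float(np.exp(loge_hat)),
        log_likelihood=-float(best.fun),
        cov_log=cov,
        groups=groups,
    )
    if len(groups) > 2:
        stat, df, p = goodness_of_fit(fit, groups)
        fit.gof_statistic, fit.gof_df, fit.gof_p = stat, df, p
    return fit


def _cov_log(family, b, loge, dose, n, dead) -> np.ndarray | None:
    """Observed-information covariance of (b, ln e) by central differences."""
    theta = np.array([b, loge], dtype=float)
    h = 1e-5 * np.maximum(1.0, np.abs(theta))

    def f(t):
        return -_loglik(family, t[0], t[1], dose, n, dead)

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i], ej[j] = h[i], h[j]
            hess[i, j] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None
    return cov


def goodness_of_fit(fit: DoseResponseFit, groups) -> tuple[float, int, float]:
    """Deviance of the fit against the saturated binomial model.

    Referred to χ² with ``#groups − 2`` degrees of freedom; a high
    p-value means the two-parameter curve explains the per-dose
    proportions about as well as fitting each dose its own rate.
    """
    groups, dose, n, dead = _unpack(groups)
    df = len(groups) - 2
    if df <= 0:
        raise ValueError("goodness of fit needs more than 2 dose groups")
    ll_fit = _loglik(fit.family, fit.b, np.log(fit.e), dose, n, dead)
    deviance = max(0.0, 2.0 * (_saturated_loglik(n, dead) - ll_fit))
    p = float(stats.chi2.sf(deviance, df))
    return deviance, df, p


def select_model(groups) -> DoseResponseFit:
    """Fit all three families and keep the best-fitting one.

    Selection is by highest goodness-of-fit p-value, ties broken by
    higher log-likelihood.  The full candidate list is kept on the
    returned fit as ``candidates`` for reporting.
    """
    fits: list[DoseResponseFit] = []
    errors: list[str] = []
    for family in FAMILIES:
        try:
            fits.append(fit_model(groups, family))
        except (SeparationError, FitError, ValueError) as exc:  # pragma: no cover
            errors.append(f"{family}: {exc}")
    if not fits:
        raise FitError("every model family failed: " + "; ".join(errors))
    best = max(fits, key=lambda f: (f.gof_p, f.log_likelihood))
    best.candidates = {f.family: f for f in fits}
    return best


def _log_lc(family: str, b: float, loge: float, level: float) -> tuple[float, float]:
    """Closed-form log lethal dose and its derivative with respect to b."""
    if family == "LL2":
        c = np.log((1.0 - level) / level)
    elif family == "W1_2":
        c = np.log(-np.log(level))
    elif family == "W2_2":
        c = np.log(-np.log1p(-level))
    else:
        raise ValueError(f"unknown family {family!r}")
    return loge + c / b, -c / b**2


def lethal_dose(fit: DoseResponseFit, level: float = 0.5, alpha: float = 0.05) -> LCEstimate:
    """Dose producing the given mortality level under the fitted curve.

    For LL2 at level 0.5 this is exactly ``e``.  The confidence interval
    comes from the delta method on the log-dose scale using the
    observed-information covariance of ``(b, ln e)``.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie strictly between 0 and 1")
    loge = np.log(fit.e)
    log_lc, dlc_db = _log_lc(fit.family, fit.b, loge, level)
    dose = float(np.exp(log_lc))
    if fit.cov_log is None:
        return LCEstimate(level=level, dose=dose, ci_low=dose, ci_high=dose)
    grad = np.array([dlc_db, 1.0])  # d log_lc / d(b, ln e)
    var = float(grad @ fit.cov_log @ grad)
    if var < 0 or not np.isfinite(var):
        return LCEstimate(level=level, dose=dose, ci_low=dose, ci_high=dose)
    se = np.sqrt(var)
    z = stats.norm.ppf(1 - alpha / 2)
    return LCEstimate(
        level=level,
        dose=dose,
        ci_low=float(np.exp(log_lc - z * se)),
        ci_high=float(np.exp(log_lc + z * se)),
        se_log=float(se),
    )
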