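"""Poisson regression of per-trial assembly activity on stimulus value.

The trial-wise activation count of an assembly in the post-CS+ window is
regressed on the model-derived value trace with a log link,
``log(mu_t) = beta0 + beta * V_CS+(t)``.  For pooling across assemblies
and sessions the coefficient is standardized,
``beta_bar = beta * sigma(V) / sigma(mu_hat)`` (sigma over trials, fitted
means), and transformed to ``beta_star = exp(beta_bar) - 1`` so that a
positive value reads directly as a positive activity-value correlation.

The baseline-subtraction control repeats the fit on response counts minus
per-trial baseline activity; because differences can be negative the
control uses a Gaussian identity-link fit (with the same standardization)
whenever the Poisson likelihood is no longer applicable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["RegressionResult", "poisson_value_regression", "baseline_subtracted_control"]


@dataclass
class RegressionResult:
    beta0: float
    beta_reg: float
    beta_bar: float
    beta_star: float
    t_stat: float
    p_value: float
    n_trials: int
    family: str = "poisson"
    degenerate: bool = False


def _standardize(beta: float, v: np.ndarray, mu_hat: np.ndarray) -> tuple[float, float]:
    s_v = np.std(v, ddof=1)
    s_mu = np.std(mu_hat, ddof=1)
    if s_mu == 0:
        return 0.0, 0.0
    beta_bar = beta * s_v / s_mu
    return beta_bar, float(np.expm1(beta_bar))


def poisson_value_regression(counts: np.ndarray, v: np.ndarray,
                             min_trials: int = 20) -> RegressionResult:
    """Maximum-likelihood Poisson fit of counts on the value trace."""
    counts = np.asarray(counts, dtype=float)
    v = np.asarray(v, dtype=float)
    if counts.size != v.size:
        raise ValueError("counts and value trace must align trial-wise")
    if counts.size < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if not np.all(np.isfinite(v)):
        raise ValueError("value trace must be finite")
    if np.std(v) == 0:
        raise ValueError("constant value trace: regression coefficient undefined")
    if np.all(counts == 0):
        logger.warning("all-zero activation counts: degenerate regression")
        return RegressionResult(-np.inf, 0.0, 0.0, 0.0, 0.0, 1.0,
                                counts.size, degenerate=True)
    X = sm.add_constant(v)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    beta0, beta = fit.params
    beta_bar, beta_star = _standardize(beta, v, fit.fittedvalues)
    return RegressionResult(
        beta0=float(beta0),
        beta_reg=float(beta),
        beta_bar=float(beta_bar),
        beta_star=beta_star,
        t_stat=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n_trials=counts.size,
    )


def baseline_subtracted_control(counts: np.ndarray, baseline_counts: np.ndarray,
                                v: np.ndarray, min_trials: int = 20) -> RegressionResult:
    """Repeat the regression on baseline-subtracted activity.

    With a zero baseline this reduces exactly to the Poisson fit; when
    differences go negative the fit falls back to an ordinary Gaussian
    identity-link regression (logged), standardized identically.
    """
    counts = np.asarray(counts, dtype=float)
    baseline_counts = np.asarray(baseline_counts, dtype=float)
    if counts.shape != baseline_counts.shape:
        raise ValueError("response and baseline counts must share trial indices")
    diff = counts - baseline_counts
    if np.all(diff >= 0) and np.all(diff == np.round(diff)):
        return poisson_value_regression(diff, v, min_trials)
    logger.info("negative baseline-subtracted counts: Gaussian identity-link fit")
    v = np.asarray(v, dtype=float)
    if np.std(v) == 0:
        raise ValueError("constant value trace: regression coefficient undefined")
    if diff.size < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    X = sm.add_constant(v)
    fit = sm.OLS(diff, X).fit()
    beta0, beta = fit.params
    beta_bar, beta_star = _standardize(beta, v, fit.fittedvalues)
    return RegressionResult(
        beta0=float(beta0),
        beta_reg=float(beta),
        beta_bar=float(beta_bar),
        beta_star=beta_star,
        t_stat=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n_trials=diff.size,
        family="gaussian",
    )
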