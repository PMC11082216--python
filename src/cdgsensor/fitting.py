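"""Shared fit-result container and confidence-interval helpers.

All nonlinear fits in the package return a :class:`FitResult` (or a thin
domain-specific wrapper around one) carrying point estimates, asymptotic 95%
confidence intervals, the residual noise scale and bookkeeping metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class FitResult:
    """Container for a nonlinear least-squares fit.

    Attributes
    ----------
    params : dict
        Named point estimates.
    ci95 : dict
        Per-parameter 95% confidence interval ``(lo, hi)``; each interval
        contains its point estimate. Parameters whose uncertainty could not
        be evaluated map to ``(nan, nan)``.
    residual_sd : float
        Standard deviation of the (weighted) fit residuals.
    n_obs : int
        Number of observations used.
    model_name : str
        Identifier of the model that was fitted.
    derived : dict
        Quantities computed from the estimates (fold changes, kinetic Kd,
        microscopic site constants, ...), not free parameters.
    jackknife_se : dict or None
        Leave-one-out jackknife standard errors, when computed.
    """

    params: dict
    ci95: dict
    residual_sd: float
    n_obs: int
    model_name: str
    derived: dict = field(default_factory=dict)
    jackknife_se: dict | None = None

    def __post_init__(self):
        if self.n_obs < len(self.params) + 1:
            raise ValueError(
                f"n_obs={self.n_obs} too small for {len(self.params)} free parameters"
            )
        for name, (lo, hi) in self.ci95.items():
            est = self.params.get(name)
            if est is not None and np.isfinite(lo) and np.isfinite(hi):
                if not (lo <= est <= hi):
                    raise ValueError(f"CI for {name} does not contain its estimate")


def t_factor(dof: int) -> float:
    """Two-sided 95% Student-t multiplier for ``dof`` residual degrees of freedom."""
    if dof <= 0:
        return np.inf
    return float(stats.t.ppf(0.975, dof))


def ci_from_stderr(estimates: dict, stderrs: dict, dof: int) -> dict:
    """Asymptotic 95% CIs (t-distribution) from point estimates and standard errors.

    Parameters without a finite standard error get ``(nan, nan)``.
    """
    t = t_factor(dof)
    out = {}
    for name, est in estimates.items():
        se = stderrs.get(name)
        if se is None or not np.isfinite(se):
            out[name] = (np.nan, np.nan)
        else:
            out[name] = (est - t * se, est + t * se)
    return out


def lmfit_stderrs(result) -> dict:
    """Extract per-parameter standard errors from an lmfit MinimizerResult."""
    out = {}
    for name, par in result.params.items():
        if par.vary:
            out[name] = par.stderr if par.stderr is not None else np.nan
    return out


def residual_sd(residuals: np.ndarray, n_free: int) -> float:
    """Unbiased residual standard deviation given ``n_free`` fitted parameters."""
    r = np.asarray(residuals, dtype=float).ravel()
    dof = r.size - n_free
    if dof <= 0:
        return float(np.sqrt(np.mean(r**2))) if r.size else np.nan
    return float(np.sqrt(np.sum(r**2) / dof))


def jackknife_se(estimates: np.ndarray) -> np.ndarray:
    """Jackknife standard error from an ``(n, p)`` array of leave-one-out estimates.

    Uses the standard jackknife variance formula
    ``SE^2 = (n-1)/n * sum_i (theta_i - theta_bar)^2``.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    n = est.shape[0]
    if n < 2:
        return np.full(est.shape[1], np.nan)
    mean = est.mean(axis=0)
    return np.sqrt((n - 1) / n * np.sum((est - mean) ** 2, axis=0))
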