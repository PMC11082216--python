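"""Equilibrium sensor calibration: Hill/4PL dose-response model and fits.

A single-fluorescent-protein biosensor read out at a fixed excitation
wavelength follows a four-parameter logistic ("variable slope") isotherm in
ligand concentration ``c``::

    S(c) = bottom + (top - bottom) / (1 + (kd / c)**hill)

with a *signed* Hill slope: channels whose signal rises with ligand carry
``hill > 0`` (the 497-nm excitation channel of cdGreen-type sensors), channels
that fall with ligand carry ``hill < 0`` (the 405-nm channel). ``S(kd)`` is
exactly the midpoint ``(top + bottom)/2`` for any slope, and ``S(0)`` is taken
by limit (``bottom`` for positive slopes, ``top`` for negative ones) rather
than by evaluating the singular expression.

The module also provides the stoichiometric-titration breakpoint estimate: a
continuous two-segment linear fit of signal against the ligand:protein molar
ratio in the tight-binding regime, whose intersection abscissa reports the
binding stoichiometry (two c-di-GMP per protein for BldD-based sensors).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateFitError, InvalidParameterError, NoBreakpointError
from .fitting import FitResult, ci_from_stderr, lmfit_stderrs, residual_sd, t_factor

CHANNELS = ("ex497", "ex405", "ratio")


@dataclass(frozen=True)
class SensorIsothermParams:
    """Calibration of one sensor readout channel.

    Parameters
    ----------
    bottom, top : float
        Asymptotic signals at zero and saturating ligand (arbitrary
        fluorescence units). For negative Hill slopes the roles are exchanged
        by the limit behaviour of the 4PL form.
    kd : float
        Equilibrium dissociation constant, molar. Must be positive.
    hill : float
        Signed Hill slope (dimensionless, nonzero).
    """

    bottom: float
    top: float
    kd: float
    hill: float

    def __post_init__(self):
        vals = (self.bottom, self.top, self.kd, self.hill)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite isotherm parameters: {vals}")
        if self.kd <= 0:
            raise InvalidParameterError(f"kd must be positive, got {self.kd}")
        if self.hill == 0:
            raise InvalidParameterError("hill slope must be nonzero")

    @property
    def fold_change(self) -> float:
        """max(bottom, top) / min(bottom, top); >= 1 for positive asymptotes."""
        lo, hi = sorted((self.bottom, self.top))
        if lo <= 0:
            return np.inf
        return hi / lo


def hill_response(conc, params: SensorIsothermParams):
    """Evaluate the 4PL isotherm at concentration(s) ``conc`` (molar, >= 0).

    Zero concentrations are handled by the analytic limit, never by dividing
    by zero: ``bottom`` for ``hill > 0``, ``top`` for ``hill < 0``.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("ligand concentrations must be >= 0")
    scalar = conc.ndim == 0
    c = np.atleast_1d(conc)
    out = np.empty_like(c)
    zero = c == 0
    limit_at_zero = params.bottom if params.hill > 0 else params.top
    out[zero] = limit_at_zero
    cz = c[~zero]
    out[~zero] = params.bottom + (params.top - params.bottom) / (
        1.0 + (params.kd / cz) ** params.hill
    )
    return float(out[0]) if scalar else out


def _pooled_noise_sd(conc: np.ndarray, signal: np.ndarray) -> float:
    """Replicate-based noise estimate: pooled SD within concentration groups,
    falling back to half the median absolute successive difference."""
    df = pd.DataFrame({"c": conc, "s": signal})
    grp = df.groupby("c")["s"]
    counts = grp.count()
    if (counts > 1).any():
        sds = grp.std(ddof=1).dropna()
        if len(sds):
            return float(np.sqrt(np.mean(sds**2)))
    order = np.argsort(conc)
    d = np.diff(signal[order])
    return float(np.median(np.abs(d)) / np.sqrt(2)) if d.size else 0.0


def _fit_4pl(
    x: np.ndarray,
    y: np.ndarray,
    weights: str = "relative",
    model_name: str = "4pl_variable_slope",
) -> FitResult:
    """Core weighted 4PL fit with deterministic multi-start initialization.

    kd seeds are log-spaced across the positive part of the concentration
    grid; hill seeds run through {-3, -1, 1, 3} in fixed order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = x > 0
    if np.unique(x[pos]).size < 5:
        raise InvalidParameterError(
            ">= 5 distinct nonzero concentrations are required for a 4PL fit"
        )

    noise = _pooled_noise_sd(x, y)
    # flatness is judged on per-concentration means so replicate scatter
    # cannot masquerade as a dose response
    mean_range = float(np.ptp(pd.DataFrame({"c": x, "s": y}).groupby("c")["s"].mean()))
    if mean_range < 3 * noise:
        raise DegenerateFitError(
            f"signal range {mean_range:.3g} < 3 x noise scale {noise:.3g}: flat response"
        )

    w = 1.0 / np.clip(np.abs(y), 1e-12, None) if weights == "relative" else np.ones_like(y)

    def resid(p):
        params = SensorIsothermParams(
            p["bottom"].value, p["top"].value, 10.0 ** p["log10_kd"].value, p["hill"].value
        )
        return (hill_response(x, params) - y) * w

    kd_seeds = np.logspace(np.log10(x[pos].min()), np.log10(x[pos].max()), 5)
    best = None
    for kd0 in kd_seeds:
        for hill0 in (-3.0, -1.0, 1.0, 3.0):
            p = lmfit.Parameters()
            lo, hi = float(np.min(y)), float(np.max(y))
            if hill0 > 0:
                p.add("bottom", value=lo)
                p.add("top", value=hi)
            else:
                p.add("bottom", value=hi)
                p.add("top", value=lo)
            p.add("log10_kd", value=np.log10(kd0), min=np.log10(x[pos].min()) - 3,
                  max=np.log10(x[pos].max()) + 3)
            p.add("hill", value=hill0, min=-10, max=10)
            try:
                res = lmfit.minimize(resid, p, method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr - 1e-12 * (1 + best.chisqr):
                best = res
    if best is None or not best.success:
        from .errors import ConvergenceError

        raise ConvergenceError(
            "4PL fit failed to converge from every start",
            diagnostics={"kd_seeds": list(kd_seeds)},
        )

    bp = best.params
    kd = 10.0 ** bp["log10_kd"].value
    est = {
        "bottom": bp["bottom"].value,
        "top": bp["top"].value,
        "kd": kd,
        "hill": bp["hill"].value,
    }
    se = lmfit_stderrs(best)
    # The 4PL is invariant under (bottom, top, hill) -> (top, bottom, -hill);
    # canonicalize to top >= bottom so the hill sign carries the direction.
    if est["top"] < est["bottom"]:
        est["bottom"], est["top"] = est["top"], est["bottom"]
        est["hill"] = -est["hill"]
        se["bottom"], se["top"] = se.get("top", np.nan), se.get("bottom", np.nan)
    dof = len(y) - 4
    t = t_factor(dof)
    ci = ci_from_stderr(
        {k: est[k] for k in ("bottom", "top", "hill")},
        {k: se.get(k, np.nan) for k in ("bottom", "top", "hill")},
        dof,
    )
    se_l = se.get("log10_kd", np.nan)
    if np.isfinite(se_l):
        ci["kd"] = (10.0 ** (bp["log10_kd"].value - t * se_l),
                    10.0 ** (bp["log10_kd"].value + t * se_l))
    else:
        ci["kd"] = (np.nan, np.nan)

    iso = SensorIsothermParams(**est)
    return FitResult(
        params=est,
        ci95=ci,
        residual_sd=residual_sd(best.residual, 4),
        n_obs=len(y),
        model_name=model_name,
        derived={"fold_change": iso.fold_change},
    )


def fit_dose_response(
    data: pd.DataFrame, channel: str, weights: str = "relative"
) -> FitResult:
    """Fit the 4PL isotherm to a tidy dose-response table.

    Parameters
    ----------
    data : DataFrame
        Columns ``conc_M, channel, replicate, signal``. Repeated measurements
        of the same well are treated as replicates.
    channel : {"ex497", "ex405", "ratio"}
        The ``ratio`` channel is constructed as the per-concentration mean of
        ex497 divided by the per-concentration mean of ex405 (averaging before
        division avoids ratio-of-noisy-singletons instability), then fitted.
    weights : {"relative", "none"}
        ``relative`` (default) weights residuals by 1/|signal|, matching the
        multiplicative noise of fluorescence plate readers.

    Returns
    -------
    FitResult
        ``params``: bottom, top, kd (molar), hill; ``derived['fold_change']``
        is the ratio of the larger to the smaller asymptote.
    """
    if channel not in CHANNELS:
        raise InvalidParameterError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    required = {"conc_M", "channel", "signal"}
    if not required.issubset(data.columns):
        raise InvalidParameterError(f"dose-response table needs columns {sorted(required)}")
    if (data["conc_M"] < 0).any():
        raise InvalidParameterError("ligand concentrations must be >= 0")

    if channel == "ratio":
        have = set(data["channel"].unique())
        if not {"ex497", "ex405"}.issubset(have):
            raise InvalidParameterError("ratio channel requires both ex497 and ex405 data")
        means = (
            data[data["channel"].isin(["ex497", "ex405"])]
            .groupby(["conc_M", "channel"])["signal"]
            .mean()
            .unstack("channel")
        )
        x = means.index.to_numpy(dtype=float)
        y = (means["ex497"] / means["ex405"]).to_numpy(dtype=float)
        return _fit_4pl(x, y, weights=weights, model_name="4pl_ratio")

    sub = data[data["channel"] == channel]
    if sub.empty:
        raise InvalidParameterError(f"no rows for channel {channel!r}")
    return _fit_4pl(
        sub["conc_M"].to_numpy(dtype=float),
        sub["signal"].to_numpy(dtype=float),
        weights=weights,
    )


@dataclass(frozen=True)
class StoichiometryResult:
    """Breakpoint of a stoichiometric (tight-binding) titration.

    ``breakpoint_ratio`` is the ligand:protein molar ratio at which the two
    fitted line segments intersect; ``segment_slopes`` are the pre- and
    post-breakpoint slopes.
    """

    breakpoint_ratio: float
    segment_slopes: tuple
    residual_sd: float
    n_obs: int


def _bilinear_sse(x: np.ndarray, y: np.ndarray, x0: float):
    """Least-squares continuous two-segment fit with hinge at ``x0``."""
    A = np.column_stack([np.ones_like(x), x, np.clip(x - x0, 0, None)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(np.sum((A @ coef - y) ** 2))
    return sse, coef


def stoichiometric_breakpoint(
    ratio, signal, alpha: float = 0.05
) -> StoichiometryResult:
    """Estimate the plateau breakpoint of a stoichiometric titration.

    Fits a continuous piecewise-linear model (two segments joined at a free
    hinge) by profiling the hinge position over a dense grid with local
    refinement, and tests it against a single straight line with an F-test.

    Raises
    ------
    NoBreakpointError
        If the two-segment model is not significantly better than a single
        line at level ``alpha``.
    """
    x = np.asarray(ratio, dtype=float)
    y = np.asarray(signal, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < 8:
        raise InvalidParameterError(
            "stoichiometric breakpoint needs >= 8 points (>= 4 per segment)"
        )

    lo, hi = x[2], x[-3]
    grid = np.linspace(lo, hi, 256)
    sses = np.array([_bilinear_sse(x, y, x0)[0] for x0 in grid])
    i = int(np.argmin(sses))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if b > a:
        ref = optimize.minimize_scalar(
            lambda x0: _bilinear_sse(x, y, x0)[0], bounds=(a, b), method="bounded"
        )
        x0 = float(ref.x)
    else:
        x0 = float(grid[i])
    sse2, coef = _bilinear_sse(x, y, x0)

    # single-line null model
    A1 = np.column_stack([np.ones_like(x), x])
    c1, _, _, _ = np.linalg.lstsq(A1, y, rcond=None)
    sse1 = float(np.sum((A1 @ c1 - y) ** 2))
    dof2 = n - 4
    if sse2 <= 0:
        pval = 0.0
    else:
        F = ((sse1 - sse2) / 2) / (sse2 / dof2)
        pval = float(stats.f.sf(F, 2, dof2))
    if pval >= alpha:
        raise NoBreakpointError(
            f"two-segment fit not better than a line (F-test p={pval:.3g})"
        )

    s1 = float(coef[1])
    s2 = float(coef[1] + coef[2])
    if abs(s2) > abs(s1):
        warnings.warn(
            "post-breakpoint slope exceeds pre-breakpoint slope in magnitude; "
            "titration may not be in the tight-binding regime"
        )
    return StoichiometryResult(
        breakpoint_ratio=x0,
        segment_slopes=(s1, s2),
        residual_sd=float(np.sqrt(sse2 / dof2)) if dof2 > 0 else np.nan,
        n_obs=n,
    )
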