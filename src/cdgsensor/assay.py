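"""Sensor-coupled real-time enzyme activity assay analysis.

Diguanylate cyclases (DGC, make c-di-GMP from 2 GTP) and phosphodiesterases
(PDE, break it down) are assayed by following the fluorescence of an
equilibrium-readout biosensor as the reaction proceeds. Raw plate traces are
normalized to the time-averaged signal of a saturated-sensor control well,
progression curves are fitted with a 4PL-in-time model with shared asymptotes
across replicates, and the half-maximal time EC50 (a.k.a. I50) converts to a
specific activity through the sensor's dissociation constant:

    DGC:  activity = Kd_sensor / (EC50 * [DGC])           (s^-1)
    PDE:  activity = ([cdG]0 - Kd_sensor) / (EC50 * [PDE]) (s^-1)

Both formulas are exact when turnover is approximately zero-order through the
sensor's transition: the sensor signal reaches half-max exactly when the
c-di-GMP concentration crosses Kd (midpoint identity of the Hill form, any
slope). A hyperbolic fit of activity against GTP concentration estimates the
GTP binding constant of GTP-activated PDEs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .errors import (
    CensoredEC50Error,
    InvalidDesignError,
    InvalidParameterError,
    NormalizationError,
)
from .fitting import FitResult, ci_from_stderr, lmfit_stderrs, residual_sd, t_factor

ROLES = ("sample", "sensor_only", "sensor_plus_cdG")
DEFAULT_KD_SENSOR_UM = 1.24  # cdGreen2 497-nm channel Kd, µM


@dataclass
class ProgressionCurve:
    """One well's time course: time in seconds, signal in arbitrary units.
    ``normalized`` is filled in by :func:`normalize_plate`."""

    time: np.ndarray
    signal: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise InvalidParameterError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("time must be strictly increasing")


@dataclass
class AssayPlate:
    """A plate of progression curves with per-well roles and metadata.

    ``roles`` maps well id to one of ``sample``, ``sensor_only`` or
    ``sensor_plus_cdG`` (the saturating control used for normalization).
    ``metadata`` carries enzyme/substrate concentrations and, for dose
    series, per-well ligand doses.
    """

    wells: dict
    roles: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for wid, role in self.roles.items():
            if role not in ROLES:
                raise InvalidParameterError(f"unknown role {role!r} for well {wid}")
        times = [w.time for w in self.wells.values()]
        if times and not all(
            t.shape == times[0].shape and np.allclose(t, times[0]) for t in times
        ):
            raise InvalidParameterError("all wells must share the time grid")

    def wells_with_role(self, role: str) -> dict:
        return {wid: w for wid, w in self.wells.items() if self.roles.get(wid) == role}


@dataclass
class TimecourseFit:
    """4PL-in-time fit: EC50 is the half-maximal time (seconds); top and
    bottom are shared across the fitted replicate curves."""

    ec50: float
    top: float
    bottom: float
    slope: float
    ci95: dict
    residual_sd: float
    n_obs: int
    model_name: str = "4pl_in_time"


@dataclass
class EnzymeActivityResult:
    """Specific activity in µM c-di-GMP per µM enzyme per second (s^-1)."""

    specific_activity: float
    mode: str
    ec50: float
    enzyme_conc: float
    kd_sensor: float
    cdg0: float | None = None


def normalize_plate(plate: AssayPlate) -> AssayPlate:
    """Divide every well's raw signal by the time-averaged saturated control.

    The divisor is the mean over the whole time course of the mean of all
    ``sensor_plus_cdG`` wells, so normalization is gain-invariant and
    idempotent (it always recomputes from the raw ``signal``).
    """
    controls = plate.wells_with_role("sensor_plus_cdG")
    if not controls:
        raise NormalizationError("no sensor_plus_cdG control well on the plate")
    ctrl = float(np.mean([np.mean(w.signal) for w in controls.values()]))
    if ctrl <= 0:
        raise NormalizationError(f"saturated-control mean {ctrl} is not positive")
    new_wells = {
        wid: replace(w, normalized=w.signal / ctrl) for wid, w in plate.wells.items()
    }
    return AssayPlate(wells=new_wells, roles=dict(plate.roles),
                      metadata=dict(plate.metadata))


def _curve_values(curve: ProgressionCurve) -> np.ndarray:
    return curve.normalized if curve.normalized is not None else curve.signal


def _logistic_time(t, bottom, top, ec50, slope):
    out = np.empty_like(t)
    zero = t == 0
    out[zero] = bottom if slope > 0 else top
    tz = t[~zero]
    out[~zero] = bottom + (top - bottom) / (1.0 + (ec50 / tz) ** slope)
    return out


def fit_progression(
    curves: list[ProgressionCurve], direction: str = "auto"
) -> TimecourseFit:
    """Fit replicate progression curves with a shared-asymptote 4PL in time.

    ``direction``: ``"rising"`` (DGC), ``"falling"`` (PDE) or ``"auto"``
    (detected from the sign of the overall signal change). All parameters —
    bottom, top, slope and EC50 — are shared across the replicate curves,
    matching the "shared value for all data sets" constraint used for
    replicate fits. The signed slope carries the direction: positive rising,
    negative falling; EC50 is always the half-maximal time.

    Raises
    ------
    CensoredEC50Error
        If the fitted EC50 falls outside the observation window (no
        transition observed); the error carries the usable bound.
    """
    if not curves:
        raise InvalidParameterError("no curves given")
    t = curves[0].time
    ys = [_curve_values(c) for c in curves]
    if any(c.time.shape != t.shape or not np.allclose(c.time, t) for c in curves):
        raise InvalidParameterError("curves must share the time grid")

    ymean = np.mean(ys, axis=0)
    d = float(np.mean(ymean[-3:]) - np.mean(ymean[:3]))
    if direction == "auto":
        direction = "rising" if d > 0 else "falling"
    if direction not in ("rising", "falling"):
        raise InvalidParameterError(f"unknown direction {direction!r}")

    sign = 1.0 if direction == "rising" else -1.0
    lo, hi = float(np.min(ymean)), float(np.max(ymean))
    half = (lo + hi) / 2.0
    cross = np.flatnonzero(np.diff(np.sign(ymean - half)))
    ec0 = float(t[cross[0]]) if cross.size else float(np.median(t))

    p = lmfit.Parameters()
    p.add("bottom", value=lo if sign > 0 else hi)
    p.add("top", value=hi if sign > 0 else lo)
    p.add("log10_ec50", value=np.log10(max(ec0, t[1])),
          min=np.log10(max(t[1] / 10, 1e-6)), max=np.log10(t[-1] * 100))
    p.add("slope", value=2.0 * sign)

    def resid(pars):
        model = _logistic_time(
            t, pars["bottom"].value, pars["top"].value,
            10.0 ** pars["log10_ec50"].value, pars["slope"].value,
        )
        return np.concatenate([model - y for y in ys])

    res = lmfit.minimize(resid, p, method="leastsq")
    bp = res.params
    ec50 = 10.0 ** bp["log10_ec50"].value
    if not (t[0] <= ec50 <= t[-1]):
        bound = t[-1] if ec50 > t[-1] else t[0]
        raise CensoredEC50Error(
            f"half-maximal time {ec50:.3g}s outside the observation window "
            f"[{t[0]:.3g}, {t[-1]:.3g}]s",
            bound=float(bound),
        )

    est = {"bottom": bp["bottom"].value, "top": bp["top"].value,
           "slope": bp["slope"].value}
    se = lmfit_stderrs(res)
    n_obs = sum(y.size for y in ys)
    dof = n_obs - 4
    tfac = t_factor(dof)
    ci = ci_from_stderr(est, {k: se.get(k, np.nan) for k in est}, dof)
    s = se.get("log10_ec50", np.nan)
    lv = bp["log10_ec50"].value
    ci["ec50"] = (10.0 ** (lv - tfac * s), 10.0 ** (lv + tfac * s)) if np.isfinite(s) else (np.nan, np.nan)

    return TimecourseFit(
        ec50=float(ec50),
        top=est["top"],
        bottom=est["bottom"],
        slope=est["slope"],
        ci95=ci,
        residual_sd=residual_sd(res.residual, 4),
        n_obs=n_obs,
    )


def specific_activity(
    fit: TimecourseFit | float,
    mode: str,
    enzyme_conc: float,
    cdg0: float | None = None,
    kd_sensor: float = DEFAULT_KD_SENSOR_UM,
) -> EnzymeActivityResult:
    """Convert a half-maximal time into a specific enzyme activity (s^-1).

    Parameters
    ----------
    fit : TimecourseFit or float
        Fitted progression curve, or the EC50 itself in seconds.
    mode : {"DGC", "PDE"}
    enzyme_conc : float
        Enzyme concentration in µM.
    cdg0 : float
        Initial c-di-GMP substrate concentration in µM (PDE mode only);
        must exceed ``kd_sensor`` or the formula is undefined.
    kd_sensor : float
        Sensor dissociation constant in µM (defaults to the cdGreen2 497-nm
        channel value, 1.24 µM).
    """
    ec50 = fit.ec50 if isinstance(fit, TimecourseFit) else float(fit)
    if ec50 <= 0 or enzyme_conc <= 0 or kd_sensor <= 0:
        raise InvalidParameterError("ec50, enzyme_conc and kd_sensor must be positive")
    mode = mode.upper()
    if mode == "DGC":
        act = kd_sensor / (ec50 * enzyme_conc)
    elif mode == "PDE":
        if cdg0 is None:
            raise InvalidParameterError("PDE mode requires the initial c-di-GMP cdg0")
        if cdg0 <= kd_sensor:
            raise InvalidDesignError(
                f"PDE activity formula undefined for cdg0={cdg0} <= kd_sensor={kd_sensor}"
            )
        act = (cdg0 - kd_sensor) / (ec50 * enzyme_conc)
    else:
        raise InvalidParameterError(f"mode must be DGC or PDE, got {mode!r}")
    return EnzymeActivityResult(
        specific_activity=float(act), mode=mode, ec50=ec50,
        enzyme_conc=enzyme_conc, kd_sensor=kd_sensor, cdg0=cdg0,
    )


def fit_gtp_dose_response(gtp_conc, activity) -> FitResult:
    """Fit a binding hyperbola ``v(G) = v_max * G / (kd_gtp + G)``.

    ``gtp_conc`` in µM; ``activity`` may be specific activities or 1/EC50
    values — the fitted ``kd_gtp`` is invariant to the overall scale.
    Emits a warning when the dose range does not reach saturation
    (max dose < 2 x fitted kd), in which case kd is only bounded below.
    """
    g = np.asarray(gtp_conc, dtype=float)
    v = np.asarray(activity, dtype=float)
    if np.unique(g).size < 4:
        raise InvalidParameterError(">= 4 GTP concentrations are required")

    p = lmfit.Parameters()
    p.add("v_max", value=float(np.max(v)), min=0)
    p.add("kd_gtp", value=float(np.median(g)), min=1e-12)

    def resid(pars):
        return pars["v_max"] * g / (pars["kd_gtp"] + g) - v

    res = lmfit.minimize(resid, p, method="leastsq")
    est = {"v_max": res.params["v_max"].value, "kd_gtp": res.params["kd_gtp"].value}
    se = lmfit_stderrs(res)
    dof = len(g) - 2
    ci = ci_from_stderr(est, se, dof)
    if est["kd_gtp"] > np.max(g) / 2:
        warnings.warn(
            "no saturation observed within the dose range: kd_gtp is only "
            "bounded from below"
        )
    return FitResult(
        params=est,
        ci95=ci,
        residual_sd=residual_sd(res.residual, 2),
        n_obs=len(g),
        model_name="gtp_hyperbola",
    )
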