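"""Binding kinetics of the biosensor: dissociation-by-dilution and global
association fits, plus rate-constant arithmetic.

Dissociation by dilution follows a one-phase exponential decay
``S(t) = span * exp(-k_off * t) + plateau``; the half-life is ``ln 2 / k_off``
by definition, so ``t_half * k_off == ln 2`` holds exactly for every fit.

Association under pseudo-first-order conditions (ligand far above sensor)
relaxes with observed rate ``k_obs(L) = k_on * L + k_off`` toward the
single-step occupancy plateau ``L / (L + k_off/k_on)``; traces recorded at
several ligand concentrations are fitted globally with ``k_on``, ``k_off``
and the amplitude shared, and the kinetic ``Kd = k_off / k_on`` is derived,
never fitted separately.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import (
    DegenerateFitError,
    InvalidParameterError,
    UnderIdentifiedWarning,
    WrongDirectionError,
)
from .fitting import FitResult, ci_from_stderr, lmfit_stderrs, residual_sd, t_factor

LN2 = float(np.log(2.0))


@dataclass
class KineticTrace:
    """A single fluorescence time trace.

    ``time`` in minutes (strictly increasing), ``signal`` in arbitrary units.
    ``ligand_conc`` (molar) is required for association traces.
    """

    time: np.ndarray
    signal: np.ndarray
    label: str = ""
    ligand_conc: float | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise InvalidParameterError("time and signal must have equal length")
        if self.time.size < 5:
            raise InvalidParameterError("kinetic traces need >= 5 points")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("time must be strictly increasing")


@dataclass
class DissociationFit:
    """One-phase exponential decay fit. ``t_half = ln2 / k_off`` identically."""

    k_off: float
    span: float
    plateau: float
    ci95: dict
    residual_sd: float
    n_obs: int
    model_name: str = "one_phase_decay"

    @property
    def t_half(self) -> float:
        return LN2 / self.k_off


@dataclass
class GlobalKineticFit:
    """Global pseudo-first-order association fit.

    ``kd_kinetic = k_off / k_on`` is a derived field; the identity
    ``kd_kinetic * k_on == k_off`` therefore holds exactly.
    """

    k_on: float
    k_off: float
    s_max: float
    ci95: dict
    residual_sd: float
    n_obs: int
    model_name: str = "association_global"

    @property
    def kd_kinetic(self) -> float:
        return self.k_off / self.k_on

    def k_obs(self, ligand_conc: float) -> float:
        """Observed relaxation rate at ligand concentration L (molar)."""
        return self.k_on * ligand_conc + self.k_off


def derive_rate_constants(k_off: float, kd: float) -> dict:
    """Rate-constant arithmetic: ``k_on = k_off / kd`` and ``t_half = ln2 / k_off``.

    ``k_off`` in min^-1, ``kd`` in molar; returns k_on in M^-1 min^-1 and
    t_half in minutes.
    """
    if not (np.isfinite(k_off) and np.isfinite(kd)) or k_off <= 0 or kd <= 0:
        raise InvalidParameterError(f"k_off and kd must be positive, got {k_off}, {kd}")
    return {"k_on": k_off / kd, "t_half": LN2 / k_off}


def _subtract_baseline(trace: KineticTrace, baseline: KineticTrace) -> np.ndarray:
    """Pointwise baseline subtraction, interpolating the baseline onto the
    sample time grid when the grids differ."""
    if trace.time.shape == baseline.time.shape and np.allclose(trace.time, baseline.time):
        return trace.signal - baseline.signal
    return trace.signal - np.interp(trace.time, baseline.time, baseline.signal)


def fit_dissociation(
    trace: KineticTrace,
    baseline: KineticTrace | None = None,
    weights: str = "relative",
) -> DissociationFit:
    """Fit a one-phase exponential decay to a dissociation-by-dilution trace.

    ``baseline``, when given, is a matched protein-only dilution trace whose
    readings are subtracted before fitting (corrects the transient
    protein-dilution artifact seen for high-affinity sensor variants).
    ``weights="relative"`` (default) weights residuals by 1/|signal|,
    matching multiplicative fluorescence noise, which keeps the asymptotic
    confidence intervals calibrated; ``"none"`` gives ordinary least squares.
    """
    y = _subtract_baseline(trace, baseline) if baseline is not None else trace.signal.copy()
    t = trace.time

    head = float(np.mean(y[:3]))
    tail = float(np.mean(y[-3:]))
    if tail >= head:
        raise WrongDirectionError(
            "trace is not decreasing overall; dissociation model does not apply"
        )
    noise = float(np.std(np.diff(y)) / np.sqrt(2)) if len(y) > 3 else 0.0
    span0 = head - tail
    if span0 < 3 * noise:
        raise DegenerateFitError("decay span indistinguishable from noise")

    # log-linear initial guess for the rate
    z = y - tail + 0.05 * span0
    pos = z > 0
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos], np.log(z[pos]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-9)

    p = lmfit.Parameters()
    p.add("k_off", value=k0, min=1e-12)
    p.add("span", value=span0, min=0)
    p.add("plateau", value=tail)

    w = 1.0 / np.clip(np.abs(y), 1e-12, None) if weights == "relative" else np.ones_like(y)

    def resid(pars):
        return (pars["span"] * np.exp(-pars["k_off"] * t) + pars["plateau"] - y) * w

    res = lmfit.minimize(resid, p, method="leastsq")
    est = {k: res.params[k].value for k in ("k_off", "span", "plateau")}
    se = lmfit_stderrs(res)
    dof = len(y) - 3
    ci = ci_from_stderr(est, se, dof)
    # half-life CI by inverting the k_off interval (monotone transform)
    klo, khi = ci["k_off"]
    if np.isfinite(klo) and klo > 0:
        ci["t_half"] = (LN2 / khi, LN2 / klo)
    else:
        ci["t_half"] = (np.nan, np.nan)
    return DissociationFit(
        k_off=est["k_off"],
        span=est["span"],
        plateau=est["plateau"],
        ci95=ci,
        residual_sd=residual_sd(res.residual, 3),
        n_obs=len(y),
    )


def _association_model(t, L, k_on, k_off, s_max):
    kd = k_off / k_on
    return s_max * L / (L + kd) * (1.0 - np.exp(-(k_on * L + k_off) * t))


def _single_kobs(trace: KineticTrace) -> float:
    """Exponential-approach fit of one trace, returning k_obs."""
    t, y = trace.time, trace.signal
    p = lmfit.Parameters()
    p.add("amp", value=float(np.max(y)), min=0)
    p.add("k", value=2.0 / max(t[-1], 1e-9), min=1e-9)

    def resid(pars):
        return pars["amp"] * (1 - np.exp(-pars["k"] * t)) - y

    res = lmfit.minimize(resid, p, method="leastsq")
    return float(res.params["k"].value)


def fit_association_global(traces: list[KineticTrace]):
    """Globally fit association traces recorded at several ligand concentrations.

    All traces share ``k_on``, ``k_off`` and ``s_max``. With a single distinct
    ligand concentration the problem is under-identified: an
    :class:`UnderIdentifiedWarning` is emitted and a :class:`FitResult` with
    only ``k_obs`` is returned instead.
    """
    if not traces:
        raise InvalidParameterError("no traces given")
    concs = [tr.ligand_conc for tr in traces]
    if any(c is None or c <= 0 for c in concs):
        raise InvalidParameterError("every association trace needs ligand_conc > 0")
    distinct = np.unique(np.round(np.log10(concs), 9))
    if distinct.size < 2:
        warnings.warn(
            "single ligand concentration: k_on and k_off are not separable; "
            "returning k_obs only",
            UnderIdentifiedWarning,
        )
        k_obs = _single_kobs(traces[0])
        return FitResult(
            params={"k_obs": k_obs},
            ci95={"k_obs": (np.nan, np.nan)},
            residual_sd=np.nan,
            n_obs=traces[0].time.size,
            model_name="association_single_kobs",
        )

    # two-stage initial guess: per-trace k_obs, then k_obs = k_on*L + k_off
    kobs = np.array([_single_kobs(tr) for tr in traces])
    L = np.array(concs, dtype=float)
    slope, intercept = np.polyfit(L, kobs, 1)
    kon0 = max(slope, 1e-3)
    koff0 = max(intercept, 1e-6)
    smax0 = float(max(np.max(tr.signal) for tr in traces))

    p = lmfit.Parameters()
    p.add("log10_k_on", value=np.log10(kon0), min=-3, max=12)
    p.add("k_off", value=koff0, min=1e-9)
    p.add("s_max", value=smax0, min=0)

    def resid(pars):
        k_on = 10.0 ** pars["log10_k_on"].value
        parts = [
            _association_model(tr.time, tr.ligand_conc, k_on, pars["k_off"].value,
                               pars["s_max"].value) - tr.signal
            for tr in traces
        ]
        return np.concatenate(parts)

    res = lmfit.minimize(resid, p, method="leastsq")
    k_on = 10.0 ** res.params["log10_k_on"].value
    est = {"k_on": k_on, "k_off": res.params["k_off"].value,
           "s_max": res.params["s_max"].value}
    se = lmfit_stderrs(res)
    n_obs = sum(tr.time.size for tr in traces)
    dof = n_obs - 3
    t = t_factor(dof)
    ci = ci_from_stderr(
        {"k_off": est["k_off"], "s_max": est["s_max"]},
        {"k_off": se.get("k_off", np.nan), "s_max": se.get("s_max", np.nan)},
        dof,
    )
    se_l = se.get("log10_k_on", np.nan)
    lk = res.params["log10_k_on"].value
    ci["k_on"] = (
        (10.0 ** (lk - t * se_l), 10.0 ** (lk + t * se_l))
        if np.isfinite(se_l)
        else (np.nan, np.nan)
    )
    # kinetic Kd CI via relative-error propagation of the ratio k_off/k_on
    kd = est["k_off"] / est["k_on"]
    rel = []
    if np.isfinite(se.get("k_off", np.nan)):
        rel.append(se["k_off"] / est["k_off"])
    if np.isfinite(se_l):
        rel.append(np.log(10) * se_l)
    if rel:
        sd_kd = kd * float(np.hypot(*rel)) if len(rel) == 2 else kd * rel[0]
        ci["kd_kinetic"] = (kd - t * sd_kd, kd + t * sd_kd)
    else:
        ci["kd_kinetic"] = (np.nan, np.nan)

    return GlobalKineticFit(
        k_on=est["k_on"],
        k_off=est["k_off"],
        s_max=est["s_max"],
        ci95=ci,
        residual_sd=residual_sd(res.residual, 3),
        n_obs=n_obs,
    )
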