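"""Seeded synthetic-data generators for every input the analyses consume.

Each generator is a pure function of its specification and seed: the same
arguments always produce bit-identical output. Defaults reproduce the study
conditions of the in vitro characterization designs (12-point log-spaced
dose grids with two replicates and 2% multiplicative noise; 10-s sampled
20-min dissociation traces at 1% noise; the 1 x 0.4 µl + 19 x 1.8 µl ITC
protocol with additive per-injection noise; 16-h plate courses sampled every
minute; branching lineages with an asymmetric c-di-GMP trough in one
daughter). Fluorescence noise is multiplicative by default (plate-reader
coefficients of variation scale with signal); ITC injection noise is
additive in kcal/mol.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayPlate, ProgressionCurve
from .errors import InvalidDesignError, InvalidParameterError
from .isotherm import SensorIsothermParams, hill_response
from .itc import FourSiteModelParams, ITCProtocol, ITCThermogram, simulate_thermogram
from .kinetics import KineticTrace
from .lineage import CellTrack


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for a generator: multiplicative (fractional sd) or
    additive (sd in signal units), plus the RNG seed."""

    kind: str = "multiplicative"
    sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("multiplicative", "additive"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise InvalidParameterError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.asarray(values, dtype=float).copy()
        eps = rng.normal(0.0, self.sd, size=np.shape(values))
        if self.kind == "multiplicative":
            return values * (1.0 + eps)
        return values + eps


@dataclass(frozen=True)
class DynamicsSpec:
    """Single-cell c-di-GMP dynamics emulated by the lineage generator.

    One daughter of every division inherits a transient low-c-di-GMP state
    (a trough of ``trough_duration`` minutes, smoothed with ~2-min logistic
    edges) while the other stays high — the stalked/swarmer asymmetry.
    """

    high_level: float = 1000.0
    low_level: float = 300.0
    trough_duration: float = 20.0
    interdivision_time: float = 75.0

    def __post_init__(self):
        if not (self.high_level > self.low_level > 0):
            raise InvalidParameterError("need high_level > low_level > 0")
        if not (0 < self.trough_duration < self.interdivision_time):
            raise InvalidParameterError("trough must be shorter than the cell cycle")


def gen_dose_response(
    params: SensorIsothermParams,
    conc_grid,
    n_rep: int = 2,
    noise: NoiseSpec = NoiseSpec(),
    channel: str = "ex497",
) -> pd.DataFrame:
    """Generate a tidy dose-response table from the forward isotherm.

    Returns columns ``conc_M, channel, replicate, signal``; replicates share
    the concentration grid. Warns when the grid does not span the sensor Kd.
    """
    conc = np.asarray(conc_grid, dtype=float)
    pos = conc[conc > 0]
    if pos.size and not (pos.min() < params.kd < pos.max()):
        warnings.warn("concentration grid does not span the transition (kd)")
    rng = noise.rng()
    rows = []
    for rep in range(n_rep):
        clean = hill_response(conc, params)
        rows.append(pd.DataFrame({
            "conc_M": conc,
            "channel": channel,
            "replicate": rep,
            "signal": noise.apply(clean, rng),
        }))
    return pd.concat(rows, ignore_index=True)


def gen_kinetic_traces(
    mode: str,
    true_params: dict,
    design: dict,
    noise: NoiseSpec = NoiseSpec(sd=0.01),
) -> list:
    """Generate exponential kinetic traces.

    ``mode="dissociation"``: ``true_params`` needs ``k_off`` (min^-1),
    ``span`` and ``plateau``; ``design`` needs ``t_max_min`` and ``dt_s``
    (defaults 20 min, 10 s).

    ``mode="association"``: ``true_params`` needs ``k_on`` (M^-1 min^-1),
    ``k_off`` and ``s_max``; ``design`` needs ``ligand_concs_M`` plus
    ``t_max_min``/``dt_s``; each trace relaxes at
    ``k_obs = k_on * L + k_off`` toward ``s_max * L / (L + k_off/k_on)``.
    """
    t_max = design.get("t_max_min", 20.0)
    dt = design.get("dt_s", 10.0) / 60.0
    t = np.arange(0.0, t_max + dt / 2, dt)
    rng = noise.rng()
    if mode == "dissociation":
        k = true_params["k_off"]
        span = true_params.get("span", 1.0)
        plateau = true_params.get("plateau", 0.0)
        clean = span * np.exp(-k * t) + plateau
        return [KineticTrace(t, noise.apply(clean, rng), label="dissociation")]
    if mode == "association":
        kon, koff = true_params["k_on"], true_params["k_off"]
        smax = true_params.get("s_max", 1.0)
        kd = koff / kon
        traces = []
        for L in design["ligand_concs_M"]:
            clean = smax * L / (L + kd) * (1.0 - np.exp(-(kon * L + koff) * t))
            traces.append(
                KineticTrace(t, noise.apply(clean, rng),
                             label=f"L={L:.3g}M", ligand_conc=float(L))
            )
        return traces
    raise InvalidParameterError(f"unknown mode {mode!r}")


def gen_itc_thermogram(
    protocol: ITCProtocol,
    params: FourSiteModelParams,
    noise: NoiseSpec = NoiseSpec(kind="additive", sd=0.15),
    dilution_heat: float = -0.10,
):
    """Simulate a sample thermogram and its matched ligand-into-buffer blank.

    The sample carries the binding heats plus a small constant dilution heat
    per injection; the blank carries the dilution heat only. Both receive
    independent additive noise, so blank subtraction removes the offset in
    expectation (exactly at zero noise). Returns ``(sample, blank)``.
    """
    clean = simulate_thermogram(protocol, params).heats
    rng = noise.rng()
    sample = ITCThermogram(noise.apply(clean + dilution_heat, rng))
    blank = ITCThermogram(noise.apply(np.full_like(clean, dilution_heat), rng))
    return sample, blank


def gen_assay_plate(
    enzyme: dict,
    substrate0: float,
    sensor: SensorIsothermParams,
    duration_h: float = 16.0,
    dt_min: float = 1.0,
    noise: NoiseSpec = NoiseSpec(sd=0.02),
    gtp_modulation: dict | None = None,
    n_rep: int = 1,
) -> AssayPlate:
    """Simulate a plate of sensor-coupled enzyme progression curves.

    The enzyme turns over at a constant (zero-order) rate
    ``rho = specific_rate * conc`` (µM/s): DGC production is capped at
    ``substrate0 / 2`` (two GTP per c-di-GMP); PDE degradation is floored at
    zero c-di-GMP. The sensor reads the instantaneous c-di-GMP concentration
    through its equilibrium isotherm (quasi-steady readout). Control wells
    with sensor alone and sensor plus saturating c-di-GMP are included.

    ``enzyme``: ``{"mode": "DGC"|"PDE", "specific_rate": s^-1, "conc": µM}``.
    ``substrate0``: initial GTP (DGC) or c-di-GMP (PDE), µM.
    ``gtp_modulation``: optional ``{"kd_gtp": µM, "gtp_doses": [µM, ...]}``;
    one sample well (per replicate) per dose, with the rate scaled by
    ``G / (kd_gtp + G)``.
    """
    mode = enzyme["mode"].upper()
    kd_um = sensor.kd * 1e6
    if mode == "PDE" and substrate0 <= kd_um:
        raise InvalidDesignError(
            f"PDE design needs substrate0 > sensor Kd ({kd_um:.3g} µM)"
        )
    t_s = np.arange(0.0, duration_h * 3600.0 + 1e-9, dt_min * 60.0)
    rng = noise.rng()

    def cdg_course(rate_um_per_s):
        if mode == "DGC":
            return np.minimum(rate_um_per_s * t_s, substrate0 / 2.0)
        return np.maximum(substrate0 - rate_um_per_s * t_s, 0.0)

    def readout(cdg_um):
        return hill_response(np.clip(cdg_um, 0, None) * 1e-6, sensor)

    rho0 = enzyme["specific_rate"] * enzyme["conc"]  # µM/s
    doses = gtp_modulation["gtp_doses"] if gtp_modulation else [None]

    wells, roles, well_meta = {}, {}, {}
    for dose in doses:
        scale = 1.0 if dose is None else dose / (gtp_modulation["kd_gtp"] + dose)
        clean = readout(cdg_course(rho0 * scale))
        for rep in range(n_rep):
            wid = "sample" if dose is None else f"sample_G{dose:g}"
            if n_rep > 1:
                wid += f"_r{rep}"
            wells[wid] = ProgressionCurve(t_s, noise.apply(clean, rng))
            roles[wid] = "sample"
            well_meta[wid] = {"gtp_dose_uM": dose, "replicate": rep}

    sensor_only = np.full_like(t_s, hill_response(0.0, sensor))
    saturated = np.full_like(t_s, hill_response(1.0, sensor))  # 1 M >> kd
    wells["sensor_only"] = ProgressionCurve(t_s, noise.apply(sensor_only, rng))
    roles["sensor_only"] = "sensor_only"
    wells["sensor_plus_cdG"] = ProgressionCurve(t_s, noise.apply(saturated, rng))
    roles["sensor_plus_cdG"] = "sensor_plus_cdG"

    return AssayPlate(
        wells=wells,
        roles=roles,
        metadata={
            "mode": mode,
            "enzyme_conc_uM": enzyme["conc"],
            "specific_rate_s": enzyme["specific_rate"],
            "substrate0_uM": substrate0,
            "sensor_kd_uM": kd_um,
            "wells": well_meta,
        },
    )


def _trough_profile(t_min, dynamics: DynamicsSpec, edge_width: float = 2.0):
    """Smoothed square trough: 1 inside [0, trough_duration], 0 outside,
    with logistic edges of ~``edge_width`` minutes."""
    rise = 1.0 / (1.0 + np.exp((t_min - dynamics.trough_duration) / edge_width))
    onset = 1.0 / (1.0 + np.exp(-(t_min + edge_width) / edge_width))
    return rise * onset


def gen_lineage_tracks(
    depth: int,
    dynamics: DynamicsSpec = DynamicsSpec(),
    frame_interval: float = 5.0,
    error_rates: dict | None = None,
    seed: int = 0,
    split_concentration: float = 200.0,
):
    """Generate a full binary lineage with asymmetric c-di-GMP dynamics.

    Cells grow exponentially (length doubling over one interdivision time)
    and divide into two daughters whose length split is Beta-distributed
    around 0.5. One daughter per division (chosen at random) inherits the
    low-c-di-GMP state: its intensity dips to ``low_level`` for the trough
    duration before recovering; the other stays at ``high_level``.

    ``error_rates``: ``{"jump_prob": per-frame probability of an injected
    single-frame tracking glitch (15-25% length error), "length_noise_sd",
    "intensity_noise_sd"}`` (multiplicative sds); all default to 0.

    Returns ``(tracks, truth)`` where ``truth`` is a DataFrame of
    ``cell_id, label`` ground-truth high/low identities (the root is high).
    """
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    err = {"jump_prob": 0.0, "length_noise_sd": 0.0, "intensity_noise_sd": 0.0}
    if error_rates:
        err.update(error_rates)
    rng = np.random.default_rng(seed)

    frames_per_cell = int(round(dynamics.interdivision_time / frame_interval))
    growth = np.log(2.0) / dynamics.interdivision_time

    tracks, truth_rows = [], []
    # queue of (cell_id, parent_id, birth_frame, birth_length, is_low, depth)
    queue = [("c0", None, 0, 2.0, False, 0)]
    while queue:
        cid, parent, birth_frame, L0, is_low, d = queue.pop(0)
        n = frames_per_cell
        tloc = np.arange(n) * frame_interval
        length = L0 * np.exp(growth * tloc)
        if err["length_noise_sd"] > 0:
            length = length * (1.0 + rng.normal(0, err["length_noise_sd"], n))
        if err["jump_prob"] > 0:
            glitch = rng.random(n) < err["jump_prob"]
            if glitch.any():
                size = rng.uniform(0.15, 0.25, glitch.sum())
                sign = rng.choice([-1.0, 1.0], glitch.sum())
                length[glitch] *= 1.0 + sign * size
        if is_low:
            prof = _trough_profile(tloc, dynamics)
            fitc = dynamics.high_level - (dynamics.high_level - dynamics.low_level) * prof
        else:
            fitc = np.full(n, dynamics.high_level)
        if err["intensity_noise_sd"] > 0:
            fitc = fitc * (1.0 + rng.normal(0, err["intensity_noise_sd"], n))

        tracks.append(CellTrack(
            cell_id=cid,
            data=pd.DataFrame({
                "frame": birth_frame + np.arange(n),
                "time_min": (birth_frame + np.arange(n)) * frame_interval,
                "length_um": length,
                "fitc_mean": fitc,
            }),
            parent_id=parent,
        ))
        truth_rows.append({"cell_id": cid, "label": "low" if is_low else "high"})

        if d < depth:
            a = split_concentration
            s = rng.beta(a, a)
            L_div = L0 * np.exp(growth * dynamics.interdivision_time)
            low_first = bool(rng.random() < 0.5)
            kids = [(f"{cid}.0", s), (f"{cid}.1", 1.0 - s)]
            for j, (kid, frac) in enumerate(kids):
                queue.append((
                    kid, cid, birth_frame + n, L_div * frac,
                    (j == 0) == low_first, d + 1,
                ))
    return tracks, pd.DataFrame(truth_rows)
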