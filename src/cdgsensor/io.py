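"""CSV/YAML ingestion and export for the table dialects used by the analyses.

Dose-response tables: ``conc_M, channel, replicate, signal``.
Kinetic traces: ``time_min, signal, label, ligand_conc_M``.
ITC thermograms: ``injection_index, volume_ul, heat_kcal_per_mol`` (or a
``heat_ucal`` column converted through the protocol); protocol as YAML.
Assay plates: long ``well, role, time_s, signal`` plus a metadata YAML.
Cell tracks: ``cell_id, parent_id, frame, time_min, length_um, fitc_mean``.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .assay import AssayPlate, ProgressionCurve
from .errors import InvalidParameterError
from .itc import ITCProtocol, ITCThermogram
from .kinetics import KineticTrace
from .lineage import tracks_from_table


def read_dose_response(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"conc_M", "channel", "signal"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"{path}: expected columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


def read_kinetic_traces(path) -> list:
    """One KineticTrace per distinct ``label``."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        df["label"] = "trace"
    traces = []
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("time_min")
        conc = None
        if "ligand_conc_M" in grp.columns and grp["ligand_conc_M"].notna().any():
            conc = float(grp["ligand_conc_M"].iloc[0])
        traces.append(KineticTrace(
            grp["time_min"].to_numpy(), grp["signal"].to_numpy(),
            label=str(label), ligand_conc=conc,
        ))
    return traces


def read_itc_protocol(path) -> ITCProtocol:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return ITCProtocol(
        injection_volumes=tuple(spec["injection_volumes_ul"]),
        syringe_ligand_conc=float(spec["syringe_ligand_conc_M"]),
        cell_protein_conc=float(spec["cell_protein_conc_M"]),
        cell_volume=float(spec.get("cell_volume_ul", 200.0)),
        temperature=float(spec.get("temperature_C", 30.0)),
    )


def write_itc_protocol(protocol: ITCProtocol, path):
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "injection_volumes_ul": list(protocol.injection_volumes),
                "syringe_ligand_conc_M": protocol.syringe_ligand_conc,
                "cell_protein_conc_M": protocol.cell_protein_conc,
                "cell_volume_ul": protocol.cell_volume,
                "temperature_C": protocol.temperature,
            },
            fh,
        )


def read_itc_thermogram(path, protocol: ITCProtocol | None = None) -> ITCThermogram:
    """Read per-injection heats; a ``heat_ucal`` column is converted to
    kcal per mole of injectant using the protocol."""
    df = pd.read_csv(path).sort_values("injection_index")
    if "heat_kcal_per_mol" in df.columns:
        return ITCThermogram(df["heat_kcal_per_mol"].to_numpy())
    if "heat_ucal" not in df.columns:
        raise InvalidParameterError(f"{path}: need heat_kcal_per_mol or heat_ucal")
    if protocol is None:
        raise InvalidParameterError("raw-µcal thermogram needs a protocol for conversion")
    vols = np.asarray(protocol.injection_volumes) * 1e-6  # L
    moles = vols * protocol.syringe_ligand_conc
    return ITCThermogram(df["heat_ucal"].to_numpy() * 1e-9 / moles)


def write_itc_thermogram(thermogram: ITCThermogram, path):
    pd.DataFrame({
        "injection_index": np.arange(1, len(thermogram) + 1),
        "heat_kcal_per_mol": thermogram.heats,
    }).to_csv(path, index=False)


def read_assay_plate(plate_csv, meta_yaml=None) -> AssayPlate:
    df = pd.read_csv(plate_csv)
    wells, roles = {}, {}
    for wid, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_s")
        wells[str(wid)] = ProgressionCurve(
            grp["time_s"].to_numpy(), grp["signal"].to_numpy()
        )
        roles[str(wid)] = grp["role"].iloc[0]
    meta = {}
    if meta_yaml is not None:
        with open(meta_yaml) as fh:
            meta = yaml.safe_load(fh) or {}
    return AssayPlate(wells=wells, roles=roles, metadata=meta)


def write_assay_plate(plate: AssayPlate, path):
    rows = []
    for wid, curve in plate.wells.items():
        rows.append(pd.DataFrame({
            "well": wid,
            "role": plate.roles[wid],
            "time_s": curve.time,
            "signal": curve.signal,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_tracks(path, species_profile: str = "caulobacter") -> list:
    return tracks_from_table(pd.read_csv(path), species_profile=species_profile)


def write_tracks(tracks: list, path):
    rows = []
    for t in tracks:
        d = t.data.copy()
        d.insert(0, "cell_id", t.cell_id)
        d.insert(1, "parent_id", t.parent_id if t.parent_id is not None else "")
        rows.append(d)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_fit_json(fit, path):
    """Serialize a FitResult-like object (params/ci95/derived) to JSON."""
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list, np.ndarray)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    payload = {
        "model_name": getattr(fit, "model_name", None),
        "params": clean(getattr(fit, "params", {})),
        "ci95": clean(getattr(fit, "ci95", {})),
        "derived": clean(getattr(fit, "derived", {})),
        "residual_sd": clean(getattr(fit, "residual_sd", None)),
        "n_obs": getattr(fit, "n_obs", None),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
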