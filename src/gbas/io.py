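"""CSV readers/writers for the package's tabular interfaces.

All formats are plain UTF-8 CSV with a header row:

* assay traces      — ``time_s, absorbance, replicate_id, condition_id``
* amperogram        — ``time_s, current_uA`` plus a sidecar event table
  ``time_s, delta_glucose_mM, species, concentration_M, vehicle_dmso``
* dual measurements — ``sample_id, electrode_id, mean_uA, sd_uA, n,
  glucose_mM_est`` (electrode ids ``gdh5e`` / ``gdh_wt``)
* screen table      — see :data:`gbas.screening.SCREEN_COLUMNS`
* SS annotation     — ``residue, ss_class, interface``
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .amperometry import Amperogram, ElectrodeSpec, InjectionEvent
from .decoder import DualMeasurement, GroupStats
from .errors import InvalidInputError, MissingDataError
from .kinetics import AssayTrace, LigandDose
from .screening import SCREEN_COLUMNS, SS_CLASSES

__all__ = [
    "write_assay_traces", "read_assay_traces",
    "write_amperogram", "read_amperogram",
    "write_dual_measurements", "read_dual_measurements",
    "read_screen_table", "read_ss_annotation",
]


def write_assay_traces(path: str | Path, traces: Sequence[tuple[str, AssayTrace]]) -> None:
    """Write labelled assay traces; ``traces`` is (condition_id, trace) pairs."""
    frames = [
        pd.DataFrame({
            "time_s": tr.times_s,
            "absorbance": tr.absorbance_600,
            "replicate_id": tr.replicate_id,
            "condition_id": cond,
        })
        for cond, tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_assay_traces(path: str | Path) -> pd.DataFrame:
    """Read an assay-trace CSV, validating columns and time ordering."""
    df = pd.read_csv(path)
    required = {"time_s", "absorbance", "replicate_id", "condition_id"}
    if not required.issubset(df.columns):
        raise MissingDataError(f"assay trace CSV must have columns {sorted(required)}")
    for (_, _), grp in df.groupby(["condition_id", "replicate_id"]):
        if not np.all(np.diff(grp["time_s"].to_numpy()) > 0):
            raise InvalidInputError("trace times must be strictly increasing")
    return df


def write_amperogram(trace_path: str | Path, events_path: str | Path, amp: Amperogram) -> None:
    pd.DataFrame({"time_s": amp.times_s, "current_uA": amp.current_uA}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(
        [
            {
                "time_s": e.time_s,
                "delta_glucose_mM": e.delta_glucose_mM,
                "species": e.dose.species,
                "concentration_M": e.dose.concentration_M,
                "vehicle_dmso": e.dose.vehicle_dmso,
            }
            for e in amp.events
        ]
    ).to_csv(events_path, index=False)


def read_amperogram(
    trace_path: str | Path,
    events_path: str | Path,
    electrode: ElectrodeSpec | None = None,
) -> Amperogram:
    tr = pd.read_csv(trace_path)
    ev = pd.read_csv(events_path)
    if not {"time_s", "current_uA"}.issubset(tr.columns):
        raise MissingDataError("amperogram CSV needs time_s and current_uA columns")
    events = tuple(
        InjectionEvent(
            float(row.time_s),
            float(row.delta_glucose_mM),
            LigandDose(str(row.species), float(row.concentration_M),
                       float(getattr(row, "vehicle_dmso", 0.0))),
        )
        for row in ev.itertuples()
    )
    return Amperogram(
        tr["time_s"].to_numpy(), tr["current_uA"].to_numpy(),
        events, electrode or ElectrodeSpec(),
    )


def write_dual_measurements(
    path: str | Path, measurements: Sequence[tuple[str, DualMeasurement]]
) -> None:
    """Write (sample_id, measurement) pairs, two rows per sample."""
    rows = []
    for sid, m in measurements:
        for eid, g in (("gdh5e", m.i_5e), ("gdh_wt", m.i_wt)):
            rows.append({
                "sample_id": sid, "electrode_id": eid,
                "mean_uA": g.mean, "sd_uA": g.sd, "n": g.n,
                "glucose_mM_est": m.glucose_mM_est,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dual_measurements(path: str | Path) -> list[tuple[str, DualMeasurement]]:
    df = pd.read_csv(path)
    required = {"sample_id", "electrode_id", "mean_uA", "sd_uA", "n"}
    if not required.issubset(df.columns):
        raise MissingDataError(f"dual-measurement CSV must have columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        by_id = grp.set_index("electrode_id")
        try:
            r5 = by_id.loc["gdh5e"]
            rw = by_id.loc["gdh_wt"]
        except KeyError as exc:
            raise MissingDataError(
                f"sample {sid!r} needs both 'gdh5e' and 'gdh_wt' rows"
            ) from exc
        est = r5.get("glucose_mM_est")
        est = None if est is None or pd.isna(est) else float(est)
        out.append((
            str(sid),
            DualMeasurement(
                GroupStats(float(r5["mean_uA"]), float(r5["sd_uA"]), int(r5["n"])),
                GroupStats(float(rw["mean_uA"]), float(rw["sd_uA"]), int(rw["n"])),
                est,
            ),
        ))
    return out


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise MissingDataError(f"screen table lacks columns: {missing}")
    return df


def read_ss_annotation(path: str | Path, n_positions: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"residue", "ss_class"}.issubset(df.columns):
        raise MissingDataError("SS annotation needs residue and ss_class columns")
    bad = set(df["ss_class"].unique()) - set(SS_CLASSES)
    if bad:
        raise InvalidInputError(f"unknown secondary-structure classes: {sorted(bad)}")
    if n_positions is not None and set(df["residue"]) != set(range(1, n_positions + 1)):
        raise InvalidInputError(f"annotation must cover residues 1..{n_positions}")
    return df
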