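"""YAML run-configuration serialization.

A run config is a YAML mapping with an ``enzymes:`` section holding one
:class:`~gbas.kinetics.EnzymeParams` record per name, plus free-form
sections (``electrode``, ``fuel_cell``, ``oect``, ``simulation``) that map
directly onto the corresponding dataclass constructors.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .amperometry import ElectrodeSpec
from .efc_oect import FuelCellSpec, OectSpec
from .errors import ConfigError
from .kinetics import EnzymeParams

__all__ = [
    "enzyme_to_dict", "enzyme_from_dict",
    "save_run_config", "load_run_config",
]


def enzyme_to_dict(e: EnzymeParams) -> dict[str, Any]:
    d = asdict(e)
    d["ligand_range_M"] = list(e.ligand_range_M)
    d["selectivity"] = dict(e.selectivity)
    return d


def enzyme_from_dict(d: Mapping[str, Any]) -> EnzymeParams:
    d = dict(d)
    if "ligand_range_M" in d:
        d["ligand_range_M"] = tuple(float(x) for x in d["ligand_range_M"])
    try:
        return EnzymeParams(**d)
    except TypeError as exc:
        raise ConfigError(f"bad enzyme record: {exc}") from exc


def save_run_config(
    path: str | Path,
    enzymes: Mapping[str, EnzymeParams],
    electrode: ElectrodeSpec | None = None,
    fuel_cell: FuelCellSpec | None = None,
    oect: OectSpec | None = None,
    extra: Mapping[str, Any] | None = None,
) -> None:
    doc: dict[str, Any] = {
        "enzymes": {name: enzyme_to_dict(e) for name, e in enzymes.items()}
    }
    if electrode is not None:
        doc["electrode"] = asdict(electrode)
    if fuel_cell is not None:
        doc["fuel_cell"] = asdict(fuel_cell)
    if oect is not None:
        doc["oect"] = asdict(oect)
    if extra:
        doc.update(dict(extra))
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_run_config(path: str | Path) -> dict[str, Any]:
    """Parse a run config; dataclass sections are instantiated, the rest kept."""
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    if not isinstance(doc, dict) or "enzymes" not in doc:
        raise ConfigError("run config must be a mapping with an 'enzymes' section")
    out: dict[str, Any] = dict(doc)
    out["enzymes"] = {
        name: enzyme_from_dict(rec) for name, rec in doc["enzymes"].items()
    }
    for key, cls in (("electrode", ElectrodeSpec), ("fuel_cell", FuelCellSpec),
                     ("oect", OectSpec)):
        if key in doc:
            try:
                out[key] = cls(**doc[key])
            except TypeError as exc:
                raise ConfigError(f"bad {key} section: {exc}") from exc
    return out
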