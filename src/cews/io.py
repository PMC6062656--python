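"""File formats: observation/admission/event CSVs and YAML configs.

Observation CSV header (empty cell = missing)::

    admission_id,timestamp,heart_rate,respiratory_rate,systolic_bp,
    diastolic_bp,temperature,spo2,avpu,on_oxygen,imputed

Timestamps are ISO-8601, timezone-naive local ward time.  ``imputed`` is a
semicolon-joined list of variable names filled by imputation.  Scoring
systems and centile specs are human-editable YAML; write -> read round-trips
are lossless.
"""

from __future__ import annotations

import csv
import math
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .derivation import CentileSpec
from .model import (
    AVPU_LEVELS,
    BandTableError,
    EWSDefinition,
    ObservationSet,
    ScoreBand,
    VariableBandTable,
)
from .outcomes import ClinicalEvent

OBSERVATION_COLUMNS = ("admission_id", "timestamp", "heart_rate",
                       "respiratory_rate", "systolic_bp", "diastolic_bp",
                       "temperature", "spo2", "avpu", "on_oxygen", "imputed")
ADMISSION_COLUMNS = ("admission_id", "age", "specialty", "admit_time",
                     "discharge_time", "discharged_alive")
EVENT_COLUMNS = ("admission_id", "event_type", "timestamp")

BUILTIN_DEFINITIONS = ("ccews", "mcews", "mcews_o2", "news")

_NUMERIC_FIELDS = ("heart_rate", "respiratory_rate", "systolic_bp",
                   "diastolic_bp", "temperature", "spo2")


def _parse_float(text: str, column: str) -> float | None:
    if text == "":
        return None
    value = float(text)
    if not math.isfinite(value):
        raise ValueError(f"{column}: non-finite value")
    return value


def _parse_bool(text: str, column: str) -> bool | None:
    if text == "":
        return None
    lowered = text.strip().lower()
    if lowered in ("true", "1", "yes"):
        return True
    if lowered in ("false", "0", "no"):
        return False
    raise ValueError(f"{column}: cannot parse boolean {text!r}")


def read_observations(path) -> tuple[list[ObservationSet], list[dict]]:
    """Parse an observations CSV; malformed rows are reported, not dropped
    silently.  Returns (observations, error report rows)."""
    observations: list[ObservationSet] = []
    errors: list[dict] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        missing = [c for c in OBSERVATION_COLUMNS if c != "imputed"
                   and c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"observations CSV missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                kwargs = {"admission_id": row["admission_id"],
                          "timestamp": datetime.fromisoformat(row["timestamp"])}
                for col in _NUMERIC_FIELDS:
                    kwargs[col] = _parse_float(row[col].strip(), col)
                avpu = row["avpu"].strip()
                kwargs["avpu"] = avpu or None
                kwargs["on_oxygen"] = _parse_bool(row["on_oxygen"], "on_oxygen")
                imputed = row.get("imputed", "") or ""
                kwargs["imputed_flags"] = frozenset(
                    f for f in imputed.split(";") if f)
                observations.append(ObservationSet(**kwargs))
            except (ValueError, KeyError) as exc:
                errors.append({"line": i, "error": str(exc), "raw": dict(row)})
    return observations, errors


def write_observations(observations: Iterable[ObservationSet], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(OBSERVATION_COLUMNS)
        for obs in observations:
            row = [obs.admission_id, obs.timestamp.isoformat()]
            for col in _NUMERIC_FIELDS:
                value = getattr(obs, col)
                row.append("" if value is None else repr(float(value)))
            row.append(obs.avpu or "")
            row.append("" if obs.on_oxygen is None else str(obs.on_oxygen).lower())
            row.append(";".join(sorted(obs.imputed_flags)))
            writer.writerow(row)


def observations_to_frame(observations: Sequence[ObservationSet]) -> pd.DataFrame:
    records = []
    for obs in observations:
        records.append({
            "admission_id": obs.admission_id, "timestamp": obs.timestamp,
            **{col: getattr(obs, col) for col in _NUMERIC_FIELDS},
            "avpu": obs.avpu, "on_oxygen": obs.on_oxygen,
            "imputed": ";".join(sorted(obs.imputed_flags))})
    return pd.DataFrame(records, columns=list(OBSERVATION_COLUMNS))


def frame_to_observations(frame: pd.DataFrame) -> list[ObservationSet]:
    observations = []
    for row in frame.itertuples(index=False):
        kwargs = {"admission_id": str(row.admission_id),
                  "timestamp": pd.Timestamp(row.timestamp).to_pydatetime()}
        for col in _NUMERIC_FIELDS:
            value = getattr(row, col)
            kwargs[col] = None if pd.isna(value) else float(value)
        avpu = getattr(row, "avpu", None)
        kwargs["avpu"] = None if (avpu is None or pd.isna(avpu) or avpu == "") else str(avpu)
        oxy = getattr(row, "on_oxygen", None)
        kwargs["on_oxygen"] = None if (oxy is None or pd.isna(oxy)) else bool(oxy)
        imputed = getattr(row, "imputed", "")
        if imputed is None or pd.isna(imputed):
            imputed = ""
        kwargs["imputed_flags"] = frozenset(f for f in str(imputed).split(";") if f)
        observations.append(ObservationSet(**kwargs))
    return observations


def read_admissions(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ADMISSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"admissions CSV missing columns {missing}")
    frame["admit_time"] = pd.to_datetime(frame["admit_time"])
    frame["discharge_time"] = pd.to_datetime(frame["discharge_time"])
    if frame["discharged_alive"].dtype == object:
        frame["discharged_alive"] = frame["discharged_alive"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes"))
    return frame


def write_admissions(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    for col in ("admit_time", "discharge_time"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_events(path) -> list[ClinicalEvent]:
    frame = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"events CSV missing columns {missing}")
    return [ClinicalEvent(admission_id=str(r.admission_id),
                          event_type=str(r.event_type),
                          timestamp=pd.Timestamp(r.timestamp).to_pydatetime())
            for r in frame.itertuples(index=False)]


def write_events(events, path) -> None:
    if isinstance(events, pd.DataFrame):
        out = events.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False, columns=list(EVENT_COLUMNS))
        return
    frame = pd.DataFrame([{"admission_id": e.admission_id,
                           "event_type": e.event_type,
                           "timestamp": e.timestamp.isoformat()}
                          for e in events], columns=list(EVENT_COLUMNS))
    frame.to_csv(path, index=False)


# --- scoring-system configs -------------------------------------------------

def definition_to_dict(definition: EWSDefinition) -> dict:
    doc: dict = {"name": definition.name}
    if definition.provenance:
        doc["provenance"] = definition.provenance
    doc["oxygen_increment"] = int(definition.oxygen_increment)
    doc["avpu_map"] = {k: int(v) for k, v in definition.avpu_map.items()}
    variables: dict = {}
    for var, table in definition.tables.items():
        entry: dict = {"resolution": float(table.resolution)}
        if table.admissible_min is not None or table.admissible_max is not None:
            adm = {}
            if table.admissible_min is not None:
                adm["min"] = float(table.admissible_min)
            if table.admissible_max is not None:
                adm["max"] = float(table.admissible_max)
            entry["admissible"] = adm
        bands = []
        for band in table.bands:
            item: dict = {"score": int(band.score)}
            if band.lower != -math.inf:
                item["lower"] = float(band.lower)
            if band.upper != math.inf:
                item["upper"] = float(band.upper)
            bands.append(item)
        entry["bands"] = bands
        variables[var] = entry
    doc["variables"] = variables
    return doc


def definition_from_dict(doc: dict) -> EWSDefinition:
    tables: dict[str, VariableBandTable] = {}
    for var, entry in doc["variables"].items():
        admissible = entry.get("admissible", {}) or {}
        bands = tuple(ScoreBand(score=int(b["score"]),
                                lower=float(b.get("lower", -math.inf)),
                                upper=float(b.get("upper", math.inf)))
                      for b in entry["bands"])
        try:
            tables[var] = VariableBandTable(
                variable=var, bands=bands,
                resolution=float(entry.get("resolution", 1.0)),
                admissible_min=admissible.get("min"),
                admissible_max=admissible.get("max"))
        except BandTableError as exc:
            raise BandTableError(f"invalid band table for {var}: {exc}") from exc
    return EWSDefinition(name=str(doc["name"]), tables=tables,
                         avpu_map={str(k): int(v)
                                   for k, v in doc["avpu_map"].items()},
                         oxygen_increment=int(doc.get("oxygen_increment", 0)),
                         provenance=str(doc.get("provenance", "")))


def read_ews_definition(path) -> EWSDefinition:
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    return definition_from_dict(doc)


def write_ews_definition(definition: EWSDefinition, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(definition_to_dict(definition), handle,
                       sort_keys=False, default_flow_style=False)


def builtin_definition(name: str) -> EWSDefinition:
    """Load one of the shipped systems: ccews, mcews, mcews_o2, news."""
    if name not in BUILTIN_DEFINITIONS:
        raise ValueError(f"unknown builtin {name!r}; "
                         f"available: {BUILTIN_DEFINITIONS}")
    text = resources.files("cews.configs").joinpath(f"{name}.yaml").read_text()
    return definition_from_dict(yaml.safe_load(text))


def resolve_definition(name_or_path: str) -> EWSDefinition:
    """Builtin name if it matches, otherwise a YAML path."""
    if name_or_path in BUILTIN_DEFINITIONS:
        return builtin_definition(name_or_path)
    return read_ews_definition(name_or_path)


# --- centile-spec configs ---------------------------------------------------

def centile_specs_from_dict(doc: dict) -> list[CentileSpec]:
    specs = []
    for var, entry in doc["specs"].items():
        admissible = entry.get("admissible", {}) or {}
        upper = entry.get("upper")
        specs.append(CentileSpec(
            variable=var,
            lower={float(p): int(s) for p, s in entry["lower"].items()},
            upper=None if upper is None
            else {float(p): int(s) for p, s in upper.items()},
            rounding_resolution=float(entry.get("resolution", 1.0)),
            admissible_min=admissible.get("min"),
            admissible_max=admissible.get("max")))
    return specs


def read_centile_specs(path) -> list[CentileSpec]:
    with open(path) as handle:
        return centile_specs_from_dict(yaml.safe_load(handle))


def write_centile_specs(specs: Sequence[CentileSpec], path) -> None:
    doc: dict = {"specs": {}}
    for spec in specs:
        entry: dict = {"resolution": float(spec.rounding_resolution),
                       "lower": {float(p): int(s) for p, s in spec.lower.items()}}
        if spec.upper is not None:
            entry["upper"] = {float(p): int(s) for p, s in spec.upper.items()}
        adm = {}
        if spec.admissible_min is not None:
            adm["min"] = float(spec.admissible_min)
        if spec.admissible_max is not None:
            adm["max"] = float(spec.admissible_max)
        if adm:
            entry["admissible"] = adm
        doc["specs"][spec.variable] = entry
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)
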