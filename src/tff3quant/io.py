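"""Cohort table I/O, report writing, and run configuration.

Cohort files are plain CSV (UTF-8, comma-separated, ``.`` decimal, empty
field = missing) with a version line ``# tff3quant-cohort v1`` above the
header so future schema changes stay detectable.  Reading never drops
rows: records with missing Prague lengths or gland counts are *flagged*,
and each analysis stage applies its own exclusion rule, so the file on
disk remains a faithful record of the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .relevance import CVResult, PatientRecord
from .synthetic import CohortSimParams, CountModel, GastricModel, GlandClassModel, GlandModel, LengthModel
from .tiling import TilingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "write_report",
    "load_config",
]

SCHEMA_VERSION = 1
_VERSION_LINE = f"# tff3quant-cohort v{SCHEMA_VERSION}"

COHORT_COLUMNS = [
    "patient_id",
    "cohort",
    "C_cm",
    "M_cm",
    "tile_count",
    "gastric_tile_count",
    "gland_count_slide2",
    "gland_count_slide15",
    "qc_pass",
]

MISSING_LENGTH = "missing_length"
MISSING_GLAND = "missing_gland_count"


@dataclass
class CohortTable:
    """Ordered patient records plus per-record missing-data flags."""

    records: list[PatientRecord]
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def flagged(self, flag: str) -> list[PatientRecord]:
        return [r for r in self.records if flag in self.flags.get(r.patient_id, [])]


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "cohort": r.cohort,
                "C_cm": r.C_cm,
                "M_cm": r.M_cm,
                "tile_count": r.tile_count,
                "gastric_tile_count": r.gastric_tile_count,
                "gland_count_slide2": r.gland_count_slide2,
                "gland_count_slide15": r.gland_count_slide15,
                "qc_pass": r.qc_pass,
            }
        )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(_VERSION_LINE + "\n")
        df.to_csv(fh, index=False)


def _parse_optional_float(value, what: str, line_no: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"line {line_no}: cannot parse {what}={value!r} as a number") from None
    if out < 0:
        raise ValueError(f"line {line_no}: {what} must be non-negative, got {out}")
    return out


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV into typed records.

    Rows with missing C/M are flagged ``missing_length`` (class label left
    undetermined); rows missing either gland count are flagged
    ``missing_gland_count``.  Duplicate patient ids and malformed rows are
    errors naming the id / line number.
    """
    path = Path(path)
    with open(path) as fh:
        version_line = fh.readline().strip()
        if version_line != _VERSION_LINE:
            raise ValueError(
                f"{path}: unrecognised cohort header {version_line!r}; expected {_VERSION_LINE!r}"
            )
        df = pd.read_csv(fh, dtype={"patient_id": str})
    missing_cols = set(COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")

    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate patient_id {dup.iloc[0]!r}")

    records: list[PatientRecord] = []
    flags: dict[str, list[str]] = {}
    for i, row in df.iterrows():
        line_no = i + 3  # 1 version line + 1 header line, rows are 1-based
        rec_flags: list[str] = []
        C = _parse_optional_float(row["C_cm"], "C_cm", line_no)
        M = _parse_optional_float(row["M_cm"], "M_cm", line_no)
        if C is None or M is None:
            rec_flags.append(MISSING_LENGTH)
            C = M = None
        g2 = _parse_optional_float(row["gland_count_slide2"], "gland_count_slide2", line_no)
        g15 = _parse_optional_float(row["gland_count_slide15"], "gland_count_slide15", line_no)
        if g2 is None or g15 is None:
            rec_flags.append(MISSING_GLAND)
        try:
            tile_count = int(row["tile_count"])
            gastric = int(row["gastric_tile_count"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {line_no}: tile counts must be integers") from None
        qc_raw = row["qc_pass"]
        qc = None if pd.isna(qc_raw) else str(qc_raw).strip().lower() in ("true", "1", "yes")
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            cohort=str(row["cohort"]),
            C_cm=C,
            M_cm=M,
            tile_count=tile_count,
            gastric_tile_count=gastric,
            gland_count_slide2=None if g2 is None else int(g2),
            gland_count_slide15=None if g15 is None else int(g15),
            qc_pass=qc,
        )
        records.append(rec)
        if rec_flags:
            flags[rec.patient_id] = rec_flags
    return CohortTable(records, flags)


# ---------------------------------------------------------------------------
# Reports


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(results, path, format: str = "csv", precision: int = 2) -> None:
    """Write a stage result as CSV or JSON with the report rounding rules.

    Accepts a :class:`CVResult` (rendered as fold rows plus Mean and SD
    rows), a DataFrame, a dict, or a list of dicts.  Metrics are rounded
    to ``precision`` decimals; tile thresholds to one decimal.  An empty
    result is an error — never an empty file.
    """
    if isinstance(results, CVResult):
        rows = results.as_table()
        for row in rows:
            for k, v in row.items():
                if k == "tile_threshold":
                    row[k] = round(v, 1) if row.get("fold") != "sd" else round(v, 2)
                elif isinstance(v, float):
                    row[k] = round(v, precision)
        payload = rows
    elif isinstance(results, pd.DataFrame):
        if results.empty:
            raise ValueError("refusing to write an empty report")
        payload = _round_floats(results.to_dict(orient="records"), precision)
    elif dataclasses.is_dataclass(results) and not isinstance(results, type):
        payload = _round_floats(dataclasses.asdict(results), precision)
    elif isinstance(results, dict):
        payload = _round_floats(results, precision)
    elif isinstance(results, list):
        payload = _round_floats(results, precision)
    else:
        raise TypeError(f"cannot serialise report of type {type(results).__name__}")
    if not payload:
        raise ValueError("refusing to write an empty report")

    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif format == "csv":
        df = pd.DataFrame(payload if isinstance(payload, list) else [payload])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}; use 'csv' or 'json'")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Validated bundle of stage options loaded from YAML/JSON."""

    tiling: TilingConfig = field(default_factory=TilingConfig)
    simulation: CohortSimParams = field(default_factory=CohortSimParams)
    feature_transform: str = "log1p"
    folds: int = 5
    seed: int = 0
    report_precision: int = 2

    def __post_init__(self) -> None:
        if self.feature_transform not in ("log1p", "identity"):
            raise ValueError(f"unknown feature_transform {self.feature_transform!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


_SIM_SUBMODELS = {
    "length_model": LengthModel,
    "count_model": CountModel,
    "gastric_model": GastricModel,
}


def _build(cls, data: dict, what: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a :class:`RunConfig` from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"tiling", "simulation", "feature_transform", "folds", "seed", "report_precision"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")

    tiling = _build(TilingConfig, raw.get("tiling", {}), "tiling")

    sim_raw = dict(raw.get("simulation", {}))
    for key, cls in _SIM_SUBMODELS.items():
        if key in sim_raw:
            sim_raw[key] = _build(cls, sim_raw[key], key)
    if "gland_model" in sim_raw:
        gm = sim_raw["gland_model"]
        sim_raw["gland_model"] = GlandModel(
            relevant=_build(GlandClassModel, gm.get("relevant", {}), "gland_model.relevant"),
            focal=_build(GlandClassModel, gm.get("focal", {}), "gland_model.focal"),
        )
    simulation = _build(CohortSimParams, sim_raw, "simulation")

    cfg = RunConfig(
        tiling=tiling,
        simulation=simulation,
        feature_transform=raw.get("feature_transform", "log1p"),
        folds=int(raw.get("folds", 5)),
        seed=int(raw.get("seed", 0)),
        report_precision=int(raw.get("report_precision", 2)),
    )
    logger.info("effective config: %s", cfg)
    return cfg
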