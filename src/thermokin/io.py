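"""Schema-validated CSV I/O, report rendering and run logging.

One flat CSV dialect is canonical throughout: UTF-8, comma separator, header
row, ``.`` decimal. Four input schemas are supported:

========== =====================================================================
schema      columns
========== =====================================================================
decay       temperature_c, time_min, value, replicate
assay       sample_id, replicate, a520_ph1, a700_ph1, a520_ph45, a700_ph45,
            dilution_factor, final_volume_ml, dry_mass_mg
trolox      concentration_mmol, response
digestion   pretreatment, phase, time_min, tac_value, dpph_value
========== =====================================================================

Validation errors carry 1-based file line numbers (header is line 1). The
thermal summary report renders to CSV (row table with a single ``#``-prefixed
JSON footer line holding the Ea/z block) or to JSON; both renderings contain
identical, pre-rounded values and round-trip byte-identically through
:func:`read_report`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .digestion import DigestionCourse
from .errors import EmptyInputError, ParameterError, ValidationError
from .kinetics import DecaySeries, ThermalSummary
from .quantification import AbsorbanceQuadruple, PhDifferentialParams

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "validate_and_load",
    "load_decay_csv",
    "load_assay_csv",
    "load_trolox_csv",
    "load_digestion_csv",
    "report_payload",
    "render_report",
    "read_report",
    "write_run_log",
]

SCHEMAS: dict[str, dict] = {
    "decay": {
        "columns": ["temperature_c", "time_min", "value", "replicate"],
        "numeric": ["temperature_c", "time_min", "value"],
    },
    "assay": {
        "columns": [
            "sample_id", "replicate", "a520_ph1", "a700_ph1", "a520_ph45",
            "a700_ph45", "dilution_factor", "final_volume_ml", "dry_mass_mg",
        ],
        "numeric": [
            "a520_ph1", "a700_ph1", "a520_ph45", "a700_ph45",
            "dilution_factor", "final_volume_ml", "dry_mass_mg",
        ],
    },
    "trolox": {
        "columns": ["concentration_mmol", "response"],
        "numeric": ["concentration_mmol", "response"],
    },
    "digestion": {
        "columns": ["pretreatment", "phase", "time_min", "tac_value", "dpph_value"],
        "numeric": ["time_min", "tac_value", "dpph_value"],
    },
}


def _read_csv(path: Union[str, Path], schema_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file does not exist")
    if schema_name not in SCHEMAS:
        raise ParameterError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    try:
        df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty input file") from None
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    # header is line 1, first data row line 2
    df.index = df.index + 2
    for col in schema["numeric"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0]} "
                f"({df.loc[bad[0], col]!r})"
            )
        df[col] = converted
    return df


def load_decay_csv(path: Union[str, Path]) -> list[DecaySeries]:
    """Load and validate a decay CSV into per-(temperature, replicate) series."""
    df = _read_csv(path, "decay")
    neg = df.index[df["time_min"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative time at line {neg[0]}")
    series = []
    for (temp, rep), group in df.groupby(["temperature_c", "replicate"], sort=True):
        group = group.sort_values("time_min")
        dup = group["time_min"].duplicated()
        if dup.any():
            line = group.index[dup][0]
            raise ValidationError(
                f"{path}: duplicate time point within replicate at line {line}"
            )
        try:
            series.append(
                DecaySeries(
                    temperature=float(temp),
                    times=tuple(group["time_min"]),
                    values=tuple(group["value"]),
                    replicate_id=str(rep),
                )
            )
        except ValidationError as exc:
            raise ValidationError(
                f"{path}: lines {group.index[0]}–{group.index[-1]}: {exc}"
            ) from None
    return series


def load_assay_csv(
    path: Union[str, Path]
) -> list[tuple[str, str, AbsorbanceQuadruple, PhDifferentialParams]]:
    """Load an assay CSV into (sample_id, replicate, quadruple, params) rows."""
    df = _read_csv(path, "assay")
    rows = []
    for line, row in df.iterrows():
        try:
            quad = AbsorbanceQuadruple(
                a520_ph1=row["a520_ph1"], a700_ph1=row["a700_ph1"],
                a520_ph45=row["a520_ph45"], a700_ph45=row["a700_ph45"],
            )
            params = PhDifferentialParams(
                dilution_factor=row["dilution_factor"],
                final_volume=row["final_volume_ml"],
                dry_mass=row["dry_mass_mg"],
            )
        except (ValidationError, ParameterError) as exc:
            raise ValidationError(f"{path}: line {line}: {exc}") from None
        rows.append((str(row["sample_id"]), str(row["replicate"]), quad, params))
    return rows


def load_trolox_csv(path: Union[str, Path]) -> list[tuple[float, float]]:
    df = _read_csv(path, "trolox")
    return list(zip(df["concentration_mmol"], df["response"]))


def load_digestion_csv(path: Union[str, Path]) -> list[DigestionCourse]:
    """Load a digestion CSV into per-(pretreatment, phase) courses."""
    df = _read_csv(path, "digestion")
    courses = []
    for (pre, phase), group in df.groupby(["pretreatment", "phase"], sort=True):
        group = group.sort_values("time_min")
        try:
            courses.append(
                DigestionCourse(
                    pretreatment=str(pre),
                    phase=str(phase),  # type: ignore[arg-type]
                    times=tuple(group["time_min"]),
                    tac_values=tuple(group["tac_value"]),
                    dpph_values=tuple(group["dpph_value"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(
                f"{path}: lines {group.index[0]}–{group.index[-1]}: {exc}"
            ) from None
    return courses


def validate_and_load(path: Union[str, Path], schema_name: str):
    """Dispatch to the typed loader for ``schema_name`` (decay | assay |
    trolox | digestion), with line-numbered diagnostics on failure."""
    loaders = {
        "decay": load_decay_csv,
        "assay": load_assay_csv,
        "trolox": load_trolox_csv,
        "digestion": load_digestion_csv,
    }
    if schema_name not in loaders:
        raise ParameterError(f"unknown schema {schema_name!r}")
    return loaders[schema_name](path)


# ---------------------------------------------------------------------------
# report rendering

_ROW_COLUMNS = [
    "temperature_c", "k_per_min", "k_se", "d_value_min", "half_life_min",
    "significant",
]


def _round(value: Optional[float], digits: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return round(float(value), digits)


def report_payload(summary: ThermalSummary) -> dict:
    """Flatten a :class:`~thermokin.kinetics.ThermalSummary` into the report
    dict: one row per temperature (thermostable temperatures carry null rate
    fields), plus an Ea/z footer with explicit nulls when unavailable.

    Rounding: rate constants to 6 decimals (min⁻¹), times and Ea/z to 2,
    r² to 4 — the precision the reference tables print.
    """
    rows = []
    for r in summary.rows:
        rows.append(
            {
                "temperature_c": _round(r.temperature, 1),
                "k_per_min": _round(r.k, 6),
                "k_se": _round(r.k_se, 6),
                "d_value_min": _round(r.d_value, 2),
                "half_life_min": _round(r.half_life, 2),
                "significant": True,
            }
        )
    for temp in summary.thermostable:
        rows.append(
            {
                "temperature_c": _round(temp, 1),
                "k_per_min": None, "k_se": None,
                "d_value_min": None, "half_life_min": None,
                "significant": False,
            }
        )
    rows.sort(key=lambda r: r["temperature_c"])
    arr, zf = summary.arrhenius, summary.z_fit
    footer = {
        "ea_kj_mol": _round(arr.ea, 2) if arr else None,
        "ea_se": _round(arr.ea_se, 2) if arr else None,
        "ea_r2": _round(arr.r_squared, 4) if arr else None,
        "z_c": _round(zf.z_value, 2) if zf and zf.physical else None,
        "z_se": _round(zf.z_se, 2) if zf and zf.physical else None,
        "z_r2": _round(zf.r_squared, 4) if zf else None,
        "alpha": summary.alpha,
    }
    return {"rows": rows, "footer": footer}


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        # keep integral floats stable as e.g. "120.0"
        return repr(value)
    return repr(value) if isinstance(value, float) else str(value)


def render_report(summary_or_payload, format: str = "csv") -> str:
    """Serialize a thermal summary (or a payload dict from
    :func:`read_report`) to the requested format. CSV and JSON renderings
    contain identical values; render → read → render is byte-identical."""
    if isinstance(summary_or_payload, ThermalSummary):
        payload = report_payload(summary_or_payload)
    else:
        payload = summary_or_payload
    if format == "json":
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if format != "csv":
        raise ParameterError(f"unknown report format {format!r}")
    lines = ["#" + json.dumps(payload["footer"], sort_keys=True)]
    lines.append(",".join(_ROW_COLUMNS))
    for row in payload["rows"]:
        lines.append(",".join(_format_cell(row[c]) for c in _ROW_COLUMNS))
    return "\n".join(lines) + "\n"


def read_report(text_or_path: Union[str, Path]) -> dict:
    """Parse a rendered report (CSV or JSON, text or path) back into the
    payload dict."""
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str)
        and "\n" not in text_or_path
        and Path(text_or_path).exists()
    ):
        text = Path(text_or_path).read_text(encoding="utf-8")
    else:
        text = str(text_or_path)
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValidationError("report CSV must start with a '#' footer line")
    footer = json.loads(lines[0][1:])
    header = lines[1].split(",")
    if header != _ROW_COLUMNS:
        raise ValidationError(f"unexpected report columns: {header}")
    rows = []
    for ln in lines[2:]:
        cells = ln.split(",")
        row: dict = {}
        for col, cell in zip(_ROW_COLUMNS, cells):
            if cell == "":
                row[col] = None
            elif col == "significant":
                row[col] = cell == "true"
            else:
                row[col] = float(cell)
        rows.append(row)
    return {"rows": rows, "footer": footer}


# ---------------------------------------------------------------------------
# run configuration and provenance log

@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_path: Optional[Path] = None
    alpha: float = 0.05
    dilution_correct: bool = False
    out_dir: Path = Path(".")
    seed: Optional[int] = None
    report_format: str = "csv"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ParameterError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.report_format not in ("csv", "json"):
            raise ParameterError(f"report format must be csv or json")
        if self.input_path is not None:
            self.input_path = Path(self.input_path)
            if not self.input_path.exists():
                raise ValidationError(f"input path {self.input_path} does not exist")
        self.out_dir = Path(self.out_dir)


def write_run_log(config: RunConfig, out_dir: Union[str, Path]) -> Path:
    """Write a JSON provenance record (config hash, seed, versions) beside the
    outputs; sufficient to reproduce a run."""
    import numpy
    import scipy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_dict = {
        k: str(v) if isinstance(v, Path) else v
        for k, v in dataclasses.asdict(config).items()
    }
    blob = json.dumps(config_dict, sort_keys=True)
    log = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "thermokin": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
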