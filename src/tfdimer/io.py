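"""File I/O: delimited-text tables, JSON results and run configuration.

Canonical dialect: comma-delimited UTF-8 with one header line; lines
starting with ``#`` are comments.  Concentrations are always µM in files;
times in seconds.  Results are written as flat key–value JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .isotherms import IsothermPoint
from .stopflow import KineticTrace

__all__ = [
    "TableSchema",
    "ISOTHERM_SCHEMA",
    "TRACE_SCHEMA",
    "KOBS_SCHEMA",
    "read_table",
    "write_table",
    "read_isotherm",
    "write_isotherm",
    "read_trace",
    "write_trace",
    "write_json",
    "read_json",
    "RunConfig",
]


@dataclass(frozen=True)
class TableSchema:
    """Column contract for a delimited-text table."""

    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    monotone_increasing: str | None = None  # column that must strictly increase


ISOTHERM_SCHEMA = TableSchema("isotherm", ("conc_uM", "y"), ("sigma",))
TRACE_SCHEMA = TableSchema("trace", ("time_s", "signal"), (), "time_s")
KOBS_SCHEMA = TableSchema("kobs", ("conc_uM", "kobs_per_s"))


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a delimited-text table against a schema.

    Errors name the offending file row (1-based, counting header and
    comment lines) so instrument exports can be fixed by hand.  A
    header-only file returns an empty table with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # Track physical line numbers so errors point at the real file row.
    rows: list[list[str]] = []
    line_nos: list[int] = []
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            cells = [c.strip() for c in text.split(",")]
            if header is None:
                header = cells
            else:
                rows.append(cells)
                line_nos.append(lineno)
    if header is None:
        raise ValueError(f"{path}: no header line found")
    missing = [c for c in schema.required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header={header}")
    if not rows:
        warnings.warn(f"{path}: header-only file, returning empty table", UserWarning)
        return pd.DataFrame(columns=list(header))

    df = pd.DataFrame(rows, columns=header)
    df.index = pd.Index(line_nos, name="file_row")
    keep = [c for c in schema.required + schema.optional if c in df.columns]
    df = df[keep]
    for col in keep:
        numeric = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = numeric.isna() & df[col].replace("", np.nan).notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at file row {row}"
            )
        df[col] = numeric
    if schema.monotone_increasing:
        col = schema.monotone_increasing
        diffs = df[col].diff().iloc[1:]
        bad = diffs <= 0
        if bad.any():
            row = int(df.index[1:][bad.to_numpy()][0])
            raise ValueError(
                f"{path}: column {col!r} must be strictly increasing; "
                f"violation at file row {row}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a table in the canonical comma-delimited dialect."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)


def read_isotherm(path: str | Path) -> list[IsothermPoint]:
    """Load isotherm points from a ``conc_uM,y[,sigma]`` table."""
    df = read_table(path, ISOTHERM_SCHEMA)
    points = []
    for _, row in df.iterrows():
        sigma = row.get("sigma")
        if sigma is not None and pd.isna(sigma):
            sigma = None
        points.append(IsothermPoint(CT=float(row["conc_uM"]), y=float(row["y"]),
                                    sigma=None if sigma is None else float(sigma)))
    return points


def write_isotherm(points: Sequence[IsothermPoint], path: str | Path) -> None:
    data = {"conc_uM": [p.CT for p in points], "y": [p.y for p in points]}
    if any(p.sigma is not None for p in points):
        data["sigma"] = [p.sigma if p.sigma is not None else "" for p in points]
    write_table(pd.DataFrame(data), path)


def read_trace(path: str | Path) -> KineticTrace:
    """Load a stopped-flow trace from a ``time_s,signal`` table.

    Metadata travels in a JSON sidecar ``<path>.meta.json`` when present.
    """
    df = read_table(path, TRACE_SCHEMA)
    meta_path = Path(str(path) + ".meta.json")
    meta = read_json(meta_path) if meta_path.exists() else {}
    return KineticTrace(t=df["time_s"].to_numpy(), signal=df["signal"].to_numpy(),
                        meta=meta)


def write_trace(trace: KineticTrace, path: str | Path) -> None:
    write_table(pd.DataFrame({"time_s": trace.t, "signal": trace.signal}), path)
    if trace.meta:
        write_json(trace.meta, Path(str(path) + ".meta.json"))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


@dataclass
class RunConfig:
    """Validated run configuration for the command-line pipeline."""

    inputs: list[str] = dc_field(default_factory=list)
    output_dir: str = "results"
    seed: int = 0
    Mm_kDa: float = 48.0
    Kd_dim_uM: float = 2.0
    baseline_policy: str = "none"
    coupling: str = "decoupled"
    concentration_axis: str = "particles"  # dimer axis: particles | monomer_equivalent
    verbosity: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON configuration file."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        for p in self.inputs:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
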