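"""Table, image and config I/O with schema validation.

Canonical table dialect is TSV (UTF-8, '.' decimal); CSV is accepted on
read.  All times are hours and all fractions live in [0, 1] internally —
percentage formatting happens only at presentation.  JSON reports carry a
``schema_version`` field.
"""

from __future__ import annotations

import json
import sys
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
import tifffile

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class TableSchema:
    """Column names/dtypes plus row-level checks (each check gets the frame
    and returns a boolean Series of valid rows)."""

    name: str
    columns: dict[str, type]
    row_checks: tuple[tuple[str, Callable[[pd.DataFrame], pd.Series]], ...] = ()


OBS_SCHEMA = TableSchema(
    name="labeling observations",
    columns={"time_h": float, "replicate": int, "n_scored": int,
             "n_edu_pos": int, "n_ph3_pos": int, "n_double_pos": int},
    row_checks=(
        ("0 <= n_edu_pos <= n_scored",
         lambda d: (d.n_edu_pos >= 0) & (d.n_edu_pos <= d.n_scored)),
        ("0 <= n_double_pos <= n_ph3_pos <= n_scored",
         lambda d: (d.n_double_pos >= 0) & (d.n_double_pos <= d.n_ph3_pos)
                   & (d.n_ph3_pos <= d.n_scored)),
        ("time_h >= 0", lambda d: d.time_h >= 0),
        ("n_scored > 0", lambda d: d.n_scored > 0),
    ),
)

FOCI_TABLE_COLUMNS = ("nucleus_id", "x", "y", "sigma", "amplitude")
CALLS_TABLE_COLUMNS = ("nucleus_id", "n_foci", "median_sigma", "call")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a delimited table against ``schema``.

    Errors name the missing column or the offending file line (header is
    line 1, first data row line 2).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows ({schema.name})") from None
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} for {schema.name}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows ({schema.name})")
    for col, dtype in schema.columns.items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as e:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r} "
                             f"at line {line}") from e
    for desc, check in schema.row_checks:
        ok = check(df)
        if not ok.all():
            line = int(df.index[~ok][0]) + 2
            raise ValueError(f"{path}: row at line {line} violates {desc}")
    return df[list(schema.columns)]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the canonical TSV dialect (CSV if the suffix says so)."""
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_json_report(payload: Mapping[str, Any], path: str | Path) -> None:
    out = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonable) + "\n")


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.Series):
        return x.to_dict()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a TOML (or YAML, by extension) run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(path.read_text())
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF or PNG image as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        from imageio.v3 import imread
        img = imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    return img


def write_image(img: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(img))


def log(msg: str) -> None:
    """Human-readable progress/config echo; results never go to stderr."""
    print(msg, file=sys.stderr)
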