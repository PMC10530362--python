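"""File formats: ratio-table CSV schema, fit-result JSON, run manifests.

Ratio tables are UTF-8 comma-separated files with a header row and units
embedded in the column names (voltage_mV, concentration_uM) to prevent
unit drift.  Unknown columns are preserved, never dropped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .fitting import FitResult

__all__ = [
    "RATIO_COLUMNS",
    "SchemaError",
    "read_ratio_table",
    "write_ratio_table",
    "fit_result_to_json",
    "write_fit_result",
    "data_hash",
    "write_manifest",
]

#: Required ratio-table columns; sd, n_cells and cell are optional.
RATIO_COLUMNS = ("compound", "receptor", "illumination",
                 "voltage_mV", "concentration_uM", "ratio")
_NUMERIC = ("voltage_mV", "concentration_uM", "ratio")
_OPTIONAL_NUMERIC = ("sd", "n_cells")


class SchemaError(ValueError):
    """Malformed ratio table (missing columns or bad rows)."""


def read_ratio_table(path) -> pd.DataFrame:
    """Read and validate a ratio-table CSV.

    Checks the required columns, numeric parseability (reporting 1-based
    data row numbers for offenders) and the ratio range (0, 1.2].
    """
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: ratio table is empty")
    missing = [c for c in RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in _NUMERIC + tuple(c for c in _OPTIONAL_NUMERIC if c in df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()] + 1
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col!r} in data row(s) {list(bad[:10])}"
            )
        if parsed.isna().any():
            rows = list((df.index[parsed.isna()] + 1)[:10])
            raise SchemaError(f"{path}: missing {col!r} in data row(s) {rows}")
        df[col] = parsed
    out_of_range = df.index[(df["ratio"] <= 0) | (df["ratio"] > 1.2)] + 1
    if len(out_of_range):
        raise SchemaError(
            f"{path}: ratio outside (0, 1.2] in data row(s) {list(out_of_range[:10])}"
        )
    return df


def write_ratio_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def data_hash(path) -> str:
    """sha256 of a file's bytes, for provenance manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def fit_result_to_json(result: FitResult, input_hash: str | None = None) -> str:
    d = result.to_dict()
    if input_hash is not None:
        d["input_sha256"] = input_hash
    return json.dumps(d, indent=2, default=float)


def write_fit_result(result: FitResult, path, input_hash: str | None = None) -> None:
    Path(path).write_text(fit_result_to_json(result, input_hash))


def write_manifest(outdir, config: dict, seed: int | None,
                   inputs: dict | None = None) -> Path:
    """Self-describing run manifest: config echo, seed, version, input hashes."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "azoblock",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs_sha256": {k: data_hash(v) for k, v in (inputs or {}).items()},
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
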