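"""Readers, writers and run manifests.

CSV is the interchange format for cell tables, licensing histograms and
crypt profiles; JSON/YAML for configurations, fit results and manifests.
Cell-table columns follow the documented schema; extra columns are
preserved, missing required columns are rejected by name.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .licensing import LicensingHistogram

__all__ = [
    "REQUIRED_CELL_COLUMNS",
    "read_cell_table",
    "write_cell_table",
    "read_histogram",
    "write_histogram",
    "write_manifest",
]

#: required columns of a per-cell marker table
REQUIRED_CELL_COLUMNS = (
    "cell_id",
    "dist_to_base_um",
    "dna_content",
    "total_mcm2",
    "bound_mcm2",
    "ki67",
    "edu",
)

_NUMERIC_CELL_COLUMNS = (
    "dist_to_base_um",
    "dna_content",
    "total_mcm2",
    "bound_mcm2",
    "ki67",
    "edu",
    "lgr5",
    "h2b_gfp",
)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell marker table from CSV.

    Raises a schema error naming any missing required column; non-numeric
    intensity values raise an error naming the offending rows (1-based
    data line numbers).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"cell table {path} is missing required column(s): {missing}"
        )
    for col in _NUMERIC_CELL_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # header is line 1
            raise ValueError(
                f"non-numeric values in column {col!r} of {path} "
                f"at line(s) {lines}"
            )
        df[col] = coerced
    if "uea_positive" in df.columns:
        df["uea_positive"] = df["uea_positive"].astype(bool)
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def write_histogram(hist: LicensingHistogram, path: str | Path) -> None:
    """Write a licensing histogram as CSV (bin_center_percent, count, stage)."""
    pd.DataFrame(
        {
            "bin_center_percent": hist.bin_centers,
            "count": hist.counts,
            "stage": hist.stage,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_histogram(path: str | Path) -> LicensingHistogram:
    df = pd.read_csv(path)
    for col in ("bin_center_percent", "count", "stage"):
        if col not in df.columns:
            raise ValueError(f"histogram file {path} is missing column {col!r}")
    stages = df["stage"].unique()
    if len(stages) != 1 or stages[0] not in LicensingHistogram.STAGES:
        raise ValueError(f"unrecognized histogram stage(s) {list(stages)} in {path}")
    return LicensingHistogram(
        bin_centers=df["bin_center_percent"].to_numpy(float),
        counts=df["count"].to_numpy(float),
        stage=str(stages[0]),
    )


def write_manifest(path: str | Path, command: str, parameters: dict, **io_paths) -> dict:
    """Write a JSON run manifest sufficient to re-run a deterministic stage."""
    from . import __version__

    manifest = {
        "tool": "cryptcycle",
        "version": __version__,
        "command": command,
        "parameters": _jsonable(parameters),
        "paths": {k: str(v) for k, v in io_paths.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
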