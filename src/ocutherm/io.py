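"""Deterministic CSV/JSON output with provenance headers.

Every CSV starts with a ``# config_hash=...`` comment so a result file can
be traced back to the exact configuration that produced it; numbers are
serialised at full double precision and re-running the same configuration
reproduces the files byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_table", "write_trace", "write_map", "write_report"]


def _check_finite(df: pd.DataFrame) -> None:
    num = df.select_dtypes(include=[np.number])
    bad = ~np.isfinite(num.to_numpy())
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value at row {num.index[i]}, column {num.columns[j]!r}"
        )


def write_table(df: pd.DataFrame, path, config_hash: str = "") -> dict:
    """Write a DataFrame as CSV with a provenance header; returns a manifest entry."""
    _check_finite(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")
    return {"path": path.name, "rows": int(len(df)), "columns": list(df.columns)}


# aliases matching what the files hold
write_trace = write_table
write_map = write_table


def write_report(report: dict, path) -> None:
    """Write the run report as deterministic, sorted JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
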