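"""Trace and table writers (CSV, JSON, markdown)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dde import SimResult
from .scenarios import ScenarioTable

__all__ = ["write_trace", "read_trace", "write_table", "trace_sidecar"]

_TRACE_COLUMNS = [
    "t",
    "theta",
    "thetadot",
    "torque_weight",
    "torque_stiffness",
    "torque_contraction",
    "cop",
]

# table column order mirrors the strategy-table layout
_TABLE_COLUMNS = [
    ("name", ""),
    ("stiffness_pct_kcrit", "Stiffness (% K_crit)"),
    ("delay_s", "Delay (s)"),
    ("p", "p (N.m/(s^2.rad))"),
    ("d", "d (N.m/(s.rad))"),
    ("peak_com", "Peak CoM"),
    ("peak_cop", "Peak CoP"),
]


def write_trace(result: SimResult, path, fmt: str = "csv") -> Path:
    """Write a simulation trace; CSV keeps >= 10 significant digits."""
    path = Path(path)
    df = pd.DataFrame({c: getattr(result, c) for c in _TRACE_COLUMNS})
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        path.write_text(json.dumps({c: df[c].tolist() for c in _TRACE_COLUMNS}))
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    return path


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def trace_sidecar(result: SimResult, classification: str | None = None) -> dict:
    """JSON-serializable summary of a simulation result."""
    out = {
        "peak_com": result.peak_com,
        "peak_cop": result.peak_cop,
        "overshoot": result.overshoot,
        "n_sign_changes": result.n_sign_changes,
        "diverged": result.diverged,
        "k_frac": result.params.k_frac,
        "tau_delay": result.params.tau_delay,
        "S": result.params.S,
        "gains": {
            "p": result.gains.p,
            "d": result.gains.d,
            "a": result.gains.a,
            "i": result.gains.i,
        },
    }
    if classification is not None:
        out["classification"] = classification
    return out


def _markdown_table(df: pd.DataFrame, ndigits: dict) -> str:
    headers = [h for _, h in _TABLE_COLUMNS]
    lines = ["| " + " | ".join(headers) + " |", "|" + "---|" * len(headers)]
    for _, row in df.iterrows():
        cells = []
        for col, _ in _TABLE_COLUMNS:
            v = row[col]
            if col == "name":
                cells.append(str(v))
            else:
                cells.append(f"{v:.{ndigits.get(col, 2)}f}")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def write_table(table: ScenarioTable, path, fmt: str = "csv") -> Path:
    """Write a strategy table as CSV (full precision), JSON or markdown
    (printed precision: 1 decimal for stiffness %, 2 elsewhere)."""
    path = Path(path)
    df = table.to_dataframe()
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        payload = {
            "title": table.title,
            "rows": df.to_dict(orient="records"),
            "pct_changes": table.pct_changes().to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "markdown":
        nd = {"stiffness_pct_kcrit": 1, "delay_s": 3}
        path.write_text(f"**{table.title}**\n\n" + _markdown_table(df, nd))
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    return path
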