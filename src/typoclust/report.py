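"""Run reporting: machine-readable JSON plus human-readable TSV tables.

One directory per run with fixed file names (qc_table.tsv, merges.tsv,
bic_table.tsv, mori.tsv, codes.csv, report.json), so downstream scripts can
rely on the layout.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RunResults", "run_report"]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class RunResults:
    """Bundle of completed analyses to be written out."""

    config: dict = field(default_factory=dict)
    qc_table: pd.DataFrame | None = None
    merges: pd.DataFrame | None = None
    bic_table: pd.DataFrame | None = None
    icl_table: pd.DataFrame | None = None
    mori_table: pd.DataFrame | None = None
    codes: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def empty(self) -> bool:
        return all(
            t is None
            for t in (
                self.qc_table,
                self.merges,
                self.bic_table,
                self.mori_table,
                self.codes,
            )
        ) and not self.extras


def run_report(results: RunResults, out_dir) -> Path:
    """Write the results bundle; returns the report.json path."""
    if results.empty():
        raise ValueError("no completed analysis to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "config": _jsonable(results.config),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": [],
    }
    tables = {
        "qc_table.tsv": results.qc_table,
        "merges.tsv": results.merges,
        "bic_table.tsv": results.bic_table,
        "icl_table.tsv": results.icl_table,
        "mori.tsv": results.mori_table,
    }
    for name, tab in tables.items():
        if tab is not None:
            tab.to_csv(out / name, sep="\t")
            summary["files"].append(name)
    if results.codes is not None:
        results.codes.to_csv(out / "codes.csv", index=False)
        summary["files"].append("codes.csv")
    summary["extras"] = _jsonable(results.extras)
    path = out / "report.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return path
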