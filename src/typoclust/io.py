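"""Dataset I/O and cluster-code persistence.

Rectangular CSV/TSV tables with a header row are the interchange format;
empty cells (or a configured sentinel) mark missing values.  Cluster code
variables and mixture-model uncertainties are appended to a copy of the
input file as new columns, the conventional way person-oriented analyses
hand partitions to downstream software.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataMatrix, Partition
from .preprocess import LikertItemSet

__all__ = ["read_dataset", "read_table", "append_cluster_codes"]


def _read_frame(path, sentinel=None) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    na = ["", "NA", "NaN"]
    if sentinel is not None:
        na.append(str(sentinel))
    header = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0].tolist()
    dups = [n for i, n in enumerate(header) if n in header[:i]]
    if dups:
        raise ValueError(f"duplicate column names: {sorted(set(dups))}")
    return pd.read_csv(path, sep=sep, na_values=na, keep_default_na=True)


def read_table(path, sentinel=None) -> pd.DataFrame:
    """Raw table as a DataFrame (delimiter inferred from the extension)."""
    return _read_frame(path, sentinel)


def read_dataset(
    path,
    var_names=None,
    id_column=None,
    sentinel=None,
    item_config: dict | None = None,
):
    """Read a CSV/TSV dataset into a DataMatrix.

    ``var_names`` selects the analysis variables (default: all numeric
    columns).  Non-numeric cells in selected columns are rejected with
    their coordinates.  When ``item_config`` declares item columns
    (``{"lo":..., "hi":..., "scales": {name: [colname, ...]},
    "max_missing": {...}}``) a LikertItemSet is returned alongside.
    """
    df = _read_frame(path, sentinel)
    if id_column is not None:
        df = df.set_index(id_column)
    cols = list(var_names) if var_names else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
    ]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"variables not in file: {missing_cols}")
    sub = df[cols]
    for c in cols:
        coerced = pd.to_numeric(sub[c], errors="coerce")
        bad = coerced.isna() & sub[c].notna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"non-numeric cell at row {row + 1}, column {c!r}: {sub[c].iloc[row]!r}"
            )
        sub = sub.assign(**{c: coerced})
    data = DataMatrix.from_dataframe(sub)
    if item_config is None:
        return data
    scales = {
        name: [df.columns.get_loc(c) for c in cols_]
        for name, cols_ in item_config["scales"].items()
    }
    itemset = LikertItemSet(
        items=df.to_numpy(float),
        lo=item_config["lo"],
        hi=item_config["hi"],
        scale_map=scales,
        max_missing=item_config.get("max_missing", {}),
    )
    return data, itemset


def append_cluster_codes(
    path_in,
    path_out,
    partitions: dict,
    uncertainties: dict | None = None,
    overwrite: bool = False,
    sentinel=None,
) -> Path:
    """Append named cluster-code columns (and optional uncertainty columns).

    ``partitions`` maps new column name -> Partition (or label vector) of
    the same length as the file.  Existing columns are preserved; name
    collisions are rejected unless ``overwrite`` is set.
    """
    path_in, path_out = Path(path_in), Path(path_out)
    df = _read_frame(path_in, sentinel)
    n = len(df)
    for name, part in partitions.items():
        labels = part.labels if isinstance(part, Partition) else np.asarray(part, int)
        if labels.size != n:
            raise ValueError(
                f"partition {name!r} has {labels.size} labels for {n} rows"
            )
        if name in df.columns and not overwrite:
            raise ValueError(f"column {name!r} already exists (pass overwrite=True)")
        df[name] = labels
    for name, u in (uncertainties or {}).items():
        u = np.asarray(u, float)
        if u.size != n:
            raise ValueError(f"uncertainty {name!r} has wrong length")
        if name in df.columns and not overwrite:
            raise ValueError(f"column {name!r} already exists (pass overwrite=True)")
        df[name] = u
    sep = "\t" if path_out.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df.to_csv(path_out, sep=sep, index=False)
    return path_out
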