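"""Localization-table I/O and reduction of raw MINFLUX events.

The reduction has two levels, mirroring how DNA-PAINT MINFLUX data map onto
molecules:

1. ``combine_traces`` -- repeated raw localizations sharing a trace ID (TID)
   come from one continuous binding event of a single imager, so they are
   collapsed to one *site* (a docking-strand location) at their mean position;
2. ``merge_subunits`` -- a marker can be visited repeatedly, producing several
   sites within ~1 nm of each other; DBSCAN with a small epsilon merges these
   into one *subunit* location.

Tables are plain pandas DataFrames.  Localization tables have columns
``tid, x, y, z`` (optionally ``t``); coordinates are nm.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

MANDATORY = ["tid", "x", "y", "z"]


class LocalizationFormatError(ValueError):
    """Raised when a localization file is missing columns or malformed."""


def _validate(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    for col in MANDATORY:
        if col not in df.columns:
            raise LocalizationFormatError(f"{source}: missing mandatory column {col!r}")
    out = df.copy()
    for col in ["x", "y", "z"] + (["t"] if "t" in df.columns else []):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(float, na_value=np.nan)))
        if len(bad):
            raise LocalizationFormatError(
                f"{source}: non-numeric or non-finite {col!r} at row {int(bad[0])}"
            )
        out[col] = vals.astype(float)
    out["tid"] = pd.to_numeric(out["tid"], errors="raise").astype(int)
    if (out["tid"] < 0).any():
        raise LocalizationFormatError(f"{source}: negative trace IDs present")
    return out


def read_localizations(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Read a localization table from CSV, TSV, or a binary .npy array.

    The dialect is inferred from the file extension when not given.  Unknown
    columns are preserved.  Coordinates are asserted to be nm.
    """
    if dialect is None:
        ext = os.path.splitext(path)[1].lower()
        dialect = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".npy": "binary-array"}.get(ext)
        if dialect is None:
            raise LocalizationFormatError(f"cannot infer dialect from extension of {path!r}")
    if dialect == "binary-array":
        arr = np.load(path, allow_pickle=False)
        if arr.dtype.names:  # structured array export
            df = pd.DataFrame({name: arr[name] for name in arr.dtype.names})
        else:
            if arr.ndim != 2 or arr.shape[1] < 4:
                raise LocalizationFormatError(f"{path}: need a (n, >=4) array of tid,x,y,z")
            df = pd.DataFrame(arr[:, :4], columns=MANDATORY)
    elif dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError:
            raise LocalizationFormatError(f"{path}: file is empty") from None
    else:
        raise LocalizationFormatError(f"unknown dialect {dialect!r}")
    if len(df) == 0:
        raise LocalizationFormatError(f"{path}: table has no rows")
    return _validate(df, source=path)


def write_localizations(df: pd.DataFrame, path: str) -> None:
    """Write a localization table: CSV/TSV (header ``tid,x,y,z[,t]``) or .npy."""
    cols = MANDATORY + (["t"] if "t" in df.columns else [])
    ext = os.path.splitext(path)[1].lower()
    if ext == ".npy":
        np.save(path, df[cols].to_numpy(float))
        return
    sep = "\t" if ext in (".tsv", ".txt") else ","
    df[cols].to_csv(path, sep=sep, index=False)


def combine_traces(table: pd.DataFrame, min_locs: int = 1) -> pd.DataFrame:
    """Collapse each trace (TID) to one site at the per-axis mean position.

    Traces with fewer than ``min_locs`` localizations are dropped.  The spread
    columns hold the per-axis sample standard deviation (0 for singletons).
    """
    if len(table) == 0:
        raise ValueError("localization table is empty")
    df = _validate(table)
    g = df.groupby("tid", sort=True)
    agg = g.agg(
        x=("x", "mean"),
        y=("y", "mean"),
        z=("z", "mean"),
        n_locs=("x", "size"),
        spread_x=("x", "std"),
        spread_y=("y", "std"),
        spread_z=("z", "std"),
    )
    agg[["spread_x", "spread_y", "spread_z"]] = agg[["spread_x", "spread_y", "spread_z"]].fillna(0.0)
    agg = agg[agg["n_locs"] >= min_locs]
    out = agg.reset_index()
    out.insert(0, "site_id", np.arange(len(out)))
    out["n_traces"] = 1
    return out[["site_id", "tid", "x", "y", "z", "n_locs", "n_traces", "spread_x", "spread_y", "spread_z"]]


def merge_subunits(sites: pd.DataFrame, eps: float = 1.0, min_pts: int = 1) -> pd.DataFrame:
    """Merge sites that re-appeared from the same marker into subunit locations.

    DBSCAN on the 3D site positions; with ``min_pts=1`` this is exactly the
    connected components of the eps-adjacency graph.  Each component collapses
    to its localization-count-weighted mean.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if len(sites) == 0:
        return pd.DataFrame(columns=["subunit_id", "x", "y", "z", "n_sites_merged", "n_locs_total", "n_traces"])
    pts = sites[["x", "y", "z"]].to_numpy(float)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    w = sites["n_locs"].to_numpy(float) if "n_locs" in sites.columns else np.ones(len(sites))
    n_traces = sites["n_traces"].to_numpy(int) if "n_traces" in sites.columns else np.ones(len(sites), int)

    rows = []
    next_id = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if lab == -1:  # DBSCAN noise (only possible for min_pts > 1): keep as singletons
            groups = [np.array([i]) for i in idx]
        else:
            groups = [idx]
        for grp in groups:
            ww = w[grp]
            pos = np.average(pts[grp], axis=0, weights=ww)
            rows.append(
                (next_id, pos[0], pos[1], pos[2], len(grp), int(ww.sum()), int(n_traces[grp].sum()))
            )
            next_id += 1
    return pd.DataFrame(rows, columns=["subunit_id", "x", "y", "z", "n_sites_merged", "n_locs_total", "n_traces"])


def precision_summary(table: pd.DataFrame) -> np.ndarray:
    """Per-axis median of per-trace standard deviations (nm).

    Only traces with >= 2 localizations contribute; raises if there are none.
    """
    df = _validate(table)
    g = df.groupby("tid")
    sizes = g.size()
    multi = sizes[sizes >= 2].index
    if len(multi) == 0:
        raise ValueError("precision undefined: no trace has >= 2 localizations")
    sds = g[["x", "y", "z"]].std().loc[multi]
    return sds.median(axis=0).to_numpy()


def reduce_localizations(
    table: pd.DataFrame, min_locs: int = 1, eps_merge: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full two-level reduction: raw localizations -> sites -> subunits."""
    sites = combine_traces(table, min_locs=min_locs)
    subunits = merge_subunits(sites, eps=eps_merge, min_pts=1)
    return sites, subunits
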