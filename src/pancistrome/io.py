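"""Plain-text fixture I/O: TSV tables, BED intervals, bedGraph tracks.

Coordinates are 0-based half-open throughout, matching BED/bedGraph.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: table names written as BED rather than TSV
_BED_TABLES = {"genes", "peaks"}


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path) -> None:
    """Write BED3/BED6 depending on the available columns."""
    cols = ["chrom", "start", "end"]
    bed = df[cols].copy()
    if (bed["start"] >= bed["end"]).any():
        raise ValueError("BED intervals require start < end")
    if "strand" in df.columns:
        name_col = next((c for c in df.columns if c.endswith("_id")), None)
        bed["name"] = df[name_col] if name_col else "."
        bed["score"] = 0
        bed["strand"] = df["strand"]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_bedgraph(chrom: str, values: np.ndarray, path) -> None:
    """Run-length-encode a per-base track into bedGraph lines."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        Path(path).write_text("")
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    vals = values[starts]
    keep = vals != 0
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts[keep], "end": ends[keep], "value": vals[keep]}
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path, length: int | None = None) -> tuple[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        return "", np.zeros(length or 0)
    size = length if length is not None else int(df["end"].max())
    values = np.zeros(size)
    for _, row in df.iterrows():
        values[int(row.start) : int(row.end)] = row.value
    return str(df["chrom"].iloc[0]), values


def write_fixtures(tables: Mapping[str, object], out_dir) -> list[Path]:
    """Write a dict of tables/tracks to a directory of text fixtures.

    Tables named ``genes``/``peaks`` become BED files; objects exposing
    ``chrom``/``values`` (coverage tracks) become bedGraph; everything
    else is a TSV with a header row.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in tables.items():
        if hasattr(obj, "values_array") and hasattr(obj, "chrom"):
            path = out / f"{name}.bedgraph"
            write_bedgraph(obj.chrom, obj.values_array, path)
        elif name in _BED_TABLES:
            path = out / f"{name}.bed"
            write_bed(obj, path)
        else:
            path = out / f"{name}.tsv"
            df = obj.reset_index() if isinstance(obj, pd.Series) else obj
            write_tsv(df, path)
        written.append(path)
    return written


def read_fixtures(in_dir) -> dict[str, pd.DataFrame]:
    """Read back every fixture written by :func:`write_fixtures`."""
    out: dict[str, pd.DataFrame] = {}
    for path in sorted(Path(in_dir).iterdir()):
        if path.suffix == ".tsv":
            out[path.stem] = read_tsv(path)
        elif path.suffix == ".bed":
            out[path.stem] = read_bed(path)
    return out
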