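"""Readers and writers for the plain-text formats the pipeline speaks.

BED (3-6 columns, strand honored), BEDPE (6+ columns, anchors canonicalized),
bedGraph tracks, and dense / sparse-triplet contact matrices.  Coordinates
are 0-based half-open throughout; malformed lines are reported with their
line numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapstats import ContactMap

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "write_matrix",
    "read_matrix",
]

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def _validate_intervals(df: pd.DataFrame, start: str, end: str, path) -> None:
    bad = df[end] <= df[start]
    if bad.any():
        lines = ", ".join(str(i + 1) for i in df.index[bad][:5])
        raise ValueError(f"{path}: end <= start at line(s) {lines}")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df.columns = BED_COLS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    _validate_intervals(df, "start", "end", path)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs at least 6 columns")
    names = BEDPE_COLS + [f"extra{k}" for k in range(df.shape[1] - 6)]
    df.columns = names[: df.shape[1]]
    for c in ("start1", "end1", "start2", "end2"):
        df[c] = df[c].astype(int)
    _validate_intervals(df, "start1", "end1", path)
    _validate_intervals(df, "start2", "end2", path)
    # canonical anchor order: anchor1 upstream of anchor2
    swap = df["start2"] < df["start1"]
    if swap.any():
        a = df.loc[swap, ["chrom1", "start1", "end1"]].to_numpy()
        df.loc[swap, ["chrom1", "start1", "end1"]] = df.loc[swap, ["chrom2", "start2", "end2"]].to_numpy()
        df.loc[swap, ["chrom2", "start2", "end2"]] = a
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = BEDPE_COLS + [c for c in df.columns if c not in BEDPE_COLS]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 4:
        raise ValueError(f"{path}: bedGraph needs exactly 4 columns")
    df.columns = ["chrom", "start", "end", "value"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    _validate_intervals(df, "start", "end", path)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def write_matrix(cmap: ContactMap, path, fmt: str = "triplet") -> None:
    """Serialize a contact map as dense TSV or sparse (bin1, bin2, count)
    triplets, with a ``#`` header carrying resolution/chrom/start."""
    header = f"# resolution={cmap.resolution} chrom={cmap.chrom} start={cmap.start} n_bins={cmap.n_bins}\n"
    if fmt == "dense":
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, cmap.matrix, delimiter="\t", fmt="%.10g")
    elif fmt == "triplet":
        iu = np.triu_indices(cmap.n_bins)
        vals = cmap.matrix[iu]
        nz = vals != 0
        with open(path, "w") as fh:
            fh.write(header)
            for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
                fh.write(f"{i}\t{j}\t{v:.10g}\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path, fmt: str = "triplet") -> ContactMap:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing matrix header line")
    meta = dict(kv.split("=") for kv in header[1:].split())
    res, chrom, start, n_bins = int(meta["resolution"]), meta["chrom"], int(meta["start"]), int(meta["n_bins"])
    if fmt == "dense":
        mat = np.loadtxt(path, delimiter="\t", skiprows=1)
        if mat.shape != (n_bins, n_bins):
            raise ValueError(f"{path}: dense matrix shape {mat.shape} != header n_bins {n_bins}")
    elif fmt == "triplet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["i", "j", "v"])
        mat = np.zeros((n_bins, n_bins))
        mat[df["i"], df["j"]] = df["v"]
        mat[df["j"], df["i"]] = df["v"]
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    return ContactMap(mat, resolution=res, chrom=chrom, start=start)
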