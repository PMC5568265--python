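"""Plain-text interchange: pair TSV, call TSV, bedGraph, BED6, TIFF stacks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracks import BinTrack

PAIR_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "count"]
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "methylated", "total"]


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=PAIR_COLUMNS)
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    calls[CALL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=CALL_COLUMNS)


def write_bedgraph(track: BinTrack, path) -> None:
    """0-based, half-open bedGraph; undefined windows are omitted."""
    df = track.to_frame()
    df = df[~np.isnan(df["value"])]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def bedgraph_to_track(
    df: pd.DataFrame, lengths: dict[str, int], window: int, name: str = ""
) -> BinTrack:
    """Project bedGraph rows onto fixed windows (rows must align to windows)."""
    from .tracks import tile_genome

    bins = tile_genome(lengths, window)
    key = bins.set_index(["chrom", "start"]).index
    values = np.full(len(bins), np.nan)
    src = df.set_index(["chrom", "start"])["value"]
    hit = key.isin(src.index)
    values[hit] = src.loc[key[hit]].to_numpy()
    return BinTrack(bins, values, window, name=name)


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    df = intervals.copy()
    df["name"] = df[name_col] if name_col else "."
    df["score"] = 0
    df["strand"] = df["strand"] if "strand" in df.columns else "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stack(stack: np.ndarray, sidecar: dict, path) -> None:
    """Multi-page TIFF plus JSON metadata sidecar next to it."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_stack(path):
    path = Path(path)
    data = tifffile.imread(path)
    meta_path = path.with_suffix(".json")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return data, meta
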