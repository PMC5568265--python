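"""Fixed-width genomic signal tracks (``BinTrack``).

A BinTrack holds one scalar per non-overlapping, genome-tiling window:
methylation ratios, compactness values, ChIP enrichment ratios, decay
exponents.  Undefined windows carry NaN and every consumer treats NaN as
"no value", never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout


@dataclass
class BinTrack:
    """Per-window scalar signal.

    ``bins`` has columns chrom/start/end (0-based, half-open) in genome
    order; ``values`` aligns with it, NaN where undefined.
    """

    bins: pd.DataFrame
    values: np.ndarray
    resolution: int
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bins):
            raise ValueError("values and bins length mismatch")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def same_bins(self, other: "BinTrack") -> bool:
        a, b = self.bins, other.bins
        return (
            len(a) == len(b)
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["value"] = self.values
        return out

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return (self.bins["chrom"] == chrom).to_numpy()


def tile_genome(
    lengths: dict[str, int] | GenomeLayout, resolution: int
) -> pd.DataFrame:
    """Genome-tiling bins at ``resolution``; last bin per chromosome may be short."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(lengths, GenomeLayout):
        lengths = {c: lengths.length(c) for c in lengths.chrom_names}
    rows = []
    for chrom, length in lengths.items():
        starts = np.arange(0, length, resolution)
        ends = np.minimum(starts + resolution, length)
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        )
    return pd.concat(rows, ignore_index=True)


def empty_track(
    lengths: dict[str, int] | GenomeLayout,
    resolution: int,
    name: str = "",
) -> BinTrack:
    bins = tile_genome(lengths, resolution)
    return BinTrack(bins, np.full(len(bins), np.nan), resolution, name=name)
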