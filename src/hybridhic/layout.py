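"""Genome layout for a two-subgenome hybrid.

A hybrid reference concatenates the chromosomes of both parents; here
subgenome ``A`` plays the role of the smaller, TE-poor genome (5
chromosomes, *A. thaliana*-like) and subgenome ``B`` the larger, TE-rich
one (8 chromosomes, re-labelled to follow A's, i.e. chromosomes 6-13).
Each chromosome is tiled by non-overlapping segments labelled ``arm``,
``pericentromere`` or ``masked`` (assembly gaps / N-runs, which behave as
invisible in every sequencing assay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEGMENT_LABELS = ("arm", "pericentromere", "masked")


@dataclass
class GenomeLayout:
    """Chromosome structure, segmentation and TE-density track.

    Parameters
    ----------
    chromosomes
        DataFrame with columns ``name``, ``length`` (bp) and ``subgenome``
        (``"A"`` or ``"B"``), in reference order.
    segments
        DataFrame with columns ``chrom``, ``start``, ``end``, ``label``;
        per chromosome the intervals are sorted, non-overlapping and tile
        ``[0, length)`` exactly.
    te_density
        DataFrame with columns ``chrom``, ``start``, ``end``, ``value``;
        fraction of each fixed-width window covered by transposable
        elements, in [0, 1].
    """

    chromosomes: pd.DataFrame
    segments: pd.DataFrame
    te_density: pd.DataFrame
    te_window: int = 10_000
    _lengths: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        self._lengths = dict(
            zip(self.chromosomes["name"], self.chromosomes["length"])
        )
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes["name"])

    def length(self, chrom: str) -> int:
        return int(self._lengths[chrom])

    def subgenome(self, chrom: str) -> str:
        row = self.chromosomes.loc[self.chromosomes["name"] == chrom]
        return str(row["subgenome"].iloc[0])

    def chroms_of(self, subgenome: str) -> list[str]:
        sel = self.chromosomes["subgenome"] == subgenome
        return list(self.chromosomes.loc[sel, "name"])

    def segments_of(self, chrom: str, label: str | None = None) -> pd.DataFrame:
        seg = self.segments[self.segments["chrom"] == chrom]
        if label is not None:
            seg = seg[seg["label"] == label]
        return seg.reset_index(drop=True)

    def masked_intervals(self) -> pd.DataFrame:
        return self.segments[self.segments["label"] == "masked"].reset_index(
            drop=True
        )

    def segment_label_at(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """Segment label of position(s) on a chromosome (vectorised)."""
        seg = self.segments_of(chrom)
        starts = seg["start"].to_numpy()
        idx = np.searchsorted(starts, np.atleast_1d(pos), side="right") - 1
        idx = np.clip(idx, 0, len(seg) - 1)
        return seg["label"].to_numpy()[idx]

    def te_density_at(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        te = self.te_density[self.te_density["chrom"] == chrom]
        starts = te["start"].to_numpy()
        idx = np.searchsorted(starts, np.atleast_1d(pos), side="right") - 1
        idx = np.clip(idx, 0, len(te) - 1)
        return te["value"].to_numpy()[idx]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for _, row in self.chromosomes.iterrows():
            if row["length"] <= 0:
                raise ValueError(
                    f"chromosome {row['name']!r} has non-positive length "
                    f"{row['length']}"
                )
            if row["subgenome"] not in ("A", "B"):
                raise ValueError(
                    f"chromosome {row['name']!r}: subgenome must be 'A' or 'B'"
                )
        for chrom in self.chrom_names:
            seg = self.segments_of(chrom)
            if seg.empty:
                raise ValueError(f"chromosome {chrom!r} has no segments")
            if not set(seg["label"]).issubset(SEGMENT_LABELS):
                bad = set(seg["label"]) - set(SEGMENT_LABELS)
                raise ValueError(f"unknown segment labels {bad!r}")
            starts = seg["start"].to_numpy()
            ends = seg["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != self.length(chrom):
                raise ValueError(f"segments do not tile chromosome {chrom!r}")
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError(
                    f"segments overlap or leave gaps on chromosome {chrom!r}"
                )
            if not np.all(ends > starts):
                raise ValueError(f"empty segment on chromosome {chrom!r}")
        vals = self.te_density["value"].to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("te_density values must lie in [0, 1]")

    def mean_te_density(self, subgenome: str, label: str = "arm") -> float:
        """Mean TE density over windows whose midpoint lies in `label` segments."""
        vals = []
        for chrom in self.chroms_of(subgenome):
            te = self.te_density[self.te_density["chrom"] == chrom]
            mids = (te["start"].to_numpy() + te["end"].to_numpy()) // 2
            labels = self.segment_label_at(chrom, mids)
            vals.append(te["value"].to_numpy()[labels == label])
        allv = np.concatenate(vals) if vals else np.array([])
        return float(np.mean(allv)) if allv.size else float("nan")
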