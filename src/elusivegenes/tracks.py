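"""Regulatory-landscape features from interval tracks.

Four track-derived features are assigned per gene from processed
epigenomic data consumed as BED / bedGraph:

* ATAC peak density -- peaks per kb over the gene body plus a flanking
  margin (default 2 kb each side);
* TAD membership and length -- a gene is "inside" a topologically
  associating domain only when fully contained in one (the longest, if
  nested); genes straddling a boundary count as outside;
* mean replication-timing signal -- overlap-length-weighted mean of a
  percentage-normalised Repli-seq bedGraph over the gene span;
* LAD overlap -- whether the gene intersects a lamina-associated domain
  by at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModel

__all__ = [
    "DEFAULT_ATAC_FLANK",
    "IntervalTrack",
    "peak_density",
    "tad_assignment",
    "mean_signal",
    "lad_overlap_flag",
]

DEFAULT_ATAC_FLANK = 2000


class IntervalTrack:
    """A named set of genomic intervals (0-based half-open), optionally scored."""

    def __init__(self, name: str, intervals: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required <= set(intervals.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if (intervals["start"] >= intervals["end"]).any():
            raise ValueError(f"track {name!r}: interval with start >= end")
        if "score" in intervals.columns and not pd.api.types.is_numeric_dtype(intervals["score"]):
            raise ValueError(f"track {name!r}: non-numeric scores")
        if "score" in intervals.columns and intervals["score"].isna().any():
            raise ValueError(f"track {name!r}: missing scores")
        self.name = name
        self.intervals = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.has_scores = "score" in intervals.columns
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            data = sub["score"] if self.has_scores else sub["start"]
            self._trees[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"], data)
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int):
        tree = self._trees.get(chrom)
        return [] if tree is None else sorted(tree.overlap(start, end))

    @classmethod
    def read_bed(cls, path, name: Optional[str] = None) -> "IntervalTrack":
        """3- or 5-column BED (chrom, start, end[, name, score])."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
        if df.shape[1] >= 5:
            df = df.rename(columns={4: "score"})
            df = df[["chrom", "start", "end", "score"]]
        else:
            df = df[["chrom", "start", "end"]]
        return cls(name or str(path), df)

    @classmethod
    def read_bedgraph(cls, path, name: Optional[str] = None) -> "IntervalTrack":
        """4-column bedGraph (chrom, start, end, signal)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] < 4:
            raise ValueError("bedGraph requires 4 columns")
        df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "score"})
        return cls(name or str(path), df[["chrom", "start", "end", "score"]])


def peak_density(
    gene: GeneModel,
    peaks: IntervalTrack,
    flank: int = DEFAULT_ATAC_FLANK,
    chrom_length: Optional[int] = None,
) -> float:
    """Peaks per kb over the gene span extended by *flank* bp on each side."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    w_start = max(0, gene.start - flank)
    w_end = gene.end + flank
    if chrom_length is not None:
        w_end = min(w_end, chrom_length)
    n = len(peaks.overlapping(gene.chrom, w_start, w_end))
    return n / ((w_end - w_start) / 1000.0)


def tad_assignment(
    gene: GeneModel, tads: IntervalTrack, containment: bool = True
) -> tuple[bool, Optional[int]]:
    """(inside, length of containing TAD) -- inside requires full containment.

    With ``containment=False`` any >= 1 bp overlap counts as inside and the
    longest overlapping domain is reported.
    """
    hits = tads.overlapping(gene.chrom, gene.start, gene.end)
    if containment:
        hits = [iv for iv in hits if iv.begin <= gene.start and iv.end >= gene.end]
    if not hits:
        return False, None
    return True, max(iv.end - iv.begin for iv in hits)


def mean_signal(gene: GeneModel, signal: IntervalTrack) -> Optional[float]:
    """Overlap-length-weighted mean score over the gene span; None if no overlap."""
    if not signal.has_scores:
        raise ValueError(f"track {signal.name!r} carries no scores")
    total = 0.0
    weight = 0
    for iv in signal.overlapping(gene.chrom, gene.start, gene.end):
        ov = min(iv.end, gene.end) - max(iv.begin, gene.start)
        total += iv.data * ov
        weight += ov
    if weight == 0:
        return None
    return total / weight


def lad_overlap_flag(gene: GeneModel, lads: IntervalTrack) -> bool:
    """True iff the gene span intersects any domain by >= 1 bp."""
    return bool(lads.overlapping(gene.chrom, gene.start, gene.end))
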