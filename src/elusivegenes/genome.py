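"""Per-gene genomic context: GC content, length, gene density, variant density.

Coordinates are 0-based half-open internally; GFF3/GTF (1-based closed)
is converted on read, BED-style tables are consumed natively. Features
follow the whole-gene convention: GC content is computed over the full
genomic span including introns and UTRs, and local gene density uses the
window from the 3rd gene upstream to the 3rd gene downstream (fewer near
chromosome ends), reported as genes per Mb.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional

import gffutils
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "VariantSet",
    "VARIANT_CLASSES",
    "gene_gc_content",
    "gene_length",
    "local_gene_density",
    "variant_density",
]

VARIANT_CLASSES = ("rare_snv", "deletion_cnv", "duplication_cnv")


@dataclass(frozen=True)
class GeneModel:
    """One gene locus; start/end are 0-based half-open base pairs."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")


class GenomeAnnotation:
    """Gene-level annotation: genes per chromosome, sorted by start."""

    def __init__(self, genes: list[GeneModel], chrom_lengths: Optional[dict[str, int]] = None):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort(key=lambda g: (g.start, g.end, g.gene_id))
        self.chrom_lengths = dict(chrom_lengths or {})
        for chrom, length in self.chrom_lengths.items():
            for g in self.by_chrom.get(chrom, []):
                if g.end > length:
                    raise ValueError(f"gene {g.gene_id} exceeds {chrom} length {length}")

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    @classmethod
    def from_gff3(cls, path, feature_type: str = "gene") -> "GenomeAnnotation":
        """Load gene-level records from GFF3 (1-based closed -> half-open)."""
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = [
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
            for feat in db.features_of_type(feature_type)
        ]
        chrom_lengths = {}
        for directive in db.directives:
            if directive.startswith("sequence-region"):
                parts = directive.split()
                if len(parts) == 4:
                    chrom_lengths[parts[1]] = int(parts[3])
        return cls(genes, chrom_lengths=chrom_lengths)


def gene_gc_content(sequences, gene: GeneModel) -> float:
    """GC fraction of the full genomic span of *gene* (introns and UTRs included).

    *sequences* is any mapping of chromosome name to sliceable sequence
    (e.g. a ``pyfaidx.Fasta`` or a plain dict of strings). Ambiguous bases
    are excluded from numerator and denominator; strand-independent.
    """
    if gene.chrom not in sequences:
        raise KeyError(f"chromosome {gene.chrom!r} absent from sequence source")
    seq = str(sequences[gene.chrom][gene.start : gene.end]).upper()
    if len(seq) < gene.end - gene.start:
        raise ValueError(f"gene {gene.gene_id} span exceeds {gene.chrom} sequence")
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError(f"gene {gene.gene_id}: no unambiguous bases in span")
    return gc / acgt


def gene_length(gene: GeneModel) -> int:
    return gene.end - gene.start


def local_gene_density(annotation: GenomeAnnotation, gene_id: str, n_flanking: int = 3) -> float:
    """Genes per Mb in the window spanning the gene and its flanking neighbours.

    The window runs from the start of the ``n_flanking``-th gene upstream to
    the end of the ``n_flanking``-th gene downstream on the same chromosome
    (fewer near chromosome ends, where the actual gene count is used), so an
    interior gene's window holds exactly ``2*n_flanking + 1`` genes.
    """
    gene = annotation[gene_id]
    neighbours = annotation.by_chrom[gene.chrom]
    idx = bisect_left([ (g.start, g.end, g.gene_id) for g in neighbours ],
                      (gene.start, gene.end, gene.gene_id))
    lo = max(0, idx - n_flanking)
    hi = min(len(neighbours) - 1, idx + n_flanking)
    window = neighbours[lo : hi + 1]
    w_start = window[0].start
    w_end = max(g.end for g in window)  # overlapping neighbours cannot truncate the window
    return len(window) / (w_end - w_start) * 1e6


class VariantSet:
    """Population variants (rare SNVs, deletion/duplication CNVs) by class."""

    def __init__(self, records: pd.DataFrame):
        required = {"chrom", "start", "end", "vclass"}
        if not required <= set(records.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        bad = set(records["vclass"]) - set(VARIANT_CLASSES)
        if bad:
            raise ValueError(f"unknown variant classes: {sorted(bad)}")
        if (records["start"] >= records["end"]).any():
            raise ValueError("variant with start >= end")
        self.records = records.reset_index(drop=True)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for (chrom, vclass), sub in records.groupby(["chrom", "vclass"], sort=False):
            self._trees[(chrom, vclass)] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"])
            )

    @classmethod
    def read_tsv(cls, path) -> "VariantSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def count_overlapping(self, gene: GeneModel, vclass: str) -> int:
        tree = self._trees.get((gene.chrom, vclass))
        if tree is None:
            return 0
        return len(tree.overlap(gene.start, gene.end))


def variant_density(variants: VariantSet, gene: GeneModel, vclass: str) -> float:
    """Variants of one class overlapping the gene span, per base pair."""
    if vclass not in VARIANT_CLASSES:
        raise ValueError(f"unknown variant class {vclass!r}")
    return variants.count_overlapping(gene, vclass) / gene_length(gene)
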