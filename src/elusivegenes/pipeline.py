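"""End-to-end stages: classify gene fates, assemble features, compare groups.

Each stage is a plain function over a :class:`PipelineConfig`; the CLI is
a thin wrapper. Stages communicate through TSV files with fixed column
order, so any stage can be re-run from its inputs and reruns with an
identical config produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import pyfaidx
import yaml

from . import expression as expr
from . import genetree as gt
from . import losses as ls
from . import stats as st
from . import tracks as tr
from .genome import GenomeAnnotation, VariantSet, gene_gc_content, gene_length, local_gene_density, variant_density
from .taxonomy import Taxonomy, load_taxonomy, species_ages

logger = logging.getLogger("elusivegenes")

__all__ = ["PipelineConfig", "run_classify", "run_features", "run_compare"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    taxonomy: Optional[str] = None
    trees: Optional[str] = None
    annotation: Optional[str] = None
    genome: Optional[str] = None
    expression: Optional[str] = None
    scores: Optional[str] = None
    variants: Optional[str] = None
    atac: Optional[str] = None
    tads: Optional[str] = None
    lads: Optional[str] = None
    repli: Optional[str] = None
    exclusions: Optional[str] = None
    outdir: str = "."

    min_branch_length: float = gt.DEFAULT_MIN_BRANCH_LENGTH
    min_loss_events: int = ls.MIN_LOSS_EVENTS
    max_duplicates: int = ls.MAX_DUPLICATES
    h_threshold: float = expr.DEFAULT_H_THRESHOLD
    significance: float = st.SIGNIFICANCE_LEVEL
    atac_flank: int = tr.DEFAULT_ATAC_FLANK
    tad_containment: bool = True
    leaf_delimiter: str = gt.LEAF_DELIMITER
    negate_score_columns: tuple[str, ...] = ("z_synonymous", "z_missense", "z_lof")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "negate_score_columns" in data:
            data["negate_score_columns"] = tuple(data["negate_score_columns"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _log_run(config: PipelineConfig, stage: str) -> None:
    logger.info("stage=%s seed=%d config_hash=%s", stage, config.seed, config.config_hash())


# ---------------------------------------------------------------------------
# classification


def _classify_tree(
    newick: str,
    taxonomy: Taxonomy,
    ages: dict[str, int],
    config: PipelineConfig,
    tree_id: str,
) -> list[ls.GeneFateCall]:
    tree = gt.read_gene_tree(newick)
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    delim = config.leaf_delimiter
    focal = taxonomy.focal_species

    if n_leaves >= 3:
        tree = gt.collapse_short_branches(tree, config.min_branch_length)
        tree = gt.root_by_age_balance(tree, ages, focal, delim)
        events = gt.annotate_species_overlap_events(tree, delim)
        groups = gt.extract_focal_subtrees(tree, events, focal, delim, source_tree_id=tree_id)
    elif n_leaves == 2:
        tree = gt.root_by_age_balance(tree, ages, focal, delim)
        events = gt.annotate_species_overlap_events(tree, delim)
        groups = gt.extract_focal_subtrees(tree, events, focal, delim, source_tree_id=tree_id)
    else:  # single-leaf family: the focal gene alone
        leaf = next(tree.leaf_node_iter())
        sp, gid = gt.parse_leaf_label(leaf.taxon.label, delim)
        if sp != focal:
            return []
        groups = [
            gt.OrthologGroup(
                focal_gene_id=gid, members={sp: [gid]},
                source_tree_id=tree_id, n_duplicates=0,
            )
        ]

    calls = []
    for group in groups:
        profile = ls.build_presence_profile(group, taxonomy)
        loss_events = ls.infer_ancestral_losses(profile, taxonomy)
        age = gt.infer_gene_age(group, ages)
        calls.append(ls.classify_fate(profile, loss_events, group.n_duplicates, age=age))
    return calls


def run_classify(config: PipelineConfig, write: bool = True) -> pd.DataFrame:
    """Collapse, root, annotate and extract every tree; classify each focal gene.

    Trees are read from ``config.trees``: a file with one Newick per line,
    or a directory of ``*.nwk`` files. Unparseable trees are logged and
    skipped (counted), never fatal. Returns the fate table and, if *write*,
    stores ``fates.tsv`` under ``config.outdir``.
    """
    _log_run(config, "classify")
    taxonomy = load_taxonomy(Path(config.taxonomy))
    ages = species_ages(taxonomy)

    tree_source = Path(config.trees)
    if tree_source.is_dir():
        items = [(p.stem, p.read_text().strip()) for p in sorted(tree_source.glob("*.nwk"))]
    else:
        items = [
            (f"tree{i:05d}", line.strip())
            for i, line in enumerate(tree_source.read_text().splitlines())
            if line.strip()
        ]

    calls: list[ls.GeneFateCall] = []
    n_skipped = 0
    for tree_id, newick in items:
        try:
            calls.extend(_classify_tree(newick, taxonomy, ages, config, tree_id))
        except Exception as exc:  # unreadable tree: log and move on
            n_skipped += 1
            logger.warning("skipping tree %s: %s", tree_id, exc)
    if n_skipped:
        logger.warning("%d trees skipped", n_skipped)

    if config.exclusions:
        excluded = [
            line.strip()
            for line in Path(config.exclusions).read_text().splitlines()
            if line.strip()
        ]
        calls = ls.apply_exclusions(calls, excluded)

    fates = ls.calls_to_frame(calls)
    if write:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        fates.to_csv(out / "fates.tsv", sep="\t", index=False)
    return fates


# ---------------------------------------------------------------------------
# feature assembly


def run_features(config: PipelineConfig, fates: Optional[pd.DataFrame] = None,
                 write: bool = True) -> pd.DataFrame:
    """Join genomic, expression, regulatory and ingested features per gene.

    Every feature is computed only where its input covers the gene; missing
    data stay missing (NaN), never zero. Gene-id mismatches between inputs
    are reported with counts.
    """
    _log_run(config, "features")
    out = Path(config.outdir)
    if fates is None:
        fates = pd.read_csv(out / "fates.tsv", sep="\t")
    table = fates.set_index("gene_id")[["fate", "n_duplicates", "age"]].copy()

    annotation = GenomeAnnotation.from_gff3(config.annotation) if config.annotation else None
    if annotation is not None:
        genome = pyfaidx.Fasta(str(config.genome)) if config.genome else None
        known = [gid for gid in table.index if gid in annotation.genes]
        n_missing = len(table) - len(known)
        if n_missing:
            logger.warning("%d genes absent from annotation", n_missing)
        rows = {}
        for gid in known:
            gene = annotation[gid]
            row = {
                "gene_length": gene_length(gene),
                "gene_density": local_gene_density(annotation, gid),
            }
            if genome is not None and gene.chrom in genome:
                row["gc_content"] = gene_gc_content(genome, gene)
            rows[gid] = row
        table = table.join(pd.DataFrame.from_dict(rows, orient="index"))

        if config.variants:
            variants = VariantSet.read_tsv(config.variants)
            for vclass, column in (
                ("rare_snv", "rare_snv_density"),
                ("deletion_cnv", "deletion_cnv_density"),
                ("duplication_cnv", "duplication_cnv_density"),
            ):
                table[column] = pd.Series(
                    {
                        gid: variant_density(variants, annotation[gid], vclass)
                        for gid in known
                    }
                )

        track_specs = [
            ("atac", config.atac, tr.IntervalTrack.read_bed),
            ("tads", config.tads, tr.IntervalTrack.read_bed),
            ("lads", config.lads, tr.IntervalTrack.read_bed),
            ("repli", config.repli, tr.IntervalTrack.read_bedgraph),
        ]
        loaded = {
            name: reader(path, name) for name, path, reader in track_specs if path
        }
        if loaded:
            rows = {}
            for gid in known:
                gene = annotation[gid]
                row = {}
                if "atac" in loaded:
                    row["atac_peak_density"] = tr.peak_density(
                        gene, loaded["atac"], config.atac_flank,
                        annotation.chrom_lengths.get(gene.chrom),
                    )
                if "tads" in loaded:
                    inside, length = tr.tad_assignment(
                        gene, loaded["tads"], containment=config.tad_containment
                    )
                    row["tad_inside"] = inside
                    row["tad_length"] = length
                if "lads" in loaded:
                    row["lad_overlap"] = tr.lad_overlap_flag(gene, loaded["lads"])
                if "repli" in loaded:
                    row["repli_signal"] = tr.mean_signal(gene, loaded["repli"])
                rows[gid] = row
            table = table.join(pd.DataFrame.from_dict(rows, orient="index"))

    if config.expression:
        mat = expr.read_expression_tsv(config.expression)
        shared = table.index.intersection(mat.index)
        if len(shared) < len(table):
            logger.warning("%d genes absent from expression matrix", len(table) - len(shared))
        table = table.join(expr.expression_features(mat, config.h_threshold))

    if config.scores:
        scores = pd.read_csv(config.scores, sep="\t").set_index("gene_id")
        for col in config.negate_score_columns:
            if col in scores.columns:  # compared as opposite numbers
                scores[col] = -scores[col]
        table = table.join(scores)

    table = table.reset_index().rename(columns={"index": "gene_id"})
    if write:
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.tsv", sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# comparison


NUMERIC_FEATURES = [
    "gc_content", "gene_length", "gene_density",
    "rare_snv_density", "deletion_cnv_density", "duplication_cnv_density",
    "h_prime", "max_tpm",
    "atac_peak_density", "tad_length", "repli_signal",
    "ka", "ks", "ki", "z_synonymous", "z_missense", "z_lof",
]
BOOLEAN_FEATURES = ["lad_overlap", "tad_inside", "restricted_expression"]

FEATURE_FAMILIES = {
    "gc_content": "genomic", "gene_length": "genomic", "gene_density": "genomic",
    "rare_snv_density": "variants", "deletion_cnv_density": "variants",
    "duplication_cnv_density": "variants",
    "h_prime": "expression", "max_tpm": "expression",
    "restricted_expression": "expression",
    "atac_peak_density": "regulation", "tad_length": "regulation",
    "repli_signal": "regulation", "lad_overlap": "regulation", "tad_inside": "regulation",
    "ka": "substitution", "ks": "substitution", "ki": "substitution",
    "z_synonymous": "constraint", "z_missense": "constraint", "z_lof": "constraint",
}


def default_contrasts(table: pd.DataFrame, h_threshold: float = expr.DEFAULT_H_THRESHOLD
                      ) -> list[st.Contrast]:
    """Elusive vs non-elusive; restricted vs ubiquitous within elusive."""
    numeric = [f for f in NUMERIC_FEATURES if f in table.columns and table[f].notna().any()]
    boolean = [f for f in BOOLEAN_FEATURES if f in table.columns and table[f].notna().any()]
    contrasts = [
        st.Contrast(
            name="elusive_vs_non_elusive",
            side_a=("elusive", table["fate"] == ls.ELUSIVE),
            side_b=("non_elusive", table["fate"] == ls.NON_ELUSIVE),
            numeric_features=numeric,
            boolean_features=boolean,
            families=FEATURE_FAMILIES,
        )
    ]
    if "h_prime" in table.columns:
        elusive = table["fate"] == ls.ELUSIVE
        restricted = elusive & (table["h_prime"] < h_threshold)
        ubiquitous = elusive & (table["h_prime"] >= h_threshold)
        if restricted.any() and ubiquitous.any():
            sub_numeric = [f for f in numeric if f not in ("h_prime", "max_tpm")]
            sub_boolean = [f for f in boolean if f != "restricted_expression"]
            contrasts.append(
                st.Contrast(
                    name="restricted_vs_ubiquitous_elusive",
                    side_a=("restricted", restricted),
                    side_b=("ubiquitous", ubiquitous),
                    numeric_features=sub_numeric,
                    boolean_features=sub_boolean,
                    families=FEATURE_FAMILIES,
                )
            )
    return contrasts


def run_compare(config: PipelineConfig, features: Optional[pd.DataFrame] = None,
                write: bool = True) -> pd.DataFrame:
    """Run the declared fate-group contrasts with family-wise BH correction."""
    _log_run(config, "compare")
    out = Path(config.outdir)
    if features is None:
        features = pd.read_csv(out / "features.tsv", sep="\t")
    contrasts = default_contrasts(features, config.h_threshold)
    result = st.compare_fate_groups(features, contrasts, alpha=config.significance)
    result = result.sort_values(["contrast", "family", "feature"]).reset_index(drop=True)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    return result
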