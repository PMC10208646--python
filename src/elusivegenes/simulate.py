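"""Synthetic cohort generator: taxonomy, gene histories, genome, omics tracks.

Generates a complete, internally consistent input set for the pipeline —
a hierarchical taxonomy with focal groups, gene trees with planted
taxon-level losses and duplications, a genome layout with class-dependent
GC and gene spacing, Dirichlet tissue-expression profiles, external
substitution-rate / constraint-score columns, variant tables, and
epigenomic interval tracks with class-dependent enrichment — so the whole
analysis runs and can be validated without any external download.

Two gene classes are simulated. The ``loss_prone`` class emulates the
empirical profile of repeatedly lost (elusive) genes: high taxon-level
loss rate, elevated substitution rates, high GC, dense gene neighbourhood,
short genes, spatially restricted / low expression, fewer open-chromatin
peaks, lamina association, late replication, TAD-boundary-rich
surroundings. The ``conserved`` class emulates pan-mammalian single-copy
genes (loss rate 0) with the opposite feature profile. The generator's
truth table records, per gene, the planted class, the branches on which
losses occurred, and the fate implied by the true presence pattern.

Losses are simulated on the species taxonomy (each edge one time unit),
not on gene trees, so planted truth lives at the clade level where the
inference operates. Every generator is a pure function of (config, seed):
reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .taxonomy import CladeNode, Taxonomy

__all__ = [
    "ClassParams",
    "CohortConfig",
    "simulate_taxonomy",
    "simulate_gene_histories",
    "simulate_genome_layout",
    "simulate_expression",
    "simulate_scores_and_variants",
    "simulate_tracks",
    "write_cohort",
]

BASES = np.frombuffer(b"ATCG", dtype="S1")

# Substream identifiers so that each generator draws from an independent,
# reproducible stream of the single cohort seed.
_STREAMS = {
    "histories": 1,
    "layout": 2,
    "expression": 3,
    "tracks": 4,
    "scores": 5,
}


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one gene class."""

    loss_rate: float = 0.0  # per-branch loss intensity (branch length 1)
    dup_prob: float = 0.0  # probability of one extra focal-lineage family copy
    rate_multiplier: float = 1.0  # gene-tree branch-length scale
    gc: float = 0.42  # GC probability within gene spans
    gene_length_median: float = 6000.0  # bp (lognormal median)
    spacing_mean: float = 30000.0  # bp, exponential intergenic gap
    dirichlet_alpha: float = 5.0  # tissue-profile concentration
    zero_expression_frac: float = 0.0  # fraction of silent (all-zero) genes
    expression_scale: float = 500.0  # median total TPM over tissues
    atac_rate: float = 0.4  # peaks per kb around the gene
    lad_prob: float = 0.25  # probability the gene sits in a LAD
    tad_gap_cut_prob: float = 0.12  # boundary probability per intergenic gap
    tad_split_prob: float = 0.02  # boundary forced inside the gene
    repli_offset: float = 8.0  # added to the replication-timing baseline
    snv_rate: float = 1.0  # rare SNVs per kb
    cnv_rate: float = 0.05  # CNVs per kb (each class)
    z_mean: float = 0.5  # mean constraint Z-score
    ka_scale: float = 0.05  # median K_A


def default_class_params() -> dict[str, ClassParams]:
    """The default contrast preset: loss-prone vs conserved genes."""
    return {
        "loss_prone": ClassParams(
            loss_rate=0.30,
            dup_prob=0.05,
            rate_multiplier=2.0,
            gc=0.55,
            gene_length_median=3000.0,
            spacing_mean=10000.0,
            dirichlet_alpha=0.05,
            zero_expression_frac=0.2,
            expression_scale=10.0,
            atac_rate=0.1,
            lad_prob=0.5,
            tad_gap_cut_prob=0.5,
            tad_split_prob=0.3,
            repli_offset=-20.0,
            snv_rate=3.0,
            cnv_rate=0.15,
            z_mean=-1.0,
            ka_scale=0.15,
        ),
        "conserved": ClassParams(),
    }


def null_class_params() -> dict[str, ClassParams]:
    """All class parameters equal (no planted contrast); for calibration."""
    base = ClassParams(loss_rate=0.0, dup_prob=0.0)
    return {"loss_prone": base, "conserved": base}


@dataclass
class CohortConfig:
    seed: int = 0
    n_groups: int = 15
    species_per_group: int = 3
    n_genes: dict[str, int] = field(default_factory=lambda: {"loss_prone": 200, "conserved": 800})
    classes: dict[str, ClassParams] = field(default_factory=default_class_params)
    n_tissues: int = 54
    n_chromosomes: int = 4
    branch_length_sigma: float = 0.3
    intergenic_gc: float = 0.41
    placement_block: int = 25  # genes per same-class placement block
    repli_bin: int = 20000
    focal_species: str = "focal"

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def validate(self) -> None:
        for name, params in self.classes.items():
            if params.loss_rate < 0 or not (0 <= params.dup_prob <= 1):
                raise ValueError(f"class {name!r}: invalid loss/duplication parameters")
            if params.dirichlet_alpha <= 0:
                raise ValueError(f"class {name!r}: Dirichlet concentration must be > 0")
            if not (0 < params.gc < 1):
                raise ValueError(f"class {name!r}: GC probability must be in (0,1)")


# ---------------------------------------------------------------------------
# taxonomy


def simulate_taxonomy(config: CohortConfig) -> Taxonomy:
    """Balanced-ladder taxonomy: paired focal groups nested around the focal species.

    Consecutive groups are joined two-by-two into superclades, and the
    superclades stack outward from the focal species, so sibling groups can
    be lost jointly (exercising the hierarchy merge rule) and divergence
    ranks span the ladder. Deterministic given the config (no randomness is
    needed: species identity is positional).
    """
    if config.n_groups < 2:
        raise ValueError("need at least 2 focal groups")
    groups = []
    for gi in range(1, config.n_groups + 1):
        name = f"G{gi:02d}"
        species = [f"{name.lower()}_sp{si}" for si in range(1, config.species_per_group + 1)]
        groups.append(CladeNode(name=name, children=[CladeNode(name=sp) for sp in species]))
    units: list[CladeNode] = []
    for i in range(0, len(groups) - 1, 2):
        units.append(
            CladeNode(name=f"P{i // 2 + 1:02d}", children=[groups[i], groups[i + 1]])
        )
    if len(groups) % 2:
        units.append(groups[-1])
    node = CladeNode(name=config.focal_species)
    for i, unit in enumerate(units, start=1):
        node = CladeNode(name=f"anc{i:02d}", children=[unit, node])
    return Taxonomy(
        root=node,
        focal_groups=[g.name for g in groups],
        focal_species=config.focal_species,
    )


# ---------------------------------------------------------------------------
# gene histories


def _focal_path(taxonomy: Taxonomy) -> set[str]:
    path = set()
    node = taxonomy.clades[taxonomy.focal_species]
    while node is not None:
        path.add(node.name)
        node = node.parent
    return path


def _simulate_presence(
    taxonomy: Taxonomy, p_loss: float, focal_path: set[str], rng: np.random.Generator
) -> tuple[set[str], list[str]]:
    """One presence history; returns (present species, branches where loss hit)."""
    present_species: set[str] = set()
    lost_branches: list[str] = []

    def walk(node: CladeNode) -> None:
        for child in node.children:
            if child.name not in focal_path and rng.random() < p_loss:
                lost_branches.append(child.name)
                continue
            if child.is_leaf:
                present_species.add(child.name)
            else:
                walk(child)

    walk(taxonomy.root)
    present_species.add(taxonomy.focal_species)
    return present_species, lost_branches


def _true_loss_clades(present: set[str], taxonomy: Taxonomy) -> list[str]:
    """Maximal fully-absent clades covering >= 1 focal group (ground truth)."""
    events: list[str] = []

    def walk(node: CladeNode) -> None:
        species = node.species_under()
        if not (species & present):
            if any(taxonomy.group_species(g) <= species for g in taxonomy.focal_groups):
                events.append(node.name)
            return
        for child in node.children:
            walk(child)

    walk(taxonomy.root)
    return events


def _induced_newick(
    taxonomy: Taxonomy,
    present: set[str],
    gene_id: str,
    copy_suffix: str,
    scale: float,
    sigma: float,
    focal: str,
    rng: np.random.Generator,
) -> Optional[str]:
    """Newick of the taxonomy restricted to *present*, unit edges scaled with noise."""

    def edge_len() -> float:
        return scale * float(rng.lognormal(mean=0.0, sigma=sigma))

    def build(node: CladeNode) -> Optional[tuple[str, float]]:
        if node.is_leaf:
            if node.name not in present:
                return None
            if node.name == focal:
                gid = f"{gene_id}{copy_suffix}"
            else:
                gid = f"{gene_id}{copy_suffix}_{node.name}"
            return f"{node.name}|{gid}", edge_len()
        kids = [k for k in (build(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            sub, length = kids[0]
            return sub, length + edge_len()
        inner = "(" + ",".join(f"{s}:{l:.6f}" for s, l in kids) + ")"
        return inner, edge_len()

    built = build(taxonomy.root)
    if built is None:
        return None
    return built[0]


def simulate_gene_histories(
    taxonomy: Taxonomy, config: CohortConfig
) -> tuple[list[str], pd.DataFrame]:
    """Simulate per-gene presence histories and emit induced gene trees.

    Presence evolves root-to-tip on the taxonomy: on every branch off the
    focal lineage the gene is lost with probability 1 - exp(-lambda), and a
    loss is inherited by all descendants. With probability delta the whole
    family is duplicated at its root, yielding a second focal-species copy
    with an independently evolved species complement. The emitted Newick is
    the induced tree on surviving leaves (unrooted representation), branch
    lengths 1 x class rate multiplier x lognormal noise.

    Returns (newick strings, truth table). Truth rows carry the planted
    class, the loss branches, and ``planted_fate``: the fate the decision
    rule assigns to the *true* presence pattern.
    """
    config.validate()
    rng = config.rng("histories")
    focal_path = _focal_path(taxonomy)
    n_species = len(taxonomy.species)

    newicks: list[str] = []
    rows: list[dict] = []
    gene_index = 0
    for class_name in sorted(config.n_genes):
        params = config.classes[class_name]
        p_loss = 1.0 - math.exp(-params.loss_rate)
        for _ in range(config.n_genes[class_name]):
            gene_index += 1
            gene_id = f"g{gene_index:05d}"
            present, lost_branches = _simulate_presence(taxonomy, p_loss, focal_path, rng)
            n_dup = 1 if rng.random() < params.dup_prob else 0

            subtrees = []
            primary = _induced_newick(
                taxonomy, present, gene_id, "", params.rate_multiplier,
                config.branch_length_sigma, config.focal_species, rng,
            )
            subtrees.append(primary)
            if n_dup:
                dup_present, _ = _simulate_presence(taxonomy, p_loss, focal_path, rng)
                subtrees.append(
                    _induced_newick(
                        taxonomy, dup_present, gene_id, "_dup1", params.rate_multiplier,
                        config.branch_length_sigma, config.focal_species, rng,
                    )
                )
            if len(subtrees) == 1:
                newick = f"{subtrees[0]};"
            else:  # family duplicated at its root
                stem = 0.5 * params.rate_multiplier
                newick = "(" + ",".join(f"{s}:{stem:.6f}" for s in subtrees) + ");"
            newicks.append(newick)

            true_losses = _true_loss_clades(present, taxonomy)
            if len(true_losses) >= 2 and n_dup <= 3:
                fate = "elusive"
            elif len(present) == n_species and n_dup == 0:
                fate = "non_elusive"
            else:
                fate = "unclassified"
            rows.append(
                {
                    "gene_id": gene_id,
                    "planted_class": class_name,
                    "planted_fate": fate,
                    "n_true_losses": len(true_losses),
                    "lost_clades": ",".join(true_losses),
                    "lost_branches": ",".join(lost_branches),
                    "n_duplicates": n_dup,
                    "n_present_species": len(present),
                }
            )
    truth = pd.DataFrame(rows)
    return newicks, truth


# ---------------------------------------------------------------------------
# genome layout


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    cum = np.array([(1 - gc) / 2, 1 - gc, 1 - gc / 2, 1.0])
    return BASES[np.searchsorted(cum, rng.random(n), side="right").clip(0, 3)]


def simulate_genome_layout(
    truth: pd.DataFrame, config: CohortConfig
) -> tuple[dict[str, str], pd.DataFrame]:
    """Place genes on synthetic chromosomes; draw sequence with class GC.

    Genes are laid out in same-class blocks (``placement_block`` genes per
    block, block order shuffled) so that a gene's 7-gene density window is
    dominated by its own class's intergenic spacing, which is exponential
    with a class-dependent mean. Gene lengths are lognormal around a
    class-dependent median (loss-prone genes shorter). Returns
    (chromosome sequences, gene table with 0-based half-open coordinates).
    """
    config.validate()
    rng = config.rng("layout")

    blocks: list[list[str]] = []
    for class_name, sub in truth.groupby("planted_class", sort=True):
        ids = sub["gene_id"].to_numpy().copy()
        rng.shuffle(ids)
        for i in range(0, len(ids), config.placement_block):
            blocks.append(list(ids[i : i + config.placement_block]))
    order = rng.permutation(len(blocks))
    class_of = dict(zip(truth["gene_id"], truth["planted_class"]))

    chrom_genes: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chrom_names = list(chrom_genes)
    for bi, block_idx in enumerate(order):
        chrom_genes[chrom_names[bi % len(chrom_names)]].extend(blocks[block_idx])

    gene_rows = []
    sequences: dict[str, str] = {}
    for chrom, gene_ids in chrom_genes.items():
        pos = 1000
        spans = []
        for gid in gene_ids:
            params = config.classes[class_of[gid]]
            gap = int(rng.exponential(params.spacing_mean)) + 200
            length = max(300, int(rng.lognormal(math.log(params.gene_length_median), 0.5)))
            start = pos + gap
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            spans.append((gid, start, end))
            gene_rows.append(
                {"gene_id": gid, "chrom": chrom, "start": start, "end": end, "strand": strand}
            )
            pos = end
        chrom_len = pos + 1000
        seq = _random_bases(chrom_len, config.intergenic_gc, rng)
        for gid, start, end in spans:
            seq[start:end] = _random_bases(end - start, config.classes[class_of[gid]].gc, rng)
        sequences[chrom] = seq.tobytes().decode("ascii")
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return sequences, genes


# ---------------------------------------------------------------------------
# expression


def simulate_expression(truth: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Genes x tissues TPM matrix with class-dependent pleiotropy.

    Tissue proportions are Dirichlet(alpha * 1_R) -- small alpha gives
    spatially restricted profiles (low Shannon H') -- scaled by a lognormal
    expression magnitude; a class-dependent fraction of genes is silent
    (all-zero row).
    """
    config.validate()
    rng = config.rng("expression")
    R = config.n_tissues
    tissues = [f"tissue{k + 1:02d}" for k in range(R)]
    mat = np.zeros((len(truth), R))
    for i, (gid, class_name) in enumerate(zip(truth["gene_id"], truth["planted_class"])):
        params = config.classes[class_name]
        silent = rng.random() < params.zero_expression_frac
        props = rng.dirichlet(np.full(R, params.dirichlet_alpha))
        magnitude = rng.lognormal(math.log(params.expression_scale), 1.0)
        if not silent:
            mat[i] = props * magnitude
    return pd.DataFrame(mat, index=pd.Index(truth["gene_id"], name="gene_id"), columns=tissues)


# ---------------------------------------------------------------------------
# external score columns and variants


def simulate_scores_and_variants(
    genes: pd.DataFrame, truth: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene substitution-rate / constraint-score columns and variant table.

    Emulates the externally ingested columns: K_A / K_S / K_I around a
    class-dependent scale, constraint Z-scores around a class-dependent
    mean (loss-prone genes more mutation-tolerant, hence lower Z), rare
    SNVs and deletion/duplication CNVs placed uniformly within gene spans
    at class-dependent per-kb rates.
    """
    config.validate()
    rng = config.rng("scores")
    class_of = dict(zip(truth["gene_id"], truth["planted_class"]))

    score_rows = []
    variant_rows = []
    for row in genes.itertuples(index=False):
        params = config.classes[class_of[row.gene_id]]
        ka = rng.lognormal(math.log(params.ka_scale), 0.6)
        ks = rng.lognormal(math.log(params.ka_scale * 4), 0.5)
        ki = rng.lognormal(math.log(params.ka_scale * 3), 0.5)
        score_rows.append(
            {
                "gene_id": row.gene_id,
                "ka": ka,
                "ks": ks,
                "ki": ki,
                "z_synonymous": rng.normal(params.z_mean, 1.0),
                "z_missense": rng.normal(params.z_mean, 1.0),
                "z_lof": rng.normal(params.z_mean, 1.0),
            }
        )
        length_kb = (row.end - row.start) / 1000.0
        for vclass, rate in (
            ("rare_snv", params.snv_rate),
            ("deletion_cnv", params.cnv_rate),
            ("duplication_cnv", params.cnv_rate),
        ):
            for _ in range(rng.poisson(rate * length_kb)):
                width = 1 if vclass == "rare_snv" else int(rng.integers(500, 5000))
                start = int(rng.integers(row.start, row.end))
                variant_rows.append(
                    {"chrom": row.chrom, "start": start, "end": start + width, "vclass": vclass}
                )
    scores = pd.DataFrame(score_rows)
    variants = pd.DataFrame(variant_rows, columns=["chrom", "start", "end", "vclass"])
    variants = variants.sort_values(["chrom", "start"]).reset_index(drop=True)
    return scores, variants


# ---------------------------------------------------------------------------
# epigenomic tracks


def simulate_tracks(
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    config: CohortConfig,
    chrom_lengths: dict[str, int],
) -> dict[str, pd.DataFrame]:
    """ATAC / TAD / LAD interval tracks and a Repli-seq-like bedGraph.

    Peaks are Poisson-placed around genes at class-dependent per-kb rates;
    LADs cover genes with class-dependent probability; TAD boundaries fall
    in intergenic gaps (and inside genes) with class-dependent probability,
    so loss-prone genes sit in shorter domains or straddle a boundary; the
    replication-timing signal is a smooth baseline plus a class-dependent
    offset over gene bodies (negative = late-replicating).
    """
    config.validate()
    rng = config.rng("tracks")
    class_of = dict(zip(truth["gene_id"], truth["planted_class"]))
    flank = 2000

    atac_rows, lad_rows, tad_rows, repli_rows = [], [], [], []
    for chrom, sub in genes.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        chrom_len = chrom_lengths[chrom]

        # ATAC: background + class-rate peaks in gene windows
        for start in range(0, chrom_len - 300, 100000):
            if rng.random() < 0.5:
                pos = int(rng.integers(start, min(start + 100000, chrom_len - 300)))
                atac_rows.append({"chrom": chrom, "start": pos, "end": pos + 300})
        for row in sub.itertuples(index=False):
            params = config.classes[class_of[row.gene_id]]
            w_start = max(0, row.start - flank)
            w_end = min(chrom_len, row.end + flank)
            n_peaks = rng.poisson(params.atac_rate * (w_end - w_start) / 1000.0)
            for _ in range(n_peaks):
                pos = int(rng.integers(w_start, max(w_start + 1, w_end - 300)))
                atac_rows.append({"chrom": chrom, "start": pos, "end": pos + 300})

        # LADs: cover genes with class-dependent probability, then merge
        lad_intervals = []
        for row in sub.itertuples(index=False):
            params = config.classes[class_of[row.gene_id]]
            if rng.random() < params.lad_prob:
                lad_intervals.append(
                    (
                        max(0, row.start - int(rng.integers(1000, 5000))),
                        min(chrom_len, row.end + int(rng.integers(1000, 5000))),
                    )
                )
        for start, end in _merge_intervals(lad_intervals):
            lad_rows.append({"chrom": chrom, "start": start, "end": end})

        # TADs: cut positions between genes (class of the downstream gene)
        # and, with class probability, inside the gene itself
        cuts = [0, chrom_len]
        prev_end = 0
        for row in sub.itertuples(index=False):
            params = config.classes[class_of[row.gene_id]]
            if rng.random() < params.tad_gap_cut_prob:
                cuts.append(int((prev_end + row.start) / 2))
            if rng.random() < params.tad_split_prob:
                cuts.append(int((row.start + row.end) / 2))
            prev_end = row.end
        cuts = sorted(set(cuts))
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a >= 5000:
                tad_rows.append({"chrom": chrom, "start": a, "end": b})

        # Repli-seq: smooth baseline + class offset over gene bodies
        n_bins = max(1, chrom_len // config.repli_bin)
        starts = np.arange(n_bins) * config.repli_bin
        mids = starts + config.repli_bin / 2
        signal = 55.0 + 15.0 * np.sin(2 * np.pi * mids / 4e6)
        offsets = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for row in sub.itertuples(index=False):
            params = config.classes[class_of[row.gene_id]]
            b0 = row.start // config.repli_bin
            b1 = min(n_bins - 1, row.end // config.repli_bin)
            offsets[b0 : b1 + 1] += params.repli_offset
            counts[b0 : b1 + 1] += 1
        signal = signal + np.where(counts > 0, offsets / np.maximum(counts, 1), 0.0)
        signal = np.clip(signal + rng.normal(0, 3, size=n_bins), 0.0, 100.0)
        for s, v in zip(starts, signal):
            repli_rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(min(s + config.repli_bin, chrom_len)),
                    "score": round(float(v), 3),
                }
            )

    def frame(rows, cols):
        return (
            pd.DataFrame(rows, columns=cols)
            .sort_values(["chrom", "start"])
            .reset_index(drop=True)
        )

    return {
        "atac": frame(atac_rows, ["chrom", "start", "end"]),
        "tads": frame(tad_rows, ["chrom", "start", "end"]),
        "lads": frame(lad_rows, ["chrom", "start", "end"]),
        "repli": frame(repli_rows, ["chrom", "start", "end", "score"]),
    }


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# file output


def write_cohort(config: CohortConfig, outdir) -> dict[str, Path]:
    """Generate the full cohort and write every input file the pipeline reads.

    Writes taxonomy.yaml, trees.nwk (one Newick per line, truth-table
    order), genome.fa, genes.gff3, expression.tsv, scores.tsv,
    variants.tsv, atac.bed, tads.bed, lads.bed, repli.bedgraph and
    truth.tsv into *outdir*; returns the path of each output keyed by name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    taxonomy = simulate_taxonomy(config)
    newicks, truth = simulate_gene_histories(taxonomy, config)
    sequences, genes = simulate_genome_layout(truth, config)
    chrom_lengths = {chrom: len(seq) for chrom, seq in sequences.items()}
    expression = simulate_expression(truth, config)
    scores, variants = simulate_scores_and_variants(genes, truth, config)
    tracks = simulate_tracks(genes, truth, config, chrom_lengths)

    paths: dict[str, Path] = {}

    paths["taxonomy"] = outdir / "taxonomy.yaml"
    paths["taxonomy"].write_text(taxonomy.to_yaml())

    paths["trees"] = outdir / "trees.nwk"
    paths["trees"].write_text("\n".join(newicks) + "\n")

    paths["genome"] = outdir / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    paths["annotation"] = outdir / "genes.gff3"
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for row in genes.sort_values(["chrom", "start"]).itertuples(index=False):
            fh.write(
                f"{row.chrom}\telusivegenes_sim\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )

    paths["expression"] = outdir / "expression.tsv"
    expression.round(4).to_csv(paths["expression"], sep="\t")

    paths["scores"] = outdir / "scores.tsv"
    scores.round(5).to_csv(paths["scores"], sep="\t", index=False)

    paths["variants"] = outdir / "variants.tsv"
    variants.to_csv(paths["variants"], sep="\t", index=False)

    for key, fname in (("atac", "atac.bed"), ("tads", "tads.bed"), ("lads", "lads.bed")):
        paths[key] = outdir / fname
        tracks[key].to_csv(paths[key], sep="\t", index=False, header=False)
    paths["repli"] = outdir / "repli.bedgraph"
    tracks["repli"].to_csv(paths["repli"], sep="\t", index=False, header=False)

    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
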