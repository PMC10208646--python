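"""Synthetic cohort generator: determinism, planted structure, round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

from elusivegenes.expression import expression_features
from elusivegenes.simulate import (
    ClassParams,
    CohortConfig,
    default_class_params,
    simulate_expression,
    simulate_gene_histories,
    simulate_genome_layout,
    simulate_taxonomy,
    write_cohort,
)
from elusivegenes.taxonomy import load_taxonomy, species_ages


def small_config(**kw):
    defaults = dict(seed=11, n_groups=6, species_per_group=2,
                    n_genes={"loss_prone": 40, "conserved": 60})
    defaults.update(kw)
    return CohortConfig(**defaults)


# ---------------------------------------------------------------------------
# taxonomy


def test_taxonomy_counts_and_invariants():
    tax = simulate_taxonomy(CohortConfig(n_groups=15, species_per_group=3))
    assert len(tax.species) == 46  # 15 groups x 3 + focal
    assert len(tax.focal_groups) == 15
    assert tax.focal_species == "focal"
    ages = species_ages(tax)
    assert ages["focal"] == 0
    assert max(ages.values()) >= 2  # ladder gives a spread of divergence ranks


def test_taxonomy_deterministic():
    a = simulate_taxonomy(small_config())
    b = simulate_taxonomy(small_config())
    assert a.to_yaml() == b.to_yaml()


def test_taxonomy_round_trips_through_loader():
    tax = simulate_taxonomy(small_config())
    reloaded = load_taxonomy(tax.to_yaml())
    assert reloaded.species == tax.species
    assert reloaded.focal_groups == tax.focal_groups


# ---------------------------------------------------------------------------
# gene histories


def test_zero_loss_rate_gives_all_non_elusive():
    cfg = small_config(
        classes={
            "loss_prone": ClassParams(loss_rate=0.0, dup_prob=0.0),
            "conserved": ClassParams(loss_rate=0.0, dup_prob=0.0),
        }
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    assert (truth["planted_fate"] == "non_elusive").all()
    assert (truth["n_present_species"] == len(tax.species)).all()


def test_histories_deterministic_byte_identical():
    cfg = small_config()
    tax = simulate_taxonomy(cfg)
    trees_a, truth_a = simulate_gene_histories(tax, cfg)
    trees_b, truth_b = simulate_gene_histories(tax, cfg)
    assert trees_a == trees_b
    pd.testing.assert_frame_equal(truth_a, truth_b)


def test_per_branch_loss_rate_matches_analytic_expectation():
    """Each off-focal branch loses the gene with probability 1 - exp(-lambda)."""
    lam = 0.2
    cfg = CohortConfig(
        seed=5, n_groups=4, species_per_group=2,
        n_genes={"loss_prone": 2000, "conserved": 0},
        classes={"loss_prone": ClassParams(loss_rate=lam), "conserved": ClassParams()},
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    # the branch into the outermost superclade is always reachable
    outer = tax.root.children[0].name
    hit = truth["lost_branches"].fillna("").str.split(",").apply(lambda b: outer in b)
    p_hat = hit.mean()
    p = 1 - math.exp(-lam)
    se = math.sqrt(p * (1 - p) / len(truth))
    assert abs(p_hat - p) < 4 * se


def test_planted_fates_consistent_with_counts():
    cfg = small_config()
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    for row in truth.itertuples(index=False):
        if row.planted_fate == "elusive":
            assert row.n_true_losses >= 2 and row.n_duplicates <= 3
        elif row.planted_fate == "non_elusive":
            assert row.n_present_species == len(tax.species) and row.n_duplicates == 0


# ---------------------------------------------------------------------------
# genome layout


def test_gc_concentration_around_class_parameter():
    cfg = small_config(
        n_genes={"loss_prone": 50, "conserved": 50},
        classes={
            "loss_prone": ClassParams(gc=0.60, gene_length_median=10_000),
            "conserved": ClassParams(gc=0.40, gene_length_median=10_000),
        },
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    sequences, genes = simulate_genome_layout(truth, cfg)
    class_of = dict(zip(truth["gene_id"], truth["planted_class"]))
    totals = {"loss_prone": [0, 0], "conserved": [0, 0]}
    for row in genes.itertuples(index=False):
        span = sequences[row.chrom][row.start : row.end]
        cls = class_of[row.gene_id]
        totals[cls][0] += span.count("G") + span.count("C")
        totals[cls][1] += len(span)
    assert totals["loss_prone"][0] / totals["loss_prone"][1] == pytest.approx(0.60, abs=0.01)
    assert totals["conserved"][0] / totals["conserved"][1] == pytest.approx(0.40, abs=0.01)


def test_spacing_ratio_shows_in_mean_gaps():
    cfg = small_config(
        n_genes={"loss_prone": 150, "conserved": 150},
        classes={
            "loss_prone": ClassParams(spacing_mean=10_000),
            "conserved": ClassParams(spacing_mean=50_000),
        },
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    _, genes = simulate_genome_layout(truth, cfg)
    class_of = dict(zip(truth["gene_id"], truth["planted_class"]))
    gaps = {"loss_prone": [], "conserved": []}
    for _, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        prev_end = None
        for row in sub.itertuples(index=False):
            if prev_end is not None:
                gaps[class_of[row.gene_id]].append(row.start - prev_end)
            prev_end = row.end
    ratio = np.mean(gaps["conserved"]) / np.mean(gaps["loss_prone"])
    assert 3.0 < ratio < 7.0  # ~5x by construction, Monte Carlo slack


# ---------------------------------------------------------------------------
# expression


def test_huge_alpha_approaches_uniform_entropy():
    cfg = small_config(
        n_genes={"loss_prone": 0, "conserved": 50},
        classes={
            "loss_prone": ClassParams(),
            "conserved": ClassParams(dirichlet_alpha=1e4),
        },
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    mat = simulate_expression(truth, cfg)
    h = expression_features(mat)["h_prime"]
    assert (h > math.log(cfg.n_tissues) - 0.01).all()


def test_small_alpha_entropy_matches_dirichlet_expectation():
    """Mean H' of Dirichlet(alpha) profiles equals psi(R*alpha+1) - psi(alpha+1)."""
    from scipy.special import digamma

    alpha, R = 0.05, 54
    cfg = small_config(
        n_genes={"loss_prone": 500, "conserved": 0},
        classes={
            "loss_prone": ClassParams(dirichlet_alpha=alpha),
            "conserved": ClassParams(),
        },
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    h = expression_features(simulate_expression(truth, cfg))["h_prime"]
    expected = digamma(R * alpha + 1) - digamma(alpha + 1)
    assert h.mean() == pytest.approx(expected, abs=0.1)
    # and the restricted class sits far below the broadly expressed one
    assert h.mean() < math.log(R) - 2.0


def test_zero_fraction_recovered_binomially():
    frac = 0.2
    cfg = small_config(
        n_genes={"loss_prone": 1000, "conserved": 0},
        classes={
            "loss_prone": ClassParams(zero_expression_frac=frac, dirichlet_alpha=5.0),
            "conserved": ClassParams(),
        },
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    mat = simulate_expression(truth, cfg)
    observed = (mat.sum(axis=1) == 0).mean()
    se = math.sqrt(frac * (1 - frac) / len(mat))
    assert abs(observed - frac) < 4 * se


# ---------------------------------------------------------------------------
# full cohort files


def test_cohort_files_deterministic_and_round_trip(tmp_path):
    cfg = small_config(n_genes={"loss_prone": 15, "conserved": 25})
    paths_a = write_cohort(cfg, tmp_path / "a")
    paths_b = write_cohort(cfg, tmp_path / "b")
    for key in paths_a:
        assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key

    # generated files parse with the package's own readers
    from elusivegenes.expression import read_expression_tsv
    from elusivegenes.genome import GenomeAnnotation, VariantSet
    from elusivegenes.tracks import IntervalTrack

    tax = load_taxonomy(paths_a["taxonomy"])
    assert len(tax.focal_groups) == 6
    ann = GenomeAnnotation.from_gff3(paths_a["annotation"])
    assert len(ann) == 40
    mat = read_expression_tsv(paths_a["expression"])
    assert mat.shape == (40, cfg.n_tissues)
    VariantSet.read_tsv(paths_a["variants"])
    for key in ("atac", "tads", "lads"):
        assert len(IntervalTrack.read_bed(paths_a[key])) > 0
    assert IntervalTrack.read_bedgraph(paths_a["repli"]).has_scores
    truth = pd.read_csv(paths_a["truth"], sep="\t")
    assert set(truth["gene_id"]) == set(ann.genes)


def test_lad_odds_parameter_recovery():
    """The planted LAD odds ratio (3 by default) is recovered from the BED track."""
    from elusivegenes.genome import GeneModel
    from elusivegenes.simulate import simulate_tracks
    from elusivegenes.tracks import IntervalTrack, lad_overlap_flag

    base = default_class_params()
    p_e, p_c = base["loss_prone"].lad_prob, base["conserved"].lad_prob
    target = (p_e / (1 - p_e)) / (p_c / (1 - p_c))
    assert target == pytest.approx(3.0)

    cfg = CohortConfig(
        seed=3, n_groups=4, species_per_group=2,
        n_genes={"loss_prone": 1000, "conserved": 1000},
        classes={
            # small, widely spaced genes so merged LAD extensions rarely
            # spill over onto a neighbouring gene
            "loss_prone": ClassParams(lad_prob=p_e, gene_length_median=1000,
                                      spacing_mean=25_000),
            "conserved": ClassParams(lad_prob=p_c, gene_length_median=1000,
                                     spacing_mean=25_000),
        },
    )
    tax = simulate_taxonomy(cfg)
    _, truth = simulate_gene_histories(tax, cfg)
    _, genes = simulate_genome_layout(truth, cfg)
    chrom_lengths = genes.groupby("chrom")["end"].max().add(1000).to_dict()
    tracks = simulate_tracks(genes, truth, cfg, chrom_lengths)
    lads = IntervalTrack("lads", tracks["lads"])
    class_of = dict(zip(truth["gene_id"], truth["planted_class"]))
    rates = {"loss_prone": [], "conserved": []}
    for row in genes.itertuples(index=False):
        gene = GeneModel(row.gene_id, row.chrom, row.start, row.end)
        rates[class_of[row.gene_id]].append(lad_overlap_flag(gene, lads))
    f_e, f_c = np.mean(rates["loss_prone"]), np.mean(rates["conserved"])
    odds = (f_e / (1 - f_e)) / (f_c / (1 - f_c))
    assert abs(odds - target) / target < 0.25
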