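"""Branch collapse, age-balanced rooting, event annotation, orthogroup extraction."""

import itertools
import random

import dendropy
import pytest

from elusivegenes.genetree import (
    OrthologGroup,
    annotate_species_overlap_events,
    collapse_short_branches,
    extract_focal_subtrees,
    infer_gene_age,
    parse_leaf_label,
    read_gene_tree,
    root_by_age_balance,
)


def leaves(tree):
    return sorted(l.taxon.label for l in tree.leaf_node_iter())


def n_internal(tree):
    return sum(1 for n in tree.preorder_node_iter() if not n.is_leaf())


# ---------------------------------------------------------------------------
# collapse


def test_collapse_short_internal_edge():
    tree = read_gene_tree("((A|1:1,B|1:1):0.001,C|1:1);")
    out = collapse_short_branches(tree, 0.0025)
    assert out.as_string(schema="newick").count("(") == 1  # fully multifurcated
    assert leaves(out) == ["A|1", "B|1", "C|1"]


def test_collapse_no_op_when_all_edges_long():
    tree = read_gene_tree("((A|1:1,B|1:1):0.5,(C|1:1,D|1:1):0.5);")
    before = tree.as_string(schema="newick")
    assert collapse_short_branches(tree, 0.0025).as_string(schema="newick") == before


def test_collapse_boundary_is_strict():
    tree = read_gene_tree("((A|1:1,B|1:1):0.0025,C|1:1);")
    out = collapse_short_branches(tree, 0.0025)
    assert n_internal(out) == n_internal(tree)


def test_collapse_never_removes_leaf_edges():
    tree = read_gene_tree("((A|1:0.0001,B|1:0.0001):0.0001,C|1:0.0001);")
    out = collapse_short_branches(tree)
    assert leaves(out) == ["A|1", "B|1", "C|1"]


def _random_tree(rng, n_leaves, short_prob=0.4):
    taxa = [f"s{i}|g{i}" for i in range(n_leaves)]
    nodes = [f"'{t}':1.0" for t in taxa]
    while len(nodes) > 1:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        length = 0.001 if rng.random() < short_prob else 0.5
        nodes.append(f"({a},{b}):{length}")
    return nodes[0].rsplit(":", 1)[0] + ";"


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_collapse_removes_exactly_the_short_internal_edges(seed):
    rng = random.Random(seed)
    tree = read_gene_tree(_random_tree(rng, 50))
    short_internal = sum(
        1
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None
        and not e.head_node.is_leaf()
        and e.length is not None
        and e.length < 0.0025
    )
    out = collapse_short_branches(tree)
    assert n_internal(tree) - n_internal(out) == short_internal
    assert leaves(out) == leaves(tree)


def test_collapse_is_idempotent():
    rng = random.Random(3)
    tree = read_gene_tree(_random_tree(rng, 30))
    once = collapse_short_branches(tree)
    twice = collapse_short_branches(once)
    assert once.as_string(schema="newick") == twice.as_string(schema="newick")


# ---------------------------------------------------------------------------
# rooting


AGES = {"human": 0, "chimp": 1, "mouse": 2, "dog": 3, "frog": 4}


def _bipartitions_of_root(tree):
    kids = tree.seed_node.child_nodes()
    return [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]


def test_triplet_rooting_places_oldest_as_outgroup():
    tree = read_gene_tree("((human|h:1,chimp|c:1):1,mouse|m:1);")
    rooted = root_by_age_balance(tree, AGES, "human")
    sides = _bipartitions_of_root(rooted)
    assert frozenset(["mouse|m"]) in sides


def test_two_leaf_tree_rooted_on_only_edge():
    tree = read_gene_tree("(human|h:1,mouse|m:1);")
    rooted = root_by_age_balance(tree, AGES, "human")
    assert sorted(map(sorted, _bipartitions_of_root(rooted))) == [["human|h"], ["mouse|m"]]


def test_rooting_rejects_single_leaf():
    with pytest.raises(ValueError):
        root_by_age_balance(read_gene_tree("human|h:1;"), AGES, "human")


def _score_of_side(labels, ages):
    species = [parse_leaf_label(l)[0] for l in labels]
    return (min(ages[s] for s in species), -len(labels))


def _exhaustive_best_score(tree, ages, focal):
    """Enumerate every leaf bipartition of the unrooted topology and score it."""
    all_labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    best = None
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        lower = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        upper = all_labels - lower
        if not lower or not upper:
            continue
        lower_f = any(parse_leaf_label(l)[0] == focal for l in lower)
        upper_f = any(parse_leaf_label(l)[0] == focal for l in upper)
        sides = [upper if lower_f else lower] if lower_f != upper_f else [lower, upper]
        for side in sides:
            key = _score_of_side(side, ages)
            if best is None or key > best:
                best = key
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_rooting_attains_exhaustive_maximum_score(seed):
    rng = random.Random(seed)
    species = list(AGES)
    labels = [f"{rng.choice(species)}|g{i}" for i in range(rng.randint(4, 12))]
    if not any(l.startswith("human") for l in labels):
        labels[0] = "human|g0"
    nodes = [f"'{l}':1.0" for l in labels]
    while len(nodes) > 1:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2):.3f}")
    tree = read_gene_tree(nodes[0].rsplit(":", 1)[0] + ";")
    best = _exhaustive_best_score(tree, AGES, "human")
    rooted = root_by_age_balance(tree, AGES, "human")
    # one of the two root-child sides must attain the exhaustive maximum
    side_scores = []
    for side in _bipartitions_of_root(rooted):
        if not any(parse_leaf_label(l)[0] == "human" for l in side):
            side_scores.append(_score_of_side(side, AGES))
    assert best in side_scores or not side_scores


# ---------------------------------------------------------------------------
# event annotation


def rooted(newick):
    tree = read_gene_tree(newick)
    tree.is_rooted = True
    return tree


def events_by_leafset(tree, events):
    return {
        frozenset(l.taxon.label for l in node.leaf_iter()): label
        for node, label in events.items()
    }


def test_all_speciation_when_each_species_unique():
    tree = rooted("((human|h:1,chimp|c:1):1,(mouse|m:1,dog|d:1):1);")
    events = annotate_species_overlap_events(tree)
    assert set(events.values()) == {"speciation"}


def test_duplication_at_root_of_two_copies():
    tree = rooted("((H|1:1,M|1:1):1,(H|2:1,M|2:1):1);")
    ev = events_by_leafset(tree, annotate_species_overlap_events(tree))
    assert ev[frozenset(["H|1", "M|1", "H|2", "M|2"])] == "duplication"
    assert ev[frozenset(["H|1", "M|1"])] == "speciation"
    assert ev[frozenset(["H|2", "M|2"])] == "speciation"


def test_unrooted_tree_rejected():
    tree = read_gene_tree("((A|1:1,B|1:1):1,C|1:1);")
    tree.is_rooted = False
    with pytest.raises(ValueError):
        annotate_species_overlap_events(tree)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_events_match_pairwise_intersection_oracle(seed):
    rng = random.Random(seed)
    species = ["a", "b", "c", "d"]
    labels = [f"{rng.choice(species)}|g{i}" for i in range(10)]
    nodes = [f"'{l}':1.0" for l in labels]
    while len(nodes) > 1:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        nodes.append(f"({a},{b}):1.0")
    tree = rooted(nodes[0].rsplit(":", 1)[0] + ";")
    events = annotate_species_overlap_events(tree)
    for node, label in events.items():
        child_sets = [
            {parse_leaf_label(l.taxon.label)[0] for l in c.leaf_iter()}
            for c in node.child_nodes()
        ]
        overlap = any(
            s1 & s2 for s1, s2 in itertools.combinations(child_sets, 2)
        )
        assert label == ("duplication" if overlap else "speciation")


def test_events_invariant_under_child_order():
    a = rooted("((H|1:1,M|1:1):1,(H|2:1,M|2:1):1);")
    b = rooted("((M|2:1,H|2:1):1,(M|1:1,H|1:1):1);")
    ev_a = events_by_leafset(a, annotate_species_overlap_events(a))
    ev_b = events_by_leafset(b, annotate_species_overlap_events(b))
    shared = set(ev_a) & set(ev_b)
    assert {k: ev_a[k] for k in shared} == {k: ev_b[k] for k in shared}


# ---------------------------------------------------------------------------
# extraction and gene age


def test_two_copies_give_two_groups_with_one_duplicate():
    tree = rooted("((H|1:1,M|1:1):1,(H|2:1,M|2:1):1);")
    events = annotate_species_overlap_events(tree)
    groups = extract_focal_subtrees(tree, events, "H")
    assert len(groups) == 2
    assert {g.focal_gene_id for g in groups} == {"1", "2"}
    assert all(g.n_duplicates == 1 for g in groups)
    assert all(g.species() == {"H", "M"} for g in groups)


def test_duplication_free_tree_gives_single_full_group():
    tree = rooted("((H|h:1,C|c:1):1,(M|m:1,D|d:1):1);")
    events = annotate_species_overlap_events(tree)
    groups = extract_focal_subtrees(tree, events, "H")
    assert len(groups) == 1
    assert groups[0].species() == {"H", "C", "M", "D"}
    assert groups[0].n_duplicates == 0


def test_no_focal_leaf_yields_empty_list():
    tree = rooted("((A|1:1,B|1:1):1,C|1:1);")
    events = annotate_species_overlap_events(tree)
    assert extract_focal_subtrees(tree, events, "H") == []


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_groups_partition_focal_leaves(seed):
    rng = random.Random(seed)
    species = ["H", "a", "b", "c"]
    labels = [f"{rng.choice(species)}|g{i}" for i in range(12)]
    nodes = [f"'{l}':1.0" for l in labels]
    while len(nodes) > 1:
        rng.shuffle(nodes)
        x, y = nodes.pop(), nodes.pop()
        nodes.append(f"({x},{y}):1.0")
    tree = rooted(nodes[0].rsplit(":", 1)[0] + ";")
    events = annotate_species_overlap_events(tree)
    groups = extract_focal_subtrees(tree, events, "H")
    focal_in_tree = [l for l in labels if l.startswith("H|")]
    emitted = [g.focal_gene_id for g in groups]
    assert sorted(emitted) == sorted(l.split("|")[1] for l in focal_in_tree)
    tree_species = {parse_leaf_label(l)[0] for l in labels}
    for g in groups:
        assert g.species() <= tree_species
        assert g.n_duplicates == len(focal_in_tree) - 1


def test_gene_age_is_max_over_members_and_external():
    group = OrthologGroup(focal_gene_id="g", members={"human": ["g"], "chimp": ["x"]})
    assert infer_gene_age(group, AGES) == 1
    assert infer_gene_age(group, AGES, external_age=4) == 4
    assert infer_gene_age(group, AGES, external_age=0) == 1
    with pytest.raises(KeyError):
        infer_gene_age(
            OrthologGroup(focal_gene_id="g", members={"alien": ["y"]}), AGES
        )
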