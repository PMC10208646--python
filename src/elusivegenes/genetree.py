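"""Gene-tree post-processing: branch collapse, rooting, events, orthogroups.

Input gene trees come from standard maximum-likelihood inference and are
consumed as Newick with leaf labels ``SPECIES|GENEID`` (delimiter
configurable). Four steps prepare them for presence/absence profiling:

1. ambiguously resolved bifurcations -- internal branches shorter than
   0.0025 substitutions/site -- are collapsed into multifurcations;
2. the tree is rooted on the edge that best separates the oldest lineages
   from the focal species (age-balanced outgroup selection);
3. every internal node is labelled duplication or speciation by the
   species-overlap rule (duplication iff the species sets of at least two
   child subtrees intersect);
4. maximal duplication-free subtrees containing a focal-species leaf are
   emitted as ortholog groups, and a gene age (divergence rank of the
   oldest member lineage) is assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy

__all__ = [
    "DEFAULT_MIN_BRANCH_LENGTH",
    "LEAF_DELIMITER",
    "OrthologGroup",
    "read_gene_tree",
    "parse_leaf_label",
    "leaf_species",
    "collapse_short_branches",
    "root_by_age_balance",
    "annotate_species_overlap_events",
    "extract_focal_subtrees",
    "infer_gene_age",
]

DEFAULT_MIN_BRANCH_LENGTH = 0.0025
LEAF_DELIMITER = "|"

DUPLICATION = "duplication"
SPECIATION = "speciation"


@dataclass
class OrthologGroup:
    """Per-species gene sets of one maximal duplication-free subtree.

    ``n_duplicates`` counts the *additional* focal-species copies present
    anywhere in the source tree's family (total focal leaves minus one); it
    is therefore identical for every group emitted from one tree.
    """

    focal_gene_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    source_tree_id: str = ""
    n_duplicates: int = 0

    def species(self) -> set[str]:
        return set(self.members)


def parse_leaf_label(label: str, delimiter: str = LEAF_DELIMITER) -> tuple[str, str]:
    """Split a leaf label into (species_id, gene_id)."""
    if delimiter not in label:
        raise ValueError(f"leaf label {label!r} lacks delimiter {delimiter!r}")
    species, gene = label.split(delimiter, 1)
    return species, gene


def leaf_species(node: dendropy.Node, delimiter: str = LEAF_DELIMITER) -> str:
    return parse_leaf_label(node.taxon.label, delimiter)[0]


def read_gene_tree(source: str, schema: str = "newick") -> dendropy.Tree:
    """Read a gene tree from a Newick string or a file path."""
    if "(" in source or source.rstrip().endswith(";"):
        tree = dendropy.Tree.get(data=source, schema=schema, preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=source, schema=schema, preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in gene tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and not edge.length >= 0:
            raise ValueError(f"negative or non-finite branch length: {edge.length}")
    return tree


def collapse_short_branches(
    tree: dendropy.Tree, min_len: float = DEFAULT_MIN_BRANCH_LENGTH
) -> dendropy.Tree:
    """Collapse internal branches shorter than *min_len* into multifurcations.

    The comparison is strict (< min_len); branches of exactly min_len are
    kept. Leaf branches are never collapsed. The input tree is not
    modified. Idempotent.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    out = tree.clone(depth=1)
    short = [
        edge
        for edge in out.preorder_edge_iter()
        if edge.tail_node is not None
        and not edge.head_node.is_leaf()
        and edge.length is not None
        and edge.length < min_len
    ]
    for edge in short:
        edge.collapse()
    return out


def root_by_age_balance(
    tree: dendropy.Tree,
    ages: dict[str, int],
    focal_species: str,
    delimiter: str = LEAF_DELIMITER,
) -> dendropy.Tree:
    """Root on the edge whose far side is the oldest lineage (the outgroup).

    Every edge of the (arbitrarily rooted) input topology is a candidate
    root. For a candidate, the outgroup side S is the side containing no
    focal-species leaf (if exactly one such side exists; otherwise both
    sides are scored and the better one used). Candidates are ranked by

    1. larger minimum divergence rank over the species in S (oldest
       lineages make the cleanest outgroup),
    2. then smaller ``|S|``,
    3. then lexicographically smallest leaf label in S,

    and the winner becomes the root edge, split at its midpoint. The
    procedure is deterministic.
    """
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("cannot root a tree with fewer than 2 leaves")
    for leaf in leaves:
        sp = leaf_species(leaf, delimiter)
        if sp not in ages:
            raise KeyError(f"species {sp!r} absent from age map")

    work = tree.clone(depth=1)
    all_labels = frozenset(l.taxon.label for l in work.leaf_node_iter())

    # Leaf-label set below each edge (head-node side), computed postorder.
    below: dict[dendropy.Edge, frozenset[str]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            below[node.edge] = frozenset([node.taxon.label])
        else:
            below[node.edge] = frozenset().union(*(below[c.edge] for c in node.child_nodes()))

    def side_key(labels: frozenset[str]):
        species = [parse_leaf_label(l, delimiter)[0] for l in labels]
        return (min(ages[s] for s in species), -len(labels))

    best = None  # (key, tie_label, edge)
    for edge in work.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        lower = below[edge]
        upper = all_labels - lower
        if not lower or not upper:
            continue
        sides = []
        lower_has_focal = any(parse_leaf_label(l, delimiter)[0] == focal_species for l in lower)
        upper_has_focal = any(parse_leaf_label(l, delimiter)[0] == focal_species for l in upper)
        if lower_has_focal != upper_has_focal:
            sides = [upper if lower_has_focal else lower]
        else:
            sides = [lower, upper]
        for side in sides:
            key = side_key(side)
            tie = min(side)
            if (
                best is None
                or key > best[0]
                or (key == best[0] and tie < best[1])
            ):
                best = (key, tie, edge)

    _, _, root_edge = best
    length = root_edge.length
    if length is None:
        work.reroot_at_edge(root_edge, update_bipartitions=False)
    else:
        work.reroot_at_edge(
            root_edge, length1=length / 2.0, length2=length / 2.0, update_bipartitions=False
        )
    work.is_rooted = True
    return work


def annotate_species_overlap_events(
    tree: dendropy.Tree, delimiter: str = LEAF_DELIMITER
) -> dict[dendropy.Node, str]:
    """Label each internal node duplication or speciation by species overlap.

    A node is a duplication iff some species occurs in the subtrees of at
    least two of its children (species-overlap threshold 0); multifurcating
    nodes are duplications if any pair of children overlaps. The labelling
    is invariant under permuting children.
    """
    if not tree.is_rooted:
        raise ValueError("species-overlap annotation requires a rooted tree")
    events: dict[dendropy.Node, str] = {}
    species_below: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            species_below[node] = {leaf_species(node, delimiter)}
            continue
        child_sets = [species_below[c] for c in node.child_nodes()]
        union: set[str] = set().union(*child_sets)
        overlap = len(union) < sum(len(s) for s in child_sets)
        events[node] = DUPLICATION if overlap else SPECIATION
        species_below[node] = union
    return events


def extract_focal_subtrees(
    tree: dendropy.Tree,
    events: dict[dendropy.Node, str],
    focal_species: str,
    delimiter: str = LEAF_DELIMITER,
    source_tree_id: str = "",
) -> list[OrthologGroup]:
    """Emit one ortholog group per maximal duplication-free subtree with a focal leaf.

    A subtree is duplication-free when none of its internal nodes is
    labelled duplication; within such a subtree every species occurs at
    most once, so each group carries exactly one focal-species gene. Trees
    without a focal-species leaf yield an empty list.
    """
    dup_free: dict[dendropy.Node, bool] = {}
    focal_total = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            dup_free[node] = True
            if leaf_species(node, delimiter) == focal_species:
                focal_total += 1
        else:
            dup_free[node] = events.get(node) != DUPLICATION and all(
                dup_free[c] for c in node.child_nodes()
            )

    groups: list[OrthologGroup] = []

    def visit(node: dendropy.Node) -> None:
        if dup_free[node]:
            members: dict[str, list[str]] = {}
            focal_gene = None
            for leaf in node.leaf_iter():
                sp, gid = parse_leaf_label(leaf.taxon.label, delimiter)
                members.setdefault(sp, []).append(gid)
                if sp == focal_species:
                    focal_gene = gid
            if focal_gene is not None:
                groups.append(
                    OrthologGroup(
                        focal_gene_id=focal_gene,
                        members=members,
                        source_tree_id=source_tree_id,
                        n_duplicates=focal_total - 1,
                    )
                )
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.seed_node)
    return groups


def infer_gene_age(
    group: OrthologGroup,
    ages: dict[str, int],
    external_age: Optional[int] = None,
) -> int:
    """Divergence rank of the oldest member lineage of an ortholog group.

    An externally supplied age (e.g. from a curated gene-tree database) is
    adopted whenever it is older than the age implied by the group itself.
    """
    if not group.members:
        raise ValueError("empty ortholog group has no age")
    try:
        internal = max(ages[sp] for sp in group.members)
    except KeyError as exc:
        raise KeyError(f"species {exc.args[0]!r} absent from age map") from exc
    if external_age is not None:
        return max(internal, external_age)
    return internal
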