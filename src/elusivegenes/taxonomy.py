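"""Species taxonomy with designated focal taxonomic groups.

The taxonomy is the reference frame for gene-loss inference: a rooted
hierarchy of named clades whose leaves are species, a designated focal
species (the "human" role), and an ordered list of focal groups -- clades,
typically of order-to-family rank, within which a gene must be absent from
*every* member species before a loss in the group's common ancestor is
called.

The on-disk format is a small YAML document::

    focal_species: human
    focal_groups: [Primates, Rodentia]
    tree:
      name: Mammalia
      children:
        - name: Primates
          species: [human, chimp]
        - name: Rodentia
          species: [mouse, rat]
        - shrew          # bare string = ungrouped leaf species

Internal nodes may nest arbitrarily (``children`` of mappings or strings).
Unnamed internal nodes receive deterministic names at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import yaml

__all__ = ["CladeNode", "Taxonomy", "load_taxonomy", "species_ages"]


@dataclass(eq=False)  # identity semantics: nodes key dicts during traversals
class CladeNode:
    """One node of the species hierarchy; leaves carry a species id as name."""

    name: str
    children: list["CladeNode"] = field(default_factory=list)
    parent: Optional["CladeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["CladeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def species_under(self) -> set[str]:
        return {leaf.name for leaf in self.leaves()}

    def postorder(self) -> Iterator["CladeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self


class TaxonomyError(ValueError):
    """Invalid taxonomy definition."""


class Taxonomy:
    """Rooted species hierarchy with focal groups and a focal species.

    Invariants enforced at construction:

    * clade names and species identifiers are unique;
    * every focal group names an internal clade (hence is connected);
    * focal groups are pairwise disjoint in their member species;
    * the focal species is a leaf and belongs to at most one group.

    Species assigned to no focal group are permitted; they participate only
    in the "present in all examined species" (non-elusive) test, never in
    group-level loss calls.
    """

    def __init__(self, root: CladeNode, focal_groups: Sequence[str], focal_species: str):
        self.root = root
        self.focal_groups: list[str] = list(focal_groups)
        self.focal_species = focal_species

        self.clades: dict[str, CladeNode] = {}
        self.species: list[str] = []
        for node in root.postorder():
            for child in node.children:
                child.parent = node
            if node.is_leaf:
                if node.name in self.clades:
                    raise TaxonomyError(f"duplicate species id: {node.name!r}")
                self.species.append(node.name)
            elif node.name in self.clades:
                raise TaxonomyError(f"duplicate clade name: {node.name!r}")
            self.clades[node.name] = node
        root.parent = None

        if focal_species not in self.clades or not self.clades[focal_species].is_leaf:
            raise TaxonomyError(f"focal species {focal_species!r} is not a leaf of the hierarchy")

        self._group_of: dict[str, str] = {}
        for group in self.focal_groups:
            node = self.clades.get(group)
            if node is None or node.is_leaf:
                raise TaxonomyError(f"focal group {group!r} is not a clade of the hierarchy")
            for sp in node.species_under():
                if sp in self._group_of:
                    raise TaxonomyError(
                        f"species {sp!r} belongs to two focal groups "
                        f"({self._group_of[sp]!r} and {group!r})"
                    )
                self._group_of[sp] = group

    # -- lookups -----------------------------------------------------------

    def group_of(self, species: str) -> Optional[str]:
        """Focal group containing *species*, or None if ungrouped."""
        return self._group_of.get(species)

    def group_species(self, group: str) -> set[str]:
        return self.clades[group].species_under()

    def species_set(self) -> set[str]:
        return set(self.species)

    def to_mapping(self) -> dict:
        """Round-trippable plain mapping (YAML-serialisable)."""

        def node_to_obj(node: CladeNode):
            if node.is_leaf:
                return node.name
            if all(c.is_leaf for c in node.children):
                return {"name": node.name, "species": [c.name for c in node.children]}
            return {"name": node.name, "children": [node_to_obj(c) for c in node.children]}

        return {
            "focal_species": self.focal_species,
            "focal_groups": list(self.focal_groups),
            "tree": node_to_obj(self.root),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=False)


def _build_node(obj, counter: list[int]) -> CladeNode:
    if isinstance(obj, str):
        return CladeNode(name=obj)
    if not isinstance(obj, Mapping):
        raise TaxonomyError(f"malformed taxonomy node: {obj!r}")
    name = obj.get("name")
    if name is None:
        counter[0] += 1
        name = f"clade_{counter[0]}"
    children_spec = obj.get("children")
    species_spec = obj.get("species")
    if children_spec is None and species_spec is None:
        raise TaxonomyError(f"clade {name!r} has neither children nor species")
    children: list[CladeNode] = []
    if species_spec is not None:
        children.extend(CladeNode(name=sp) for sp in species_spec)
    if children_spec is not None:
        children.extend(_build_node(c, counter) for c in children_spec)
    return CladeNode(name=name, children=children)


def load_taxonomy(definition) -> Taxonomy:
    """Parse and validate a taxonomy definition.

    *definition* may be a YAML string, an already-parsed mapping, or a path
    to a YAML file (anything with a ``read`` method or an ``os.PathLike``).
    """
    if hasattr(definition, "read"):
        definition = definition.read()
    if isinstance(definition, (str, bytes)):
        text = definition
        if isinstance(text, bytes):
            text = text.decode()
        if "\n" not in text and text.strip().endswith((".yaml", ".yml")):
            with open(text) as fh:
                text = fh.read()
        definition = yaml.safe_load(text)
    elif hasattr(definition, "__fspath__"):
        with open(definition) as fh:
            definition = yaml.safe_load(fh)
    if not isinstance(definition, Mapping):
        raise TaxonomyError("taxonomy definition must be a mapping")
    for key in ("focal_species", "tree"):
        if key not in definition:
            raise TaxonomyError(f"taxonomy definition missing {key!r}")
    root = _build_node(definition["tree"], counter=[0])
    return Taxonomy(
        root=root,
        focal_groups=definition.get("focal_groups", []),
        focal_species=definition["focal_species"],
    )


def species_ages(taxonomy: Taxonomy) -> dict[str, int]:
    """Map each species to its divergence rank from the focal species.

    Rank 0 is the focal species itself; rank *k* means the species' lineage
    joins the focal lineage at the *k*-th ancestor of the focal leaf
    (counted outward), i.e. larger ranks split earlier from the focal
    species. Species within the same join clade share a rank, so the map is
    insensitive to the textual ordering of the definition.
    """
    ages = {taxonomy.focal_species: 0}
    node = taxonomy.clades[taxonomy.focal_species]
    rank = 0
    while node.parent is not None:
        rank += 1
        for sp in node.parent.species_under():
            ages.setdefault(sp, rank)
        node = node.parent
    missing = taxonomy.species_set() - ages.keys()
    if missing:  # disconnected leaves cannot occur in a tree; defensive
        raise TaxonomyError(f"species not connected to focal lineage: {sorted(missing)}")
    return ages
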