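"""Taxon-level loss inference and elusive / non-elusive classification.

A gene retained by the focal species is profiled against the taxonomy:
for each focal taxonomic group we count member species carrying at least
one ortholog. A group with zero presence is a candidate loss in that
group's common ancestor; sibling clades that are entirely absent merge,
recursively, into a single loss at their own common ancestor, so each
reported loss event is a maximal fully-absent clade. Single-species
absences inside an otherwise present group are treated as annotation
noise and never generate a loss event.

A focal gene is then

* **elusive** -- lost independently in >= 2 such clades, with at most 3
  extra focal-species duplicates in its family;
* **non_elusive** -- present in every examined species (grouped or not)
  and single-copy in the focal species;
* **unclassified** -- everything else, including genes demoted by an
  external exclusion list (synteny / homology-search validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genetree import OrthologGroup
from .taxonomy import CladeNode, Taxonomy

__all__ = [
    "PresenceProfile",
    "LossEvent",
    "GeneFateCall",
    "build_presence_profile",
    "infer_ancestral_losses",
    "classify_fate",
    "apply_exclusions",
    "calls_to_frame",
]

ELUSIVE = "elusive"
NON_ELUSIVE = "non_elusive"
UNCLASSIFIED = "unclassified"

MIN_LOSS_EVENTS = 2
MAX_DUPLICATES = 3


@dataclass
class PresenceProfile:
    """Ortholog presence of one focal gene across the taxonomy."""

    focal_gene_id: str
    group_counts: dict[str, tuple[int, int]]  # group -> (n present, n total)
    species_presence: dict[str, bool]  # every species, grouped or not

    def all_present(self) -> bool:
        return all(self.species_presence.values())


@dataclass(frozen=True)
class LossEvent:
    """A loss placed at the common ancestor of a maximal fully-absent clade."""

    clade: str
    covered_groups: tuple[str, ...]


@dataclass
class GeneFateCall:
    gene_id: str
    fate: str
    loss_events: list[LossEvent] = field(default_factory=list)
    n_duplicates: int = 0
    age: Optional[int] = None


def build_presence_profile(group: OrthologGroup, taxonomy: Taxonomy) -> PresenceProfile:
    """Count, per focal group, the member species with >= 1 ortholog."""
    unknown = group.species() - taxonomy.species_set()
    if unknown:
        raise KeyError(f"species not in taxonomy: {sorted(unknown)}")
    present = {sp for sp, genes in group.members.items() if genes}
    group_counts = {}
    for g in taxonomy.focal_groups:
        members = taxonomy.group_species(g)
        group_counts[g] = (len(members & present), len(members))
    return PresenceProfile(
        focal_gene_id=group.focal_gene_id,
        group_counts=group_counts,
        species_presence={sp: sp in present for sp in taxonomy.species},
    )


def infer_ancestral_losses(profile: PresenceProfile, taxonomy: Taxonomy) -> list[LossEvent]:
    """Maximal fully-absent clades covering at least one focal group.

    A clade qualifies when every species beneath it lacks the ortholog and
    its parent clade retains at least one carrier; of those, only clades
    containing >= 1 entire focal group are reported (partial absence within
    a group is noise, not loss). Returned clades are pairwise disjoint.
    """
    absent = {sp for sp, pres in profile.species_presence.items() if not pres}

    all_absent: dict[CladeNode, bool] = {}
    for node in taxonomy.root.postorder():
        if node.is_leaf:
            all_absent[node] = node.name in absent
        else:
            all_absent[node] = all(all_absent[c] for c in node.children)

    events: list[LossEvent] = []

    def walk(node: CladeNode) -> None:
        if all_absent[node]:
            covered = tuple(
                g for g in taxonomy.focal_groups
                if taxonomy.group_species(g) <= node.species_under()
            )
            if covered:
                events.append(LossEvent(clade=node.name, covered_groups=covered))
            return  # maximal: do not descend into an absent clade
        for child in node.children:
            walk(child)

    walk(taxonomy.root)
    return events


def classify_fate(
    profile: PresenceProfile,
    losses: Sequence[LossEvent],
    n_duplicates: int,
    age: Optional[int] = None,
) -> GeneFateCall:
    """Apply the elusive / non-elusive decision rule to one focal gene."""
    if len(losses) >= MIN_LOSS_EVENTS and n_duplicates <= MAX_DUPLICATES:
        fate = ELUSIVE
    elif profile.all_present() and n_duplicates == 0:
        fate = NON_ELUSIVE
    else:
        fate = UNCLASSIFIED
    return GeneFateCall(
        gene_id=profile.focal_gene_id,
        fate=fate,
        loss_events=list(losses),
        n_duplicates=n_duplicates,
        age=age,
    )


def apply_exclusions(
    calls: Iterable[GeneFateCall], excluded_gene_ids: Iterable[str]
) -> list[GeneFateCall]:
    """Demote externally invalidated calls to unclassified."""
    excluded = set(excluded_gene_ids)
    out = []
    for call in calls:
        if call.gene_id in excluded and call.fate != UNCLASSIFIED:
            call = GeneFateCall(
                gene_id=call.gene_id,
                fate=UNCLASSIFIED,
                loss_events=call.loss_events,
                n_duplicates=call.n_duplicates,
                age=call.age,
            )
        out.append(call)
    return out


def calls_to_frame(calls: Iterable[GeneFateCall]) -> pd.DataFrame:
    """Tabulate fate calls (one row per focal gene) for TSV output."""
    rows = [
        {
            "gene_id": c.gene_id,
            "fate": c.fate,
            "n_losses": len(c.loss_events),
            "lost_clades": ",".join(ev.clade for ev in c.loss_events),
            "n_duplicates": c.n_duplicates,
            "age": c.age,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "fate", "n_losses", "lost_clades", "n_duplicates", "age"]
    )
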