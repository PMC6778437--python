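"""Clade-walking taxonomic assignment of a query protein.

Starting at the query leaf's parent, step ancestrally through the rooted
gene tree until reaching the first node whose clade has bootstrap support
at or above the threshold (default 50%, inclusive) *and* contains at least
one non-query leaf.  That clade's species codes are the assignment.  If the
root is reached without satisfying both conditions, the whole tree is used
(root fallback).  A tree without any non-query leaf yields the reserved
assignment "None".

Species codes are then mapped onto six taxonomic ranks.  A code known only
to a higher rank contributes an unknown-taxon label built from its lowest
known higher taxon, e.g. "Firmicutes fam." for an unknown family inside the
phylum Firmicutes.  Per rank the taxa list is de-duplicated so each taxon
contributes equally, reducing database sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import (
    NONE_TAXON,
    RANK_ABBREV,
    RANKS,
    DEFAULT_QUERY_CODE,
    GeneTree,
    TaxonomyTable,
    ValidationError,
    node_support,
    species_code,
)


@dataclass(frozen=True)
class CladeAssignment:
    """The qualifying clade found for one query protein."""

    protein_id: str
    species_codes: frozenset[str]
    support: Optional[float]  # percent; absent for root fallback / "None"
    root_fallback: bool = False
    none_flag: bool = False


@dataclass(frozen=True)
class RankAssignment:
    """Per-rank taxon sets for one protein, after unknown-rank labelling."""

    protein_id: str
    support: Optional[float]
    root_fallback: bool
    none_flag: bool
    ranks: dict[str, frozenset[str]]
    unmapped: frozenset[str] = field(default_factory=frozenset)


def assign_clade(
    gt: GeneTree,
    query_leaf: Optional[str] = None,
    support_threshold: float = 50.0,
    query_code: str = DEFAULT_QUERY_CODE,
) -> CladeAssignment:
    """Walk ancestrally from the query leaf to the smallest supported clade
    containing a non-query protein.

    ``query_leaf`` names the leaf to start from; by default the
    lexicographically first query-code leaf is used (its gene part names
    the protein).  Absent node supports fail the support condition: an
    unsupported clade is not a confident assignment.
    """
    if not gt.is_rooted:
        raise ValidationError("clade assignment requires a rooted tree")
    if not (0.0 <= support_threshold <= 100.0):
        raise ValidationError("support_threshold must be in [0, 100]")

    if query_leaf is None:
        candidates = sorted(
            (nd.taxon.label for nd in gt.query_leaves(query_code))
        )
        if not candidates:
            raise ValidationError(f"no query leaf with code {query_code!r}")
        query_leaf = candidates[0]
    node = gt.find_leaf(query_leaf)
    if node is None:
        raise ValidationError(f"query leaf {query_leaf!r} not present in tree")

    protein_id = query_leaf.rsplit("_", 1)[0]
    all_nonquery = {
        species_code(lbl)
        for lbl in gt.leaf_labels()
        if species_code(lbl) != query_code
    }
    if not all_nonquery:
        return CladeAssignment(
            protein_id=protein_id,
            species_codes=frozenset(),
            support=None,
            none_flag=True,
        )

    ancestor = node.parent_node
    while ancestor is not None:
        codes = {
            species_code(lf.taxon.label)
            for lf in ancestor.leaf_iter()
            if species_code(lf.taxon.label) != query_code
        }
        sup = node_support(ancestor)
        if codes and sup is not None and sup >= support_threshold:
            return CladeAssignment(
                protein_id=protein_id,
                species_codes=frozenset(codes),
                support=sup,
            )
        ancestor = ancestor.parent_node

    return CladeAssignment(
        protein_id=protein_id,
        species_codes=frozenset(all_nonquery),
        support=None,
        root_fallback=True,
    )


def map_to_ranks(
    assignment: CladeAssignment, taxonomy: TaxonomyTable
) -> RankAssignment:
    """Map assigned species codes onto the six taxonomic ranks.

    Codes absent from the taxonomy are recorded in ``unmapped`` (never
    silently dropped); if every code is unmapped the protein degenerates to
    the reserved taxon "None" at every rank.
    """
    if assignment.none_flag:
        ranks = {r: frozenset({NONE_TAXON}) for r in RANKS}
        return RankAssignment(
            protein_id=assignment.protein_id,
            support=assignment.support,
            root_fallback=assignment.root_fallback,
            none_flag=True,
            ranks=ranks,
        )

    unmapped = frozenset(
        c for c in assignment.species_codes if c not in taxonomy
    )
    mapped = sorted(assignment.species_codes - unmapped)
    ranks: dict[str, frozenset[str]] = {}
    for i, rank in enumerate(RANKS):
        names: set[str] = set()
        for code in mapped:
            entry = taxonomy[code]
            if entry[rank] is not None:
                names.add(entry[rank])
                continue
            for higher in RANKS[i + 1:]:
                if entry[higher] is not None:
                    names.add(f"{entry[higher]} {RANK_ABBREV[rank]}")
                    break
            else:
                names.add("Unknown")
        ranks[rank] = frozenset(names) if names else frozenset({NONE_TAXON})
    return RankAssignment(
        protein_id=assignment.protein_id,
        support=assignment.support,
        root_fallback=assignment.root_fallback,
        none_flag=False,
        ranks=ranks,
        unmapped=unmapped,
    )
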