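"""Core domain types shared across the toolkit.

Conventions
-----------
Leaf identifiers follow the UniProt-style ``GENE_SPECIES`` pattern: the
suffix after the last underscore is a species mnemonic code.  The reserved
code ``DCMF`` (configurable everywhere it is consumed) marks leaves that
belong to the query proteome.

Bootstrap supports are stored as newick internal-node labels, interpreted
as percentages in [0, 100].  A label in (0, 1] is *not* rescaled: silent
rescaling would hide data errors.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

#: Taxonomic ranks ordered from least to most inclusive.
RANKS = ("species", "genus", "family", "order", "class", "phylum")

#: Abbreviations used to label an unknown taxon at a rank, e.g. a species
#: known only to phylum level contributes "Firmicutes fam." at family rank.
RANK_ABBREV = {
    "species": "sp.",
    "genus": "gen.",
    "family": "fam.",
    "order": "ord.",
    "class": "cl.",
}

#: Reserved taxon name for proteins with no non-query homologue.
NONE_TAXON = "None"

DEFAULT_QUERY_CODE = "DCMF"


class TaxawalkError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TaxawalkError):
    """A file could not be parsed."""


class ValidationError(TaxawalkError):
    """Parsed or constructed data violates a documented invariant."""


def species_code(leaf_label: str) -> str:
    """Species mnemonic code of a leaf: the suffix after the last underscore.

    A label without an underscore is returned unchanged (it is its own code).
    """
    return leaf_label.rsplit("_", 1)[-1]


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def node_support(node: dendropy.Node) -> Optional[float]:
    """Bootstrap support of an internal node, or None if unlabelled."""
    label = node.label
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError as exc:  # pragma: no cover - guarded at parse time
        raise ValidationError(f"non-numeric support label {label!r}") from exc


def set_node_support(node: dendropy.Node, support: Optional[float]) -> None:
    node.label = None if support is None else f"{float(support):g}"


@dataclass
class GeneTree:
    """A per-protein phylogenetic tree.

    Wraps a :class:`dendropy.Tree`.  Internal node labels carry bootstrap
    supports (percent); leaves carry taxa whose labels are the sequence
    identifiers.
    """

    tree: dendropy.Tree
    name: Optional[str] = None

    # -- basic accessors ----------------------------------------------------

    @property
    def is_rooted(self) -> bool:
        return self.tree.is_rooted is True

    def leaf_nodes(self) -> list[dendropy.Node]:
        return self.tree.leaf_nodes()

    def leaf_labels(self) -> list[str]:
        return [nd.taxon.label for nd in self.tree.leaf_node_iter()]

    def species_codes(self) -> set[str]:
        return {species_code(lbl) for lbl in self.leaf_labels()}

    def query_leaves(self, query_code: str = DEFAULT_QUERY_CODE) -> list[dendropy.Node]:
        return [
            nd
            for nd in self.tree.leaf_node_iter()
            if species_code(nd.taxon.label) == query_code
        ]

    def find_leaf(self, label: str) -> Optional[dendropy.Node]:
        for nd in self.tree.leaf_node_iter():
            if nd.taxon.label == label:
                return nd
        return None

    def clone(self) -> "GeneTree":
        """Independent deep copy (supports, lengths and taxa preserved)."""
        return GeneTree(tree=copy.deepcopy(self.tree), name=self.name)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "GeneTree":
        """Check documented invariants; return self for chaining."""
        seen: set[str] = set()
        for nd in self.tree.leaf_node_iter():
            if nd.taxon is None or not nd.taxon.label:
                raise ValidationError("leaf without identifier")
            if nd.taxon.label in seen:
                raise ValidationError(f"duplicate leaf identifier {nd.taxon.label!r}")
            seen.add(nd.taxon.label)
        for nd in self.tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < 0:
                raise ValidationError(f"negative branch length {nd.edge.length}")
            if not nd.is_leaf():
                sup = node_support(nd)
                if sup is not None and not (0.0 <= sup <= 100.0):
                    raise ValidationError(f"support {sup} outside [0, 100]")
        return self


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTable:
    """Maps species mnemonic codes to names at six taxonomic ranks.

    ``entries[code][rank]`` is a taxon name or ``None`` (rank unknown).
    Invariant: if a rank is known, every more inclusive rank up to phylum
    is known as well.
    """

    entries: dict[str, dict[str, Optional[str]]] = field(default_factory=dict)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> dict[str, Optional[str]]:
        return self.entries[code]

    def __len__(self) -> int:
        return len(self.entries)

    def codes(self) -> list[str]:
        return list(self.entries)

    def taxa_at(self, rank: str) -> set[str]:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return {e[rank] for e in self.entries.values() if e[rank] is not None}

    def add(self, code: str, **ranks: Optional[str]) -> None:
        if not code:
            raise ValidationError("empty species code")
        if code in self.entries:
            raise ValidationError(f"duplicate species code {code!r}")
        entry = {r: ranks.get(r) or None for r in RANKS}
        self.entries[code] = entry
        self._validate_entry(code, entry)

    @staticmethod
    def _validate_entry(code: str, entry: dict[str, Optional[str]]) -> None:
        for i, rank in enumerate(RANKS):
            if entry[rank] is not None:
                missing = [r for r in RANKS[i + 1:] if entry[r] is None]
                if missing:
                    raise ValidationError(
                        f"species code {code!r}: rank {rank!r} is present but "
                        f"higher rank(s) {missing} are absent"
                    )

    def validate(self) -> "TaxonomyTable":
        for code, entry in self.entries.items():
            self._validate_entry(code, entry)
        return self

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence with empty identifier")
        if not self.seq:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


SequenceSet = list[SequenceRecord]


def check_unique_ids(seqs: SequenceSet) -> None:
    seen: set[str] = set()
    for rec in seqs:
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
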