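"""Readers and writers for the formats the pipeline touches.

newick gene trees (internal-node labels = bootstrap percentages), FASTA
sequence sets, and the seven-column TSV taxonomy table.  Reading followed
by writing is the identity on every format (up to float formatting and
line wrapping).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .core import (
    RANKS,
    GeneTree,
    ParseError,
    SequenceRecord,
    SequenceSet,
    TaxonomyTable,
    ValidationError,
    check_unique_ids,
    node_support,
)

PathLike = Union[str, os.PathLike]

TAXONOMY_COLUMNS = ("species_code",) + RANKS


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> list[GeneTree]:
    """Parse one or more newick statements into validated gene trees.

    Internal-node labels are interpreted as bootstrap percentages; a
    missing label means absent support.  Unquoted underscores in leaf
    names are preserved (UniProt-style ``GENE_SPECIES`` identifiers).
    """
    trees: list[GeneTree] = []
    statements = [s.strip() for s in text.split(";") if s.strip()]
    for i, stmt in enumerate(statements):
        try:
            tree = dendropy.Tree.get(
                data=stmt + ";",
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ParseError(f"malformed newick in tree {i}: {exc}") from exc
        gt = GeneTree(tree=tree, name=f"tree{i}")
        try:
            gt.validate()
            _check_supports(gt, i)
        except ValidationError as exc:
            raise ValidationError(f"tree {i}: {exc}") from exc
        trees.append(gt)
    return trees


def _check_supports(gt: GeneTree, index: int) -> None:
    for nd in gt.tree.preorder_internal_node_iter():
        label = nd.label
        if label in (None, ""):
            continue
        try:
            value = float(label)
        except ValueError:
            raise ValidationError(f"non-numeric internal-node label {label!r}")
        if not (0.0 <= value <= 100.0):
            raise ValidationError(f"support {value} outside [0, 100]")


def read_newick(path: PathLike) -> list[GeneTree]:
    """Read all trees from a newick file (one or more ``;``-terminated trees)."""
    path = Path(path)
    trees = parse_newick(path.read_text())
    stem = path.stem
    for i, gt in enumerate(trees):
        gt.name = stem if len(trees) == 1 else f"{stem}.{i}"
    return trees


def newick_string(gt: GeneTree) -> str:
    """Serialise one gene tree to a newick statement (with rooting marker)."""
    return gt.tree.as_string(
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    ).strip()


def write_newick(trees: Union[GeneTree, Iterable[GeneTree]], path: PathLike) -> None:
    if isinstance(trees, GeneTree):
        trees = [trees]
    lines = [newick_string(gt) for gt in trees]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree_dir(directory: PathLike, pattern: str = "*.nwk") -> list[GeneTree]:
    """Read every newick file in a directory, sorted by filename."""
    files = sorted(Path(directory).glob(pattern))
    trees: list[GeneTree] = []
    for f in files:
        trees.extend(read_newick(f))
    return trees


# ---------------------------------------------------------------------------
# taxonomy TSV
# ---------------------------------------------------------------------------

def read_taxonomy(path: PathLike) -> TaxonomyTable:
    """Read a seven-column TSV taxonomy table.

    Header must be ``species_code`` followed by the six ranks from species
    to phylum.  Empty cells denote unknown ranks and are stored as None.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"cannot read taxonomy table {path}: {exc}") from exc
    if tuple(df.columns) != TAXONOMY_COLUMNS:
        raise ValidationError(
            f"taxonomy header must be {list(TAXONOMY_COLUMNS)}, got {list(df.columns)}"
        )
    table = TaxonomyTable()
    for _, row in df.iterrows():
        table.add(
            row["species_code"].strip(),
            **{r: (row[r].strip() or None) for r in RANKS},
        )
    return table


def write_taxonomy(table: TaxonomyTable, path: PathLike) -> None:
    rows = [
        {"species_code": code, **{r: (entry[r] or "") for r in RANKS}}
        for code, entry in table.entries.items()
    ]
    pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> SequenceSet:
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    check_unique_ids(records)
    return records


def write_fasta(records: SequenceSet, path: PathLike) -> None:
    check_unique_ids(records)
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")
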