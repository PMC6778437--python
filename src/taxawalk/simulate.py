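"""Synthetic gene trees, taxonomies and sequence sets with known ground truth.

The generator emulates the inputs of a proteome-wide phylogenomic placement
study: for every simulated query protein, a gene tree containing exactly one
query leaf (or a lineage-specific duplicate pair when in-paralogues are
planted) plus leaves sampled from a fully known taxonomy.  One clade — the
query together with species drawn from a single "true" source taxon — is
planted with high bootstrap support; every other internal node receives low
support.  The clade-walking assignment stage must therefore recover exactly
the planted clade, which is recorded in a truth record.

Sequence sets are parent sequences plus point-mutated (optionally truncated)
copies at a controlled target identity, so redundancy reduction and
consensus statistics can be checked against planted truth.

Randomness: a single integer seed feeds a :class:`numpy.random.SeedSequence`
which spawns one child stream per generator, in the fixed order taxonomy,
gene trees, sequences.  Identical seed implies identical outputs, and each
generator is also individually reproducible from the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    RANKS,
    DEFAULT_QUERY_CODE,
    GeneTree,
    SequenceRecord,
    SequenceSet,
    TaxonomyTable,
    ValidationError,
)
from .io import parse_newick

_STREAMS = ("taxonomy", "trees", "sequences")

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator.

    Defaults define the study conditions used throughout the test-suite:
    well-separated supports (planted clade ~95, distractors <=30 versus the
    50% assignment threshold), modest gene trees (8-16 leaves), a 48-species
    six-rank taxonomy, and 95%-identity sequence copies of length 1000.
    """

    seed: int = 0

    # taxonomy shape
    n_phyla: int = 3
    classes_per_phylum: int = 1
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2

    # gene trees
    n_trees: int = 200
    min_leaves: int = 8
    max_leaves: int = 16
    true_rank: str = "family"
    true_taxon: Optional[str] = None  # None = drawn per tree
    min_clade_species: int = 2
    max_clade_species: int = 4
    true_support_mean: float = 95.0
    true_support_sd: float = 2.0
    distractor_support_mean: float = 20.0
    distractor_support_sd: float = 8.0
    distractor_support_max: float = 30.0
    inparalogue_rate: float = 0.1
    branch_length_mean: float = 0.1
    query_code: str = DEFAULT_QUERY_CODE

    # sequence sets
    n_parents: int = 5
    copies_per_parent: int = 3
    seq_length: int = 1000
    target_identity: float = 0.95
    indel_rate: float = 0.0
    max_trim: int = 20

    def validate(self) -> "SimConfig":
        counts = (
            self.n_phyla, self.classes_per_phylum, self.orders_per_class,
            self.families_per_order, self.genera_per_family,
            self.species_per_genus, self.n_trees, self.min_leaves,
            self.max_leaves, self.min_clade_species, self.max_clade_species,
            self.n_parents, self.copies_per_parent,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all counts must be >= 1")
        if not (0.0 <= self.inparalogue_rate <= 1.0):
            raise ValidationError("inparalogue_rate must be in [0, 1]")
        if not (0.0 <= self.indel_rate <= 1.0):
            raise ValidationError("indel_rate must be in [0, 1]")
        if not (0.0 < self.target_identity <= 1.0):
            raise ValidationError("target_identity must be in (0, 1]")
        if self.seq_length < 10:
            raise ValidationError("seq_length must be >= 10")
        if self.true_rank not in RANKS:
            raise ValidationError(f"true_rank must be one of {RANKS}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation option(s): {sorted(unknown)}")
        return cls(**d).validate()


@dataclass(frozen=True)
class TreeTruth:
    """Ground truth for one simulated gene tree."""

    protein_id: str
    clade_codes: frozenset[str]
    support: float
    query_leaves: tuple[str, ...]
    true_taxon: str


@dataclass(frozen=True)
class SequenceTruth:
    """Ground truth for one simulated sequence set."""

    parents: tuple[str, ...]
    copy_parent: dict[str, str]
    #: (copy, parent) pairs whose planted identity meets the NR threshold
    redundant_pairs: tuple[tuple[str, str], ...]
    #: exact fraction-identical of each copy to its parent (over the copy)
    planted_identity: dict[str, float]


def _rng_for(config: SimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def simulate_taxonomy(config: SimConfig) -> TaxonomyTable:
    """Fully populated six-rank taxonomy with the configured shape."""
    config.validate()
    table = TaxonomyTable()
    idx = 0
    for p in range(1, config.n_phyla + 1):
        phylum = f"Phylum{p}"
        for c in range(1, config.classes_per_phylum + 1):
            klass = f"Class{p}.{c}"
            for o in range(1, config.orders_per_class + 1):
                order = f"Order{p}.{c}.{o}"
                for f in range(1, config.families_per_order + 1):
                    fam = f"Family{p}.{c}.{o}.{f}"
                    for g in range(1, config.genera_per_family + 1):
                        genus = f"Genus{p}.{c}.{o}.{f}.{g}"
                        for s in range(1, config.species_per_genus + 1):
                            idx += 1
                            code = f"S{idx:04d}"
                            table.add(
                                code,
                                species=f"{genus} {code.lower()}",
                                genus=genus,
                                family=fam,
                                order=order,
                                **{"class": klass},
                                phylum=phylum,
                            )
    return table


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def _random_join(fragments: list[str], rng: np.random.Generator,
                 support_fn, length_fn) -> str:
    """Random bifurcating (Yule-like) join of newick fragments.

    ``support_fn()`` labels every internal node created by the join.
    """
    frags = list(fragments)
    while len(frags) > 1:
        i, j = rng.choice(len(frags), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = frags.pop(j)
        left = frags.pop(i)
        sup = support_fn()
        label = "" if sup is None else f"{sup:g}"
        frags.append(f"({left}:{length_fn():.6f},{right}:{length_fn():.6f}){label}")
    return frags[0]


def simulate_gene_tree(
    taxonomy: TaxonomyTable,
    config: SimConfig,
    rng: np.random.Generator,
    index: int = 0,
) -> tuple[GeneTree, TreeTruth]:
    """One gene tree with a planted, highly supported true clade.

    The query leaf's parent path runs: (optional in-paralogue cherry) ->
    planted clade node (high support) -> low-support distractor nodes ->
    root, so clade walking at the default 50% threshold must return exactly
    the planted clade's species codes.
    """
    config.validate()
    rank = config.true_rank
    if config.true_taxon is not None:
        true_taxon = config.true_taxon
        pool = [c for c in taxonomy if taxonomy[c][rank] == true_taxon]
        if not pool:
            raise ValidationError(
                f"true taxon {true_taxon!r} absent from taxonomy at rank {rank!r}"
            )
    else:
        taxa = sorted(taxonomy.taxa_at(rank))
        true_taxon = taxa[int(rng.integers(len(taxa)))]
        pool = [c for c in taxonomy if taxonomy[c][rank] == true_taxon]

    length_fn = lambda: float(rng.exponential(config.branch_length_mean)) + 1e-6

    def low_support() -> float:
        v = rng.normal(config.distractor_support_mean, config.distractor_support_sd)
        return float(np.clip(round(v), 0.0, config.distractor_support_max))

    def high_support() -> float:
        v = rng.normal(config.true_support_mean, config.true_support_sd)
        return float(np.clip(round(v), 0.0, 100.0))

    protein_id = f"P{index:04d}"
    query_leaves = [f"{protein_id}_{config.query_code}"]
    if rng.random() < config.inparalogue_rate:
        query_leaves.append(f"{protein_id}b_{config.query_code}")

    k_max = min(config.max_clade_species, len(pool))
    k_min = min(config.min_clade_species, k_max)
    k = int(rng.integers(k_min, k_max + 1))
    clade_codes = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    n_leaves = int(rng.integers(config.min_leaves, config.max_leaves + 1))
    n_distract = max(1, n_leaves - k - len(query_leaves))
    other = [c for c in taxonomy if c not in set(clade_codes)]
    distract_codes = [other[i] for i in rng.integers(0, len(other), size=n_distract)]

    counter = 0

    def leaf(code: str) -> str:
        nonlocal counter
        counter += 1
        return f"g{counter}_{code}"

    # query block: single leaf, or a cherry of in-paralogue copies
    query_frag = _random_join(list(query_leaves), rng, low_support, length_fn)
    clade_leaf_frags = [leaf(c) for c in clade_codes]
    inner = _random_join(clade_leaf_frags, rng, low_support, length_fn)
    support = high_support()
    clade_frag = (
        f"({query_frag}:{length_fn():.6f},{inner}:{length_fn():.6f}){support:g}"
    )

    distract_frags = [leaf(c) for c in distract_codes]
    root_children = distract_frags + [clade_frag]
    # join all but the final (root) merge with low supports; root unlabelled
    while len(root_children) > 2:
        i, j = rng.choice(len(root_children), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = root_children.pop(j)
        left = root_children.pop(i)
        root_children.append(
            f"({left}:{length_fn():.6f},{right}:{length_fn():.6f}){low_support():g}"
        )
    newick = (
        f"[&R] ({root_children[0]}:{length_fn():.6f},"
        f"{root_children[1]}:{length_fn():.6f});"
    )

    gt = parse_newick(newick)[0]
    gt.name = protein_id
    truth = TreeTruth(
        protein_id=protein_id,
        clade_codes=frozenset(clade_codes),
        support=support,
        query_leaves=tuple(query_leaves),
        true_taxon=true_taxon,
    )
    return gt, truth


def simulate_gene_trees(
    config: SimConfig, taxonomy: Optional[TaxonomyTable] = None
) -> list[tuple[GeneTree, TreeTruth]]:
    """``config.n_trees`` trees from the dedicated "trees" random stream."""
    config.validate()
    if taxonomy is None:
        taxonomy = simulate_taxonomy(config)
    rng = _rng_for(config, "trees")
    return [
        simulate_gene_tree(taxonomy, config, rng, index=i)
        for i in range(config.n_trees)
    ]


# ---------------------------------------------------------------------------
# sequence sets
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return NUCLEOTIDES[rng.integers(0, 4, size=length)]


def _mutate(parent: np.ndarray, rng: np.random.Generator, sub_rate: float,
            indel_rate: float) -> np.ndarray:
    seq = parent.copy()
    hits = rng.random(len(seq)) < sub_rate
    for i in np.nonzero(hits)[0]:
        choices = NUCLEOTIDES[NUCLEOTIDES != seq[i]]
        seq[i] = choices[rng.integers(0, len(choices))]
    if indel_rate > 0:
        keep = rng.random(len(seq)) >= indel_rate
        seq = seq[keep]
    return seq


def simulate_sequences(
    config: SimConfig, nr_threshold: float = 99.0
) -> tuple[SequenceSet, SequenceTruth]:
    """Parent sequences plus mutated, slightly truncated copies.

    Copies carry point substitutions at rate ``1 - target_identity`` and are
    trimmed by up to ``max_trim`` residues, so the parent is always the
    longer member of each redundant pair.  The planted identity of a copy is
    the exact fraction of positions identical to its parent over the copy's
    length (the shorter sequence), computed directly from the mutation mask
    — independent of any aligner.
    """
    config.validate()
    rng = _rng_for(config, "sequences")
    sub_rate = 1.0 - config.target_identity
    records: SequenceSet = []
    parents: list[str] = []
    copy_parent: dict[str, str] = {}
    redundant: list[tuple[str, str]] = []
    planted: dict[str, float] = {}
    for p in range(1, config.n_parents + 1):
        pid = f"parent{p:02d}"
        parent = _random_seq(rng, config.seq_length)
        records.append(SequenceRecord(pid, "".join(parent)))
        parents.append(pid)
        for c in range(1, config.copies_per_parent + 1):
            cid = f"parent{p:02d}.copy{c}"
            trim = int(rng.integers(1, config.max_trim + 1))
            mutated = _mutate(parent, rng, sub_rate, config.indel_rate)
            copy_seq = mutated[: len(mutated) - trim]
            records.append(SequenceRecord(cid, "".join(copy_seq)))
            copy_parent[cid] = pid
            if config.indel_rate == 0:
                ident = float(np.mean(copy_seq == parent[: len(copy_seq)])) * 100.0
                planted[cid] = ident
                if ident >= nr_threshold:
                    redundant.append((cid, pid))
    truth = SequenceTruth(
        parents=tuple(parents),
        copy_parent=copy_parent,
        redundant_pairs=tuple(redundant),
        planted_identity=planted,
    )
    return records, truth


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------

def write_truth(
    tree_truths: Sequence[TreeTruth], seq_truth: Optional[SequenceTruth], path
) -> None:
    payload = {
        "trees": [
            {
                "protein_id": t.protein_id,
                "clade_codes": sorted(t.clade_codes),
                "support": t.support,
                "query_leaves": list(t.query_leaves),
                "true_taxon": t.true_taxon,
            }
            for t in tree_truths
        ],
        "sequences": None
        if seq_truth is None
        else {
            "parents": list(seq_truth.parents),
            "copy_parent": seq_truth.copy_parent,
            "redundant_pairs": [list(p) for p in seq_truth.redundant_pairs],
            "planted_identity": seq_truth.planted_identity,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
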