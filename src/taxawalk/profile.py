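"""Proteome-level taxonomic profiles from per-protein rank assignments.

Two combination strategies:

* **unweighted** — each protein distributes one unit of mass equally over
  the taxa it maps to at a rank (five taxa -> 0.2 each);
* **bootstrap-weighted** — the equal split is multiplied by the clade's
  bootstrap support as a fraction (two taxa at 80% support -> 0.4 each).
  Root-fallback and "None" assignments carry weight 1.0.

Taxa whose *unweighted* combined score falls below an exclusion threshold
(default 1.0) are removed and scores recalculated iteratively: each affected
protein's mass is re-split equally over its surviving taxa (default), or, in
"drop" mode, sub-threshold taxa are simply removed and the per-taxon share
of the original 1/k split is forfeited.  A protein whose taxa are all
excluded is reassigned to the reserved taxon "None", so in re-split mode the
total unweighted mass always equals the number of proteins.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import NONE_TAXON, RANKS, ValidationError
from .assign import RankAssignment


def unweighted_shares(taxa: Iterable[str]) -> dict[str, float]:
    """Equal split of one protein over its k taxa: 1/k each."""
    taxa = sorted(set(taxa))
    if not taxa:
        raise ValidationError("cannot split a protein over an empty taxon set")
    share = 1.0 / len(taxa)
    return {t: share for t in taxa}


def weighted_shares(
    taxa: Iterable[str],
    support: Optional[float] = None,
    root_fallback: bool = False,
) -> dict[str, float]:
    """Bootstrap-weighted split: (1/k) x (support/100).

    Root-fallback assignments (and assignments without a recorded support,
    e.g. "None") use weight 1.0.
    """
    if root_fallback or support is None:
        weight = 1.0
    else:
        if not (0.0 <= support <= 100.0):
            raise ValidationError(f"support {support} outside [0, 100]")
        weight = support / 100.0
    return {t: s * weight for t, s in unweighted_shares(taxa).items()}


@dataclass
class RankProfile:
    """Combined taxonomic profile at one rank.

    ``frame`` columns: unweighted, weighted, unweighted_pct, weighted_pct,
    indexed by taxon and sorted by descending weighted score (ties by
    name).  ``assigned_sets`` records each protein's surviving taxon set
    after iterative exclusion.
    """

    rank: str
    n_proteins: int
    frame: pd.DataFrame
    excluded: tuple[str, ...]
    assigned_sets: dict[str, frozenset[str]]

    def top_taxon(self) -> str:
        return str(self.frame.index[0])


def _scores(
    sets: Mapping[str, frozenset[str]], denom: Mapping[str, int]
) -> dict[str, float]:
    # accumulate in sorted order so results are independent of input order
    acc: dict[str, float] = defaultdict(float)
    for pid in sorted(sets):
        taxa = sets[pid]
        if not taxa:
            continue
        share = 1.0 / denom[pid]
        for t in sorted(taxa):
            acc[t] += share
    return dict(acc)


def combine_rank(
    assignments: Sequence[RankAssignment],
    rank: str,
    exclusion_threshold: float = 1.0,
    mode: str = "resplit",
) -> RankProfile:
    """Combine one rank's assignments with iterative low-score exclusion."""
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    if mode not in ("resplit", "drop"):
        raise ValidationError(f"mode must be 'resplit' or 'drop', got {mode!r}")
    if not assignments:
        raise ValidationError("need at least one assignment")

    sets: dict[str, frozenset[str]] = {}
    weight: dict[str, float] = {}
    original_k: dict[str, int] = {}
    for a in assignments:
        taxa = a.ranks[rank]
        if not taxa:
            raise ValidationError(
                f"protein {a.protein_id!r}: empty taxon set at rank {rank!r}"
            )
        if a.protein_id in sets:
            raise ValidationError(f"duplicate protein id {a.protein_id!r}")
        sets[a.protein_id] = taxa
        original_k[a.protein_id] = len(taxa)
        if a.root_fallback or a.none_flag or a.support is None:
            weight[a.protein_id] = 1.0
        else:
            weight[a.protein_id] = a.support / 100.0

    excluded: list[str] = []
    while True:
        denom = (
            {pid: len(s) for pid, s in sets.items() if s}
            if mode == "resplit"
            else original_k
        )
        scores = _scores(sets, denom)
        low = sorted(
            t
            for t, v in scores.items()
            if t != NONE_TAXON and v < exclusion_threshold - 1e-12
        )
        if not low:
            break
        excluded.extend(low)
        low_set = set(low)
        new_sets = {}
        for pid, taxa in sets.items():
            kept = taxa - low_set
            if not kept:
                kept = frozenset({NONE_TAXON})
                original_k[pid] = 1
            new_sets[pid] = frozenset(kept)
        sets = new_sets

    denom = (
        {pid: len(s) for pid, s in sets.items()}
        if mode == "resplit"
        else original_k
    )
    unweighted = _scores(sets, denom)
    wscores: dict[str, float] = defaultdict(float)
    for pid in sorted(sets):
        share = weight[pid] / denom[pid]
        for t in sorted(sets[pid]):
            wscores[t] += share

    n = len(assignments)
    total_w = sum(wscores.values())
    rows = []
    for taxon in unweighted:
        rows.append(
            {
                "taxon": taxon,
                "unweighted": unweighted[taxon],
                "weighted": wscores[taxon],
                "unweighted_pct": unweighted[taxon] / n * 100.0,
                "weighted_pct": (
                    wscores[taxon] / total_w * 100.0 if total_w > 0 else 0.0
                ),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["taxon", "unweighted", "weighted", "unweighted_pct", "weighted_pct"]
    ).set_index("taxon")
    frame = frame.sort_values(
        by=["weighted", "taxon"], ascending=[False, True], kind="mergesort"
    )
    return RankProfile(
        rank=rank,
        n_proteins=n,
        frame=frame,
        excluded=tuple(excluded),
        assigned_sets=dict(sets),
    )


def combine(
    assignments: Sequence[RankAssignment],
    exclusion_threshold: float = 1.0,
    mode: str = "resplit",
) -> dict[str, RankProfile]:
    """Rank profiles for all six ranks."""
    return {
        rank: combine_rank(assignments, rank, exclusion_threshold, mode)
        for rank in RANKS
    }
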