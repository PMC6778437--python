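"""Global pairwise identity and its two uses: non-redundant reduction and
multi-copy consensus/identity statistics.

Identity is defined from an optimal Needleman-Wunsch global alignment as
(identical aligned positions) / (length of the shorter sequence) x 100 —
the "shorter sequence" convention used when collapsing redundant contigs.
Default scoring: match +1, mismatch -1, gap open -2, gap extend -1;
BLOSUM62 is available for proteins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import SequenceRecord, SequenceSet, ValidationError, check_unique_ids

_NUC_CHARS = frozenset("ACGTUN")


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    matrix: Optional[str] = None  # e.g. "BLOSUM62"; overrides match/mismatch


DEFAULT_SCORING = AlignmentScoring()
BLOSUM62_SCORING = AlignmentScoring(gap_open=-11.0, gap_extend=-1.0, matrix="BLOSUM62")


def _alphabet(seq: str) -> str:
    return "nucleotide" if set(seq.upper()) <= _NUC_CHARS else "protein"


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> float:
    """Percent identity over the shorter sequence, from a global alignment.

    Case-insensitive and symmetric in its arguments.  Raises on an
    apparent alphabet mismatch (nucleotide vs protein, judged from the
    residue characters).
    """
    sa = (a.seq if isinstance(a, SequenceRecord) else a).upper()
    sb = (b.seq if isinstance(b, SequenceRecord) else b).upper()
    if not sa or not sb:
        raise ValidationError("cannot align an empty sequence")
    if _alphabet(sa) != _alphabet(sb):
        raise ValidationError("alphabet mismatch between sequences")
    alignment = _alignment(sa, sb, scoring)
    identities = alignment.counts().identities
    return identities / min(len(sa), len(sb)) * 100.0


def _alignment(sa: str, sb: str, scoring: AlignmentScoring):
    return _aligner(scoring).align(sa, sb)[0]


def identity_matrix(
    seqs: SequenceSet, scoring: AlignmentScoring = DEFAULT_SCORING
) -> pd.DataFrame:
    """Symmetric all-by-all identity matrix (diagonal = 100)."""
    check_unique_ids(seqs)
    ids = [r.id for r in seqs]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for x, y in itertools.combinations(seqs, 2):
        v = global_identity(x, y, scoring)
        mat.loc[x.id, y.id] = v
        mat.loc[y.id, x.id] = v
    return mat


def nr_reduce(
    seqs: SequenceSet,
    threshold: float = 99.0,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> SequenceSet:
    """Greedy non-redundant reduction keeping the longer sequence.

    Sequences are processed in decreasing length order (length ties broken
    lexicographically by identifier); a sequence is discarded when its
    identity to any already-retained sequence reaches the threshold.  The
    retained set is returned in the input order and has all pairwise
    identities below the threshold.
    """
    if not seqs:
        raise ValidationError("need at least one sequence")
    check_unique_ids(seqs)
    retained: list[SequenceRecord] = []
    for rec in sorted(seqs, key=lambda r: (-len(r), r.id)):
        if any(
            global_identity(rec, kept, scoring) >= threshold for kept in retained
        ):
            continue
        retained.append(rec)
    kept_ids = {r.id for r in retained}
    return [r for r in seqs if r.id in kept_ids]


@dataclass(frozen=True)
class CopyStats:
    """Mean pairwise identity and consensus of a multi-copy gene family."""

    mean_identity: float  # percent, 2 decimal places (round-half-even)
    consensus: SequenceRecord
    n_pairs: int


def copy_identity_stats(
    seqs: SequenceSet,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    consensus_id: str = "consensus",
) -> CopyStats:
    """Mean over all unordered pairs of global identity, plus the per-column
    majority consensus of the star-merged multiple alignment.

    Column ties choose the alphabetically first residue; a residue beats a
    gap on ties, and majority-gap columns are omitted from the consensus.
    """
    if len(seqs) < 2:
        raise ValidationError("copy statistics need at least 2 sequences")
    check_unique_ids(seqs)
    idents = [
        global_identity(a, b, scoring) for a, b in itertools.combinations(seqs, 2)
    ]
    mean_identity = round(sum(idents) / len(idents), 2)
    rows = _star_msa(seqs, scoring)
    consensus = _majority_consensus(rows)
    return CopyStats(
        mean_identity=mean_identity,
        consensus=SequenceRecord(consensus_id, consensus),
        n_pairs=len(idents),
    )


def _star_msa(seqs: SequenceSet, scoring: AlignmentScoring) -> list[str]:
    """Multiple alignment by progressive pairwise merging onto a centre.

    The centre is the longest sequence (ties by identifier); every other
    sequence is aligned to the ungapped centre and merged column-wise under
    the once-a-gap-always-a-gap rule.
    """
    ordered = sorted(seqs, key=lambda r: (-len(r), r.id))
    centre, rest = ordered[0], ordered[1:]
    master = centre.seq.upper()
    rows: list[str] = [master]
    for rec in rest:
        aln = _alignment(centre.seq.upper(), rec.seq.upper(), scoring)
        cg, sg = str(aln[0]), str(aln[1])
        master, rows = _merge(master, rows, cg, sg)
    return rows


def _merge(
    master: str, rows: list[str], cg: str, sg: str
) -> tuple[str, list[str]]:
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_new: list[str] = []
    i = j = 0
    while i < len(master) or j < len(cg):
        if i < len(master) and master[i] == "-":
            out_master.append("-")
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_new.append("-")
            i += 1
        elif j < len(cg) and cg[j] == "-":
            out_master.append("-")
            for r in out_rows:
                r.append("-")
            out_new.append(sg[j])
            j += 1
        else:
            out_master.append(master[i])
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_new.append(sg[j])
            i += 1
            j += 1
    merged_rows = ["".join(r) for r in out_rows] + ["".join(out_new)]
    return "".join(out_master), merged_rows


def _majority_consensus(rows: list[str]) -> str:
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        # residues beat gaps on ties; alphabetical among residues
        best = min(counts, key=lambda ch: (-counts[ch], ch == "-", ch))
        if best != "-":
            out.append(best)
    return "".join(out)
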