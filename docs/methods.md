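# Methods

This note documents the models, parameters and numerical choices behind
`taxawalk`, and what the synthetic-data tests do and do not demonstrate.

## Gene-tree curation

**Midpoint rooting.**  The root is placed at the midpoint of the longest
leaf-to-leaf path.  The diameter is found by a double sweep (the farthest
leaf from an arbitrary leaf is one end of a longest path, which is exact
on trees with non-negative branch lengths); the root then bisects that
path, splitting an edge when the midpoint falls strictly inside one and
rooting at the node when it coincides with a node (tolerance 1e-12 on
accumulated path length).  Rooting preserves all patristic distances.
Trees whose branch lengths are all zero have no unique midpoint and are
rejected.  In the pipeline, trees that arrive already rooted are left as
they are; only unrooted inputs are midpoint rooted.

**Paralogous subfamilies.**  An internal node is flagged when its two
child clades each contain at least two distinct species and share at
least one species — the classic signature of a gene duplication predating
speciation.  Only strictly bifurcating nodes are considered; a polytomy
does not define the two ancestral clades the rule requires, and the
upstream tree builders this pipeline expects produce bifurcating trees.

**In-paralogue restriction.**  Within each flagged subfamily, every
non-query species with more than one leaf keeps only the leaf with the
smallest patristic distance to the nearest query leaf; ties break on the
lexicographically smaller leaf identifier.  "Closest homologue" is
operationalised as tree distance because trees are the only input at this
stage; a sequence-identity notion of closeness would require the
alignments, which the curation step does not see.  Query in-paralogues are
always kept, and same-species duplicates outside any subfamily are kept.
Nested subfamilies are handled by taking the union of the per-subfamily
prune sets, so an outer subfamily can prune a leaf an inner one would have
kept.  Degree-2 nodes created by pruning are suppressed with their branch
lengths summed.  The operation is idempotent.  Curation is single-pass;
callers wanting the iterate-and-rebuild loop of interactive curation tools
should loop externally, re-inferring trees between passes.

## Clade-walking assignment

From the query leaf's parent upward, the first node with clade bootstrap
support ≥ threshold *and* at least one non-query leaf is the assignment.
Choices worth stating:

* the threshold (default 50 %) is **inclusive**;
* a node with **absent** support fails the support condition — an
  unlabelled clade cannot be called confidently supported, so the walk
  continues upward (conservative);
* supports are read literally as percentages in [0, 100]; a label in
  (0, 1] is *not* rescaled, because silent rescaling would mask data
  errors (fraction-scaled inputs must be converted explicitly);
* the walk includes the root node itself; only if the root also fails does
  the assignment fall back to the whole tree, recorded with an **absent**
  support;
* a tree whose leaves are all query copies is assigned the reserved taxon
  `None`.

Newick internal-node labels are taken to be the support of the clade the
node subtends; the label-on-node convention makes "the branch's support"
and "the clade's support" the same thing.

## Rank mapping

Codes map to (species, genus, family, order, class, phylum).  A code with
no name at a rank contributes `<lowest known higher taxon> <abbrev>.`
with abbreviations sp., gen., fam., ord., cl.; the taxonomy-table
invariant (a known rank implies all higher ranks known) guarantees such a
higher taxon exists for any partially known code.  Codes absent from the
taxonomy are reported in an `unmapped` column and in run warnings rather
than silently dropped; they contribute no taxon mass.  Per-rank taxon sets
are de-duplicated, so a clade of five congeneric species contributes one
genus, not five.

## Profile combination

Per rank, protein *p* with *k* taxa contributes 1/*k* per taxon
(unweighted) and (1/*k*) × (*s_p*/100) (weighted), with weight 1.0 for
root-fallback and `None` assignments — a fallback is the tree's full
evidence, not a low-confidence clade, so down-weighting it to zero would
discard the proteins with the least specific signal entirely.

Exclusion iterates on the **unweighted** scores: all taxa below the
threshold (default 1.0) are removed each round and scores recalculated
until none remain below it.  Two recalculation behaviours are provided:

* **resplit** (default): an affected protein re-splits its unit mass
  equally over its surviving taxa; total unweighted mass is conserved and
  always equals the protein count (a protein whose taxa are all excluded
  is reassigned to `None`);
* **drop**: surviving taxa keep their original 1/*k* share and the
  excluded share is forfeited.

The iteration terminates in at most one round per distinct taxon and its
result is a fixed point: recombining the surviving per-protein sets
excludes nothing further.  Scores are accumulated in sorted
(protein, taxon) order, so profiles are bitwise independent of input
order.  Weighted scores are computed over the surviving taxon sets, so
both strategies describe the same final support set.  Reported
percentages are score/n_proteins × 100 (unweighted) and the weighted
scores normalised to 100 (weighted).

## Sequence identity

Identity = identical aligned positions / length of the shorter sequence
× 100, from an optimal Needleman–Wunsch global alignment (match +1,
mismatch −1, gap open −2, gap extend −1; BLOSUM62 with −11/−1 gaps
available for proteins).  Defining identity via a deterministic optimal
global alignment, rather than via coverage of local BLAST hits as
pipeline tools built on BLAST do, makes results reproducible but means
printed identities from such tools are only comparable within a
method-sensitivity tolerance.  Among co-optimal alignments the aligner's
first traceback is used; its match count can differ from another
co-optimal alignment's by at most the tie structure of the scoring, which
the tests account for by checking against the full co-optimal set.

NR reduction processes sequences in decreasing length order (ties by
identifier) and discards any sequence reaching the threshold against an
already-retained one — so the longer member of a redundant pair is always
the one kept, and the output's pairwise identities are all below the
threshold.  The consensus of a copy set is the per-column majority of a
star alignment (all sequences pairwise-aligned to the longest and merged
under once-a-gap-always-a-gap); ties prefer a residue over a gap and the
alphabetically first residue otherwise, and majority-gap columns are
omitted.  Mean pairwise identity is reported to two decimals,
round-half-even.

## Synthetic data

The generator emulates the *inputs* of a proteome-wide placement study
with a known answer.  Per tree: one query leaf (plus a second,
cherry-attached copy at the in-paralogue rate, default 0.1), a planted
clade of 2–4 species drawn from one source taxon (default rank: family)
joined to the query at a node with support ~N(95, 2), and distractor
leaves drawn with replacement from the rest of a fully populated 48-species
taxonomy (3 phyla × 2 orders × 2 families × 2 genera × 2 species), all
other internal nodes supported ~N(20, 8) clipped to [0, 30].  Topologies
are random bifurcations with exponential branch lengths (mean 0.1):
topological realism is irrelevant to the clade walk, which sees only leaf
labels, supports and (for curation) path lengths.  Every node on the
query's ancestral path except the planted clade node is low-supported, so
the planted clade is the unique correct answer at the 50 % threshold and
recovery can be scored exactly.

Sequence sets are uniform-random parents with point-substituted copies at
rate 1 − target identity (default 0.95 over length 1000) and a small
terminal truncation (≤ 20 nt) so the parent is the longer member of each
pair; indels default to 0 so the planted identity is analytically
controlled, and each copy's exact identity-to-parent is recorded in the
truth record straight from the mutation mask, independent of any aligner.
The redundancy-recovery tests plant copies at target identity 0.999 over
length 1000, placing them far inside the 99 % threshold (a copy would
need > 10 substitutions, probability ~1e-7, to escape).

One integer seed drives everything: a `numpy` `SeedSequence` spawns one
child stream per generator (taxonomy, trees, sequences, in that order),
so outputs are fully reproducible and each generator is individually
reproducible from the same seed.

**What passing these tests shows — and does not.**  Recovery of planted
clades shows the walk, mapping and combination are implemented correctly
under well-separated supports; it says nothing about real data where
support separation is weaker, trees contain reconstruction artefacts,
homologue sampling is biased by database composition, or horizontal gene
transfer decouples gene trees from the species history.  Likewise the
substitution-only sequence model validates the redundancy and consensus
machinery, not the behaviour of identity scores under real indel
patterns.

## Problem sizes in the test-suite

Tests run on simulated data sized for completeness of coverage rather
than realism: 500 trees for oracle equivalence of the clade walk
(checked leaf-for-leaf against an independent ancestor enumeration built
on a second tree library), 200 trees for planted-truth recovery (≥ 95 %
required, planted support 95 vs distractors ≤ 30), 200 random profiles
for the exclusion fixed-point and conservation laws, and 50 seeded
sequence sets for redundancy recovery.  A full proteome-scale run
(thousands of trees) is a straight scale-up of the same code paths.

## Known limitations

* Re-rooting a tree whose supports were computed under a different
  rooting can change which clade a label refers to; supports are kept
  attached to their nodes, which is the standard (and only possible)
  behaviour without the bootstrap replicates.
* The alphabet check in `global_identity` is a character heuristic; a
  short peptide over {A, C, G, T, N} residues is indistinguishable from
  DNA.
* Polytomies never qualify as paralogous subfamilies (see above) and a
  polytomous node on the query path is treated like any other node by the
  clade walk.
* The star-alignment consensus is exact for the substitution-dominated
  copy sets it is meant for (near-identical gene copies); for deeply
  diverged families a profile-based MSA would be preferable.
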