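# taxawalk

Phylogenomic taxonomic profiling of a query proteome from per-protein gene
trees.  Given one phylogenetic tree per predicted protein (each containing
the query protein plus its homologues from known species), `taxawalk`
curates each tree, assigns the query protein to the smallest
bootstrap-supported clade containing a non-query homologue, maps that
clade's species onto six taxonomic ranks, and combines the per-protein
assignments into proteome-level taxon profiles.  It was built for placing
novel, hard-to-classify bacteria — the motivating case is an uncultured
dichloromethane-fermenting *Peptococcaceae* member whose query leaves carry
the species code `DCMF` — but every code and threshold is configurable.

## The method

**Curation.**  Unrooted gene trees are midpoint rooted (the root bisects
the longest leaf-to-leaf path).  Gene-duplication nodes ("paralogous
subfamilies") are detected as internal nodes whose two child clades each
contain ≥ 2 distinct species and share ≥ 1 species.  Within such a
subfamily, multiple leaves from one non-query species are in-paralogues or
sequence variants: only the leaf with the smallest patristic distance to
the nearest query leaf is kept.  Query in-paralogues are always kept.

**Clade walk.**  Starting at the query leaf's parent, step ancestrally
until the first node with bootstrap support ≥ *t* (default *t* = 50 %,
inclusive) whose clade contains at least one non-query leaf.  That clade's
species codes are the assignment.  If the root is reached first, the whole
tree is used (root fallback); a tree with no non-query homologue is
assigned the reserved taxon `None`.

**Rank mapping.**  Species codes (the UniProt-style suffix after the last
underscore in each leaf name) map onto species, genus, family, order,
class and phylum.  A code known only to a higher rank contributes an
unknown-taxon label, e.g. `Firmicutes fam.` for an unknown family within
the phylum Firmicutes.  Per rank, the taxa list is de-duplicated so each
taxon contributes equally.

**Combination.**  For a protein mapping to *k* taxa at a rank, each taxon
receives 1/*k* (unweighted) or (1/*k*) × (*s*/100) where *s* is the
clade's percent bootstrap support (weighted; root-fallback weight 1.0).
So a protein split over five taxa gives 0.2 each, and two taxa at 80 %
support give 0.4 each (= 0.5 × 0.8).  Any taxon whose combined unweighted
score falls below 1.0 is excluded and scores are recalculated iteratively,
each affected protein re-splitting its mass over its surviving taxa.

**Sequence utilities.**  `global_identity` scores a Needleman–Wunsch
global alignment and reports identical positions over the length of the
shorter sequence; `nrseq` greedily collapses sequence sets to
non-redundant representatives at a 99 % identity threshold, keeping the
longer member of each redundant pair; `copystats` reports the mean
pairwise identity and majority-rule consensus of a multi-copy gene family
(e.g. the rRNA copies of one genome).

A synthetic-data generator produces gene trees with a planted,
highly-supported true clade, a fully known taxonomy, and sequence sets
with planted redundancy — so the whole pipeline is testable against known
ground truth without any external data.

## Worked example

```sh
taxawalk run --config config.yaml
```

with `config.yaml`:

```yaml
outdir: out
seed: 1
simulate:
  n_trees: 200
  true_taxon: Family1.1.1.1
```

prints stage logs to stderr:

```
[taxawalk:simulate] seed=1 n_trees=200
[taxawalk:curate] 200 trees, 86 in-paralogue leaves pruned
[taxawalk:assign] 200 proteins (0 fallback, 0 none)
[taxawalk:profile] profiles written for species, genus, family, order, class, phylum
[taxawalk:nrseq] 20 -> 20 sequences
```

and writes `out/profile_family.tsv`:

```
taxon	unweighted	weighted	unweighted_pct	weighted_pct
Family1.1.1.1	200.000000	190.050000	100.000000	100.000000
```

All 200 simulated proteins were planted in clades drawn from family
`Family1.1.1.1` with bootstrap support ≈ 95, so the unweighted score is the
full protein count (200), the bootstrap-weighted score is ≈ 0.95 × 200,
and the family receives 100 % of the profile.  86 planted in-paralogue
leaves were pruned during curation; no tree needed root fallback.
`out/report.json` records the same counts machine-readably, and
`out/assignments.tsv` holds the per-protein clade, support and rank
columns.

The same stages are available as `simulate`, `curate`, `assign`,
`profile`, `nrseq` and `copystats` subcommands, and as library functions
(`taxawalk.assign_clade`, `taxawalk.combine`, ...).

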