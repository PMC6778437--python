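"""End-to-end orchestration: simulate -> curate -> assign -> profile.

All results go to files under the configured output directory; identical
configuration and inputs produce byte-identical outputs (floats are
printed with fixed 6-decimal precision, JSON keys are sorted, and no
timestamps are recorded).
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .core import (
    RANKS,
    DEFAULT_QUERY_CODE,
    GeneTree,
    TaxawalkError,
    TaxonomyTable,
    ValidationError,
)
from . import io as twio
from .assign import CladeAssignment, RankAssignment, assign_clade, map_to_ranks
from .curation import filter_inparalogs, midpoint_root
from .identity import nr_reduce
from .profile import combine
from .simulate import (
    SimConfig,
    simulate_gene_trees,
    simulate_sequences,
    simulate_taxonomy,
    write_truth,
)


class StageError(TaxawalkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    """Run configuration; round-trips unchanged through YAML."""

    outdir: str = "taxawalk_out"
    trees: Optional[str] = None  # newick file or directory of *.nwk
    taxonomy: Optional[str] = None  # seven-column TSV
    sequences: Optional[str] = None  # FASTA for NR reduction
    query_code: str = DEFAULT_QUERY_CODE
    support_threshold: float = 50.0
    exclusion_threshold: float = 1.0
    nr_threshold: float = 99.0
    combine_mode: str = "resplit"
    seed: int = 0
    simulate: Optional[SimConfig] = None

    def validate(self) -> "PipelineConfig":
        if not (0.0 <= self.support_threshold <= 100.0):
            raise ValidationError("support_threshold must be in [0, 100]")
        if not (0.0 <= self.nr_threshold <= 100.0):
            raise ValidationError("nr_threshold must be in [0, 100]")
        if self.exclusion_threshold < 0.0:
            raise ValidationError("exclusion_threshold must be >= 0")
        if self.combine_mode not in ("resplit", "drop"):
            raise ValidationError("combine_mode must be 'resplit' or 'drop'")
        if self.simulate is not None:
            self.simulate.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown pipeline option(s): {sorted(unknown)}")
        cfg = cls(**d)
        if sim is not None:
            cfg.simulate = SimConfig.from_dict(sim)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )


def _log(stage: str, message: str) -> None:
    print(f"[taxawalk:{stage}] {message}", file=sys.stderr)


def assignments_to_frame(
    pairs: list[tuple[CladeAssignment, RankAssignment]]
) -> pd.DataFrame:
    rows = []
    for ca, ra in pairs:
        rows.append(
            {
                "protein_id": ra.protein_id,
                "support": "" if ra.support is None else f"{ra.support:.6f}",
                "root_fallback": int(ra.root_fallback),
                "none": int(ra.none_flag),
                "species_codes": ";".join(sorted(ca.species_codes)),
                **{r: ";".join(sorted(ra.ranks[r])) for r in RANKS},
                "unmapped": ";".join(sorted(ra.unmapped)),
            }
        )
    cols = ["protein_id", "support", "root_fallback", "none", "species_codes"]
    cols += list(RANKS) + ["unmapped"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_assignments(df: pd.DataFrame) -> list[RankAssignment]:
    out = []
    for _, row in df.iterrows():
        support = None if str(row["support"]).strip() == "" else float(row["support"])
        ranks = {
            r: frozenset(x for x in str(row[r]).split(";") if x) for r in RANKS
        }
        out.append(
            RankAssignment(
                protein_id=str(row["protein_id"]),
                support=support,
                root_fallback=bool(int(row["root_fallback"])),
                none_flag=bool(int(row["none"])),
                ranks=ranks,
                unmapped=frozenset(
                    x for x in str(row.get("unmapped", "")).split(";") if x
                ),
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; return (and write) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "warnings": []}

    trees_path = config.trees
    taxonomy_path = config.taxonomy
    sequences_path = config.sequences

    # -- simulate ----------------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        simdir = outdir / "simulated"
        simdir.mkdir(exist_ok=True)
        _log("simulate", f"seed={sim.seed} n_trees={sim.n_trees}")
        taxonomy = simulate_taxonomy(sim)
        twio.write_taxonomy(taxonomy, simdir / "taxonomy.tsv")
        sim_pairs = simulate_gene_trees(sim, taxonomy)
        twio.write_newick([gt for gt, _ in sim_pairs], simdir / "trees.nwk")
        seqs, seq_truth = simulate_sequences(sim, nr_threshold=config.nr_threshold)
        twio.write_fasta(seqs, simdir / "sequences.fasta")
        write_truth([t for _, t in sim_pairs], seq_truth, simdir / "truth.json")
        report["stages"]["simulate"] = {
            "n_trees": len(sim_pairs),
            "n_species": len(taxonomy),
            "n_sequences": len(seqs),
        }
        trees_path = trees_path or str(simdir / "trees.nwk")
        taxonomy_path = taxonomy_path or str(simdir / "taxonomy.tsv")
        sequences_path = sequences_path or str(simdir / "sequences.fasta")

    # -- load inputs -------------------------------------------------------
    if trees_path is None or taxonomy_path is None:
        raise StageError("assign", "no gene trees / taxonomy configured")
    tp = Path(trees_path)
    try:
        trees = twio.read_tree_dir(tp) if tp.is_dir() else twio.read_newick(tp)
    except FileNotFoundError as exc:
        raise StageError("assign", f"cannot read gene trees: {exc}") from exc
    if not trees:
        raise StageError("assign", f"no gene trees found in {trees_path}")
    taxonomy = twio.read_taxonomy(taxonomy_path)

    # -- curate ------------------------------------------------------------
    curated: list[GeneTree] = []
    pruned_leaves = 0
    for gt in trees:
        try:
            rooted = gt if gt.is_rooted else midpoint_root(gt)
            filtered = filter_inparalogs(rooted, query_code=config.query_code)
        except TaxawalkError as exc:
            raise StageError("curate", f"tree {gt.name}: {exc}") from exc
        pruned_leaves += len(rooted.leaf_labels()) - len(filtered.leaf_labels())
        curated.append(filtered)
    twio.write_newick(curated, outdir / "curated.nwk")
    report["stages"]["curate"] = {
        "n_trees": len(curated),
        "n_leaves_pruned": pruned_leaves,
    }
    _log("curate", f"{len(curated)} trees, {pruned_leaves} in-paralogue leaves pruned")

    # -- assign ------------------------------------------------------------
    pairs: list[tuple[CladeAssignment, RankAssignment]] = []
    n_fallback = n_none = 0
    for gt in curated:
        try:
            ca: CladeAssignment = assign_clade(
                gt,
                support_threshold=config.support_threshold,
                query_code=config.query_code,
            )
        except TaxawalkError as exc:
            raise StageError("assign", f"tree {gt.name}: {exc}") from exc
        ra = map_to_ranks(ca, taxonomy)
        if ra.unmapped:
            report["warnings"].append(
                f"protein {ra.protein_id}: unmapped species codes "
                + ",".join(sorted(ra.unmapped))
            )
        n_fallback += ca.root_fallback
        n_none += ca.none_flag
        pairs.append((ca, ra))
    ranked = [ra for _, ra in pairs]
    frame = assignments_to_frame(pairs)
    frame.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    report["stages"]["assign"] = {
        "n_proteins": len(ranked),
        "n_root_fallback": n_fallback,
        "n_none": n_none,
    }
    _log("assign", f"{len(ranked)} proteins ({n_fallback} fallback, {n_none} none)")

    # -- profile -----------------------------------------------------------
    profiles = combine(
        ranked,
        exclusion_threshold=config.exclusion_threshold,
        mode=config.combine_mode,
    )
    summary = {}
    for rank in RANKS:
        prof = profiles[rank]
        prof.frame.reset_index().to_csv(
            outdir / f"profile_{rank}.tsv",
            sep="\t",
            index=False,
            float_format="%.6f",
        )
        summary[rank] = {
            "top_taxon": prof.top_taxon(),
            "n_taxa": int(len(prof.frame)),
            "excluded": list(prof.excluded),
        }
    (outdir / "profile_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    report["stages"]["profile"] = {
        "ranks": len(RANKS),
        "top_taxa": {r: summary[r]["top_taxon"] for r in RANKS},
    }
    _log("profile", "profiles written for " + ", ".join(RANKS))

    # -- nrseq (optional) --------------------------------------------------
    if sequences_path is not None:
        seqs = twio.read_fasta(sequences_path)
        try:
            kept = nr_reduce(seqs, threshold=config.nr_threshold)
        except TaxawalkError as exc:
            raise StageError("nrseq", str(exc)) from exc
        twio.write_fasta(kept, outdir / "nr.fasta")
        report["stages"]["nrseq"] = {
            "n_input": len(seqs),
            "n_retained": len(kept),
            "threshold": config.nr_threshold,
        }
        _log("nrseq", f"{len(seqs)} -> {len(kept)} sequences")

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
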