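"""End-to-end orchestration: simulate -> census -> logos -> trees -> report.

A single run is driven by a :class:`RunConfig` (flat key set, YAML
loadable). All randomness fans out from one master seed via
``numpy.random.SeedSequence`` so stages are independently reproducible,
and every stage reads and writes plain files so any stage can be rerun
in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import box_motifs, classifier, phylo, psn_grouping, synthetic_data
from .errors import StageError, ValidationError
from .io_formats import write_newick, write_report, write_seeds
from .tree import TreeNode, to_newick

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    out_dir: str = "trcensus_run"
    seed: int = 0
    log_level: str = "INFO"
    # simulate
    n_genomes: int = 20
    composition: Dict[str, int] = field(
        default_factory=lambda: {"TR1": 1, "TRi": 1, "TR3": 1, "FdR": 1})
    frac_trx3: float = 0.5
    n_background: int = 4
    mutation_rate: float = 0.02
    # seed panel
    seeds_per_family: int = 5
    seed_divergence: float = 0.10
    # census thresholds
    psn_threshold: float = 0.35
    pseudocount: float = 20.0
    evalue_max: float = 1e-10
    max_runs: int = 10
    info_threshold_bits: float = 2.0
    majority_fraction: float = 0.7
    # phylo
    flank_min_fraction: float = 0.5
    min_block_length: int = 2
    gaps_allowed: bool = True
    bootstrap: int = 0
    min_clade_size: int = 2

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValidationError("config file must hold a mapping")
        return cls.from_dict(data)

    def census_config(self) -> classifier.CensusConfig:
        return classifier.CensusConfig(
            psn_threshold=self.psn_threshold,
            pseudocount=self.pseudocount,
            evalue_max=self.evalue_max,
            max_runs=self.max_runs,
            info_threshold_bits=self.info_threshold_bits,
            majority_fraction=self.majority_fraction,
            seed=self.seed)


def _child_seeds(master: int, n: int) -> List[int]:
    return [int(s.generate_state(1)[0])
            for s in np.random.SeedSequence(master).spawn(n)]


def _tree_payload(tree: Optional[TreeNode]) -> Optional[str]:
    return to_newick(tree) if tree is not None else None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the JSON summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest: Dict[str, str] = {}

    def checkpoint(stage: str, status: str) -> None:
        manifest[stage] = status
        with open(manifest_path, "w") as handle:
            json.dump(manifest, handle, indent=2)
            handle.write("\n")

    sim_seed, seed_panel_seed, boot_seed = _child_seeds(config.seed, 3)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
    }

    try:
        # -- simulate -----------------------------------------------------
        checkpoint("simulate", "running")
        dataset = synthetic_data.make_dataset(
            config.n_genomes, config.composition, config.frac_trx3,
            config.n_background, config.mutation_rate, seed=sim_seed)
        data_dir = out_dir / "data"
        synthetic_data.write_dataset(dataset, data_dir)
        seeds = synthetic_data.make_seed_set(
            config.seeds_per_family, config.seed_divergence,
            seed=seed_panel_seed)
        write_seeds(seeds, data_dir / "seeds.fasta",
                    data_dir / "seed_labels.tsv")
        checkpoint("simulate", "done")

        # -- census -------------------------------------------------------
        checkpoint("census", "running")
        outcome = classifier.run_census(
            dataset.genomes, seeds, config.census_config(),
            trx3_seed=synthetic_data.trx3_seed_record(),
            layouts=synthetic_data.seed_layouts(seeds))
        organism_of = {p.protein_id: g.organism_id
                       for g in dataset.genomes for p in g.proteins}
        class_of_org = dataset.class_map()
        rows = []
        for pid, a in sorted(outcome.result.assignments.items()):
            org = organism_of.get(pid, "")
            rows.append({
                "protein_id": pid, "organism_id": org,
                "class": class_of_org.get(org, ""),
                "assigned_label": a.final_label,
                "score_bits": round(a.score_bits, 4),
                "rule_trace": ";".join(a.rule_trace)})
        summary["group_history"] = {
            fam: trace.iterations for fam, trace in outcome.traces.items()}
        summary["label_counts_by_class"] = {
            cls: {k: int(v) for k, v in row.items()}
            for cls, row in outcome.occurrence.to_dict("index").items()}
        summary["cooccurrence"] = {
            "TRi_and_TR1_genomes": int(
                (outcome.cooccurrence["TRi"]
                 & outcome.cooccurrence["TR1"]).sum()),
            "presence": {org: {k: bool(v) for k, v in row.items()}
                         for org, row in
                         outcome.cooccurrence.to_dict("index").items()},
        }
        psn_grouping.write_groups(
            [g for g in outcome.groups.values()], out_dir / "groups.tsv")
        checkpoint("census", "done")

        # -- logos --------------------------------------------------------
        checkpoint("logos", "running")
        logo_dir = out_dir / "logos"
        logo_dir.mkdir(exist_ok=True)
        consensus: Dict[str, Dict[str, str]] = {}
        for fam, boxes in sorted(outcome.boxes.items()):
            members = sorted(outcome.groups[fam].member_ids)
            if not members:
                continue
            for box_name, strings in (
                    ("boxA", [boxes.boxA[p] for p in members
                              if p in boxes.boxA]),
                    ("boxB", [boxes.boxB[p] for p in members
                              if p in boxes.boxB])):
                if not strings:
                    continue
                logo = box_motifs.make_logo(strings)
                box_motifs.write_logo_tsv(
                    logo, logo_dir / f"{fam}_{box_name}.tsv")
                consensus.setdefault(fam, {})[box_name] = \
                    box_motifs.consensus_motif(
                        logo, config.info_threshold_bits,
                        config.majority_fraction)
        summary["consensus_motifs"] = consensus
        checkpoint("logos", "done")

        # -- trees --------------------------------------------------------
        checkpoint("trees", "running")
        tree_dir = out_dir / "trees"
        tree_dir.mkdir(exist_ok=True)
        registry = {p.protein_id: p for g in dataset.genomes
                    for p in g.proteins}
        class_of_leaf = {}
        tr_ids = sorted(pid for pid, a in outcome.result.assignments.items()
                        if a.final_label in synthetic_data.FAMILY_LABELS)
        for pid in tr_ids:
            class_of_leaf[pid] = class_of_org[organism_of[pid]]
        block_params = phylo.BlockParameters(
            config.flank_min_fraction, config.min_block_length,
            config.gaps_allowed)
        seed_record_of = {label: rec for rec, (_p, label, _s)
                          in zip(seeds.records(), seeds.entries)}
        anchor_family = {"TR1": "TR1", "FdR": "TR1", "TRi": "TRi",
                         "TR3": "TR3", "dcTR1": "TR3"}

        def build_member_tree(member_ids, anchor_rec):
            msa = box_motifs.align_group(
                [registry[p] for p in member_ids], anchor_rec)
            msa = box_motifs.MSA(
                [m for m in msa.member_ids if m != anchor_rec.protein_id],
                [r for m, r in zip(msa.member_ids, msa.rows)
                 if m != anchor_rec.protein_id])
            selection = phylo.select_blocks(msa, block_params)
            return msa, selection, phylo.nj_tree(
                phylo.distance_matrix(msa, selection))

        trees_summary: Dict[str, dict] = {}
        per_family: Dict[str, dict] = {}
        all_flags = []
        for fam, group in sorted(outcome.groups.items()):
            members = sorted(group.member_ids & set(tr_ids))
            if len(members) < 3:
                continue
            anchor_rec = seed_record_of[anchor_family[fam]]
            msa, selection, fam_tree = build_member_tree(members, anchor_rec)
            outgroup_leaves = [p for p in members
                               if class_of_leaf[p]
                               == synthetic_data.OUTGROUP_CLASS]
            rooted = None
            if outgroup_leaves and len(outgroup_leaves) < len(members):
                try:
                    rooted = phylo.root_with_outgroup(fam_tree,
                                                      outgroup_leaves)
                except ValidationError as exc:
                    logger.info("%s: outgroup rooting skipped: %s", fam, exc)
            final_tree = rooted or fam_tree
            write_newick(final_tree, tree_dir / f"{fam}.nwk")
            flags = phylo.flag_incongruent_leaves(
                final_tree, class_of_leaf, config.min_clade_size)
            all_flags.extend(
                {"family": fam, "leaf": leaf, "own_class": own,
                 "surrounding_class": other} for leaf, own, other in flags)
            # organism-collapsed copy against the reference taxonomy
            rf = None
            orgs_seen: Dict[str, str] = {}
            for pid in members:
                orgs_seen.setdefault(organism_of[pid], pid)
            if len(orgs_seen) >= 3:
                collapsed = phylo.prune_to(final_tree,
                                           sorted(orgs_seen.values()))
                for leaf in collapsed.leaves():
                    leaf.name = organism_of[leaf.name]
                ref = phylo.prune_to(dataset.reference_tree,
                                     sorted(orgs_seen))
                rf = phylo.robinson_foulds(collapsed, ref)
            entry = {"n_leaves": len(members), "rooted": rooted is not None,
                     "rf_to_reference": rf}
            if config.bootstrap > 0:
                support = phylo.bootstrap_support(
                    msa, selection, config.bootstrap, seed=boot_seed)
                entry["mean_bootstrap_support"] = (
                    round(float(np.mean(list(support.values()))), 4)
                    if support else None)
            per_family[fam] = entry

        dups = []
        if len(tr_ids) >= 3:
            _msa, _sel, combined_tree = build_member_tree(
                tr_ids, seed_record_of["TR1"])
            write_newick(combined_tree, tree_dir / "combined.nwk")
            dups = phylo.detect_duplications(combined_tree, organism_of)
        trees_summary = {
            "per_family": per_family,
            "hgt_flags": all_flags,
            "duplication_candidates": [
                {"organism_id": d.organism_id, "leaves": d.leaf_ids,
                 "mrca_leaves": d.mrca_leaf_ids} for d in dups],
        }
        summary["trees"] = trees_summary
        write_newick(dataset.reference_tree, tree_dir / "reference.nwk")
        checkpoint("trees", "done")

        # -- report -------------------------------------------------------
        checkpoint("report", "running")
        acc = classifier.accuracy(outcome.result, dataset.truth)
        cm = classifier.confusion_matrix(outcome.result, dataset.truth)
        summary["truth_evaluation"] = {
            "accuracy": round(acc, 6),
            "confusion_matrix": {t: {k: int(v) for k, v in row.items()}
                                 for t, row in cm.to_dict("index").items()},
        }
        write_report(rows, summary, out_dir / "report.tsv",
                     out_dir / "summary.json")
        checkpoint("report", "done")
    except ValidationError:
        raise
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        failed = [k for k, v in manifest.items() if v == "running"]
        stage = failed[0] if failed else "unknown"
        checkpoint(stage, f"failed: {exc}")
        raise StageError(f"stage {stage} failed: {exc}") from exc
    return summary
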