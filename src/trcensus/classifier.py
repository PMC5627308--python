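"""Iterative trusted-cutoff enrichment and final subfamily assignment.

Each seed-anchored group is enriched by rebuilding a BoxB profile from
its current members, setting the trusted cutoff to the lowest-scoring
member, rescoring the PNDO pool, and adding every protein at or above
the cutoff — repeated until membership is constant. Final labels come
from the split rules: TR1-group members without both active-site
cysteines become FdR; TR3-group members whose genome lacks a detectable
Trx3-like partner become dcTR1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import box_motifs, profile_search, psn_grouping
from .box_motifs import BoxRegions, SeedLayout
from .errors import FormatError, StageError, ValidationError
from .io_formats import (FAMILY_LABELS, GenomeRecord, ProteinRecord, SeedSet)
from .profile_search import ProfileModel
from .psn_grouping import HomologGroup

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class CensusConfig:
    """All thresholds of the census, with documented defaults."""

    psn_threshold: float = 0.35
    pseudocount: float = 20.0
    evalue_max: float = 1e-10
    max_runs: int = 10
    info_threshold_bits: float = 2.0
    majority_fraction: float = 0.7
    box_spacer: int = box_motifs.BOX_SPACER
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.psn_threshold <= 1.0:
            raise ValidationError("psn_threshold must be within [0, 1]")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be positive")
        if self.max_runs < 1:
            raise ValidationError("max_runs must be >= 1")


@dataclass
class EnrichmentTrace:
    """Per-run membership counts, cutoffs and additions."""

    iterations: List[Tuple[int, int, float, List[str]]] = field(
        default_factory=list)
    converged: bool = False


@dataclass
class Assignment:
    final_label: str
    score_bits: float
    group_of_origin: str
    rule_trace: List[str]


@dataclass
class ClassificationResult:
    """Final label, score and rule trace per protein."""

    assignments: Dict[str, Assignment]

    def label_of(self, protein_id: str) -> str:
        entry = self.assignments.get(protein_id)
        return entry.final_label if entry else "unassigned"


@dataclass
class CensusOutcome:
    result: ClassificationResult
    groups: Dict[str, HomologGroup]
    traces: Dict[str, EnrichmentTrace]
    boxes: Dict[str, BoxRegions]
    profiles: Dict[str, ProfileModel]
    occurrence: pd.DataFrame
    cooccurrence: pd.DataFrame
    pndo_ids: List[str]


# -- enrichment ------------------------------------------------------------

def enrich_group(group: HomologGroup,
                 pndo_pool: Sequence[ProteinRecord],
                 registry: Dict[str, ProteinRecord],
                 anchor_seed: ProteinRecord,
                 layout: SeedLayout,
                 max_runs: int = 10,
                 pseudocount: float = 20.0,
                 background: Optional[np.ndarray] = None,
                 ) -> Tuple[HomologGroup, EnrichmentTrace, ProfileModel]:
    """Grow a group with its own trusted-cutoff BoxB profile to fixpoint.

    Each run re-aligns the current members around the original anchor
    seed, rebuilds the BoxB profile, sets the cutoff to the minimum
    member score, and adds every pool protein at or above it. Membership
    never shrinks; convergence is an unchanged member set.
    """
    members: Set[str] = set(group.member_ids)
    if not members:
        raise ValidationError("cannot enrich an empty group")
    trace = EnrichmentTrace()
    history = list(group.history)
    profile: Optional[ProfileModel] = None
    for run in range(1, max_runs + 1):
        records = [registry[pid] for pid in sorted(members)]
        msa = box_motifs.align_group(records, anchor_seed)
        boxes = box_motifs.extract_boxes(msa, layout)
        region_ids = [pid for pid in msa.member_ids if pid in members]
        regions = [boxes.boxB[pid] for pid in region_ids]
        profile = profile_search.build_profile(
            regions, background, pseudocount, member_ids=region_ids)
        profile = profile_search.trusted_cutoff(
            profile, [registry[pid].sequence for pid in region_ids])
        added = []
        for protein in pndo_pool:
            if protein.protein_id in members:
                continue
            if len(protein.sequence) < profile.width:
                continue
            hit = profile_search.score(profile, protein.sequence,
                                       protein.protein_id)
            if hit.score_bits >= profile.trusted_cutoff:
                added.append(protein.protein_id)
        added.sort()
        members.update(added)
        history.append(len(members))
        trace.iterations.append((run, len(members),
                                 float(profile.trusted_cutoff), added))
        if not added:
            trace.converged = True
            break
    if not trace.converged:
        logger.warning("group %s: enrichment did not converge in %d runs",
                       group.label, max_runs)
    enriched = HomologGroup(group.label, members, set(group.seed_ids),
                            history)
    return enriched, trace, profile


# -- split rules -----------------------------------------------------------

def split_tr1_fdr(tr1_group: HomologGroup, box_regions: BoxRegions
                  ) -> Tuple[HomologGroup, HomologGroup, List[str]]:
    """Partition by the strict two-cysteine active-site rule."""
    tr1_ids: Set[str] = set()
    fdr_ids: Set[str] = set()
    unassigned: List[str] = []
    for pid in sorted(tr1_group.member_ids):
        box_a = box_regions.boxA.get(pid)
        if box_a is None:
            logger.warning("member %s: no BoxA available; left unassigned",
                           pid)
            unassigned.append(pid)
            continue
        if box_motifs.active_site_cys_count(box_a) == 2:
            tr1_ids.add(pid)
        else:
            fdr_ids.add(pid)
    tr1 = HomologGroup("TR1", tr1_ids, tr1_group.seed_ids & tr1_ids)
    fdr = HomologGroup("FdR", fdr_ids, tr1_group.seed_ids & fdr_ids)
    return tr1, fdr, unassigned


_local_aligner = Align.PairwiseAligner()
_local_aligner.mode = "local"
_local_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_local_aligner.open_gap_score = -11
_local_aligner.extend_gap_score = -1


def detect_trx3_partner(genome: GenomeRecord, trx3_seed: ProteinRecord,
                        evalue_max: float = 1e-10) -> bool:
    """True iff some genome protein hits the Trx3 seed below ``evalue_max``.

    Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1);
    E = K * m * n * exp(-lambda * S) with the gapped BLOSUM62 defaults,
    where m is the seed length and n the summed genome protein length.
    """
    if evalue_max <= 0:
        raise ValidationError("evalue_max must be positive")
    if not genome.proteins:
        return False
    m = len(trx3_seed.sequence)
    n = sum(len(p.sequence) for p in genome.proteins)
    best = max(_local_aligner.score(trx3_seed.sequence, p.sequence)
               for p in genome.proteins)
    evalue = KA_K * m * n * math.exp(-KA_LAMBDA * best)
    return evalue < evalue_max


def split_tr3_dctr1(tr3_group: HomologGroup,
                    genomes: Sequence[GenomeRecord],
                    trx3_seed: ProteinRecord,
                    evalue_max: float = 1e-10,
                    organism_of: Optional[Dict[str, str]] = None
                    ) -> Tuple[HomologGroup, HomologGroup, List[str]]:
    """Partition by Trx3-partner presence in each member's genome."""
    genome_of = {g.organism_id: g for g in genomes}
    partner_cache: Dict[str, bool] = {}
    tr3_ids: Set[str] = set()
    dctr1_ids: Set[str] = set()
    unassigned: List[str] = []
    for pid in sorted(tr3_group.member_ids):
        organism = (organism_of or {}).get(pid)
        if organism is None:
            logger.warning("member %s: organism unresolvable; left "
                           "unassigned", pid)
            unassigned.append(pid)
            continue
        genome = genome_of.get(organism)
        if genome is None:
            logger.warning("member %s: organism %s has no genome record; "
                           "left unassigned", pid, organism)
            unassigned.append(pid)
            continue
        if organism not in partner_cache:
            partner_cache[organism] = detect_trx3_partner(
                genome, trx3_seed, evalue_max)
        (tr3_ids if partner_cache[organism] else dctr1_ids).add(pid)
    tr3 = HomologGroup("TR3", tr3_ids, tr3_group.seed_ids & tr3_ids)
    dctr1 = HomologGroup("dcTR1", dctr1_ids,
                         tr3_group.seed_ids & dctr1_ids)
    return tr3, dctr1, unassigned


# -- full census -----------------------------------------------------------

def _seed_layouts(seeds: SeedSet, box_spacer: int,
                  layouts: Optional[Dict[str, SeedLayout]]
                  ) -> Dict[str, SeedLayout]:
    """CxxC-anchored layouts, falling back to the family's modal start.

    A diverged seed can have lost a cysteine of the CxxC motif; its BoxA
    start is then taken from the most common located start among seeds of
    the same family.
    """
    located: Dict[str, Optional[int]] = {}
    starts_by_family: Dict[str, List[int]] = {}
    for pid, label, seq in seeds.entries:
        if layouts and pid in layouts:
            continue
        try:
            start = box_motifs.locate_boxa_start(seq)
        except FormatError:
            start = None
        located[pid] = start
        if start is not None:
            starts_by_family.setdefault(label, []).append(start)
    out: Dict[str, SeedLayout] = {}
    for pid, label, seq in seeds.entries:
        if layouts and pid in layouts:
            out[pid] = layouts[pid]
            continue
        family_starts = starts_by_family.get(label)
        if not family_starts:
            raise FormatError(
                f"no CxxC anchor locatable in any {label} seed")
        modal = max(set(family_starts), key=family_starts.count)
        start = located[pid] if located[pid] == modal else modal
        if located[pid] is not None and located[pid] != modal:
            logger.info("seed %s: CxxC at %d deviates from family mode %d; "
                        "using the mode", pid, located[pid], modal)
        out[pid] = SeedLayout(pid, start,
                              start + box_motifs.BOXA_WIDTH + box_spacer)
    return out


def run_census(genomes: Sequence[GenomeRecord], seeds: SeedSet,
               config: Optional[CensusConfig] = None,
               trx3_seed: Optional[ProteinRecord] = None,
               layouts: Optional[Dict[str, SeedLayout]] = None
               ) -> CensusOutcome:
    """Compose PNDO detection, PSN grouping, enrichment and split rules."""
    config = config or CensusConfig()
    registry: Dict[str, ProteinRecord] = {}
    organism_of: Dict[str, str] = {}
    for genome in genomes:
        for protein in genome.proteins:
            if protein.protein_id in registry:
                raise ValidationError(
                    f"duplicate protein id {protein.protein_id!r}")
            registry[protein.protein_id] = protein
            organism_of[protein.protein_id] = genome.organism_id
    seed_records = seeds.records()
    for rec in seed_records:
        registry[rec.protein_id] = rec
    seed_ids = {rec.protein_id for rec in seed_records}
    seed_layout = _seed_layouts(seeds, config.box_spacer, layouts)

    # 1. PNDO profile from the concatenated seed BoxA+BoxB regions
    regions, member_seqs, member_ids = [], [], []
    for pid, _label, seq in seeds.entries:
        lay = seed_layout[pid]
        regions.append(
            seq[lay.boxa_start:lay.boxa_start + box_motifs.BOXA_WIDTH]
            + seq[lay.boxb_start:lay.boxb_start + box_motifs.BOXB_WIDTH])
        member_seqs.append(seq)
        member_ids.append(pid)
    pndo_profile = profile_search.build_pndo_profile(
        regions, member_seqs, member_ids, pseudocount=config.pseudocount)
    hits = profile_search.find_pndo(genomes, pndo_profile)
    pndo_ids = [h.protein_id for h in hits]
    pool = [registry[pid] for pid in pndo_ids]

    # 2. similarity network over PNDO proteins plus the injected seeds
    graph = psn_grouping.build_psn(pool + seed_records, config.psn_threshold)
    initial_groups = psn_grouping.seed_components(graph, seeds)

    # 3. iterative enrichment per family group
    enriched: Dict[str, HomologGroup] = {}
    traces: Dict[str, EnrichmentTrace] = {}
    profiles: Dict[str, ProfileModel] = {}
    for group in initial_groups:
        anchor_id = min(group.seed_ids)
        try:
            grp, trace, profile = enrich_group(
                group, pool, registry, registry[anchor_id],
                seed_layout[anchor_id], config.max_runs, config.pseudocount)
        except ValidationError as exc:
            raise StageError(f"enrichment of {group.label} failed: {exc}")
        enriched[group.label] = grp
        traces[group.label] = trace
        profiles[group.label] = profile

    # 4. overlap resolution: highest margin (score - cutoff) wins
    candidate: Dict[str, List[Tuple[float, float, str]]] = {}
    for fam, grp in enriched.items():
        profile = profiles[fam]
        for pid in grp.member_ids:
            hit = profile_search.score(profile, registry[pid].sequence, pid)
            margin = hit.score_bits - profile.trusted_cutoff
            candidate.setdefault(pid, []).append(
                (margin, hit.score_bits, fam))
    family_of: Dict[str, str] = {}
    score_of: Dict[str, float] = {}
    margin_logged: Set[str] = set()
    for pid, options in candidate.items():
        options.sort(key=lambda t: (-t[0], t[2]))
        if len(options) > 1:
            margin_logged.add(pid)
            logger.info("protein %s matched %d groups; kept %s by margin",
                        pid, len(options), options[0][2])
        family_of[pid] = options[0][2]
        score_of[pid] = options[0][1]
    final_groups: Dict[str, HomologGroup] = {}
    for fam, grp in enriched.items():
        kept = {pid for pid in grp.member_ids if family_of[pid] == fam}
        final_groups[fam] = HomologGroup(fam, kept, grp.seed_ids & kept,
                                         grp.history)

    # 5. box regions of the resolved groups
    boxes: Dict[str, BoxRegions] = {}
    for fam, grp in final_groups.items():
        if not grp.member_ids:
            continue
        anchor_id = min(enriched[fam].seed_ids)
        records = [registry[pid] for pid in sorted(grp.member_ids)]
        if len(records) >= 2:
            msa = box_motifs.align_group(records, registry[anchor_id])
        else:
            msa = box_motifs.align_group(
                records + [registry[anchor_id]], registry[anchor_id])
        boxes[fam] = box_motifs.extract_boxes(msa, seed_layout[anchor_id])

    # 6. split rules
    rule_of: Dict[str, List[str]] = {
        pid: [f"pndo_hit", f"group:{family_of[pid]}"] for pid in family_of}
    label_of: Dict[str, str] = dict(family_of)
    if "TR1" in final_groups and final_groups["TR1"].member_ids:
        tr1, fdr, miss = split_tr1_fdr(final_groups["TR1"], boxes["TR1"])
        for pid in tr1.member_ids:
            label_of[pid] = "TR1"
            rule_of[pid].append("cys_count=2->TR1")
        for pid in fdr.member_ids:
            label_of[pid] = "FdR"
            rule_of[pid].append("cys_count<2->FdR")
        for pid in miss:
            label_of[pid] = "unassigned"
            rule_of[pid].append("boxA_missing->unassigned")
        final_groups["TR1"], final_groups["FdR"] = tr1, fdr
    if ("TR3" in final_groups and final_groups["TR3"].member_ids
            and trx3_seed is not None):
        tr3, dctr1, miss = split_tr3_dctr1(
            final_groups["TR3"], genomes, trx3_seed, config.evalue_max,
            organism_of)
        # seeds have no genome; keep their family label without the rule
        for pid in tr3.member_ids:
            label_of[pid] = "TR3"
            rule_of[pid].append("trx3_present->TR3")
        for pid in dctr1.member_ids:
            label_of[pid] = "dcTR1"
            rule_of[pid].append("trx3_absent->dcTR1")
        for pid in miss:
            if pid not in seed_ids:
                label_of[pid] = "unassigned"
                rule_of[pid].append("organism_unresolved->unassigned")
        final_groups["TR3"], final_groups["dcTR1"] = tr3, dctr1

    # 7. per-protein result (seeds are reference material, not census output)
    assignments: Dict[str, Assignment] = {}
    for pid in sorted(label_of):
        if pid in seed_ids:
            continue
        trace = list(rule_of[pid])
        if pid in margin_logged:
            trace.insert(1, "margin_resolved")
        assignments[pid] = Assignment(label_of[pid], score_of[pid],
                                      family_of[pid], trace)
    result = ClassificationResult(assignments)

    occurrence = _occurrence_table(result, genomes)
    cooccurrence = _cooccurrence_table(result, genomes)
    return CensusOutcome(result, final_groups, traces, boxes, profiles,
                         occurrence, cooccurrence, pndo_ids)


def _occurrence_table(result: ClassificationResult,
                      genomes: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Label x taxonomy-class contingency table of assigned proteins."""
    counts: Dict[str, Dict[str, int]] = {}
    for genome in genomes:
        cls = genome.taxon_class
        for protein in genome.proteins:
            label = result.label_of(protein.protein_id)
            if label == "unassigned":
                continue
            counts.setdefault(cls, {}).setdefault(label, 0)
            counts[cls][label] += 1
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    return table.reindex(sorted(table.index)).reindex(
        sorted(table.columns), axis=1)


def _cooccurrence_table(result: ClassificationResult,
                        genomes: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Per-genome presence of each final label (for co-occurrence queries)."""
    rows = {}
    labels = list(FAMILY_LABELS)
    for genome in genomes:
        present = {label: False for label in labels}
        for protein in genome.proteins:
            label = result.label_of(protein.protein_id)
            if label in present:
                present[label] = True
        rows[genome.organism_id] = present
    return pd.DataFrame(rows).T.reindex(sorted(rows))


def confusion_matrix(result: ClassificationResult,
                     truth: Dict[str, str]) -> pd.DataFrame:
    """Truth x predicted counts over proteins with a TR-family truth label."""
    pairs = [(t, result.label_of(pid)) for pid, t in truth.items()
             if t in FAMILY_LABELS]
    frame = pd.DataFrame(pairs, columns=["truth", "predicted"])
    return frame.groupby(["truth", "predicted"]).size().unstack(fill_value=0)


def accuracy(result: ClassificationResult, truth: Dict[str, str]) -> float:
    """Fraction of TR-family-truth proteins assigned their true label."""
    relevant = [(pid, t) for pid, t in truth.items() if t in FAMILY_LABELS]
    if not relevant:
        raise ValidationError("truth contains no TR-family proteins")
    hits = sum(1 for pid, t in relevant if result.label_of(pid) == t)
    return hits / len(relevant)
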