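"""Protein similarity networks and seed-anchored homolog groups.

Similarity is global-alignment identity (match +1, mismatch 0, linear
gap -1): the number of identically aligned positions divided by the
alignment length. Edges at or above the threshold define the network;
connected components containing seed proteins become homolog groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import pandas as pd
from Bio import Align

from .errors import ValidationError
from .io_formats import ProteinRecord, SeedSet

logger = logging.getLogger(__name__)


@dataclass
class HomologGroup:
    """A labeled set of member protein ids with its anchoring seeds."""

    label: str
    member_ids: Set[str]
    seed_ids: Set[str] = field(default_factory=set)
    history: List[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.seed_ids <= self.member_ids:
            raise ValidationError("seed_ids must be a subset of member_ids")


@dataclass
class PSNGraph:
    """Undirected similarity graph; retains all computed pair similarities."""

    nodes: List[str]
    edges: List[Tuple[str, str, float]]
    threshold: float
    similarities: Dict[FrozenSet[str], float] = field(default_factory=dict)

    def similarity(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.similarities.get(frozenset((a, b)), 0.0)

    def components(self) -> List[Set[str]]:
        """Connected components via union-find, deterministically ordered."""
        parent = {n: n for n in self.nodes}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, _sim in self.edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        comps: Dict[str, Set[str]] = {}
        for n in self.nodes:
            comps.setdefault(find(n), set()).add(n)
        return sorted(comps.values(), key=lambda c: min(c))


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def pairwise_similarity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Global-alignment identity in [0, 1]; symmetric by construction."""
    if not a.sequence or not b.sequence:
        raise ValidationError("cannot align empty sequences")
    # canonical ordering makes the chosen optimal alignment, and hence the
    # identity, independent of argument order
    s1, s2 = sorted((a.sequence, b.sequence))
    if s1 == s2:
        return 1.0
    aln = _aligner.align(s1, s2)[0]
    identities = int(aln.counts().identities)
    return identities / aln.length


def build_psn(proteins: Sequence[ProteinRecord], threshold: float) -> PSNGraph:
    """All-vs-all similarity network; edges kept iff sim >= threshold."""
    if threshold < 0.0:
        raise ValidationError("threshold must be >= 0")
    ordered = sorted(proteins, key=lambda p: p.protein_id)
    ids = [p.protein_id for p in ordered]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate protein ids in PSN input")
    sims: Dict[FrozenSet[str], float] = {}
    edges: List[Tuple[str, str, float]] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            sim = pairwise_similarity(ordered[i], ordered[j])
            sims[frozenset((ids[i], ids[j]))] = sim
            if sim >= threshold:
                edges.append((ids[i], ids[j], sim))
    return PSNGraph(ids, edges, threshold, sims)


def seed_components(graph: PSNGraph, seeds: SeedSet) -> List[HomologGroup]:
    """Groups from components containing seeds, one group per family.

    In a component with seeds of several families, each non-seed member
    goes to the family of its highest-similarity seed (ties break to the
    lexicographically smallest label, logged). Seedless components are
    not grouped; they stay in the PNDO pool for later enrichment.
    """
    seed_family = {pid: label for pid, label, _ in seeds.entries}
    node_set = set(graph.nodes)
    for pid in seed_family:
        if pid not in node_set:
            raise ValidationError(f"seed {pid!r} absent from the graph")

    members: Dict[str, Set[str]] = {}
    anchors: Dict[str, Set[str]] = {}
    for component in graph.components():
        comp_seeds = sorted(s for s in component if s in seed_family)
        if not comp_seeds:
            continue
        families = sorted({seed_family[s] for s in comp_seeds})
        for s in comp_seeds:
            fam = seed_family[s]
            members.setdefault(fam, set()).add(s)
            anchors.setdefault(fam, set()).add(s)
        for node in sorted(component):
            if node in seed_family:
                continue
            if len(families) == 1:
                best = families[0]
            else:
                best_sim = -1.0
                best = None
                tied = []
                for s in comp_seeds:
                    sim = graph.similarity(node, s)
                    fam = seed_family[s]
                    if sim > best_sim:
                        best_sim, best, tied = sim, fam, [fam]
                    elif sim == best_sim and fam not in tied:
                        tied.append(fam)
                if len(tied) > 1:
                    best = min(tied)
                    logger.info("node %s tied between families %s; "
                                "assigned %s", node, sorted(tied), best)
            members.setdefault(best, set()).add(node)
    return [HomologGroup(fam, members[fam], anchors.get(fam, set()),
                         history=[len(members[fam])])
            for fam in sorted(members)]


def write_edge_list(graph: PSNGraph, path) -> None:
    pd.DataFrame(graph.edges, columns=["id_a", "id_b", "similarity"]).to_csv(
        path, sep="\t", index=False)


def write_groups(groups: Sequence[HomologGroup], path) -> None:
    rows = []
    for group in groups:
        anchor = ",".join(sorted(group.seed_ids))
        for pid in sorted(group.member_ids):
            rows.append((pid, group.label, anchor))
    pd.DataFrame(rows, columns=["protein_id", "label", "seed_anchor"]).to_csv(
        path, sep="\t", index=False)
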