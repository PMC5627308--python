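"""Synthetic proteomes with planted TR-family motif structure.

Every pipeline stage is testable without downloading genomes: proteins
are instantiated from family templates that carry the FAD-binding motifs
(GxGxxG, ATG, GxFAAGD) and the BoxA/BoxB active-site/NAD(P)H-binding
motifs, genomes carry an optional Trx3-like partner, and a reference
taxonomy tree over two ingroup classes plus an outgroup is emitted.

Template semantics: a pattern position is a fixed residue, a bracketed
alternative set (``[RK]``), or ``x`` (free). Each family resolves its
pattern against a family-specific backbone sequence: free positions take
the backbone letter, bracketed positions take the first alternative, so
every family has a concrete ~300-residue reference sequence. Proteins
are the reference with i.i.d. per-position mutations at ``mutation_rate``
(replacement drawn uniformly over the 20 letters).

Backbone letters deliberately exclude cysteine so the only C..C match in
any reference is the planted active site; this keeps CxxC anchoring
exact. Background (non-TR) proteins are uniform over all 20 letters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .box_motifs import BOX_SPACER, BOXA_WIDTH, BOXB_WIDTH, SeedLayout
from .errors import ValidationError
from .io_formats import (AMINO_ACIDS, FAMILY_LABELS, SEED_LABELS,
                         GenomeRecord, ProteinRecord, SeedSet, write_fasta,
                         write_genome_table)
from .tree import TreeNode, parse_newick

#: backbone alphabet: the 20 amino acids minus cysteine (see module doc).
_BACKBONE_ALPHABET = AMINO_ACIDS.replace("C", "")

PROTEIN_LENGTH = 300
BOXA_OFFSET = 120
BOXB_OFFSET = BOXA_OFFSET + BOXA_WIDTH + BOX_SPACER
FAD_MOTIFS = {"GxGxxG": 5, "ATG": 34, "GxFAAGD": 60}

TRX3_LENGTH = 105
TRX3_MOTIF = "WCGPC"
TRX3_MOTIF_OFFSET = 30

INGROUP_CLASSES = ("Deltaproteobacteria_like", "Clostridia_like")
OUTGROUP_CLASS = "Actinobacteria_like"
CLASSES = INGROUP_CLASSES + (OUTGROUP_CLASS,)
_PHYLUM_OF = {
    "Deltaproteobacteria_like": "Proteobacteria_like",
    "Clostridia_like": "Firmicutes_like",
    "Actinobacteria_like": "Actinobacteria_like",
}

_BOXA_PATTERNS = {
    "TR1": "G[RK]GVSYCxxCxxxxxxFxxxxxxGGGxxAxE",
    "TRi": "G[KR]GVSYCxxCxxxxxxFxxxxxxGxGxxAxN",
    "FdR": "G[RK]GVSYSxxSxxxxxxFxxxxxxGGGxxAxE",
    "TR3": "CxQVHYCxxCxxxxxxPxxxxxxGGGxxAxE",
    "dcTR1": "GKGVHYCxxCxxxxxxMxxxxxxGGGxxAxE",
}
_BOXB_PATTERNS = {
    "TR1": "xxxVxxxHRRDx[FL]Rxxxxxx",
    "FdR": "xxxVxxxHRRDx[FL]Rxxxxxx",
    "TRi": "xxxVxxxTQGKxxSIxxxxx",
    "TR3": "xxxVxxxxNGKxxSIxxxxx",
    "dcTR1": "xxxVxxxxNGKxxSIxxxxx",
}

# backbone derivation: (parent family or None for the ancestral sequence,
# substitution rate applied to the parent backbone, rng salt)
_BACKBONE_PLAN = {
    "TR1": (None, 0.0, 11),
    "TRi": (None, 0.35, 12),
    "TR3": (None, 0.30, 13),
    "FdR": ("TR1", 0.02, 14),
    "dcTR1": ("TR3", 0.02, 15),
}
_MASTER_SEED = 761_2020

#: taxon-class divergence applied to linker/tail positions only (boxes and
#: FAD motifs untouched), giving gene trees a class signal without moving
#: classification scores; the outgroup class diverges most.
CLASS_DIVERGENCE = {
    "Deltaproteobacteria_like": 0.05,
    "Clostridia_like": 0.05,
    "Actinobacteria_like": 0.12,
}
_CLASS_SALT = {"Deltaproteobacteria_like": 21, "Clostridia_like": 22,
               "Actinobacteria_like": 23}


def parse_pattern(pattern: str) -> List[str]:
    """Tokenize a motif pattern into per-column specs.

    Each token is ``"x"`` (free), a single residue, or a string of
    alternative residues (from a bracketed group).
    """
    tokens = []
    for tok in re.findall(r"\[[A-Z]+\]|[A-Zx]", pattern):
        tokens.append(tok[1:-1] if tok.startswith("[") else tok)
    if sum(len(t) for t in re.findall(r"\[[A-Z]+\]|[A-Zx]",
                                      pattern)) != len(pattern):
        raise ValidationError(f"unparseable pattern {pattern!r}")
    return tokens


@dataclass
class FamilyTemplate:
    """Motif layout and concrete reference sequence for one TR family."""

    label: str
    boxA_template: str
    boxB_template: str
    flanking: Dict[str, int]
    total_length: int
    reference: str

    def __post_init__(self):
        if len(parse_pattern(self.boxA_template)) != BOXA_WIDTH:
            raise ValidationError("BoxA template must span 31 columns")
        if len(parse_pattern(self.boxB_template)) != BOXB_WIDTH:
            raise ValidationError("BoxB template must span 20 columns")
        if len(self.reference) != self.total_length:
            raise ValidationError("reference/total_length mismatch")

    @property
    def boxA_reference(self) -> str:
        return self.reference[BOXA_OFFSET:BOXA_OFFSET + BOXA_WIDTH]

    @property
    def boxB_reference(self) -> str:
        return self.reference[BOXB_OFFSET:BOXB_OFFSET + BOXB_WIDTH]


def _random_backbone(rng: np.random.Generator, length: int) -> List[str]:
    return [_BACKBONE_ALPHABET[i]
            for i in rng.integers(len(_BACKBONE_ALPHABET), size=length)]


def _substitute(seq: List[str], rate: float,
                rng: np.random.Generator) -> List[str]:
    out = list(seq)
    mask = rng.random(len(seq)) < rate
    draws = rng.integers(len(_BACKBONE_ALPHABET), size=int(mask.sum()))
    for pos, d in zip(np.flatnonzero(mask), draws):
        out[pos] = _BACKBONE_ALPHABET[d]
    return out


def _overlay(seq: List[str], pattern: str, offset: int) -> None:
    for j, token in enumerate(parse_pattern(pattern)):
        if token != "x":
            seq[offset + j] = token[0]  # first alternative resolves brackets


_template_cache: Dict[str, FamilyTemplate] = {}


def _backbone(label: str) -> List[str]:
    parent, rate, salt = _BACKBONE_PLAN[label]
    if parent is None:
        base = _random_backbone(np.random.default_rng(_MASTER_SEED),
                                PROTEIN_LENGTH)
    else:
        base = _backbone(parent)
    return _substitute(base, rate, np.random.default_rng(_MASTER_SEED + salt))


def family_template(label: str) -> FamilyTemplate:
    """The canonical template (and reference sequence) for a family."""
    if label not in FAMILY_LABELS:
        raise ValidationError(f"unknown family label {label!r}")
    if label not in _template_cache:
        seq = _backbone(label)
        for motif, offset in FAD_MOTIFS.items():
            _overlay(seq, motif, offset)
        _overlay(seq, _BOXA_PATTERNS[label], BOXA_OFFSET)
        _overlay(seq, _BOXB_PATTERNS[label], BOXB_OFFSET)
        _template_cache[label] = FamilyTemplate(
            label=label,
            boxA_template=_BOXA_PATTERNS[label],
            boxB_template=_BOXB_PATTERNS[label],
            flanking=dict(FAD_MOTIFS),
            total_length=PROTEIN_LENGTH,
            reference="".join(seq),
        )
    return _template_cache[label]


def _linker_positions() -> List[int]:
    covered = set()
    for motif, offset in FAD_MOTIFS.items():
        covered.update(range(offset, offset + len(parse_pattern(motif))))
    covered.update(range(BOXA_OFFSET, BOXA_OFFSET + BOXA_WIDTH))
    covered.update(range(BOXB_OFFSET, BOXB_OFFSET + BOXB_WIDTH))
    return [p for p in range(PROTEIN_LENGTH) if p not in covered]


_class_ref_cache: Dict[Tuple[str, str], str] = {}


def class_reference(label: str, taxon_class: str) -> str:
    """Family reference with deterministic class-level linker divergence."""
    if taxon_class not in CLASS_DIVERGENCE:
        raise ValidationError(f"unknown taxon class {taxon_class!r}")
    key = (label, taxon_class)
    if key not in _class_ref_cache:
        seq = list(family_template(label).reference)
        rate = CLASS_DIVERGENCE[taxon_class]
        salt = 1000 * _CLASS_SALT[taxon_class] + _BACKBONE_PLAN[label][2]
        rng = np.random.default_rng(_MASTER_SEED + salt)
        positions = _linker_positions()
        mask = rng.random(len(positions)) < rate
        draws = rng.integers(len(_BACKBONE_ALPHABET), size=int(mask.sum()))
        for idx, d in zip(np.flatnonzero(mask), draws):
            seq[positions[idx]] = _BACKBONE_ALPHABET[d]
        _class_ref_cache[key] = "".join(seq)
    return _class_ref_cache[key]


def trx3_reference() -> str:
    seq = _random_backbone(np.random.default_rng(_MASTER_SEED + 99),
                           TRX3_LENGTH)
    for j, c in enumerate(TRX3_MOTIF):
        seq[TRX3_MOTIF_OFFSET + j] = c
    return "".join(seq)


def trx3_seed_record() -> ProteinRecord:
    return ProteinRecord("seed_Trx3", trx3_reference(),
                         organism_id="__seed__", description="Trx3 template")


def _mutate(reference: str, mutation_rate: float,
            rng: np.random.Generator) -> str:
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValidationError("mutation_rate must be within [0, 1]")
    seq = list(reference)
    mask = rng.random(len(seq)) < mutation_rate
    draws = rng.integers(len(AMINO_ACIDS), size=int(mask.sum()))
    for pos, d in zip(np.flatnonzero(mask), draws):
        seq[pos] = AMINO_ACIDS[d]
    return "".join(seq)


def make_protein(label: str, mutation_rate: float,
                 rng: np.random.Generator, protein_id: str = "",
                 organism_id: str = "",
                 taxon_class: Optional[str] = None) -> ProteinRecord:
    """Instantiate a family member from its (class-adjusted) reference."""
    if taxon_class is None:
        reference = family_template(label).reference
    else:
        reference = class_reference(label, taxon_class)
    seq = _mutate(reference, mutation_rate, rng)
    return ProteinRecord(protein_id or f"{label}_protein", seq,
                         organism_id=organism_id,
                         description=f"planted {label}")


def make_trx3(mutation_rate: float, rng: np.random.Generator,
              protein_id: str, organism_id: str = "") -> ProteinRecord:
    return ProteinRecord(protein_id,
                         _mutate(trx3_reference(), mutation_rate, rng),
                         organism_id=organism_id,
                         description="planted Trx3 partner")


def make_background(rng: np.random.Generator, protein_id: str,
                    organism_id: str = "",
                    length: int = PROTEIN_LENGTH) -> ProteinRecord:
    seq = "".join(AMINO_ACIDS[i]
                  for i in rng.integers(len(AMINO_ACIDS), size=length))
    return ProteinRecord(protein_id, seq, organism_id=organism_id,
                         description="background")


def template_layout(seed_id: str) -> SeedLayout:
    """Box layout for any unmutated template instantiation."""
    return SeedLayout(seed_id, BOXA_OFFSET, BOXB_OFFSET)


@dataclass
class SyntheticDataset:
    """Genomes plus ground truth and a class-structured reference tree."""

    genomes: List[GenomeRecord]
    truth: Dict[str, str]  # protein_id -> family label | "Trx3" | "background"
    reference_tree: TreeNode
    rng_seed: int

    def class_map(self) -> Dict[str, str]:
        return {g.organism_id: g.taxon_class for g in self.genomes}

    def all_proteins(self) -> List[ProteinRecord]:
        return [p for g in self.genomes for p in g.proteins]


def _class_clade(organism_ids: List[str], length: float) -> TreeNode:
    if len(organism_ids) == 1:
        return TreeNode(organism_ids[0], length)
    node = TreeNode(None, length)
    for gid in organism_ids:
        node.add_child(TreeNode(gid, 0.1))
    return node


def build_reference_tree(class_of: Dict[str, str]) -> TreeNode:
    """Rooted tree grouping organisms by class, outgroup attached last."""
    by_class: Dict[str, List[str]] = {}
    for gid in sorted(class_of):
        by_class.setdefault(class_of[gid], []).append(gid)
    ingroup = [c for c in INGROUP_CLASSES if by_class.get(c)]
    root = TreeNode()
    if len(ingroup) == 1:
        root.add_child(_class_clade(by_class[ingroup[0]], 0.2))
    elif ingroup:
        inner = TreeNode(None, 0.2)
        for cls in ingroup:
            inner.add_child(_class_clade(by_class[cls], 0.2))
        root.add_child(inner)
    if by_class.get(OUTGROUP_CLASS):
        root.add_child(_class_clade(by_class[OUTGROUP_CLASS], 0.4))
    return root


def make_dataset(n_genomes: int,
                 per_genome_composition: Dict[str, int],
                 frac_trx3: float = 0.0,
                 n_background: int = 5,
                 mutation_rate: float = 0.0,
                 seed: int = 0) -> SyntheticDataset:
    """Generate a dataset of genomes with planted TR proteins.

    Taxonomy classes are assigned round-robin (two ingroup classes plus
    the outgroup class). If the composition requests TR3 proteins, each
    genome carries a Trx3-like partner with probability ``frac_trx3``;
    TR3 proteins in partner-less genomes are truth-labeled ``dcTR1``
    (the split rule is defined by partner presence, not sequence).
    """
    if not 0.0 <= frac_trx3 <= 1.0:
        raise ValidationError("frac_trx3 must be within [0, 1]")
    if n_genomes < 1:
        raise ValidationError("n_genomes must be >= 1")
    for label, count in per_genome_composition.items():
        if label not in FAMILY_LABELS:
            raise ValidationError(f"unknown composition label {label!r}")
        if count < 0:
            raise ValidationError("composition counts must be >= 0")

    rng = np.random.default_rng(seed)
    genomes: List[GenomeRecord] = []
    truth: Dict[str, str] = {}
    for i in range(n_genomes):
        gid = f"g{i + 1:03d}"
        cls = CLASSES[i % len(CLASSES)]
        lineage = (_PHYLUM_OF[cls], cls, f"order_{cls[:6]}",
                   f"family_{gid}", f"genus_{gid}")
        proteins: List[ProteinRecord] = []
        tr3_ids: List[str] = []
        for label in sorted(per_genome_composition):
            for c in range(per_genome_composition[label]):
                pid = f"{gid}_{label}_{c + 1}"
                proteins.append(make_protein(label, mutation_rate, rng,
                                             pid, gid, taxon_class=cls))
                truth[pid] = label
                if label == "TR3":
                    tr3_ids.append(pid)
        if per_genome_composition.get("TR3", 0) > 0:
            if rng.random() < frac_trx3:
                pid = f"{gid}_Trx3"
                proteins.append(make_trx3(mutation_rate, rng, pid, gid))
                truth[pid] = "Trx3"
            else:
                for pid in tr3_ids:
                    truth[pid] = "dcTR1"
        for k in range(n_background):
            pid = f"{gid}_bg_{k + 1}"
            proteins.append(make_background(rng, pid, gid))
            truth[pid] = "background"
        genomes.append(GenomeRecord(gid, lineage, proteins))

    tree = build_reference_tree(
        {g.organism_id: g.taxon_class for g in genomes})
    return SyntheticDataset(genomes, truth, tree, seed)


def make_seed_set(n_per_family: int = 5, mutation_rate: float = 0.10,
                  seed: int = 2021) -> SeedSet:
    """Seed proteins (TRi/TR1/TR3) instantiated from the templates.

    The defaults emulate a diverse panel of experimentally known
    reference proteins: with several diverged seeds per family the
    trusted cutoff (minimum seed score) sits safely below the scores of
    clean family members, which is what makes cutoff-based recovery of
    unseen homologs possible at all.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for fam in SEED_LABELS:
        for k in range(n_per_family):
            rec = make_protein(fam, mutation_rate, rng,
                               f"seed_{fam}_{k + 1}")
            entries.append((rec.protein_id, fam, rec.sequence))
    return SeedSet(entries)


def seed_layouts(seed_set: SeedSet) -> Dict[str, SeedLayout]:
    """Template box layouts for every seed in a synthetic seed set."""
    return {pid: template_layout(pid) for pid, _label, _seq in
            seed_set.entries}


def hgt_fixture() -> Tuple[TreeNode, Dict[str, str], str]:
    """A gene tree with one cross-class transfer planted.

    Returns (tree, leaf->class map, name of the transferred leaf). The
    transferred leaf is a Deltaproteobacteria-like sequence nested inside
    the Clostridia-like clade.
    """
    newick = ("((((c1:0.05,c2:0.05):0.05,hgt_d9:0.10):0.10,c3:0.15):0.20,"
              "((d1:0.05,d2:0.05):0.10,d3:0.12):0.20,"
              "(o1:0.10,o2:0.10):0.40);")
    tree = parse_newick(newick)
    class_map = {"c1": "Clostridia_like", "c2": "Clostridia_like",
                 "c3": "Clostridia_like",
                 "d1": "Deltaproteobacteria_like",
                 "d2": "Deltaproteobacteria_like",
                 "d3": "Deltaproteobacteria_like",
                 "hgt_d9": "Deltaproteobacteria_like",
                 "o1": OUTGROUP_CLASS, "o2": OUTGROUP_CLASS}
    return tree, class_map, "hgt_d9"


# -- on-disk emission ------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir) -> Dict[str, Path]:
    """Write FASTA per genome, genome table, truth table and Newick tree."""
    out_dir = Path(out_dir)
    proteome_dir = out_dir / "proteomes"
    proteome_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for genome in dataset.genomes:
        fasta_name = f"{genome.organism_id}.fasta"
        write_fasta(genome.proteins, proteome_dir / fasta_name)
        rows.append({
            "organism_id": genome.organism_id,
            "phylum": genome.lineage[0], "class": genome.lineage[1],
            "order": genome.lineage[2], "family": genome.lineage[3],
            "genus": genome.lineage[4], "proteome_file": fasta_name,
        })
    table_path = out_dir / "genomes.tsv"
    write_genome_table(rows, table_path)
    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(sorted(dataset.truth.items()),
                 columns=["protein_id", "label"]).to_csv(
        truth_path, sep="\t", index=False)
    tree_path = out_dir / "reference_tree.nwk"
    from .io_formats import write_newick
    write_newick(dataset.reference_tree, tree_path)
    return {"proteome_dir": proteome_dir, "genome_table": table_path,
            "truth": truth_path, "reference_tree": tree_path}
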