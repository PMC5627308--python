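"""Readers and writers for the formats the pipeline touches.

FASTA proteomes, the genome/taxonomy table, seed FASTA + label TSV,
Newick trees, and the final classification report (TSV + JSON).

FASTA dialect: the first whitespace-delimited header token is the record
id, the remainder the description. Sequences are uppercased; letters
outside the strict 20-letter alphabet (plus X) are coerced to X with a
logged warning so real-world proteomes pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .errors import FormatError
from .tree import TreeNode, parse_newick, to_newick

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS) | {"X"}

FAMILY_LABELS = ("TRi", "TR1", "FdR", "TR3", "dcTR1")
SEED_LABELS = ("TRi", "TR1", "TR3")

LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass
class ProteinRecord:
    """An amino-acid sequence with its identity and genome of origin."""

    protein_id: str
    sequence: str
    organism_id: str = ""
    description: str = ""

    def __post_init__(self):
        if not self.protein_id:
            raise FormatError("protein_id must be non-empty")
        if not self.sequence or any(c.isspace() for c in self.sequence):
            raise FormatError(
                f"invalid sequence for protein {self.protein_id!r}")


@dataclass
class GenomeRecord:
    """An organism with its 5-rank lineage and protein set."""

    organism_id: str
    lineage: Tuple[str, str, str, str, str]
    proteins: List[ProteinRecord] = field(default_factory=list)

    def __post_init__(self):
        if len(self.lineage) != 5 or any(not r for r in self.lineage):
            raise FormatError(
                f"genome {self.organism_id!r}: lineage must have exactly "
                f"5 non-empty ranks {LINEAGE_RANKS}")
        self.lineage = tuple(self.lineage)
        for p in self.proteins:
            if p.organism_id != self.organism_id:
                raise FormatError(
                    f"protein {p.protein_id!r} carries organism "
                    f"{p.organism_id!r}, expected {self.organism_id!r}")

    @property
    def taxon_class(self) -> str:
        return self.lineage[1]


@dataclass
class SeedSet:
    """Reference proteins with subfamily labels anchoring the census."""

    entries: List[Tuple[str, str, str]]  # (protein_id, family_label, sequence)

    def __post_init__(self):
        for pid, label, _seq in self.entries:
            if label not in SEED_LABELS:
                raise FormatError(
                    f"seed {pid!r}: label {label!r} not in {SEED_LABELS}")
        if not self.entries:
            raise FormatError("seed set is empty")

    def by_family(self) -> Dict[str, List[Tuple[str, str]]]:
        out: Dict[str, List[Tuple[str, str]]] = {}
        for pid, label, seq in self.entries:
            out.setdefault(label, []).append((pid, seq))
        return out

    def records(self) -> List[ProteinRecord]:
        return [ProteinRecord(pid, seq, organism_id="__seed__",
                              description=f"seed {label}")
                for pid, label, seq in self.entries]


# -- FASTA ----------------------------------------------------------------

def _clean_sequence(raw: str, protein_id: str) -> str:
    seq = raw.upper()
    bad = sorted({c for c in seq if c not in _VALID})
    if bad:
        logger.warning("protein %s: non-standard letters %s mapped to X",
                       protein_id, "".join(bad))
        seq = "".join(c if c in _VALID else "X" for c in seq)
    return seq


def read_fasta(path) -> List[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects."""
    path = Path(path)
    records: List[ProteinRecord] = []
    seen = set()
    header = None
    chunks: List[str] = []

    def flush():
        if header is None:
            return
        tokens = header.split(None, 1)
        if not tokens:
            raise FormatError(f"{path}: empty FASTA header")
        pid = tokens[0]
        if pid in seen:
            raise FormatError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = _clean_sequence("".join(chunks), pid)
        if not seq:
            raise FormatError(f"{path}: record {pid!r} has no sequence")
        records.append(ProteinRecord(
            pid, seq, description=tokens[1] if len(tokens) > 1 else ""))

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before any header")
                chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            handle.write(f">{rec.protein_id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i:i + width] + "\n")


# -- genome table ---------------------------------------------------------

GENOME_TABLE_COLUMNS = ("organism_id", "phylum", "class", "order",
                        "family", "genus", "proteome_file")


def read_genome_table(path, proteome_dir) -> List[GenomeRecord]:
    """Read the genome/taxonomy TSV and load each row's proteome FASTA."""
    path = Path(path)
    proteome_dir = Path(proteome_dir)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENOME_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    genomes: List[GenomeRecord] = []
    for _, row in table.iterrows():
        if row[list(GENOME_TABLE_COLUMNS)].isna().any():
            raise FormatError(
                f"{path}: row for organism {row.get('organism_id')!r} has "
                f"missing fields")
        lineage = tuple(row[r] for r in LINEAGE_RANKS)
        proteome_path = proteome_dir / row["proteome_file"]
        if not proteome_path.exists():
            raise FileNotFoundError(f"proteome file not found: {proteome_path}")
        proteins = read_fasta(proteome_path)
        stamped = [ProteinRecord(p.protein_id, p.sequence,
                                 organism_id=row["organism_id"],
                                 description=p.description)
                   for p in proteins]
        genomes.append(GenomeRecord(row["organism_id"], lineage, stamped))
    return genomes


def write_genome_table(rows: Sequence[dict], path) -> None:
    pd.DataFrame(rows, columns=list(GENOME_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False)


# -- seeds ----------------------------------------------------------------

def read_seeds(fasta_path, labels_path) -> SeedSet:
    """Read seed sequences (FASTA) and their family labels (TSV)."""
    records = {r.protein_id: r for r in read_fasta(fasta_path)}
    table = pd.read_csv(labels_path, sep="\t", dtype=str)
    for col in ("protein_id", "family_label"):
        if col not in table.columns:
            raise FormatError(f"{labels_path}: missing column {col!r}")
    entries = []
    for _, row in table.iterrows():
        pid = row["protein_id"]
        if pid not in records:
            raise FormatError(f"seed {pid!r} not present in {fasta_path}")
        entries.append((pid, row["family_label"], records[pid].sequence))
    return SeedSet(entries)


def write_seeds(seed_set: SeedSet, fasta_path, labels_path) -> None:
    write_fasta(seed_set.records(), fasta_path)
    pd.DataFrame(
        [(pid, label) for pid, label, _ in seed_set.entries],
        columns=["protein_id", "family_label"],
    ).to_csv(labels_path, sep="\t", index=False)


# -- Newick ---------------------------------------------------------------

def read_newick(path) -> TreeNode:
    with open(path) as handle:
        return parse_newick(handle.read())


def write_newick(tree: TreeNode, path) -> None:
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        raise FormatError("tree leaves must have unique names")
    with open(path, "w") as handle:
        handle.write(to_newick(tree) + "\n")


# -- classification report ------------------------------------------------

REPORT_COLUMNS = ("protein_id", "organism_id", "class", "assigned_label",
                  "score_bits", "rule_trace")


def write_report(rows: Sequence[dict], summary: dict, tsv_path, json_path) -> None:
    """Write the per-protein report TSV and the JSON run summary."""
    frame = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    frame.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
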