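"""BoxA/BoxB sub-region extraction, sequence logos and consensus motifs.

The active-site/NAD(P)H-binding region of each homolog group is split
into two fixed-width sub-regions: BoxA (31 columns; Trx-binding G[R/K]G,
VSY, the CxxC active site, the aromatic Trx-binding column and the
GGGxxAxE pyrophosphate motif) and BoxB (20 columns; the 2'-phosphate
binding motif, HRRD-type or TQ/NGK-type).

Group members are star-aligned around an anchor seed, and box columns
follow the seed's residues, so member insertions never inflate the
31/20-column contract.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import FormatError, ValidationError
from .io_formats import AMINO_ACIDS, ProteinRecord

BOXA_WIDTH = 31
BOXB_WIDTH = 20
#: residues between the end of BoxA and the start of BoxB in the modeled
#: domain architecture (fixed spacer; member insertions are handled by the
#: alignment, not by this constant).
BOX_SPACER = 8

#: 0-based offsets of the two active-site cysteines inside BoxA (CxxC).
CYS_POSITIONS = (6, 9)

_MAX_INFO = math.log2(len(AMINO_ACIDS))


@dataclass
class MSA:
    """Equal-length gapped rows over the member ids, in input order."""

    member_ids: List[str]
    rows: List[str]

    def __post_init__(self):
        if len(self.member_ids) != len(self.rows):
            raise ValidationError("MSA ids and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("MSA rows must have equal length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, member_id: str) -> str:
        try:
            return self.rows[self.member_ids.index(member_id)]
        except ValueError:
            raise ValidationError(f"member {member_id!r} not in MSA") from None


@dataclass
class SeedLayout:
    """BoxA/BoxB start positions in the anchor seed's own coordinates."""

    seed_id: str
    boxa_start: int
    boxb_start: int

    def __post_init__(self):
        if self.boxa_start < 0 or self.boxb_start <= self.boxa_start:
            raise ValidationError("box starts must satisfy 0 <= A < B")


@dataclass
class BoxRegions:
    """Per-member 31-column BoxA and 20-column BoxB strings."""

    boxA: Dict[str, str]
    boxB: Dict[str, str]
    anchors: Tuple[int, int]  # MSA columns of BoxA col 1 and BoxB col 1

    def __post_init__(self):
        for pid, s in self.boxA.items():
            if len(s) != BOXA_WIDTH:
                raise ValidationError(f"BoxA of {pid!r} is not {BOXA_WIDTH} aa")
        for pid, s in self.boxB.items():
            if len(s) != BOXB_WIDTH:
                raise ValidationError(f"BoxB of {pid!r} is not {BOXB_WIDTH} aa")


@dataclass
class SequenceLogo:
    """Per-column residue frequencies (gaps excluded) and information."""

    frequencies: List[Dict[str, float]]
    information: np.ndarray  # bits per column

    @property
    def width(self) -> int:
        return len(self.frequencies)


def _star_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def align_group(members: Sequence[ProteinRecord],
                anchor_seed: ProteinRecord) -> MSA:
    """Star alignment of the members around ``anchor_seed``.

    Each member is globally aligned to the seed (BLOSUM62, affine gaps
    open -10 / extend -1 in matrix half-bits) and the pairwise alignments
    are merged on the seed's coordinates ("once a gap, always a gap").
    Row order equals the input order; if the anchor is not among the
    members it is prepended as the first row.
    """
    ordered = list(members)
    if all(m.protein_id != anchor_seed.protein_id for m in ordered):
        ordered = [anchor_seed] + ordered
    if len(ordered) < 2:
        raise ValidationError("alignment needs at least 2 sequences")

    aligner = _star_aligner()
    seed_seq = anchor_seed.sequence
    L = len(seed_seq)
    per_member = []  # (insertions per seed gap slot, residue per seed pos)
    for member in ordered:
        if member.sequence == seed_seq:
            ins = [""] * (L + 1)
            aligned = list(seed_seq)
        else:
            aln = aligner.align(seed_seq, member.sequence)[0]
            gapped_seed, gapped_mem = str(aln[0]), str(aln[1])
            ins = [""] * (L + 1)
            aligned = [None] * L
            k = 0
            for cs, cm in zip(gapped_seed, gapped_mem):
                if cs == "-":
                    ins[k] += cm
                else:
                    aligned[k] = cm
                    k += 1
        per_member.append((ins, aligned))

    ins_max = [max(len(pm[0][k]) for pm in per_member) for k in range(L + 1)]
    rows = []
    for ins, aligned in per_member:
        parts = []
        for k in range(L + 1):
            parts.append(ins[k].ljust(ins_max[k], "-"))
            if k < L:
                parts.append(aligned[k])
        rows.append("".join(parts))
    return MSA([m.protein_id for m in ordered], rows)


def locate_boxa_start(sequence: str, scan_start: int = 0,
                      scan_end: Optional[int] = None) -> int:
    """Seed-coordinate BoxA start inferred from the first CxxC match.

    The CxxC active site occupies BoxA columns 7-10, so BoxA starts six
    residues before the first cysteine of the motif.
    """
    window = sequence[scan_start:scan_end]
    match = re.search(r"C..C", window)
    if match is None:
        raise FormatError("no CxxC active-site anchor found in the seed")
    start = scan_start + match.start() - CYS_POSITIONS[0]
    if start < 0:
        raise FormatError("CxxC anchor too close to the N-terminus for BoxA")
    return start


def default_layout(seed: ProteinRecord,
                   box_spacer: int = BOX_SPACER) -> SeedLayout:
    """Layout anchored on the seed's CxxC with the configured spacer."""
    boxa_start = locate_boxa_start(seed.sequence)
    return SeedLayout(seed.protein_id, boxa_start,
                      boxa_start + BOXA_WIDTH + box_spacer)


def extract_boxes(msa: MSA, layout: SeedLayout) -> BoxRegions:
    """Slice the BoxA/BoxB columns that carry the seed's box residues."""
    seed_row = msa.row(layout.seed_id)
    seed_cols = [i for i, c in enumerate(seed_row) if c != "-"]
    seed_len = len(seed_cols)
    if layout.boxb_start + BOXB_WIDTH > seed_len:
        raise ValidationError("seed too short for the configured box layout")
    cols_a = seed_cols[layout.boxa_start:layout.boxa_start + BOXA_WIDTH]
    cols_b = seed_cols[layout.boxb_start:layout.boxb_start + BOXB_WIDTH]
    box_a = {pid: "".join(row[c] for c in cols_a)
             for pid, row in zip(msa.member_ids, msa.rows)}
    box_b = {pid: "".join(row[c] for c in cols_b)
             for pid, row in zip(msa.member_ids, msa.rows)}
    return BoxRegions(box_a, box_b, (cols_a[0], cols_b[0]))


def make_logo(box_strings: Sequence[str]) -> SequenceLogo:
    """Column frequencies over non-gap letters and information in bits.

    R_j = log2(20) + sum_a f(j,a) * log2 f(j,a); an all-gap column has
    R_j = 0 and an empty frequency vector.
    """
    if not box_strings:
        raise ValidationError("cannot build a logo from zero strings")
    width = len(box_strings[0])
    if any(len(s) != width for s in box_strings):
        raise ValidationError("logo strings must have equal length")
    frequencies: List[Dict[str, float]] = []
    information = np.zeros(width)
    for j in range(width):
        letters = [s[j] for s in box_strings
                   if s[j] not in ("-", "X")]
        if not letters:
            frequencies.append({})
            continue
        freqs: Dict[str, float] = {}
        for c in letters:
            if c not in AMINO_ACIDS:
                raise FormatError(f"letter {c!r} not in the alphabet")
            freqs[c] = freqs.get(c, 0.0) + 1.0
        total = sum(freqs.values())
        freqs = {c: v / total for c, v in sorted(freqs.items())}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        frequencies.append(freqs)
        information[j] = max(0.0, _MAX_INFO - entropy)
    return SequenceLogo(frequencies, information)


def consensus_motif(logo: SequenceLogo, info_threshold_bits: float = 2.0,
                    majority_fraction: float = 0.7) -> str:
    """Pattern string: letter, bracketed pair, or ``x`` per column."""
    if info_threshold_bits <= 0 or majority_fraction <= 0:
        raise ValidationError("consensus thresholds must be positive")
    out = []
    for j in range(logo.width):
        freqs = logo.frequencies[j]
        if not freqs or logo.information[j] < info_threshold_bits:
            out.append("x")
            continue
        ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked[0][1] >= majority_fraction:
            out.append(ranked[0][0])
        elif len(ranked) > 1 and ranked[0][1] + ranked[1][1] >= majority_fraction:
            out.append(f"[{ranked[0][0]}{ranked[1][0]}]")
        else:
            out.append("x")
    return "".join(out)


def active_site_cys_count(box_a: str) -> int:
    """Number of cysteines at the CxxC positions (BoxA columns 7 and 10)."""
    if len(box_a) != BOXA_WIDTH:
        raise ValidationError(f"BoxA string must be {BOXA_WIDTH} aa")
    return sum(1 for p in CYS_POSITIONS if box_a[p] == "C")


# -- output helpers -------------------------------------------------------

def write_logo_tsv(logo: SequenceLogo, path) -> None:
    rows = []
    for j, freqs in enumerate(logo.frequencies):
        for residue, freq in freqs.items():
            rows.append((j, residue, freq, logo.information[j]))
        if not freqs:
            rows.append((j, "-", 0.0, 0.0))
    pd.DataFrame(rows, columns=["column", "residue", "frequency",
                                "info_bits"]).to_csv(path, sep="\t",
                                                     index=False)


def render_logo_png(logo: SequenceLogo, path, title: str = "") -> None:
    """Simple information-content bar rendering (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, logo.width * 0.3), 3))
    ax.bar(range(1, logo.width + 1), logo.information, color="steelblue")
    for j, freqs in enumerate(logo.frequencies):
        if freqs:
            top = max(freqs.items(), key=lambda kv: kv[1])[0]
            ax.text(j + 1, logo.information[j], top, ha="center",
                    va="bottom", fontsize=7)
    ax.set_xlabel("column")
    ax.set_ylabel("information (bits)")
    ax.set_ylim(0, _MAX_INFO + 0.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_msa_fasta(msa: MSA, path) -> None:
    with open(path, "w") as handle:
        for pid, row in zip(msa.member_ids, msa.rows):
            handle.write(f">{pid}\n{row}\n")
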