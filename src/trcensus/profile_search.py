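"""Fixed-width position-specific scoring profiles with trusted cutoffs.

A profile is built from equal-length (possibly gapped) region strings and
scores sequences by an ungapped sliding window; scores are in bits. The
trusted cutoff of a profile is the minimum score of the full-length
sequences it was built from, so every building member re-passes its own
profile by construction.

This is a deliberate simplification of a profile HMM: the regions modeled
here are fixed-width, which makes insert/delete states unnecessary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .io_formats import AMINO_ACIDS, GenomeRecord

AA_INDEX: Dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)
_X_INDEX = _N_AA  # sentinel column scoring 0 bits


def uniform_background() -> np.ndarray:
    return np.full(_N_AA, 1.0 / _N_AA)


@dataclass
class ProfileModel:
    """Position-specific log-odds model (bits) with optional trusted cutoff."""

    width: int
    log_odds: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    trusted_cutoff: Optional[float] = None
    member_ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.width < 1:
            raise ValidationError("profile width must be >= 1")
        if self.log_odds.shape != (self.width, _N_AA):
            raise ValidationError("log_odds shape mismatch")


@dataclass
class ProfileHit:
    protein_id: str
    score_bits: float
    offset: int


def build_profile(region_strings: Sequence[str],
                  background: Optional[np.ndarray] = None,
                  pseudocount: float = 1.0,
                  member_ids: Optional[Sequence[str]] = None) -> ProfileModel:
    """Build a profile from equal-length region strings.

    Per column j and residue a::

        f(j,a) = (count(j,a) + pseudocount * background(a))
                 / (n_nongap(j) + pseudocount)
        log_odds(j,a) = log2(f(j,a) / background(a))

    Gap characters (``-``) and ``X`` carry no information and are excluded
    from the counts; an all-gap column therefore has zero log-odds.
    """
    if not region_strings:
        raise ValidationError("cannot build a profile from zero strings")
    width = len(region_strings[0])
    if any(len(s) != width for s in region_strings):
        raise ValidationError("region strings must all have the same length")
    if width < 1:
        raise ValidationError("region strings must be non-empty")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    bg = uniform_background() if background is None else np.asarray(
        background, dtype=float)
    if bg.shape != (_N_AA,) or not np.isclose(bg.sum(), 1.0):
        raise ValidationError("background must be 20 probabilities summing to 1")

    counts = np.zeros((width, _N_AA))
    for s in region_strings:
        for j, c in enumerate(s.upper()):
            if c in ("-", "X"):
                continue
            if c not in AA_INDEX:
                raise FormatError(f"letter {c!r} not in the amino-acid alphabet")
            counts[j, AA_INDEX[c]] += 1
    n_nongap = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount * bg) / (n_nongap + pseudocount)
    log_odds = np.log2(freqs / bg)
    return ProfileModel(width=width, log_odds=log_odds, background=bg,
                        pseudocount=pseudocount,
                        member_ids=list(member_ids or []))


def _encode(sequence: str) -> np.ndarray:
    idx = np.empty(len(sequence), dtype=np.intp)
    for i, c in enumerate(sequence):
        if c == "X":
            idx[i] = _X_INDEX
        else:
            try:
                idx[i] = AA_INDEX[c]
            except KeyError:
                raise FormatError(
                    f"letter {c!r} not scoreable (gaps are not allowed in "
                    f"query sequences)") from None
    return idx


def score(profile: ProfileModel, sequence: str,
          protein_id: str = "") -> ProfileHit:
    """Best ungapped window score in bits; ties go to the smallest offset."""
    if len(sequence) < profile.width:
        raise ValidationError(
            f"sequence ({len(sequence)} aa) shorter than profile width "
            f"({profile.width})")
    idx = _encode(sequence.upper())
    # extra zero column so X contributes 0 bits in every profile column
    lo = np.hstack([profile.log_odds, np.zeros((profile.width, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(idx, profile.width)
    scores = lo[np.arange(profile.width), windows].sum(axis=1)
    offset = int(np.argmax(scores))  # argmax returns the first maximum
    return ProfileHit(protein_id, float(scores[offset]), offset)


def trusted_cutoff(profile: ProfileModel,
                   member_sequences: Sequence[str]) -> ProfileModel:
    """Return a copy with cutoff = min member score (lowest true positive)."""
    if not member_sequences:
        raise ValidationError("cannot set a trusted cutoff from zero members")
    cutoff = min(score(profile, s).score_bits for s in member_sequences)
    return replace(profile, trusted_cutoff=cutoff)


def find_pndo(genomes: Sequence[GenomeRecord],
              profile: ProfileModel) -> List[ProfileHit]:
    """All proteins scoring at or above the trusted cutoff, best first."""
    if profile.trusted_cutoff is None:
        raise ValidationError("profile has no trusted cutoff set")
    hits: List[ProfileHit] = []
    for genome in genomes:
        for protein in genome.proteins:
            if len(protein.sequence) < profile.width:
                continue
            hit = score(profile, protein.sequence, protein.protein_id)
            if hit.score_bits >= profile.trusted_cutoff:
                hits.append(hit)
    hits.sort(key=lambda h: (-h.score_bits, h.protein_id))
    return hits


def build_pndo_profile(region_strings: Sequence[str],
                       member_sequences: Sequence[str],
                       member_ids: Sequence[str],
                       background: Optional[np.ndarray] = None,
                       pseudocount: float = 1.0) -> ProfileModel:
    """Profile over the concatenated seed BoxA+BoxB regions, cutoff set."""
    profile = build_profile(region_strings, background, pseudocount,
                            member_ids)
    return trusted_cutoff(profile, member_sequences)


# -- serialization --------------------------------------------------------

def write_profile(profile: ProfileModel, tsv_path, json_path) -> None:
    rows = [(j, a, profile.log_odds[j, AA_INDEX[a]])
            for j in range(profile.width) for a in AMINO_ACIDS]
    pd.DataFrame(rows, columns=["column", "residue", "log_odds"]).to_csv(
        tsv_path, sep="\t", index=False)
    sidecar = {
        "background": list(profile.background),
        "pseudocount": profile.pseudocount,
        "trusted_cutoff": profile.trusted_cutoff,
        "member_ids": profile.member_ids,
        "width": profile.width,
    }
    with open(json_path, "w") as handle:
        json.dump(sidecar, handle, indent=2)
        handle.write("\n")


def read_profile(tsv_path, json_path) -> ProfileModel:
    frame = pd.read_csv(tsv_path, sep="\t")
    with open(json_path) as handle:
        sidecar = json.load(handle)
    width = int(sidecar["width"])
    log_odds = np.zeros((width, _N_AA))
    for _, row in frame.iterrows():
        log_odds[int(row["column"]), AA_INDEX[row["residue"]]] = row["log_odds"]
    return ProfileModel(
        width=width, log_odds=log_odds,
        background=np.asarray(sidecar["background"]),
        pseudocount=float(sidecar["pseudocount"]),
        trusted_cutoff=sidecar["trusted_cutoff"],
        member_ids=list(sidecar["member_ids"]))
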