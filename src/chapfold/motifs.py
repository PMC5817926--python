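"""Sequence-level chaperone substrate recognition scanners.

Two complementary views of how the DnaK system picks its clients:

* the type-I Hsp40 (DnaJ/Ydj1) binding motif, a 7-position consensus
  ``G X [LMQ] {P} X {P} {CIMPVW}`` (brackets: allowed set; braces:
  excluded set) — ubiquitin carries it at positions 47-53 (GKQLEDG);
* a sliding-window hydrophobicity heuristic for DnaK, which targets
  roughly five-residue hydrophobic patches enriched in Leu/Ile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MotifMatch",
    "DNAJ_CONSENSUS_LENGTH",
    "scan_dnaj_consensus",
    "scan_dnak_patches",
    "read_fasta",
    "KYTE_DOOLITTLE",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity codes accepted in input but failing every motif position
#: (including wildcards) — a conservative choice.
AMBIGUOUS_AA = set("BJOUXZ")

DNAJ_CONSENSUS_LENGTH = 7
_POS3_ALLOWED = set("LMQ")
_POS7_EXCLUDED = set("CIMPVW")


class InvalidSequenceError(ValueError):
    pass


@dataclass(frozen=True)
class MotifMatch:
    """One consensus hit; positions are 1-based inclusive in the parent
    numbering (``offset`` maps fragment to parent coordinates)."""

    seq_id: str
    start: int
    end: int
    match: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.match):
            raise ValueError("start/end inconsistent with match length")


def _validate(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - STANDARD_AA - AMBIGUOUS_AA)
    if bad:
        raise InvalidSequenceError(
            f"invalid residue codes: {', '.join(bad)}")
    return seq


def _matches_consensus(window: str) -> bool:
    """Literal 7-position rule G / any / [LMQ] / not-P / any / not-P / not-{CIMPVW}.

    Ambiguous codes never satisfy a position, wildcards included.
    """
    if any(c in AMBIGUOUS_AA for c in window):
        return False
    return (window[0] == "G"
            and window[2] in _POS3_ALLOWED
            and window[3] != "P"
            and window[5] != "P"
            and window[6] not in _POS7_EXCLUDED)


def scan_dnaj_consensus(sequence: str, offset: int = 1,
                        seq_id: str = "seq") -> list[MotifMatch]:
    """All (possibly overlapping) 7-mers matching the Hsp40 consensus.

    ``offset`` is the parent-numbering position of the first residue
    (e.g. 45 for the capped ubiquitin fragment FAGKQLEDGRT), so reported
    coordinates line up with the parent protein.
    """
    seq = _validate(sequence)
    hits = []
    for i in range(len(seq) - DNAJ_CONSENSUS_LENGTH + 1):
        window = seq[i:i + DNAJ_CONSENSUS_LENGTH]
        if _matches_consensus(window):
            hits.append(MotifMatch(seq_id, offset + i,
                                   offset + i + DNAJ_CONSENSUS_LENGTH - 1,
                                   window))
    return hits


#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def scan_dnak_patches(sequence: str, window: int = 5, *,
                      scale: dict[str, float] | None = None,
                      threshold: float = 2.0, li_bonus: float = 0.5,
                      offset: int = 1):
    """Sliding-window hydrophobicity scores and candidate DnaK patches.

    Explicitly a heuristic: the score of each window is the mean hydropathy
    (Kyte-Doolittle by default) plus ``li_bonus`` times the Leu/Ile
    fraction, reflecting DnaK's preference for Leu/Ile-rich ~5-residue
    patches.  Windows with score >= ``threshold`` are reported as patches.

    Returns ``(scores, patches)``: scores is an array with one entry per
    window (position i covers residues i..i+window-1), patches a list of
    ``(start, end, score)`` in parent numbering.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = _validate(sequence)
    if window > len(seq):
        raise ValueError("window longer than sequence")
    sc = scale or KYTE_DOOLITTLE
    vals = np.asarray([sc.get(c, min(sc.values())) for c in seq])
    li = np.asarray([1.0 if c in "LI" else 0.0 for c in seq])
    kernel = np.ones(window) / window
    scores = (np.convolve(vals, kernel, mode="valid")
              + li_bonus * np.convolve(li, kernel, mode="valid"))
    patches = [(offset + i, offset + i + window - 1, float(s))
               for i, s in enumerate(scores) if s >= threshold]
    return scores, patches


def read_fasta(path) -> dict[str, str]:
    """Sequences from a FASTA file as {record id: string}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(Path(path)), "fasta")}
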