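"""CRAC / CARC cholesterol-recognition motif scanning.

A CRAC motif reads N→C as apolar (V/L) — aromatic (Y/F) — basic (R/K); the
CARC motif lists the same anchors in the reverse order (basic — aromatic —
apolar), still read N→C.  Consecutive anchors are separated by one to five
residues; the spacer is counted as the number of residues STRICTLY BETWEEN
the anchors, so K490 → Y495 has a spacer of 4.  Tryptophan does not qualify
as the aromatic anchor.  All hits are enumerated, overlaps included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

APOLAR = set("VL")
AROMATIC = set("YF")
BASIC = set("RK")

_ANCHOR_ORDER = {
    "CRAC": (APOLAR, AROMATIC, BASIC),
    "CARC": (BASIC, AROMATIC, APOLAR),
}


@dataclass(frozen=True)
class MotifHit:
    kind: str
    apolar: tuple[int, str]
    aromatic: tuple[int, str]
    basic: tuple[int, str]

    @property
    def anchors(self) -> tuple[tuple[int, str], ...]:
        """Anchor (position, letter) pairs in N→C order."""
        trio = (self.apolar, self.aromatic, self.basic)
        return tuple(sorted(trio))

    @property
    def span(self) -> tuple[int, int]:
        pos = [p for p, _ in self.anchors]
        return (pos[0], pos[-1])

    def __str__(self) -> str:  # e.g. "CARC K490-Y495-V501"
        return self.kind + " " + "-".join(f"{a}{p}" for p, a in self.anchors)


def scan_motifs(sequence: str, kinds: Iterable[str] = ("CRAC", "CARC"),
                spacer_range: tuple[int, int] = (1, 5),
                offset: int = 1) -> list[MotifHit]:
    """Enumerate every CRAC/CARC hit in a one-letter sequence.

    Positions are reported in the supplied numbering: ``offset`` is the
    residue number of the first sequence letter.
    """
    sequence = sequence.upper()
    for i, ch in enumerate(sequence):
        if ch not in AMINO_ALPHABET:
            raise ValueError(f"illegal residue {ch!r} at position {offset + i}")
    if offset < 1:
        raise ValueError("offset must be >= 1")
    lo, hi = spacer_range
    hits: list[MotifHit] = []
    n = len(sequence)
    for kind in kinds:
        c1, c2, c3 = _ANCHOR_ORDER[kind]
        first = [i for i, ch in enumerate(sequence) if ch in c1]
        for i in first:
            for j in range(i + lo + 1, min(i + hi + 2, n)):
                if sequence[j] not in c2:
                    continue
                for k in range(j + lo + 1, min(j + hi + 2, n)):
                    if sequence[k] not in c3:
                        continue
                    trio = {"CRAC": (i, j, k), "CARC": (k, j, i)}[kind]
                    ia, ja, ib = trio  # apolar, aromatic, basic indices
                    hits.append(MotifHit(
                        kind,
                        apolar=(offset + ia, sequence[ia]),
                        aromatic=(offset + ja, sequence[ja]),
                        basic=(offset + ib, sequence[ib])))
    hits.sort(key=lambda h: (h.span, h.kind))
    return hits


def mask_hits(hits: Sequence[MotifHit], membrane_facing) -> list[MotifHit]:
    """Keep hits whose three anchor positions are all membrane facing."""
    facing = set(membrane_facing)
    return [h for h in hits
            if all(pos in facing for pos, _ in h.anchors)]


def read_fasta(path) -> tuple[str, str]:
    """First record of a FASTA file as (id, sequence)."""
    from Bio import SeqIO
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq)
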