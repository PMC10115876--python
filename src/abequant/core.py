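"""Shared sequence/coordinate machinery and domain types.

Conventions used throughout the package:

* Genomic coordinates are 0-based half-open internally; 1-based positions
  appear only at VCF-like/report boundaries.
* Protospacer positions are 1-based counting from the PAM-distal end, so the
  HbE target adenine is A5 and the bystander is A6.
* For minus-strand protospacers, window positions always refer to the
  protospacer strand; reference-strand bases are complemented before any
  window logic (the deaminated base is A on the protospacer strand and
  appears as T->C on the reference minus strand).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

# IUPAC nucleotide codes as sets of concrete bases.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes permitted).

    Raises ``ValueError`` naming the offending position for any character
    outside the IUPAC nucleotide alphabet.
    """
    for i, ch in enumerate(seq):
        if ch.upper() not in IUPAC:
            raise ValueError(f"non-nucleotide character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff every base of ``seq`` falls in the IUPAC class of the
    corresponding ``pattern`` symbol.

    Ambiguous bases in ``seq`` match only if their full nucleotide set is
    contained in the pattern symbol's set (so an N base matches an N pattern
    but not a G pattern).
    """
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    for p, s in zip(pattern.upper(), seq.upper()):
        try:
            pset = IUPAC[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {p!r} in pattern") from None
        try:
            sset = IUPAC[s]
        except KeyError:
            raise ValueError(f"invalid nucleotide {s!r} in sequence") from None
        if not sset <= pset:
            return False
    return True


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ProtospacerSpec:
    """The guide: 20-nt spacer, PAM, editing window and target adenines.

    ``spacer`` is written 5'->3' with position 1 PAM-distal.  The HbE guide's
    target adenine sits at protospacer position 5 with a bystander at
    position 6; the deaminase editing window defaults to positions [4, 8].
    The actual clinical spacer sequence is configuration, never hard-coded.
    """

    spacer: str
    pam_pattern: str = "NGG"
    locus: GenomicInterval | None = None
    editing_window: tuple[int, int] = (4, 8)
    target_positions: frozenset[int] = frozenset({5, 6})

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError(f"spacer must be 20 nt, got {len(self.spacer)}")
        for i, ch in enumerate(self.spacer.upper()):
            if ch not in "ACGT":
                raise ValueError(
                    f"spacer contains non-ACGT character {ch!r} at position {i}"
                )
        lo, hi = self.editing_window
        if not (1 <= lo <= hi <= 20):
            raise ValueError(
                f"editing window must satisfy 1 <= low <= high <= 20, got [{lo}, {hi}]"
            )
        if not self.pam_pattern:
            raise ValueError("pam_pattern must be nonempty")
        for ch in self.pam_pattern.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {ch!r} in PAM pattern")
        if not set(self.target_positions) <= set(range(lo, hi + 1)):
            raise ValueError(
                f"target positions {sorted(self.target_positions)} outside "
                f"editing window [{lo}, {hi}]"
            )
        object.__setattr__(self, "spacer", self.spacer.upper())
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        object.__setattr__(self, "target_positions", frozenset(self.target_positions))

    @property
    def window_positions(self) -> range:
        """1-based protospacer positions inside the editing window."""
        lo, hi = self.editing_window
        return range(lo, hi + 1)

    def window_adenines(self, protospacer: str | None = None) -> list[int]:
        """1-based window positions carrying 'A' on the protospacer strand."""
        seq = (protospacer if protospacer is not None else self.spacer).upper()
        return [p for p in self.window_positions if seq[p - 1] == "A"]


class AlleleOutcome(enum.Enum):
    """Per-read codon-26 classification.

    The HbE codon (AAG) deaminates to GAG (WT correction, A5 alone), GGG
    (Hb Aubenas, A5+A6) or AGG (bystander only, A6 alone).  Categories are
    mutually exclusive and exhaustive.
    """

    HBE_UNEDITED = "AAG"
    WT_CORRECTED = "GAG"
    AUBENAS = "GGG"
    AGG_VARIANT = "AGG"
    INDEL = "INDEL"
    OTHER_SUBSTITUTION = "OTHER"
    UNCLASSIFIED = "UNCLASSIFIED"

    @property
    def codon(self) -> str | None:
        """The codon string attached to this outcome, if any."""
        return self.value if len(self.value) == 3 else None


CODON_OUTCOMES: dict[str, AlleleOutcome] = {
    "AAG": AlleleOutcome.HBE_UNEDITED,
    "GAG": AlleleOutcome.WT_CORRECTED,
    "GGG": AlleleOutcome.AUBENAS,
    "AGG": AlleleOutcome.AGG_VARIANT,
}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-record, line-wrapped) FASTA into a dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed6(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED6 rows as (interval, name, score) triples.

    Extra columns beyond the sixth are ignored; missing name/score/strand
    default to '.', 0 and '+'.
    """
    rows: list[tuple[GenomicInterval, str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((GenomicInterval(contig, start, end, strand), name, score))
    return rows


def write_bed6(
    rows: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
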