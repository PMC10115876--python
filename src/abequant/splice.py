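"""Quantify aberrant (cryptic) splicing from spliced alignments.

Splice junctions are extracted from skipped-region (CIGAR N) operations in
spliced reads over a region of interest.  The donor coordinate convention
is the 1-based reference position of the last exonic base before the skip,
matching how the canonical exon-1 donor of HBB is usually quoted
(chr11:5,248,159 on hg19); the acceptor is the 1-based first exonic base
after the skip.  The aberrant fraction is the share of junction counts
whose donor differs from the canonical donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pysam

from .core import GenomicInterval

BAM_CREF_SKIP = 3  # CIGAR 'N'
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass
class JunctionTable:
    """Junction counts keyed by (donor, acceptor), both 1-based."""

    counts: dict[tuple[int, int], int]
    canonical_donor: int
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of junction counts")


def count_junctions(
    alignments: str | pysam.AlignmentFile,
    region: GenomicInterval,
    canonical_donor: int,
    min_map_quality: int = 20,
) -> JunctionTable:
    """Count splice junctions in reads overlapping ``region``.

    Every skipped-region operation of a passing read contributes one count
    to its (donor, acceptor) key; a read spanning several introns
    contributes one count per skip.  Unspliced reads contribute nothing.
    """
    own = isinstance(alignments, str)
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        if region.contig not in bam.references:
            raise ValueError(f"contig {region.contig!r} absent from alignment header")
        counts: dict[tuple[int, int], int] = {}
        for read in bam.fetch(region.contig, region.start, region.end):
            if read.is_unmapped or read.mapping_quality < min_map_quality:
                continue
            pos = read.reference_start  # 0-based
            for op, length in read.cigartuples or []:
                if op == BAM_CREF_SKIP:
                    donor = pos  # 1-based last exonic base == 0-based pos
                    acceptor = pos + length + 1
                    key = (donor, acceptor)
                    counts[key] = counts.get(key, 0) + 1
                if op in _REF_CONSUMING:
                    pos += length
        return JunctionTable(counts, canonical_donor, sum(counts.values()))
    finally:
        if own:
            bam.close()


def aberrant_fraction(table: JunctionTable) -> float | None:
    """Fraction of junction counts using a non-canonical donor.

    Returns None (undefined) for an empty table.
    """
    if table.total == 0:
        return None
    aberrant = sum(
        n for (donor, _acceptor), n in table.counts.items()
        if donor != table.canonical_donor
    )
    return aberrant / table.total
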