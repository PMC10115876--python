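"""Quantify base-editing outcomes at the target codon from paired amplicon reads.

The stage mirrors a standard amplicon-sequencing analysis: overlapping read
pairs are consensus-merged, each merged read is aligned to the amplicon
reference, and the codon-26 triplet is read out and classified as unedited
HbE (AAG), WT-corrected (GAG), Hb Aubenas (GGG), the AGG bystander variant,
an indel, or another substitution.  "Editing efficiency" is the fraction of
classified reads carrying one of the two benign corrected codons
(WT_CORRECTED + AUBENAS); whether the rare AGG outcome counts as correction
is configurable and excluded by default.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align, SeqIO

from .core import (
    CODON_OUTCOMES,
    AlleleOutcome,
    GenomicInterval,
    ProtospacerSpec,
    reverse_complement,
)

DEFAULT_MIN_BASE_QUALITY = 20

# Affine-gap global alignment defaults; heavily penalised gap opens keep
# sequencing mismatches from being explained away as spurious indels.
_ALIGN_PARAMS = dict(match=2.0, mismatch=-2.0, gap_open=-10.0, gap_extend=-1.0)


@dataclass(frozen=True)
class MergedRead:
    """A consensus-merged read pair (or a single read treated as merged)."""

    sequence: str
    qualities: tuple[int, ...]
    merged_from_overlap: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")


@dataclass
class OutcomeTable:
    """Per-sample outcome counts, frequencies and summary rates.

    Frequencies are over classified reads (everything except UNCLASSIFIED)
    and sum to 1.  ``editing_efficiency`` is None for an empty table.
    """

    counts: dict[AlleleOutcome, int]
    total_classified: int
    frequencies: dict[AlleleOutcome, float]
    editing_efficiency: float | None
    indel_frequency: float | None

    @property
    def defined(self) -> bool:
        return self.total_classified > 0


def merge_read_pair(
    r1_seq: str,
    r1_qual: Sequence[int],
    r2_seq: str,
    r2_qual: Sequence[int],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> MergedRead | None:
    """FLASH-style ungapped overlap merge of an innie read pair.

    ``r2`` is the reverse-strand mate and is reverse-complemented before the
    overlap search.  The best offset is the one with the most matching bases
    among offsets whose overlap is at least ``min_overlap`` long and has a
    mismatch fraction at most ``max_mismatch_frac``; at disagreeing overlap
    positions the higher-quality base wins (ties go to read 1).  Returns
    None when no acceptable overlap exists (failure is signalled, not
    raised).
    """
    if not r1_seq or not r2_seq:
        raise ValueError("empty read")
    if len(r1_seq) != len(r1_qual) or len(r2_seq) != len(r2_qual):
        raise ValueError("sequence and qualities must have equal length")
    f1 = r1_seq.upper()
    f2 = reverse_complement(r2_seq.upper())
    q1 = np.asarray(r1_qual, dtype=np.int32)
    q2 = np.asarray(r2_qual, dtype=np.int32)[::-1]
    a1 = np.frombuffer(f1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(f2.encode(), dtype=np.uint8)
    n1, n2 = len(f1), len(f2)

    best: tuple[int, int] | None = None  # (matches, -offset)
    for t in range(0, n1 - min_overlap + 1):
        ov = min(n1 - t, n2)
        if ov < min_overlap:
            break
        mism = int(np.count_nonzero(a1[t : t + ov] != a2[:ov]))
        if mism / ov > max_mismatch_frac:
            continue
        matches = ov - mism
        if best is None or matches > best[0]:
            best = (matches, t)
    if best is None:
        return None

    t = best[1]
    ov = min(n1 - t, n2)
    seq = list(f1[:t])
    qual = list(q1[:t])
    for i in range(ov):
        b1, b2 = f1[t + i], f2[i]
        if b1 == b2:
            seq.append(b1)
            qual.append(int(max(q1[t + i], q2[i])))
        elif q2[i] > q1[t + i]:
            seq.append(b2)
            qual.append(int(q2[i]))
        else:
            seq.append(b1)
            qual.append(int(q1[t + i]))
    if t + n2 > n1:
        seq.extend(f2[ov:])
        qual.extend(int(q) for q in q2[ov:])
    else:
        seq.extend(f1[t + ov :])
        qual.extend(int(q) for q in q1[t + ov :])
    return MergedRead("".join(seq), tuple(qual), merged_from_overlap=True)


def locate_protospacer(amplicon_ref: str, spec: ProtospacerSpec) -> GenomicInterval:
    """Find the unique protospacer occurrence (either strand) on the amplicon."""
    ref = amplicon_ref.upper()
    hits: list[GenomicInterval] = []
    start = ref.find(spec.spacer)
    while start != -1:
        hits.append(GenomicInterval("amplicon", start, start + 20, "+"))
        start = ref.find(spec.spacer, start + 1)
    rc = reverse_complement(spec.spacer)
    start = ref.find(rc)
    while start != -1:
        hits.append(GenomicInterval("amplicon", start, start + 20, "-"))
        start = ref.find(rc, start + 1)
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one protospacer match on the amplicon, found {len(hits)}"
        )
    return hits[0]


def _window_ref_span(proto: GenomicInterval, spec: ProtospacerSpec) -> tuple[int, int]:
    """Reference-coordinate half-open span of the editing window."""
    lo, hi = spec.editing_window
    if proto.strand == "+":
        return proto.start + lo - 1, proto.start + hi
    return proto.end - hi, proto.end - lo + 1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _ALIGN_PARAMS["match"]
    aligner.mismatch_score = _ALIGN_PARAMS["mismatch"]
    aligner.open_gap_score = _ALIGN_PARAMS["gap_open"]
    aligner.extend_gap_score = _ALIGN_PARAMS["gap_extend"]
    # terminal gaps model incomplete coverage, not real indels
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def classify_allele(
    read: MergedRead,
    amplicon_ref: str,
    spec: ProtospacerSpec,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    codon_interval: GenomicInterval | None = None,
) -> AlleleOutcome:
    """Classify one merged read into exactly one ``AlleleOutcome``.

    The read is globally aligned to the amplicon (affine gaps).  Any internal
    alignment gap overlapping the editing window or the codon yields INDEL;
    otherwise the codon triplet is read out and mapped AAG/GAG/GGG/AGG to
    its outcome, any other triplet to OTHER_SUBSTITUTION.  A read that does
    not cover the codon, or whose codon bases fall below
    ``min_base_quality``, is UNCLASSIFIED.
    """
    if codon_interval is None:
        raise ValueError("codon_interval is required")
    ref = amplicon_ref.upper()
    proto = locate_protospacer(ref, spec)
    win_start, win_end = _window_ref_span(proto, spec)
    c_start, c_end = codon_interval.start, codon_interval.end

    seq = read.sequence.upper()
    ref_to_read, gap_overlaps = _align_to_reference(
        seq, ref, win_start, win_end, c_start, c_end
    )
    if gap_overlaps:
        return AlleleOutcome.INDEL

    codon_chars: list[str] = []
    for pos in range(c_start, c_end):
        ridx = ref_to_read.get(pos)
        if ridx is None:
            return AlleleOutcome.UNCLASSIFIED
        if read.qualities[ridx] < min_base_quality:
            return AlleleOutcome.UNCLASSIFIED
        codon_chars.append(seq[ridx])
    codon = "".join(codon_chars)
    if codon_interval.strand == "-":
        codon = reverse_complement(codon)
    return CODON_OUTCOMES.get(codon, AlleleOutcome.OTHER_SUBSTITUTION)


def _align_to_reference(
    seq: str, ref: str, win_start: int, win_end: int, c_start: int, c_end: int
) -> tuple[dict[int, int], bool]:
    """Align read to reference; return the ref->read coordinate map and
    whether any internal alignment gap overlaps the window or codon.

    Terminal gaps (incomplete coverage at either end) are not counted as
    indels; positions they span are simply absent from the map.
    """
    if len(seq) == len(ref):
        # gapless fast path for typical substitution-only reads
        mism = sum(a != b for a, b in zip(seq, ref))
        if mism <= max(3, int(0.05 * len(ref))):
            return {i: i for i in range(len(ref))}, False

    aln = _ALIGNER.align(ref, seq)[0]
    blocks_ref, blocks_read = aln.aligned
    mapping: dict[int, int] = {}
    for (rs, re), (qs, _qe) in zip(blocks_ref, blocks_read):
        for i in range(re - rs):
            mapping[rs + i] = qs + i

    spans = ((win_start, win_end), (c_start, c_end))
    gap_overlaps = False
    for k in range(1, len(blocks_ref)):
        prev_re, prev_qe = blocks_ref[k - 1][1], blocks_read[k - 1][1]
        rs, qs = blocks_ref[k][0], blocks_read[k][0]
        for lo, hi in spans:
            if rs > prev_re and prev_re < hi and rs > lo:  # ref deletion
                gap_overlaps = True
            if qs > prev_qe and lo < prev_re < hi:  # read insertion
                gap_overlaps = True
    return mapping, gap_overlaps


def summarize_outcomes(outcomes: Iterable[AlleleOutcome]) -> OutcomeTable:
    """Count outcomes and derive frequencies, efficiency and indel rate.

    Frequencies are over classified reads only; an empty (or entirely
    unclassified) input yields an all-zero table with efficiency flagged
    undefined (None).
    """
    counts = {cat: 0 for cat in AlleleOutcome}
    for out in outcomes:
        counts[out] += 1
    total = sum(n for cat, n in counts.items() if cat is not AlleleOutcome.UNCLASSIFIED)
    if total == 0:
        freqs = {cat: 0.0 for cat in AlleleOutcome if cat is not AlleleOutcome.UNCLASSIFIED}
        return OutcomeTable(counts, 0, freqs, None, None)
    freqs = {
        cat: counts[cat] / total
        for cat in AlleleOutcome
        if cat is not AlleleOutcome.UNCLASSIFIED
    }
    efficiency = (
        counts[AlleleOutcome.WT_CORRECTED] + counts[AlleleOutcome.AUBENAS]
    ) / total
    indel_freq = counts[AlleleOutcome.INDEL] / total
    return OutcomeTable(counts, total, freqs, efficiency, indel_freq)


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(
    fastq1: str | Path, fastq2: str | Path
) -> Iterator[tuple[str, list[int], str, list[int]]]:
    """Yield (seq1, qual1, seq2, qual2) from a pair of FASTQ files."""
    with _open_maybe_gzip(fastq1) as fh1, _open_maybe_gzip(fastq2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            yield (
                str(rec1.seq),
                rec1.letter_annotations["phred_quality"],
                str(rec2.seq),
                rec2.letter_annotations["phred_quality"],
            )


def quantify_sample(
    fastq1: str | Path,
    fastq2: str | Path,
    amplicon_ref: str,
    spec: ProtospacerSpec,
    codon_interval: GenomicInterval,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[OutcomeTable, dict[str, int]]:
    """End-to-end merge + classify + summarise for one paired sample.

    Returns the outcome table and a QC block counting pairs seen and merge
    failures (failed pairs are excluded from classification).
    """
    outcomes: list[AlleleOutcome] = []
    qc = {"pairs_total": 0, "merge_failures": 0}
    for s1, q1, s2, q2 in iter_fastq_pairs(fastq1, fastq2):
        qc["pairs_total"] += 1
        merged = merge_read_pair(s1, q1, s2, q2, min_overlap, max_mismatch_frac)
        if merged is None:
            qc["merge_failures"] += 1
            continue
        outcomes.append(
            classify_allele(merged, amplicon_ref, spec, min_base_quality, codon_interval)
        )
    return summarize_outcomes(outcomes), qc
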