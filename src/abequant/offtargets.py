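"""Enumerate, merge, filter and rank candidate off-target sites.

This is the nomination funnel: an in-silico mismatch scan of the genome for
PAM-adjacent near-matches to the spacer (Cas-OFFinder-style, mismatch-only —
no DNA/RNA bulges), merged with externally nominated sites carrying read
counts (e.g. a CIRCLE-seq cut-site list supplied as BED), filtered to sites
with at least one adenine in the editing window (the only sites an adenine
base editor can alter), and ranked to choose a top-N capture panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    IUPAC,
    GenomicInterval,
    ProtospacerSpec,
    read_bed6,
    reverse_complement,
)

_BASE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
for _sym, _set in IUPAC.items():
    _BASE_MASK.setdefault(_sym, sum(_BASE_MASK[b] for b in _set))


@dataclass(frozen=True)
class CandidateSite:
    """A nominated off-target locus.

    ``matched_protospacer`` is the 20-nt genomic sequence on the protospacer
    strand (so for minus-strand sites it is the reverse complement of the
    reference interval).  ``sources`` records provenance: in-silico
    enumeration and/or an external nuclease assay site list.
    """

    interval: GenomicInterval
    matched_protospacer: str
    pam_observed: str
    mismatch_count: int
    sources: frozenset[str] = frozenset({"insilico"})
    circleseq_read_count: int | None = None
    has_adenine_in_window: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.mismatch_count <= 20):
            raise ValueError("mismatch_count must be in 0..20")
        if not self.sources:
            raise ValueError("sources must be nonempty")
        if self.circleseq_read_count is not None and self.circleseq_read_count < 0:
            raise ValueError("circleseq_read_count must be non-negative")


def _encode_masks(seq: str) -> np.ndarray:
    """Encode a sequence as 4-bit base masks (0 for non-IUPAC characters)."""
    arr = np.zeros(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        arr[i] = _BASE_MASK.get(ch, 0)
    return arr


def _scan_strand(seq: str, spec: ProtospacerSpec, max_mismatches: int) -> list[tuple[int, int]]:
    """Plus-strand scan: (start, mismatch_count) for every PAM-adjacent
    window within the mismatch radius.  Vectorised over the contig."""
    L = len(seq)
    plen = len(spec.pam_pattern)
    n = L - 20 - plen + 1
    if n <= 0:
        return []
    masks = _encode_masks(seq)
    spacer_masks = _encode_masks(spec.spacer)

    mism = np.zeros(n, dtype=np.int16)
    for j in range(20):
        mism += masks[j : j + n] != spacer_masks[j]

    pam_ok = np.ones(n, dtype=bool)
    for k, sym in enumerate(spec.pam_pattern):
        pmask = _BASE_MASK[sym]
        base = masks[20 + k : 20 + k + n]
        pam_ok &= (base != 0) & ((base & ~np.uint8(pmask)) == 0)

    hits = np.nonzero(pam_ok & (mism <= max_mismatches))[0]
    return [(int(i), int(mism[i])) for i in hits]


def enumerate_offtargets(
    genome: dict[str, str],
    spec: ProtospacerSpec,
    max_mismatches: int = 4,
) -> list[CandidateSite]:
    """Exhaustive mismatch search for PAM-adjacent spacer near-matches.

    Every 20-nt window on either strand whose 3'-adjacent bases match the
    PAM pattern and whose Hamming distance to the spacer is at most
    ``max_mismatches`` is reported exactly once.  Ambiguous reference bases
    (e.g. N) count as mismatches and never satisfy a concrete PAM symbol.
    Output is sorted by (contig, start, strand).
    """
    if max_mismatches > 8:
        raise ValueError("max_mismatches must be <= 8")
    if "N" in spec.spacer:
        raise ValueError("spacer containing N is not searchable")
    if not genome:
        raise ValueError("genome has no records")

    plen = len(spec.pam_pattern)
    sites: list[CandidateSite] = []
    for contig in genome:
        seq = genome[contig].upper()
        L = len(seq)
        for start, mm in _scan_strand(seq, spec, max_mismatches):
            sites.append(
                CandidateSite(
                    interval=GenomicInterval(contig, start, start + 20, "+"),
                    matched_protospacer=seq[start : start + 20],
                    pam_observed=seq[start + 20 : start + 20 + plen],
                    mismatch_count=mm,
                )
            )
        rc = reverse_complement(seq)
        for rc_start, mm in _scan_strand(rc, spec, max_mismatches):
            # rc[i:i+20] occupies reference [L-i-20, L-i) on the minus strand
            start = L - rc_start - 20
            sites.append(
                CandidateSite(
                    interval=GenomicInterval(contig, start, start + 20, "-"),
                    matched_protospacer=rc[rc_start : rc_start + 20],
                    pam_observed=rc[rc_start + 20 : rc_start + 20 + plen],
                    mismatch_count=mm,
                )
            )
    sites.sort(key=lambda s: (s.interval.contig, s.interval.start, s.interval.strand))
    return sites


def merge_candidates(*lists: Sequence[CandidateSite]) -> list[CandidateSite]:
    """Unify sites whose intervals overlap on the same strand.

    Overlap closure is transitive (a chain of pairwise-overlapping intervals
    merges into one site).  The merged record keeps the representative with
    the smallest mismatch count (ties: leftmost), the union of sources and
    the maximum read count.
    """
    pool = [s for lst in lists for s in lst]
    pool.sort(
        key=lambda s: (s.interval.contig, s.interval.strand, s.interval.start, s.interval.end)
    )
    merged: list[CandidateSite] = []
    group: list[CandidateSite] = []
    group_end = -1
    for site in pool:
        if (
            group
            and site.interval.contig == group[0].interval.contig
            and site.interval.strand == group[0].interval.strand
            and site.interval.start < group_end
        ):
            group.append(site)
            group_end = max(group_end, site.interval.end)
        else:
            if group:
                merged.append(_collapse(group))
            group = [site]
            group_end = site.interval.end
    if group:
        merged.append(_collapse(group))
    merged.sort(key=lambda s: (s.interval.contig, s.interval.start, s.interval.strand))
    return merged


def _collapse(group: list[CandidateSite]) -> CandidateSite:
    if len(group) == 1:
        return group[0]
    rep = min(group, key=lambda s: (s.mismatch_count, s.interval.start))
    sources = frozenset().union(*(s.sources for s in group))
    counts = [s.circleseq_read_count for s in group if s.circleseq_read_count is not None]
    return replace(
        rep,
        sources=sources,
        circleseq_read_count=max(counts) if counts else None,
    )


def filter_adenine_window(
    sites: Iterable[CandidateSite], spec: ProtospacerSpec
) -> list[CandidateSite]:
    """Retain exactly the sites with >=1 adenine (protospacer strand) at a
    window position; annotate ``has_adenine_in_window`` on every input."""
    out: list[CandidateSite] = []
    for site in sites:
        has_a = bool(spec.window_adenines(site.matched_protospacer))
        site = replace(site, has_adenine_in_window=has_a)
        if has_a:
            out.append(site)
    return out


def rank_sites(sites: Sequence[CandidateSite], n: int = 250) -> list[CandidateSite]:
    """Top-N panel selection.

    Ordering: nuclease-assay read count descending (absent counts as 0),
    then mismatch count ascending, then (contig, start).  Deterministic
    under permutation of the input.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(
        sites,
        key=lambda s: (
            -(s.circleseq_read_count or 0),
            s.mismatch_count,
            s.interval.contig,
            s.interval.start,
        ),
    )
    return ordered[:n]


def circleseq_sites_from_bed(
    path: str | Path, genome: dict[str, str], spec: ProtospacerSpec
) -> list[CandidateSite]:
    """Adapt a BED6 nuclease-assay site list (score column = read count).

    Each BED interval is interpreted as the 20-nt protospacer locus on the
    given strand; the matched protospacer and observed PAM are read from the
    genome and the mismatch count computed against the spacer.
    """
    sites: list[CandidateSite] = []
    plen = len(spec.pam_pattern)
    for iv, _name, score in read_bed6(path):
        seq = genome[iv.contig].upper()
        if iv.strand == "+":
            proto = seq[iv.start : iv.end]
            pam = seq[iv.end : iv.end + plen]
        else:
            proto = reverse_complement(seq[iv.start : iv.end])
            pam = reverse_complement(seq[max(0, iv.start - plen) : iv.start])
        mm = sum(a != b for a, b in zip(proto, spec.spacer))
        sites.append(
            CandidateSite(
                interval=iv,
                matched_protospacer=proto,
                pam_observed=pam,
                mismatch_count=mm,
                sources=frozenset({"circleseq"}),
                circleseq_read_count=int(score),
            )
        )
    return sites


def design_probes(
    sites: Iterable[CandidateSite], genome: dict[str, str], probe_length: int = 120
) -> dict[str, str]:
    """Capture probes centered on each protospacer (plus-strand sequence)."""
    probes: dict[str, str] = {}
    for site in sites:
        iv = site.interval
        mid = (iv.start + iv.end) // 2
        lo = max(0, mid - probe_length // 2)
        hi = min(len(genome[iv.contig]), lo + probe_length)
        name = f"{iv.contig}:{iv.start}-{iv.end}({iv.strand})"
        probes[name] = genome[iv.contig][lo:hi]
    return probes


def sites_from_frame(df: pd.DataFrame) -> list[CandidateSite]:
    """Inverse of :func:`sites_to_frame` (candidate TSV round-trip)."""
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            CandidateSite(
                interval=GenomicInterval(
                    str(row.contig), int(row.start), int(row.end), str(row.strand)
                ),
                matched_protospacer=str(row.protospacer),
                pam_observed="" if pd.isna(row.pam) else str(row.pam),
                mismatch_count=int(row.mismatches),
                sources=frozenset(str(row.sources).split(",")),
                circleseq_read_count=(
                    None if int(row.circleseq_reads) < 0 else int(row.circleseq_reads)
                ),
                has_adenine_in_window=(
                    None
                    if pd.isna(row.adenine_in_window) or row.adenine_in_window == ""
                    else str(row.adenine_in_window) == "True"
                ),
            )
        )
    return sites


def sites_to_frame(sites: Sequence[CandidateSite]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of candidate sites."""
    return pd.DataFrame(
        {
            "contig": [s.interval.contig for s in sites],
            "start": [s.interval.start for s in sites],
            "end": [s.interval.end for s in sites],
            "strand": [s.interval.strand for s in sites],
            "protospacer": [s.matched_protospacer for s in sites],
            "pam": [s.pam_observed for s in sites],
            "mismatches": [s.mismatch_count for s in sites],
            "sources": [",".join(sorted(s.sources)) for s in sites],
            "circleseq_reads": [
                -1 if s.circleseq_read_count is None else s.circleseq_read_count
                for s in sites
            ],
            "adenine_in_window": [
                "" if s.has_adenine_in_window is None else str(s.has_adenine_in_window)
                for s in sites
            ],
        }
    )
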