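"""Per-site deamination frequencies and off-target calls from deep capture data.

For every editing-window position of a captured candidate site, reads are
piled up and bases counted in protospacer-strand orientation (a minus-strand
site's reference T->C changes count as A->G).  Editing in a treated sample
is called against a matched control with a one-sided Fisher exact test per
position (G vs A counts, treated showing the excess), Bonferroni-aggregated
across the window, Benjamini-Hochberg adjusted across sites, and required to
show a frequency excess over the control.  The exact decision rule used by
the original capture analysis is unpublished; this module's rule (Fisher +
BH + frequency excess, alpha 0.05) is this package's explicit specification
of that step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import ProtospacerSpec
from .offtargets import CandidateSite

DEFAULT_MIN_BASE_QUALITY = 30
DEFAULT_MIN_MAP_QUALITY = 20
DEFAULT_ALPHA = 0.05

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PositionCounts:
    """Base counts at one window position, protospacer-strand orientation."""

    protospacer_position: int  # 1-based from the PAM-distal end
    ref_coord: int  # 0-based reference coordinate
    depth: int
    count_A: int
    count_G: int
    count_other: int
    is_adenine_site: bool = True  # protospacer-strand reference base is A

    @property
    def deam_freq(self) -> float:
        """Fraction of reads showing G at this (adenine) position."""
        return self.count_G / self.depth if self.depth else 0.0


@dataclass
class SiteEditingResult:
    """Editing evidence at one captured site."""

    site: CandidateSite
    per_position: list[PositionCounts]
    max_deam_freq: float
    control_max_freq: float
    p_value: float
    q_value: float | None = None
    called: bool | None = None
    callable: bool = True


def window_reference_coords(
    site: CandidateSite, spec: ProtospacerSpec
) -> list[tuple[int, int]]:
    """(protospacer position, 0-based reference coordinate) for each window
    position, honouring strand."""
    iv = site.interval
    out = []
    for p in spec.window_positions:
        if iv.strand == "+":
            out.append((p, iv.start + p - 1))
        else:
            out.append((p, iv.end - p))
    return out


def pileup_deamination(
    alignments: str | pysam.AlignmentFile,
    site: CandidateSite,
    spec: ProtospacerSpec,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_map_quality: int = DEFAULT_MIN_MAP_QUALITY,
) -> list[PositionCounts]:
    """Count protospacer-strand A/G/other at every window position.

    On a plus-strand site, read base A counts as A and G as G; on a
    minus-strand site the reference shows the complementary strand, so read
    base T counts as A and C as G.  Duplicates are not removed: legitimate
    capture depth exceeds library complexity.
    """
    own = isinstance(alignments, (str,))
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        if site.interval.contig not in bam.references:
            raise ValueError(
                f"contig {site.interval.contig!r} absent from alignment header"
            )
        results: list[PositionCounts] = []
        minus = site.interval.strand == "-"
        proto_seq = site.matched_protospacer.upper()
        for proto_pos, ref_coord in window_reference_coords(site, spec):
            count_a = count_g = count_other = 0
            for col in bam.pileup(
                site.interval.contig,
                ref_coord,
                ref_coord + 1,
                truncate=True,
                min_base_quality=min_base_quality,
                min_mapping_quality=min_map_quality,
                stepper="nofilter",
                max_depth=10_000_000,
            ):
                for pr in col.pileups:
                    if pr.is_del or pr.is_refskip or pr.query_position is None:
                        continue
                    base = pr.alignment.query_sequence[pr.query_position].upper()
                    if minus:
                        base = _COMP.get(base, "N")
                    if base == "A":
                        count_a += 1
                    elif base == "G":
                        count_g += 1
                    else:
                        count_other += 1
            results.append(
                PositionCounts(
                    protospacer_position=proto_pos,
                    ref_coord=ref_coord,
                    depth=count_a + count_g + count_other,
                    count_A=count_a,
                    count_G=count_g,
                    count_other=count_other,
                    is_adenine_site=proto_seq[proto_pos - 1] == "A",
                )
            )
        return results
    finally:
        if own:
            bam.close()


def fisher_one_sided(g_edited: int, a_edited: int, g_control: int, a_control: int) -> float:
    """One-sided Fisher exact p-value for G excess in the edited sample.

    The hypergeometric tail P(X >= g_edited) with the margins of the 2x2
    table [[g_e, a_e], [g_c, a_c]] fixed.
    """
    n_edited = g_edited + a_edited
    total = n_edited + g_control + a_control
    g_total = g_edited + g_control
    if total == 0:
        return 1.0
    return float(hypergeom.sf(g_edited - 1, total, g_total, n_edited))


def call_offtarget_editing(
    edited: Sequence[PositionCounts],
    control: Sequence[PositionCounts],
    site: CandidateSite | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> SiteEditingResult:
    """Score one site: per-position Fisher tests aggregated over the window.

    The site p-value is the minimum Bonferroni-adjusted (x number of tested
    positions) per-position p-value.  Only window positions whose
    protospacer-strand reference base is adenine are tested — at other
    positions a G count measures the reference base, not deamination.
    ``called`` here uses the raw site p-value; cohort-level BH adjustment
    and the final call are applied by :func:`finalize_calls`.  Sites with
    zero depth everywhere are flagged uncallable.
    """
    if len(edited) != len(control):
        raise ValueError("edited and control must cover the same positions")
    pairs = []
    for pe, pc in zip(edited, control):
        if pe.ref_coord != pc.ref_coord or pe.protospacer_position != pc.protospacer_position:
            raise ValueError("edited and control must cover the same positions")
        if pe.is_adenine_site:
            pairs.append((pe, pc))
    if not pairs or all(pe.depth == 0 for pe, _ in pairs) or all(
        pc.depth == 0 for _, pc in pairs
    ):
        return SiteEditingResult(
            site=site, per_position=list(edited), max_deam_freq=0.0,
            control_max_freq=0.0, p_value=1.0, q_value=1.0, called=False,
            callable=False,
        )
    width = len(pairs)
    p_min = 1.0
    for pe, pc in pairs:
        p = fisher_one_sided(pe.count_G, pe.count_A, pc.count_G, pc.count_A)
        p_min = min(p_min, min(1.0, p * width))
    max_e = max(pe.deam_freq for pe, _ in pairs)
    max_c = max(pc.deam_freq for _, pc in pairs)
    result = SiteEditingResult(
        site=site,
        per_position=list(edited),
        max_deam_freq=max_e,
        control_max_freq=max_c,
        p_value=p_min,
    )
    # standalone use: treat the raw p as its own adjusted value
    result.q_value = p_min
    result.called = (p_min <= alpha) and (max_e > max_c)
    return result


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def finalize_calls(
    results: Sequence[SiteEditingResult], alpha: float = DEFAULT_ALPHA
) -> list[SiteEditingResult]:
    """BH-adjust site p-values across the cohort and set the final calls."""
    callable_results = [r for r in results if r.callable]
    qs = bh_adjust([r.p_value for r in callable_results])
    for r, q in zip(callable_results, qs):
        r.q_value = float(q)
        r.called = (r.q_value <= alpha) and (r.max_deam_freq > r.control_max_freq)
    for r in results:
        if not r.callable:
            r.q_value = 1.0
            r.called = False
    return list(results)


def summarize_capture(results: Sequence[SiteEditingResult]) -> dict:
    """Cohort summary: called-site count, median called max frequency,
    mean depth across sites."""
    called = [r for r in results if r.called]
    depths = [
        np.mean([pc.depth for pc in r.per_position]) for r in results if r.per_position
    ]
    return {
        "n_sites": len(results),
        "n_called": len(called),
        "median_called_max_freq": (
            float(np.median([r.max_deam_freq for r in called])) if called else None
        ),
        "mean_depth": float(np.mean(depths)) if depths else None,
    }
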