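"""Seeded generators for every input the pipeline consumes, with truth.

Each generator emulates one of the study's sequencing experiments — amplicon
read pairs with planted codon outcomes, genomes with planted mismatch
off-target sites, deep capture alignments with planted per-read deamination,
motif-driven accessible/inaccessible training sequences, and spliced reads
mixing canonical and cryptic donors — and returns a :class:`TruthManifest`
holding the planted labels so downstream recovery can be checked without
re-reading generator internals.  All outputs are byte-reproducible for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .core import (
    IUPAC,
    AlleleOutcome,
    GenomicInterval,
    ProtospacerSpec,
    reverse_complement,
)
from .offtargets import CandidateSite

BASES = "ACGT"

# A synthetic HbE-like guide: the AAG codon occupies protospacer positions
# 5-7 so the target adenine is A5 and the bystander A6, and positions 4 and
# 8 are non-A so the default [4, 8] window holds exactly those two adenines.
DEFAULT_SPACER = "GCTTAAGCTGGTCCTGTGGC"
DEFAULT_PAM = "NGG"


@dataclass
class TruthManifest:
    """Machine-readable record of what a generator planted."""

    generator: str
    seed: int
    parameters: dict
    truth: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "parameters": self.parameters,
                "truth": self.truth,
            },
            indent=2,
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_hbe_like_locus(
    seed: int = 0, amplicon_length: int = 220, proto_offset: int = 60
) -> tuple[str, ProtospacerSpec, GenomicInterval]:
    """A synthetic amplicon carrying the HbE-like protospacer and codon.

    Returns (amplicon sequence, guide spec, 0-based codon interval).  The
    codon (AAG, the E26K lysine codon) sits at protospacer positions 5-7.
    """
    rng = np.random.default_rng(seed)
    while True:
        background = _random_seq(rng, amplicon_length)
        amplicon = (
            background[:proto_offset]
            + DEFAULT_SPACER
            + "TGG"  # concrete NGG PAM
            + background[proto_offset + 23 :]
        )
        # the protospacer must occur exactly once on either strand
        if (
            amplicon.count(DEFAULT_SPACER) == 1
            and reverse_complement(DEFAULT_SPACER) not in amplicon
        ):
            break
    spec = ProtospacerSpec(
        spacer=DEFAULT_SPACER,
        pam_pattern=DEFAULT_PAM,
        locus=GenomicInterval("amplicon", proto_offset, proto_offset + 20, "+"),
    )
    codon = GenomicInterval("amplicon", proto_offset + 4, proto_offset + 7, "+")
    return amplicon, spec, codon


_OUTCOME_CODONS = {
    AlleleOutcome.HBE_UNEDITED: "AAG",
    AlleleOutcome.WT_CORRECTED: "GAG",
    AlleleOutcome.AUBENAS: "GGG",
    AlleleOutcome.AGG_VARIANT: "AGG",
    AlleleOutcome.OTHER_SUBSTITUTION: "ACG",
}


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    mask = rng.random(len(seq)) < error_rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.nonzero(mask)[0]:
        alternatives = [b for b in BASES if b != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _exact_allocation(freqs: dict, n: int) -> dict:
    """Largest-remainder allocation of n items to the given frequencies."""
    keys = list(freqs)
    raw = {k: freqs[k] * n for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def gen_amplicon_reads(
    spec: ProtospacerSpec,
    amplicon_ref: str,
    codon_interval: GenomicInterval,
    outcome_freqs: dict[AlleleOutcome, float],
    n_reads: int,
    error_rate: float,
    seed: int,
    out_dir: str | Path,
    read_length: int = 150,
    quality_mode: str = "constant",
) -> tuple[Path, Path, TruthManifest]:
    """Paired amplicon FASTQ with planted codon outcomes.

    Outcome counts follow a largest-remainder exact allocation of the
    planted frequencies (read order shuffled), so recovered frequencies
    deviate from planted values only through sequencing-error
    misclassification.  Substitution errors only; INDEL outcomes delete the
    codon triplet from the fragment.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    for cat, f in outcome_freqs.items():
        if f < 0:
            raise ValueError(f"negative frequency for {cat}")
    if abs(sum(outcome_freqs.values()) - 1.0) > 1e-9:
        raise ValueError("outcome frequencies must sum to 1")

    rng = np.random.default_rng(seed)
    counts = _exact_allocation(outcome_freqs, n_reads)
    labels: list[AlleleOutcome] = []
    for cat in sorted(counts, key=lambda c: c.name):
        labels.extend([cat] * counts[cat])
    rng.shuffle(labels)  # type: ignore[arg-type]

    c_start, c_end = codon_interval.start, codon_interval.end
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fq1 = out_dir / "reads_R1.fastq"
    fq2 = out_dir / "reads_R2.fastq"
    qual_char = chr(37 + 33)  # Q37

    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for i, outcome in enumerate(labels):
            if outcome is AlleleOutcome.INDEL:
                fragment = amplicon_ref[:c_start] + amplicon_ref[c_end:]
            else:
                codon = _OUTCOME_CODONS[outcome]
                fragment = amplicon_ref[:c_start] + codon + amplicon_ref[c_end:]
            r1 = _apply_errors(rng, fragment[:read_length], error_rate)
            r2 = _apply_errors(
                rng, reverse_complement(fragment[-read_length:]), error_rate
            )
            if quality_mode == "constant":
                q1 = q2 = qual_char * read_length
            else:  # degraded 3' qualities exercise the quality filters
                ramp = [
                    chr(33 + max(2, 37 - int(30 * j / read_length)))
                    for j in range(read_length)
                ]
                q1 = q2 = "".join(ramp)
            f1.write(f"@read{i}/1\n{r1}\n+\n{q1}\n")
            f2.write(f"@read{i}/2\n{r2}\n+\n{q2}\n")

    manifest = TruthManifest(
        generator="gen_amplicon_reads",
        seed=seed,
        parameters={
            "n_reads": n_reads,
            "error_rate": error_rate,
            "read_length": read_length,
            "outcome_freqs": {c.name: f for c, f in outcome_freqs.items()},
        },
        truth={
            "labels": [o.name for o in labels],
            "planted_counts": {c.name: counts[c] for c in counts},
        },
    )
    manifest.save(out_dir / "amplicon_truth.json")
    return fq1, fq2, manifest


def _mismatch_profile(seq_codes: np.ndarray, spacer_codes: np.ndarray) -> np.ndarray:
    """Hamming distance to the spacer for every 20-nt window start."""
    n = len(seq_codes) - 20 + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    for j in range(20):
        mm += seq_codes[j : j + n] != spacer_codes[j]
    return mm


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def gen_genome_with_offtargets(
    length: int,
    spec: ProtospacerSpec,
    planted: Sequence[tuple[int, str]],
    seed: int,
    contig: str = "chrS",
    scrub_radius: int = 4,
    margin: int = 300,
) -> tuple[dict[str, str], list[dict], TruthManifest]:
    """A random genome with planted spacer near-matches at known loci.

    ``planted`` lists (mismatch_count, strand) pairs.  The background is
    scrubbed of accidental windows within ``scrub_radius`` mismatches of the
    spacer on either strand (PAM ignored, so the scrub is conservative),
    then each planted protospacer+PAM is written at an evenly spaced offset.
    Mismatches are placed outside the editing window so planted sites keep
    their window adenines.
    """
    if any(mm > scrub_radius for mm, _ in planted):
        raise ValueError("planted mismatch counts must be <= scrub_radius")
    spacing = (length - 2 * margin) // max(1, len(planted))
    if length < 2 * margin + 60 or (planted and spacing < 60):
        raise ValueError("genome too short for the requested planted sites")

    rng = np.random.default_rng(seed)
    genome = list(_random_seq(rng, length))
    spacer_codes = _encode(spec.spacer)
    rc_codes = _encode(reverse_complement(spec.spacer))
    for _round in range(20):
        codes = _encode("".join(genome))
        dirty = set()
        for pattern in (spacer_codes, rc_codes):
            mm = _mismatch_profile(codes, pattern)
            for i in np.nonzero(mm <= scrub_radius)[0]:
                dirty.add(int(i))
        if not dirty:
            break
        for i in dirty:
            for j, b in enumerate(_random_seq(rng, 20)):
                genome[i + j] = b
    else:
        raise RuntimeError("background scrub did not converge")

    lo, hi = spec.editing_window
    window = set(range(lo, hi + 1))
    mutable = [p for p in range(1, 21) if p not in window]
    plen = len(spec.pam_pattern)
    # one concrete base per PAM symbol (N -> T so PAMs never add adenines)
    pam_concrete = "".join(
        "T" if s == "N" else sorted(IUPAC[s])[0] for s in spec.pam_pattern
    )

    truth_sites: list[dict] = []
    for k, (mm_count, strand) in enumerate(planted):
        proto = list(spec.spacer)
        positions = rng.choice(len(mutable), size=mm_count, replace=False)
        for idx in positions:
            p = mutable[int(idx)]
            alternatives = [b for b in BASES if b != proto[p - 1]]
            proto[p - 1] = alternatives[rng.integers(0, 3)]
        proto_seq = "".join(proto)
        insert = proto_seq + pam_concrete
        offset = margin + k * spacing
        if strand == "-":
            insert = reverse_complement(insert)
            start = offset + plen
        else:
            start = offset
        genome[offset : offset + len(insert)] = list(insert)
        truth_sites.append(
            {
                "contig": contig,
                "start": start,
                "end": start + 20,
                "strand": strand,
                "mismatches": mm_count,
                "protospacer": proto_seq,
            }
        )

    genome_str = "".join(genome)
    manifest = TruthManifest(
        generator="gen_genome_with_offtargets",
        seed=seed,
        parameters={
            "length": length,
            "planted": [[mm, s] for mm, s in planted],
            "scrub_radius": scrub_radius,
        },
        truth={"sites": truth_sites},
    )
    return {contig: genome_str}, truth_sites, manifest


def truth_site_to_candidate(site: dict) -> CandidateSite:
    """Adapter from a generator truth record to a CandidateSite."""
    return CandidateSite(
        interval=GenomicInterval(
            site["contig"], site["start"], site["end"], site["strand"]
        ),
        matched_protospacer=site["protospacer"],
        pam_observed="",
        mismatch_count=site["mismatches"],
    )


def gen_capture_bam(
    sites: Sequence[CandidateSite],
    genome: dict[str, str],
    spec: ProtospacerSpec,
    editing_freqs: Sequence[float],
    depth: int,
    error_rate: float,
    seed: int,
    out_prefix: str | Path,
    read_length: int = 120,
) -> tuple[Path, TruthManifest]:
    """Coordinate-sorted, indexed capture BAM with planted deamination.

    Each read over a site independently converts all window adenines
    (protospacer-strand A->G; on minus-strand sites the reference shows
    T->C) with the site's planted probability, then acquires background
    substitution errors.  The manifest records, per site, the planted
    frequency and the exact number of converted reads.
    """
    from .capture import window_reference_coords

    if depth < 1:
        raise ValueError("depth must be >= 1")
    for f in editing_freqs:
        if not (0.0 <= f <= 1.0):
            raise ValueError("editing frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sam_path = out_prefix.with_suffix(".sam")
    bam_path = out_prefix.with_suffix(".bam")

    records: list[tuple[str, int, str]] = []  # (contig, pos0, sam line tail)
    edited_counts: list[int] = []
    for si, (site, freq) in enumerate(zip(sites, editing_freqs)):
        contig_seq = genome[site.interval.contig]
        coords = [c for _p, c in window_reference_coords(site, spec)]
        mid = (site.interval.start + site.interval.end) // 2
        start = max(0, min(mid - read_length // 2, len(contig_seq) - read_length))
        template = contig_seq[start : start + read_length]
        minus = site.interval.strand == "-"
        n_edited = 0
        edit_flags = rng.random(depth) < freq
        for ri in range(depth):
            seq = list(template)
            if edit_flags[ri]:
                n_edited += 1
                for c in coords:
                    j = c - start
                    if 0 <= j < read_length:
                        if minus:
                            if seq[j] == "T":
                                seq[j] = "C"
                        elif seq[j] == "A":
                            seq[j] = "G"
            read_seq = _apply_errors(rng, "".join(seq), error_rate)
            qname = f"site{si}_read{ri}"
            records.append(
                (
                    site.interval.contig,
                    start,
                    f"{qname}\t0\t{site.interval.contig}\t{start + 1}\t60\t"
                    f"{read_length}M\t*\t0\t0\t{read_seq}\t{'I' * read_length}",
                )
            )
        edited_counts.append(n_edited)

    contig_order = {c: i for i, c in enumerate(genome)}
    records.sort(key=lambda r: (contig_order[r[0]], r[1]))
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c, seq in genome.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{len(seq)}\n")
        for _c, _p, line in records:
            fh.write(line + "\n")
    with pysam.AlignmentFile(str(sam_path)) as sam_in, pysam.AlignmentFile(
        str(bam_path), "wb", template=sam_in
    ) as bam_out:
        for read in sam_in:
            bam_out.write(read)
    pysam.index(str(bam_path))

    manifest = TruthManifest(
        generator="gen_capture_bam",
        seed=seed,
        parameters={
            "depth": depth,
            "error_rate": error_rate,
            "read_length": read_length,
            "editing_freqs": list(map(float, editing_freqs)),
        },
        truth={"edited_read_counts": edited_counts},
    )
    manifest.save(out_prefix.with_suffix(".truth.json"))
    return bam_path, manifest


DEFAULT_ACCESS_MOTIF = "GGTTAACGCA"  # carries adenines a window edit can destroy


def gen_accessibility_dataset(
    n: int,
    motif: str = DEFAULT_ACCESS_MOTIF,
    input_length: int = 200,
    seed: int = 7,
) -> tuple[list[str], np.ndarray, TruthManifest]:
    """Balanced labeled sequences: positives embed the motif, negatives are
    motif-free (re-drawn on accidental occurrence)."""
    if len(motif) >= input_length:
        raise ValueError("motif must be shorter than input_length")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    n_neg = n - n_pos
    seqs: list[str] = []
    labels = np.zeros(n, dtype=int)
    for i in range(n_pos):
        base = _random_seq(rng, input_length)
        offset = int(rng.integers(0, input_length - len(motif) + 1))
        seqs.append(base[:offset] + motif + base[offset + len(motif) :])
        labels[i] = 1
    for _ in range(n_neg):
        while True:
            s = _random_seq(rng, input_length)
            if motif not in s:
                break
        seqs.append(s)
    manifest = TruthManifest(
        generator="gen_accessibility_dataset",
        seed=seed,
        parameters={"n": n, "motif": motif, "input_length": input_length},
        truth={"labels": labels.tolist()},
    )
    return seqs, labels, manifest


def gen_damage_sites(
    n_sites: int,
    n_damaging: int,
    spec: ProtospacerSpec,
    seed: int,
    motif: str = DEFAULT_ACCESS_MOTIF,
    input_length: int = 200,
    contig: str = "chrD",
) -> tuple[dict[str, str], list[CandidateSite], list[bool], TruthManifest]:
    """Candidate sites whose edits do or do not destroy an accessibility motif.

    Damaging sites embed the motif across the protospacer head so that its
    adenines fall on the editing-window positions (the A->G edit destroys
    the motif).  Half of the benign sites carry the motif well away from the
    protospacer (accessible, but the edit cannot touch it); the rest are
    motif-free (inaccessible).  Returns the genome, the sites, the planted
    per-site damaging flags and a manifest.
    """
    if n_damaging > n_sites:
        raise ValueError("n_damaging must be <= n_sites")
    # motif adenines must be alignable onto window positions 5/6
    a_idx = [i for i, b in enumerate(motif) if b == "A"]
    if not a_idx:
        raise ValueError("motif must contain an adenine")
    offset_in_proto = 5 - 1 - a_idx[0]  # motif's first A lands on position 5
    if offset_in_proto < 0 or offset_in_proto + len(motif) > 20:
        raise ValueError("motif does not fit across the protospacer head")

    rng = np.random.default_rng(seed)
    spacing = input_length + 100
    genome_len = n_sites * spacing + 2 * input_length
    genome = list(_random_seq(rng, genome_len))
    # keep the background motif-free so P(accessible) truth stays planted
    gstr = "".join(genome)
    while motif in gstr or reverse_complement(motif) in gstr:
        i = gstr.find(motif)
        if i < 0:
            i = gstr.find(reverse_complement(motif))
        for j, b in enumerate(_random_seq(rng, len(motif))):
            genome[i + j] = b
        gstr = "".join(genome)

    sites: list[CandidateSite] = []
    damaging: list[bool] = []
    kinds: list[str] = []
    for k in range(n_sites):
        start = input_length + k * spacing
        proto = list(spec.spacer)
        if k < n_damaging:
            proto[offset_in_proto : offset_in_proto + len(motif)] = list(motif)
            kind = "damaging"
        elif k % 2 == 0:
            kind = "benign_accessible"
        else:
            kind = "benign_inaccessible"
        proto_seq = "".join(proto)
        genome[start : start + 20] = list(proto_seq)
        if kind == "benign_accessible":
            moff = start + 20 + 40  # inside the context, outside the window
            genome[moff : moff + len(motif)] = list(motif)
        mm = sum(a != b for a, b in zip(proto_seq, spec.spacer))
        sites.append(
            CandidateSite(
                interval=GenomicInterval(contig, start, start + 20, "+"),
                matched_protospacer=proto_seq,
                pam_observed="",
                mismatch_count=mm,
            )
        )
        damaging.append(kind == "damaging")
        kinds.append(kind)

    manifest = TruthManifest(
        generator="gen_damage_sites",
        seed=seed,
        parameters={
            "n_sites": n_sites,
            "n_damaging": n_damaging,
            "motif": motif,
            "input_length": input_length,
        },
        truth={"damaging": damaging, "kinds": kinds},
    )
    return {contig: "".join(genome)}, sites, damaging, manifest


def gen_spliced_bam(
    canonical_donor: int,
    cryptic_donor: int,
    acceptor: int,
    cryptic_fraction: float,
    n_reads: int,
    seed: int,
    out_prefix: str | Path,
    contig: str = "chr11",
    exon_flank: int = 50,
) -> tuple[Path, TruthManifest]:
    """Coordinate-sorted spliced BAM mixing canonical and cryptic donors.

    Donor/acceptor coordinates are 1-based (donor = last exonic base,
    acceptor = first exonic base after the intron).  The cryptic read count
    is the planted fraction realised exactly (rounded), so error-free
    recovery is exact.
    """
    if not (0.0 <= cryptic_fraction <= 1.0):
        raise ValueError("cryptic_fraction must lie in [0, 1]")
    for d in (canonical_donor, cryptic_donor):
        if not (exon_flank <= d < acceptor - 1):
            raise ValueError("donors must leave room for the exon flank and intron")
    rng = np.random.default_rng(seed)
    n_cryptic = int(round(cryptic_fraction * n_reads))
    donors = [cryptic_donor] * n_cryptic + [canonical_donor] * (n_reads - n_cryptic)
    rng.shuffle(donors)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sam_path = out_prefix.with_suffix(".sam")
    bam_path = out_prefix.with_suffix(".bam")
    contig_len = acceptor + exon_flank + 1000

    records = []
    for i, donor in enumerate(donors):
        pos0 = donor - exon_flank  # 0-based start
        intron = acceptor - 1 - donor
        cigar = f"{exon_flank}M{intron}N{exon_flank}M"
        seq = "A" * (2 * exon_flank)
        records.append(
            (
                pos0,
                f"read{i}\t0\t{contig}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t"
                f"{'I' * len(seq)}",
            )
        )
    records.sort(key=lambda r: r[0])
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{contig_len}\n")
        for _p, line in records:
            fh.write(line + "\n")
    with pysam.AlignmentFile(str(sam_path)) as sam_in, pysam.AlignmentFile(
        str(bam_path), "wb", template=sam_in
    ) as bam_out:
        for read in sam_in:
            bam_out.write(read)
    pysam.index(str(bam_path))

    manifest = TruthManifest(
        generator="gen_spliced_bam",
        seed=seed,
        parameters={
            "canonical_donor": canonical_donor,
            "cryptic_donor": cryptic_donor,
            "acceptor": acceptor,
            "cryptic_fraction": cryptic_fraction,
            "n_reads": n_reads,
        },
        truth={
            "n_cryptic": n_cryptic,
            "realized_cryptic_fraction": n_cryptic / n_reads if n_reads else None,
        },
    )
    manifest.save(out_prefix.with_suffix(".truth.json"))
    return bam_path, manifest
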