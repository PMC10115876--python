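"""Off-target nomination funnel, checked against independent brute-force oracles."""

import numpy as np
import pytest

from abequant.core import GenomicInterval, ProtospacerSpec
from abequant.offtargets import (
    CandidateSite,
    circleseq_sites_from_bed,
    enumerate_offtargets,
    filter_adenine_window,
    merge_candidates,
    rank_sites,
    sites_from_frame,
    sites_to_frame,
)
from abequant.simulate import gen_genome_with_offtargets, make_hbe_like_locus

# --- independent oracles -------------------------------------------------

_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def _oracle_rc(seq):
    return "".join(_ORACLE_COMP.get(b, "N") for b in reversed(seq))


def _oracle_pam_ok(pattern, seq):
    return len(pattern) == len(seq) and all(
        b in _ORACLE_IUPAC[p] for p, b in zip(pattern, seq)
    )


def brute_force_scan(genome, spacer, pam, max_mm):
    """Naive per-position scan of every window on both strands."""
    found = set()
    for contig, seq in genome.items():
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else _oracle_rc(seq)
            for i in range(L - 20 - len(pam) + 1):
                proto = s[i : i + 20]
                if not _oracle_pam_ok(pam, s[i + 20 : i + 20 + len(pam)]):
                    continue
                mm = sum(a != b for a, b in zip(proto, spacer))
                if mm <= max_mm:
                    start = i if strand == "+" else L - i - 20
                    found.add((contig, start, strand, mm, proto))
    return found


def _site_key(s: CandidateSite):
    return (
        s.interval.contig,
        s.interval.start,
        s.interval.strand,
        s.mismatch_count,
        s.matched_protospacer,
    )


def _make_site(contig, start, strand, mm=0, proto=None, reads=None, sources=("insilico",)):
    return CandidateSite(
        interval=GenomicInterval(contig, start, start + 20, strand),
        matched_protospacer=proto or "GCTTAAGCTGGTCCTGTGGC",
        pam_observed="TGG",
        mismatch_count=mm,
        sources=frozenset(sources),
        circleseq_read_count=reads,
    )


@pytest.fixture(scope="module")
def spec():
    return make_hbe_like_locus(0)[1]


class TestEnumerate:
    def test_planted_exact_site_found_once(self, spec):
        genome, truth, _ = gen_genome_with_offtargets(5000, spec, [(0, "+")], 3)
        sites = enumerate_offtargets(genome, spec, 0)
        assert len(sites) == 1
        assert sites[0].mismatch_count == 0
        assert sites[0].interval.start == truth[0]["start"]

    def test_no_pam_means_no_sites(self, spec):
        genome = {"c": "AC" * 500}  # no G anywhere: NGG can never match
        assert enumerate_offtargets(genome, spec, 4) == []

    def test_matches_brute_force_oracle(self, spec):
        genome, _, _ = gen_genome_with_offtargets(
            30_000, spec, [(0, "+"), (2, "-"), (4, "+")], 17
        )
        sites = enumerate_offtargets(genome, spec, 4)
        oracle = brute_force_scan(genome, spec.spacer, spec.pam_pattern, 4)
        assert {_site_key(s) for s in sites} == oracle

    def test_planted_mismatch_ladder_recovered(self, spec):
        planted = [(0, "+"), (1, "-"), (2, "+"), (3, "-"), (4, "+")]
        genome, truth, _ = gen_genome_with_offtargets(60_000, spec, planted, 23)
        sites = enumerate_offtargets(genome, spec, 4)
        found = {(s.interval.start, s.interval.strand): s.mismatch_count for s in sites}
        for t in truth:
            assert found[(t["start"], t["strand"])] == t["mismatches"]

    def test_sorted_output(self, spec):
        genome, _, _ = gen_genome_with_offtargets(
            30_000, spec, [(2, "+"), (1, "-"), (3, "+")], 9
        )
        sites = enumerate_offtargets(genome, spec, 4)
        keys = [(s.interval.contig, s.interval.start, s.interval.strand) for s in sites]
        assert keys == sorted(keys)

    def test_spacer_with_n_rejected(self, spec):
        bad = ProtospacerSpec.__new__(ProtospacerSpec)  # bypass spacer validation
        object.__setattr__(bad, "spacer", "N" * 20)
        object.__setattr__(bad, "pam_pattern", "NGG")
        with pytest.raises(ValueError):
            enumerate_offtargets({"c": "ACGT" * 100}, bad, 2)


class TestMerge:
    def test_same_site_from_two_sources_unified(self):
        a = _make_site("chr1", 100, "+", mm=1, sources=("insilico",))
        b = _make_site("chr1", 100, "+", mm=1, reads=50, sources=("circleseq",))
        merged = merge_candidates([a], [b])
        assert len(merged) == 1
        assert merged[0].sources == frozenset({"insilico", "circleseq"})
        assert merged[0].circleseq_read_count == 50

    def test_disjoint_sites_kept(self):
        a = _make_site("chr1", 100, "+")
        b = _make_site("chr1", 500, "+")
        assert len(merge_candidates([a], [b])) == 2

    def test_opposite_strands_never_merge(self):
        a = _make_site("chr1", 100, "+")
        b = _make_site("chr1", 100, "-")
        assert len(merge_candidates([a, b])) == 2

    def test_matches_pairwise_closure_oracle(self):
        rng = np.random.default_rng(11)
        sites = [
            _make_site("chr1", int(start), "+", mm=int(rng.integers(0, 5)))
            for start in rng.integers(0, 400, 30)
        ]
        merged = merge_candidates(sites)
        # oracle: union-find closure over pairwise interval overlap
        parent = list(range(len(sites)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                if sites[i].interval.overlaps(sites[j].interval):
                    parent[find(i)] = find(j)
        n_groups = len({find(i) for i in range(len(sites))})
        assert len(merged) == n_groups

    def test_size_bound_and_commutativity(self):
        rng = np.random.default_rng(13)
        a = [_make_site("chr1", int(s), "+") for s in rng.integers(0, 300, 10)]
        b = [_make_site("chr1", int(s), "+") for s in rng.integers(0, 300, 10)]
        ab, ba = merge_candidates(a, b), merge_candidates(b, a)
        assert len(ab) <= len(a) + len(b)
        assert {_site_key(s) for s in ab} == {_site_key(s) for s in ba}


class TestAdenineFilter:
    def test_adenine_at_position5_retained(self, spec):
        site = _make_site("chr1", 100, "+", proto="GGGGAGGGGGGGGGGGGGGG")
        kept = filter_adenine_window([site], spec)
        assert len(kept) == 1 and kept[0].has_adenine_in_window

    def test_no_window_adenine_removed(self, spec):
        site = _make_site("chr1", 100, "+", proto="AAAGGGGGAAAAAAAAAAAA")
        assert filter_adenine_window([site], spec) == []

    def test_minus_strand_adenine_on_protospacer_strand(self, spec):
        # matched_protospacer is already protospacer-strand: the reference
        # plus strand of this minus site shows T in the window
        site = _make_site("chr1", 100, "-", proto="GGGGAGGGGGGGGGGGGGGG")
        kept = filter_adenine_window([site], spec)
        assert len(kept) == 1

    def test_subset_and_idempotent(self, spec):
        rng = np.random.default_rng(19)
        sites = [
            _make_site(
                "chr1",
                int(200 + 30 * i),
                "+",
                proto="".join("ACGT"[j] for j in rng.integers(0, 4, 20)),
            )
            for i in range(50)
        ]
        once = filter_adenine_window(sites, spec)
        keys = {_site_key(s) for s in sites}
        assert all(_site_key(s) in keys for s in once)
        assert [_site_key(s) for s in filter_adenine_window(once, spec)] == [
            _site_key(s) for s in once
        ]

    def test_agrees_with_hand_oracle_on_random_candidates(self, spec):
        rng = np.random.default_rng(23)
        lo, hi = spec.editing_window
        n_kept_oracle = 0
        sites = []
        for i in range(500):
            proto = "".join("ACGT"[j] for j in rng.integers(0, 4, 20))
            strand = "+" if i % 2 == 0 else "-"
            sites.append(_make_site("chr1", 100 + 40 * i, strand, proto=proto))
            if "A" in proto[lo - 1 : hi]:
                n_kept_oracle += 1
        kept = filter_adenine_window(sites, spec)
        assert len(kept) == n_kept_oracle


class TestRank:
    def test_fewer_sites_than_n_returns_all(self):
        sites = [_make_site("chr1", 50 * i, "+", reads=i) for i in range(10)]
        assert len(rank_sites(sites, 250)) == 10

    def test_matches_sort_oracle_under_shuffle(self):
        rng = np.random.default_rng(29)
        sites = [
            _make_site(
                "chr1",
                50 * i,
                "+",
                mm=int(rng.integers(0, 5)),
                reads=int(rng.integers(0, 100)),
            )
            for i in range(60)
        ]
        expected = sorted(
            sites,
            key=lambda s: (
                -(s.circleseq_read_count or 0),
                s.mismatch_count,
                s.interval.contig,
                s.interval.start,
            ),
        )[:20]
        for _ in range(5):
            shuffled = list(sites)
            rng.shuffle(shuffled)
            assert [_site_key(s) for s in rank_sites(shuffled, 20)] == [
                _site_key(s) for s in expected
            ]

    def test_tie_break_by_locus(self):
        a = _make_site("chr2", 100, "+", mm=2, reads=10)
        b = _make_site("chr1", 900, "+", mm=2, reads=10)
        assert rank_sites([a, b], 2)[0].interval.contig == "chr1"


class TestIO:
    def test_candidate_frame_roundtrip(self, spec):
        genome, _, _ = gen_genome_with_offtargets(10_000, spec, [(0, "+"), (2, "-")], 31)
        sites = filter_adenine_window(enumerate_offtargets(genome, spec, 4), spec)
        back = sites_from_frame(sites_to_frame(sites))
        assert [_site_key(s) for s in back] == [_site_key(s) for s in sites]

    def test_circleseq_bed_adapter(self, spec, tmp_path):
        genome, truth, _ = gen_genome_with_offtargets(8000, spec, [(1, "-")], 37)
        t = truth[0]
        bed = tmp_path / "circle.bed"
        bed.write_text(f"chrS\t{t['start']}\t{t['end']}\tcut1\t88\t-\n")
        sites = circleseq_sites_from_bed(bed, genome, spec)
        assert len(sites) == 1
        assert sites[0].circleseq_read_count == 88
        assert sites[0].matched_protospacer == t["protospacer"]
        assert sites[0].mismatch_count == t["mismatches"]
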