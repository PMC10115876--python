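"""Accessibility damage scoring: edits, predictor contract, flagging."""

import numpy as np
import pytest

from abequant.core import GenomicInterval
from abequant.damage import (
    ConvAccessibilityModel,
    apply_edit,
    predict_accessibility,
    score_site,
    train_reference_predictor,
)
from abequant.offtargets import CandidateSite
from abequant.simulate import (
    DEFAULT_ACCESS_MOTIF,
    gen_accessibility_dataset,
    gen_damage_sites,
    make_hbe_like_locus,
)


@pytest.fixture(scope="module")
def spec():
    return make_hbe_like_locus(0)[1]


class StubModel:
    """Constant-output predictor: maps exact sequences to fixed values."""

    input_length = 60
    track_ids = ("stub",)

    def __init__(self, table=None, default=0.5):
        self.table = table or {}
        self.default = default

    def predict_batch(self, sequences):
        return np.array([[self.table.get(s, self.default)] for s in sequences])


def _context(spec, strand="+", length=60):
    """A context of the given length with the spacer protospacer centered."""
    pad = (length - 20) // 2
    core = spec.spacer if strand == "+" else None
    if strand == "+":
        return "C" * pad + spec.spacer + "C" * (length - pad - 20)
    from abequant.core import reverse_complement

    return "C" * pad + reverse_complement(spec.spacer) + "C" * (length - pad - 20)


class TestApplyEdit:
    def test_empty_positions_identity(self, spec):
        ctx = _context(spec)
        assert apply_edit(ctx, spec, []) == ctx

    def test_plus_strand_single_edit(self, spec):
        ctx = _context(spec)
        edited = apply_edit(ctx, spec, [5])
        pad = (len(ctx) - 20) // 2
        assert edited[pad + 4] == "G" and ctx[pad + 4] == "A"
        assert len(edited) == len(ctx)
        diffs = [i for i, (a, b) in enumerate(zip(ctx, edited)) if a != b]
        assert diffs == [pad + 4]

    def test_minus_strand_roundtrip(self, spec):
        """Minus-strand edit shows T->C on the reference; re-deriving the
        protospacer strand shows A->G at position 5."""
        from abequant.core import reverse_complement

        ctx = _context(spec, strand="-")
        pad = (len(ctx) - 20) // 2
        edited = apply_edit(ctx, spec, [5], strand="-")
        coord = pad + 20 - 5
        assert ctx[coord] == "T" and edited[coord] == "C"
        proto_before = reverse_complement(ctx[pad : pad + 20])
        proto_after = reverse_complement(edited[pad : pad + 20])
        assert proto_before[4] == "A" and proto_after[4] == "G"

    def test_position_without_adenine_rejected(self, spec):
        with pytest.raises(ValueError, match="position 7"):
            apply_edit(_context(spec), spec, [7])  # spacer has G at position 7


class TestPredictorContract:
    def test_outputs_in_unit_interval_and_deterministic(self, reference_model):
        rng = np.random.default_rng(61)
        seqs = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, reference_model.input_length))
            for _ in range(20)
        ]
        p1 = reference_model.predict_batch(seqs)
        p2 = reference_model.predict_batch(seqs)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.array_equal(p1, p2)

    def test_wrong_length_rejected_naming_expected(self, reference_model):
        with pytest.raises(ValueError, match=str(reference_model.input_length)):
            predict_accessibility("ACGT", reference_model)

    def test_motif_scores_above_shuffled_control(self, reference_model):
        rng = np.random.default_rng(67)
        L = reference_model.input_length
        motif = DEFAULT_ACCESS_MOTIF
        diffs = []
        for _ in range(100):
            base = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
            off = int(rng.integers(0, L - len(motif)))
            with_motif = base[:off] + motif + base[off + len(motif) :]
            shuffled = list(motif)
            rng.shuffle(shuffled)
            control = base[:off] + "".join(shuffled) + base[off + len(motif) :]
            pm = reference_model.predict_batch([with_motif])[0, 0]
            pc = reference_model.predict_batch([control])[0, 0]
            diffs.append(pm - pc)
        assert np.mean(diffs) > 0.2


class TestTraining:
    def test_holdout_auroc_at_default_settings(self, reference_model):
        assert reference_model.holdout_auroc >= 0.9

    def test_permuted_labels_give_chance_auroc(self):
        seqs, labels, _ = gen_accessibility_dataset(1200, seed=71)
        rng = np.random.default_rng(73)
        permuted = rng.permutation(labels)
        model = train_reference_predictor(seqs, permuted, seed=73, epochs=8)
        assert 0.4 <= model.holdout_auroc <= 0.6

    def test_same_seed_identical_predictions(self):
        seqs, labels, _ = gen_accessibility_dataset(600, seed=79)
        m1 = train_reference_predictor(seqs, labels, seed=5, epochs=5)
        m2 = train_reference_predictor(seqs, labels, seed=5, epochs=5)
        probe, _, _ = gen_accessibility_dataset(40, seed=83)
        assert np.array_equal(m1.predict_batch(probe), m2.predict_batch(probe))

    def test_single_class_rejected(self):
        seqs, labels, _ = gen_accessibility_dataset(100, seed=89)
        with pytest.raises(ValueError):
            train_reference_predictor(seqs, np.ones_like(labels), seed=1)

    def test_save_load_roundtrip(self, reference_model, tmp_path):
        path = tmp_path / "model.npz"
        reference_model.save(path)
        loaded = ConvAccessibilityModel.load(path)
        rng = np.random.default_rng(97)
        seqs = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, reference_model.input_length))
            for _ in range(5)
        ]
        assert np.allclose(
            reference_model.predict_batch(seqs), loaded.predict_batch(seqs)
        )


class TestScoreSite:
    def _site(self, spec, ctx_len=60):
        pad = (ctx_len - 20) // 2
        genome = {"c": _context_for(spec, ctx_len)}
        site = CandidateSite(
            interval=GenomicInterval("c", pad, pad + 20, "+"),
            matched_protospacer=spec.spacer,
            pam_observed="",
            mismatch_count=0,
        )
        return site, genome

    def test_constant_model_never_flags(self, spec):
        site, genome = self._site(spec)
        res = score_site(site, genome, spec, StubModel(default=0.9))
        assert res.max_damage == pytest.approx(0.0)
        assert not res.flagged

    def test_threshold_example_flags(self, spec):
        site, genome = self._site(spec)
        ctx = genome["c"]
        table = {ctx: 0.5}
        for positions in ([5], [6], [5, 6]):
            table[apply_edit(ctx, spec, positions)] = 0.3
        res = score_site(site, genome, spec, StubModel(table))
        assert res.max_damage == pytest.approx(0.2)
        assert res.flagged  # 0.5 > 0.2 and 0.2 > 0.1

    def test_inaccessible_site_not_flagged_despite_damage(self, spec):
        site, genome = self._site(spec)
        ctx = genome["c"]
        table = {ctx: 0.15}
        for positions in ([5], [6], [5, 6]):
            table[apply_edit(ctx, spec, positions)] = 0.0
        res = score_site(site, genome, spec, StubModel(table))
        assert not res.flagged  # P(accessible) control below 0.2

    def test_gain_of_function_flag_mode(self, spec):
        site, genome = self._site(spec)
        ctx = genome["c"]
        table = {ctx: 0.5}
        for positions in ([5], [6], [5, 6]):
            table[apply_edit(ctx, spec, positions)] = 0.9
        assert not score_site(site, genome, spec, StubModel(table)).flagged
        assert score_site(site, genome, spec, StubModel(table), flag_absolute=True).flagged

    def test_no_window_adenine_rejected(self, spec):
        site, genome = self._site(spec)
        from dataclasses import replace

        bad = replace(site, matched_protospacer="G" * 20)
        with pytest.raises(ValueError):
            score_site(bad, genome, spec, StubModel())

    def test_planted_damaging_set_recovered_end_to_end(self, spec, reference_model):
        """Of 30 planted candidate sites (5 motif-destroying), the flagged
        set at default thresholds equals the planted damaging set."""
        genome, sites, damaging, _ = gen_damage_sites(30, 5, spec, seed=21)
        flags = [
            score_site(s, genome, spec, reference_model).flagged for s in sites
        ]
        assert flags == damaging


def _context_for(spec, length):
    pad = (length - 20) // 2
    return "C" * pad + spec.spacer + "C" * (length - pad - 20)
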