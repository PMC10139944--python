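"""Kinase interactions, PWM assignment, filters, STRIDE structure analysis."""

import numpy as np
import pytest
from scipy import stats as sps

from modconserv.alignments import AbundanceRecord, ModificationRecord, ParalogPair
from modconserv.annex import (
    PWM,
    KinaseInteraction,
    KinaseInteractionTable,
    StrideParseError,
    StrideRecord,
    assign_best_kinase,
    disjoint_kinase_pairs,
    filter_multi_study,
    filter_pairs_by_abundance,
    pair_structure_difference,
    parse_stride,
    pwm_site_score,
    secondary_structure_length,
    single_interaction_ratio,
)
from modconserv.pairs import SiteOfInterest
from modconserv._tables import AMINO_ACIDS


def make_table(rows):
    return KinaseInteractionTable(
        KinaseInteraction(k, s) for k, s in rows
    )


class TestSingleInteractionRatio:
    PAIR = ParalogPair("A", "B")

    def test_all_single(self):
        t = make_table([("k1", "A"), ("k2", "A"), ("k3", "B")])
        assert single_interaction_ratio(self.PAIR, t) == 1.0

    def test_all_double(self):
        t = make_table([("k1", "A"), ("k1", "B"), ("k2", "A"), ("k2", "B")])
        assert single_interaction_ratio(self.PAIR, t) == 0.0

    def test_three_single_one_double(self):
        t = make_table([("k1", "A"), ("k2", "A"), ("k3", "B"),
                        ("k4", "A"), ("k4", "B")])
        assert single_interaction_ratio(self.PAIR, t) == pytest.approx(0.75)

    def test_no_interactions_undefined(self):
        assert single_interaction_ratio(self.PAIR, make_table([("k1", "C")])) is None

    def test_monotone_as_double_becomes_single(self):
        base = [("k1", "A"), ("k1", "B"), ("k2", "A"), ("k2", "B"), ("k3", "A")]
        r0 = single_interaction_ratio(self.PAIR, make_table(base))
        # convert k2 to a single interaction
        r1 = single_interaction_ratio(
            self.PAIR, make_table([x for x in base if x != ("k2", "B")]))
        assert r1 >= r0

    def test_deduplication(self):
        t = make_table([("k1", "A"), ("k1", "A"), ("k1", "A")])
        assert len(t) == 1


def uniform_pwm(kinase, value=0.0, offsets=tuple(range(-5, 5))):
    return PWM(kinase, offsets, np.full((len(offsets), 20), value))


class TestPWMAssignment:
    SEQ = "MKRAPSGWYQCV"

    def test_motif_matched_pwm_wins(self):
        flat = uniform_pwm("k_flat", 0.1)
        match = uniform_pwm("k_match", 0.0)
        # put all weight on the observed residue one position before site 6 (P)
        row = list(match.offsets).index(-1)
        w = match.weights.copy()
        w[row, AMINO_ACIDS.index("P")] = 50.0
        match = PWM("k_match", match.offsets, w)
        assert assign_best_kinase(6, self.SEQ, [flat, match]) == "k_match"

    def test_tie_breaks_lexicographically(self):
        assert assign_best_kinase(6, self.SEQ,
                                  [uniform_pwm("kB"), uniform_pwm("kA")]) == "kA"

    def test_score_equals_hand_sum(self, rng):
        offsets = tuple(range(-5, 5))
        w = rng.random((10, 20))
        pwm = PWM("k", offsets, w)
        pos = 6
        expected = sum(
            w[r, AMINO_ACIDS.index(self.SEQ[pos - 1 + off])]
            for r, off in enumerate(offsets)
            if 1 <= pos + off <= len(self.SEQ)
        )
        assert pwm_site_score(pwm, self.SEQ, pos) == pytest.approx(expected)

    def test_terminal_offsets_skipped_not_padded(self):
        pwm = uniform_pwm("k", 1.0)
        # site at position 2: offsets −5..−2 fall off the N terminus
        assert pwm_site_score(pwm, self.SEQ, 2) == pytest.approx(6.0)

    def test_constant_shift_at_one_offset_preserves_argmax(self, rng):
        offsets = tuple(range(-5, 5))
        pwms = [PWM(f"k{i}", offsets, rng.random((10, 20))) for i in range(3)]
        before = assign_best_kinase(6, self.SEQ, pwms)
        shifted = [PWM(p.kinase_id, p.offsets, p.weights + (np.arange(10) == 2)[:, None] * 3.0)
                   for p in pwms]
        assert assign_best_kinase(6, self.SEQ, shifted) == before

    def test_empty_pwm_list_rejected(self):
        with pytest.raises(ValueError):
            assign_best_kinase(6, self.SEQ, [])

    def test_identical_proteins_never_disjoint(self, rng):
        pwms = [PWM(f"k{i}", tuple(range(-5, 5)), rng.random((10, 20)))
                for i in range(4)]
        pair = ParalogPair("A", "B")
        seqs = {"A": self.SEQ, "B": self.SEQ}
        out = disjoint_kinase_pairs({pair: ([6], [6])}, seqs, pwms)
        assert out == []

    def test_toy_disjoint_pair(self):
        pa = uniform_pwm("kA")
        wa = pa.weights.copy(); wa[5, AMINO_ACIDS.index("G")] = 10
        pb = uniform_pwm("kB")
        wb = pb.weights.copy(); wb[5, AMINO_ACIDS.index("W")] = 10
        pwms = [PWM("kA", pa.offsets, wa), PWM("kB", pb.offsets, wb)]
        pair = ParalogPair("A", "B")
        seqs = {"A": "AAAAASGAAAA", "B": "AAAAASWAAAA"}
        # offset 0 is weight row 5; position 7 carries G in A and W in B
        out = disjoint_kinase_pairs({pair: ([7], [7])}, seqs, pwms)
        assert [p.orf_a for p in out] == ["A"]


class TestFilters:
    def _pairs(self):
        return [ParalogPair("A", "B"), ParalogPair("C", "D"), ParalogPair("E", "F")]

    def test_abundance_fold_filter(self):
        ab = {o: AbundanceRecord(o, v) for o, v in
              [("A", 100), ("B", 150), ("C", 100), ("D", 250),
               ("E", 100), ("F", 200)]}
        kept = filter_pairs_by_abundance(self._pairs(), ab, max_fold=2.0)
        # 1.5-fold kept; 2.5-fold dropped; exactly 2-fold dropped (strict <)
        assert [(p.orf_a, p.orf_b) for p in kept] == [("A", "B")]

    def test_missing_abundance_dropped(self):
        ab = {"A": AbundanceRecord("A", 100), "B": AbundanceRecord("B", 120)}
        kept = filter_pairs_by_abundance(self._pairs(), ab, max_fold=2.0)
        assert len(kept) == 1

    def test_multi_study_filter(self):
        mods = [
            ModificationRecord("Y1", 5, "S", "phosphorylation", frozenset({"s1", "s2"})),
            ModificationRecord("Y2", 9, "K", "ubiquitylation", frozenset({"s1"})),
        ]
        assert len(filter_multi_study(mods, 2)) == 1
        assert filter_multi_study(mods, 1) == mods


STRIDE_FIXTURE = """\
REM  --------------- Detailed secondary structure assignment-------------
ASG  MET A    1    1    C          Coil    360.00   -35.26     120.5      ~~~~
ASG  LYS A    2    2    C          Coil    -70.00   -30.00      88.1      ~~~~
ASG  ALA A    3    3    H    AlphaHelix    -60.00   -45.00      42.3      ~~~~
ASG  LEU A    4    4    H    AlphaHelix    -62.00   -41.00      10.0      ~~~~
ASG  SER A    5    5    H    AlphaHelix    -64.00   -40.00      42.3      ~~~~
ASG  GLY A    6    6    T          Turn    -80.00    10.00      70.2      ~~~~
ASG  VAL A    7    7    C          Coil   -100.00   130.00      95.0      ~~~~
"""


class TestStride:
    def test_parse_fixture(self, tmp_path):
        p = tmp_path / "orf.stride"
        p.write_text(STRIDE_FIXTURE)
        recs = parse_stride(p, orf_id="T")
        assert len(recs) == 7
        r5 = [r for r in recs if r.position == 5][0]
        assert r5.secondary_structure == "AlphaHelix"
        assert r5.solvent_accessible_area == pytest.approx(42.3)
        assert r5.residue == "S"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.stride"
        p.write_text("REM nothing\n")
        assert parse_stride(p) == []

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.stride"
        p.write_text("ASG  MET A 1 1 C Coil bad phi\n")
        with pytest.raises(StrideParseError):
            parse_stride(p)

    def test_run_length(self, tmp_path):
        p = tmp_path / "orf.stride"
        p.write_text(STRIDE_FIXTURE)
        recs = parse_stride(p)
        assert secondary_structure_length(recs, 4) == 3   # helix 3..5
        assert secondary_structure_length(recs, 6) == 1
        # identical within one run
        assert {secondary_structure_length(recs, i) for i in (3, 4, 5)} == {3}

    def test_uncovered_position(self, tmp_path):
        p = tmp_path / "orf.stride"
        p.write_text(STRIDE_FIXTURE)
        assert secondary_structure_length(parse_stride(p), 99) is None


class TestStructureDifference:
    def _site(self, tpos=4, ppos=4):
        return SiteOfInterest(ParalogPair("T", "P"), "T", "phosphorylation",
                              "S", tpos, ppos)

    def _records(self, classes, areas, orf="T"):
        return [
            StrideRecord(orf, i + 1, "A", c, a)
            for i, (c, a) in enumerate(zip(classes, areas))
        ]

    def test_identical_structures_zero_difference(self, tmp_path):
        recs = self._records(["Coil", "AlphaHelix", "AlphaHelix", "AlphaHelix"],
                             [10, 20, 30, 40])
        label, dl, da = pair_structure_difference(self._site(3, 3), recs, recs)
        assert label == "AlphaHelix-AlphaHelix"
        assert dl == 0 and da == 0.0

    def test_run_length_difference(self):
        t = self._records(["AlphaHelix"] * 6, [10] * 6)
        p = self._records(["Coil", "AlphaHelix", "AlphaHelix", "Coil",
                           "Coil", "Coil"], [10] * 6, orf="P")
        label, dl, _ = pair_structure_difference(self._site(3, 3), t, p)
        assert label == "AlphaHelix-AlphaHelix"
        assert dl == 6 - 2

    def test_antisymmetric_under_swap(self):
        t = self._records(["AlphaHelix"] * 5, [50, 40, 30, 20, 10])
        p = self._records(["Coil"] * 5, [5, 5, 5, 5, 5], orf="P")
        site = self._site(3, 3)
        l1, d1, a1 = pair_structure_difference(site, t, p)
        l2, d2, a2 = pair_structure_difference(site, p, t)
        assert (d1, a1) == (-d2, -a2)
        assert l1.split("-") == l2.split("-")[::-1]

    def test_missing_coverage_returns_none(self):
        recs = self._records(["Coil"] * 3, [1, 2, 3])
        assert pair_structure_difference(self._site(9, 1), recs, recs) is None

    def test_symmetric_fixture_centers_at_zero(self, rng):
        """On exchangeable synthetic structures the Δ distributions center
        at 0 (sign test p > 0.05)."""
        deltas = []
        for i in range(80):
            lt = int(rng.integers(1, 8))
            lp = int(rng.integers(1, 8))
            t = self._records(["AlphaHelix"] * lt + ["Coil"] * 8, [0] * (lt + 8))
            p = self._records(["AlphaHelix"] * lp + ["Coil"] * 8,
                              [0] * (lp + 8), orf="P")
            _, dl, _ = pair_structure_difference(self._site(1, 1), t, p)
            deltas.append(dl)
        nonzero = [d for d in deltas if d != 0]
        k = sum(d > 0 for d in nonzero)
        p_sign = sps.binomtest(k, len(nonzero), 0.5).pvalue
        assert p_sign > 0.05
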