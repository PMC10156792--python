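"""Column statistics, triad activity, motif scanning and the criteria classifier."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdcore import synth
from pdcore.seqdiscrim import (
    AMINO_ACIDS,
    MAX_IC_BITS,
    AlignedSeqSet,
    classify_e3bp,
    column_stats,
    default_rules,
    motif_profile_from_group,
    scan_motifs,
    triad_activity,
)


def _msa(seqs, groups=None):
    n = len(seqs)
    return AlignedSeqSet(
        ids=tuple(f"s{i}" for i in range(n)),
        groups=tuple(groups or ["Pez"] * n),
        seqs=tuple(seqs),
    )


class TestColumnStats:
    def test_invariant_column_scores_log2_twenty(self):
        prof = column_stats(_msa(["A", "A", "A", "A"]))
        assert prof.information[0] == pytest.approx(math.log2(20))

    def test_uniform_column_scores_zero(self):
        prof = column_stats(_msa(list(AMINO_ACIDS)))
        assert prof.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_even_two_residue_split(self):
        prof = column_stats(_msa(["A"] * 5 + ["C"] * 5))
        assert prof.information[0] == pytest.approx(math.log2(20) - 1.0)

    def test_frequencies_sum_to_one(self):
        msa, _ = synth.simulate_sequences(
            synth.SeqScenario(n_per_group={"Asc": 8}, mutation_prob=0.3, seed=9)
        )
        prof = column_stats(msa)
        np.testing.assert_allclose(prof.frequencies.sum(axis=1), 1.0, atol=1e-9)
        assert ((prof.information >= -1e-12) & (prof.information <= MAX_IC_BITS + 1e-12)).all()

    def test_gap_policies(self):
        msa = _msa(["A-", "AC", "A-", "AC"])
        excl = column_stats(msa, gap_policy="exclude")
        assert excl.information[1] == pytest.approx(math.log2(20))  # only C among residues
        sym = column_stats(msa, gap_policy="symbol")
        assert sym.information[1] == pytest.approx(math.log2(21) - 1.0)

    def test_high_gap_columns_flagged(self):
        msa = _msa(["A-", "A-", "A-", "AC"])
        prof = column_stats(msa)
        assert prof.high_gap_columns == (2,)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged|length"):
            AlignedSeqSet(ids=("a", "b"), groups=("Pez", "Pez"), seqs=("AC", "ACD"))

    @given(st.permutations(range(6)))
    def test_row_order_invariance(self, perm):
        seqs = ["ACDEF", "ACDEG", "AKDEF", "ACWEF", "MCDEF", "ACDYF"]
        base = column_stats(_msa(seqs))
        shuf = column_stats(_msa([seqs[i] for i in perm]))
        np.testing.assert_allclose(base.information, shuf.information, atol=1e-12)

    def test_duplicate_row_never_decreases_modal_frequency(self):
        seqs = ["ACD", "AWD", "MCD"]
        base = column_stats(_msa(seqs)).frequencies.max(axis=1)
        dup = column_stats(_msa(seqs + [seqs[0]])).frequencies.max(axis=1)
        assert (dup >= base - 1e-12).all()


class TestTriad:
    def test_his_at_reference_column_is_active(self):
        seq = synth.reference_frame("E2")
        assert triad_activity(seq, synth.TRIAD_COLUMN)[0] == "active"

    def test_substitution_is_inactive(self):
        seq = synth.reference_frame("E2")
        mutated = seq[: synth.TRIAD_COLUMN - 1] + "S" + seq[synth.TRIAD_COLUMN :]
        state, note = triad_activity(mutated, synth.TRIAD_COLUMN)
        assert state == "inactive" and "His absent" in note

    def test_internal_gap_is_inactive_with_warning(self):
        seq = synth.reference_frame("E2")
        gapped = seq[: synth.TRIAD_COLUMN - 1] + "-" + seq[synth.TRIAD_COLUMN :]
        state, note = triad_activity(gapped, synth.TRIAD_COLUMN)
        assert state == "inactive" and "gap" in note

    def test_column_outside_covered_span_is_indeterminate(self):
        seq = "----" + synth.reference_frame("E2")[4:]
        assert triad_activity(seq, 2)[0] == "indeterminate"

    def test_invalid_column_rejected(self):
        with pytest.raises(ValueError):
            triad_activity("ACDE", 9)


class TestScanMotifs:
    def test_e2_reference_votes_e2(self):
        scan = scan_motifs(synth.reference_frame("E2"))
        assert scan.vote == "E2"
        assert scan.results["polar_EKG"]["matched"]
        assert scan.results["flanking_Arg"]["matched"]

    def test_e3bp_reference_votes_e3bp(self):
        scan = scan_motifs(synth.reference_frame("E3BP"))
        assert scan.vote == "E3BP"
        assert scan.results["Asp_Leu_hydrophobic"]["matched"]
        assert scan.results["GxI_termination"]["matched"]

    def test_asc_extension_counts_only_for_asc(self):
        seq = synth.reference_frame("E3BP", group="Asc")
        asc = scan_motifs(seq, group="Asc")
        pez = scan_motifs(seq, group="Pez")
        assert asc.results["Asc_extension"]["matched"]
        assert not pez.results["Asc_extension"]["applied"]

    def test_all_gap_record_unclassified(self):
        scan = scan_motifs("-" * synth.REF_FRAME_LENGTH)
        assert scan.vote == "unclassified"
        assert not any(r["matched"] for r in scan.results.values())

    def test_locality_outside_span_columns_do_not_matter(self):
        rng = np.random.default_rng(0)
        seq = synth.reference_frame("E3BP")
        spans = [r.span for r in default_rules()]
        inside = set()
        for lo, hi in spans:
            inside.update(range(lo - 1, hi))
        chars = list(seq)
        for j in range(len(chars)):
            if j not in inside and j != synth.TRIAD_COLUMN - 1:
                chars[j] = AMINO_ACIDS[rng.integers(20)]
        scrambled = scan_motifs("".join(chars))
        original = scan_motifs(seq)
        for name in original.results:
            assert original.results[name]["score"] == scrambled.results[name]["score"]

    def test_rule_span_beyond_alignment_rejected(self):
        with pytest.raises(ValueError, match="polar_EKG"):
            scan_motifs("ACDEF")


class TestClassifier:
    def test_all_four_criteria(self):
        v = classify_e3bp(
            {"topology": True, "e3_psbd": True, "inactive_cbd": True, "m3_motif": True}
        )
        assert v.verdict == "E3BP" and len(v.fired) == 4

    def test_basidiomycota_pattern_topology_plus_m3(self):
        v = classify_e3bp(
            {"topology": True, "e3_psbd": False, "inactive_cbd": False, "m3_motif": True}
        )
        assert v.verdict == "E3BP"

    def test_missing_gating_criterion_inconclusive(self):
        assert classify_e3bp({"topology": False}).verdict == "inconclusive"

    def test_e2_like_requires_affirmative_negatives(self):
        v = classify_e3bp(
            {"topology": True, "e3_psbd": False, "inactive_cbd": False, "m3_motif": False}
        )
        assert v.verdict == "E2-like"
        partial = classify_e3bp({"topology": True, "e3_psbd": False})
        assert partial.verdict == "inconclusive"

    def test_all_unknown_rejected(self):
        with pytest.raises(ValueError):
            classify_e3bp({})

    @given(st.tuples(*[st.sampled_from([True, False, None])] * 4))
    def test_monotone_in_criteria(self, flags):
        keys = ("topology", "e3_psbd", "inactive_cbd", "m3_motif")
        ann = dict(zip(keys, flags))
        if all(v is None for v in flags):
            return
        base = classify_e3bp(ann).verdict
        for k in keys:
            if ann[k] is False:
                stronger = dict(ann)
                stronger[k] = True
                assert not (base == "E3BP" and classify_e3bp(stronger).verdict == "E2-like")


class TestGroupProfile:
    def test_identical_records_reproduce_the_planted_sequence(self):
        msa, _ = synth.simulate_sequences(
            synth.SeqScenario(n_per_group={"Pez": 6}, mutation_prob=0.0, seed=1)
        )
        prof = motif_profile_from_group(msa, "Pez", (43, 51))
        assert prof.consensus == msa.seqs[0][42:51]
        np.testing.assert_allclose(prof.information, math.log2(20), atol=1e-12)

    def test_hydrophobic_class_symbol_on_ties(self):
        seqs = ["YLD", "FLD", "YFD", "FFD"]
        prof = motif_profile_from_group(_msa(seqs, ["Bas"] * 4), "Bas", (1, 3))
        assert prof.consensus[0] == "h"  # Y/F tie, both hydrophobic
        assert prof.consensus[2] == "D"

    def test_singleton_subset_flagged_low_support(self):
        prof = motif_profile_from_group(_msa(["ACD"], ["Sac"]), "Sac", (1, 3))
        assert prof.low_support
        np.testing.assert_allclose(prof.information, math.log2(20), atol=1e-12)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="Zyg"):
            motif_profile_from_group(_msa(["ACD"]), "Zyg", (1, 2))
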