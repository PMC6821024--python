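import dataclasses

import pytest

from dmnlkit.annotated import AnnotatedSequence, SeqFeatureRec
from dmnlkit.model import bothid_fixture, canonical_teleost_order
from dmnlkit.seqfeatures import (
    HairpinParams,
    detect_ol,
    dot_bracket,
    find_hairpin,
    find_tandem_repeats,
    scan_tas,
)
from dmnlkit.synth import SynthParams, synth_sequence

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_COMP)[::-1]


def _inert(n):
    # alternating A/C cannot base-pair with itself (no A-C, A-A, C-C
    # Watson-Crick or wobble pairs)
    return ("AC" * n)[:n]


class TestFindHairpin:
    def test_perfect_stem_found(self):
        arm = "GATCCGTAG"
        seq = _inert(10) + arm + "AACAA" + _revcomp(arm) + _inert(10)
        hp = find_hairpin(seq)
        assert hp is not None
        assert hp.stem_len_bp >= 9

    def test_short_stem_rejected(self):
        # a 6-pair arm cannot reach min_stem 8 even with the one
        # allowed mismatch absorbed as an extension
        arm = "GATCCG"
        seq = _inert(10) + arm + "AACAA" + _revcomp(arm) + _inert(10)
        assert find_hairpin(seq) is None

    def test_loop_bounds(self):
        arm = "GATCCGTA"
        # loop 18: shrinking to <= max_loop 15 would need 2 mismatch
        # extensions, exceeding the budget
        seq = arm + _inert(18) + _revcomp(arm)
        assert find_hairpin(seq) is None
        seq_ok = arm + _inert(15) + _revcomp(arm)
        assert find_hairpin(seq_ok) is not None

    def test_one_mismatch_tolerated_two_rejected(self):
        arm = "GATCCGTA"
        rc = list(_revcomp(arm))
        rc[3] = "A" if rc[3] != "A" else "C"  # break one internal pair
        one = arm + "TTT" + "".join(rc)
        hp = find_hairpin(one, HairpinParams(max_stem=8))
        assert hp is not None and hp.mismatches == 1
        rc[5] = "A" if rc[5] != "A" else "C"
        two = arm + "TTT" + "".join(rc)
        assert find_hairpin(two, HairpinParams(max_stem=8)) is None

    def test_gu_wobble_counted_not_penalized(self):
        arm = "GGTCCGTA"
        rc = list(_revcomp(arm))  # ends ...CC
        rc[-2] = "T"  # G-T wobble instead of G-C
        seq = arm + "TTT" + "".join(rc)
        hp = find_hairpin(seq, HairpinParams(max_stem=8))
        assert hp is not None
        assert hp.gu_pairs == 1 and hp.mismatches == 0

    def test_gu_disallowed_when_configured(self):
        arm = "GGTCCGTA"
        rc = list(_revcomp(arm))
        rc[-2] = "T"
        seq = arm + "TTT" + "".join(rc)
        hp = find_hairpin(seq, HairpinParams(max_stem=8, allow_gu=False))
        assert hp is None or hp.gu_pairs == 0

    def test_longer_stem_preferred(self):
        arm9 = "GATCCGTAG"
        arm8 = "CCATTGCA"
        seq = (
            arm8 + "TTT" + _revcomp(arm8) + _inert(6)
            + arm9 + "TTT" + _revcomp(arm9)
        )
        hp = find_hairpin(seq)
        assert hp.stem_len_bp >= 9

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            find_hairpin("ACGTNACGT")

    def test_dot_bracket(self):
        arm = "GATCCGTA"
        seq = arm + "TTTT" + _revcomp(arm)
        hp = find_hairpin(seq, HairpinParams(max_stem=8))
        assert dot_bracket(hp) == "((((((((....))))))))"


class TestDetectOl:
    def test_modes_recovered(self):
        arr = bothid_fixture("G.p")
        for seed, mode in (
            (1, "spacer_plus_trnaN_3prime"),
            (2, "spacer_only"),
            (3, "trnaN_middle"),
        ):
            p = dataclasses.replace(SynthParams(seed=seed), ol_mode=mode)
            out = synth_sequence(arr, p)
            hp = detect_ol(out)
            assert hp is not None
            assert hp.mode == mode

    def test_motifs_annotated(self):
        out = synth_sequence(bothid_fixture("G.p"), SynthParams(seed=5))
        hp = detect_ol(out)
        assert hp.motif5 == "GGTGG"
        assert hp.motif3 == "TAGA"

    def test_absolute_coordinates(self):
        out = synth_sequence(bothid_fixture("G.p"), SynthParams(seed=5))
        hp = detect_ol(out)
        span = out.slice(hp.start, hp.end)
        # the reported span must itself fold
        assert find_hairpin(span) is not None

    def test_canonical_layout_also_detected(self):
        out = synth_sequence(canonical_teleost_order(), SynthParams(seed=5))
        hp = detect_ol(out)
        assert hp is not None

    def test_missing_annotation_raises(self):
        annotated = AnnotatedSequence(
            seq="ACGT" * 30,
            features=[SeqFeatureRec("COI", "H", 0, 60)],
        )
        with pytest.raises(ValueError, match="N"):
            detect_ol(annotated)


class TestTandemRepeats:
    def test_exact_recovery(self):
        motif = "GATCCGTAGGCTTAACCGGATG"  # 22 bp
        seq = _inert(30) + motif * 35 + _inert(30)
        reps = find_tandem_repeats(seq)
        assert reps
        top = reps[0]
        assert top.period_bp == 22
        assert top.copies == 35.0

    def test_partial_final_copy_fractional(self):
        motif = "GATCCGTAGG"
        seq = motif * 4 + motif[:5]
        reps = find_tandem_repeats(seq)
        assert reps[0].period_bp == 10
        assert reps[0].copies == 4.5

    def test_min_copies_respected(self):
        motif = "GATCCGTAGG"
        seq = _inert(20) + motif * 2 + _inert(20)
        assert find_tandem_repeats(seq, min_copies=3) == []

    def test_non_overlapping_selection(self):
        m1, m2 = "GATCCGTAGG", "CCATTGCAAG"
        seq = m1 * 5 + _inert(15) + m2 * 3
        reps = find_tandem_repeats(seq)
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                assert a.end <= b.start or b.end <= a.start


class TestScanTas:
    def test_core_found_any_middle(self):
        for mid in "ACGT":
            seq = _inert(11) + f"ACAT{mid}TGTA" + _inert(11)
            hits = scan_tas(seq)
            assert len(hits) == 1
            assert hits[0].middle == mid

    def test_empty_when_absent(self):
        assert scan_tas(_inert(60)) == []

    def test_overlapping_hits_reported(self):
        seq = "ACATATGTACATTTGTA"
        # two cores sharing bases
        assert len(scan_tas(seq)) == 2
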