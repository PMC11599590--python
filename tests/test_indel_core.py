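"""Canonical outcome algebra: representation, microhomology, classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repairscape.indel_core import (
    CATEGORIES,
    FlankMatch,
    OutcomeCategory,
    OutcomeSpec,
    OutOfWindowError,
    TargetSite,
    apply_outcome,
    canonicalize,
    classify,
    deletion_split,
    directionality,
    enumerate_outcomes,
    equivalent_start_range,
    format_descriptor,
    insertion_flank_match,
    is_in_frame,
    microhomology_length,
    parse_descriptor,
)

from conftest import CUT, make_site


def brute_force_groups(seq: str, L: int) -> dict[str, list[int]]:
    """Group all deletions of size L by their edited sequence."""
    groups: dict[str, list[int]] = {}
    for s in range(len(seq) - L + 1):
        groups.setdefault(seq[:s] + seq[s + L :], []).append(s)
    return groups


class TestCanonicalize:
    def test_repeat_deletion_slides_leftmost(self):
        o = canonicalize("TAGCAGC", 4, 7, check_window=False)
        assert (o.del_start, o.del_end) == (1, 4)
        assert apply_outcome("TAGCAGC", o) == "TAGC"

    def test_unique_representation_unchanged(self):
        o = canonicalize("ACGT", 1, 2, check_window=False)
        assert (o.del_start, o.del_end) == (1, 2)

    def test_idempotent(self, site):
        o = canonicalize(site, site.cut - 3, site.cut + 2)
        again = canonicalize(site, o.del_start, o.del_end, o.ins_seq)
        assert o == again

    @settings(derandomize=True, max_examples=150)
    @given(
        seq=st.text(alphabet="ACGT", min_size=10, max_size=40),
        start=st.integers(0, 39),
        size=st.integers(0, 8),
        ins=st.text(alphabet="ACGT", max_size=3),
    )
    def test_equivalence_class_properties(self, seq, start, size, ins):
        """Canonical form is idempotent and preserves the edited sequence."""
        start = min(start, len(seq))
        end = min(start + size, len(seq))
        if start == end and not ins:
            return
        o = canonicalize(seq, start, end, ins, check_window=False)
        assert apply_outcome(seq, o) == seq[:start] + ins + seq[end:]
        assert canonicalize(seq, o.del_start, o.del_end, o.ins_seq, check_window=False) == o
        # every start in the equivalent range reproduces the edited sequence
        s_min, s_max = equivalent_start_range(seq, o)
        assert s_min == o.del_start <= s_max
        L, k = o.del_size, o.ins_size
        edited = apply_outcome(seq, o)
        for s in range(s_min, s_max + 1):
            assert seq[:s] + edited[s : s + k] + seq[s + L :] == edited

    def test_oracle_equivalence_small(self):
        """Canonical representative and mh length match brute-force grouping."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            for L in range(1, 7):
                for edited, starts in brute_force_groups(seq, L).items():
                    for s in starts:
                        o = canonicalize(seq, s, s + L, check_window=False)
                        assert o.del_start == min(starts)
                        assert microhomology_length(seq, o) == len(starts) - 1

    def test_out_of_window_rejected(self, repeat_free_site):
        t = repeat_free_site
        with pytest.raises(OutOfWindowError):
            canonicalize(t, t.cut - 20, t.cut - 15)
        with pytest.raises(OutOfWindowError):
            canonicalize(t, t.cut + 10, t.cut + 10, "AC")
        with pytest.raises(OutOfWindowError):
            canonicalize(t, t.cut - 5, t.cut - 1)  # stops one base short of the cut
        # touching a cut-adjacent base or the 3 nt insertion window is fine
        canonicalize(t, t.cut - 5, t.cut)
        canonicalize(t, t.cut, t.cut + 5)
        canonicalize(t, t.cut + 3, t.cut + 3, "A")

    def test_wild_type_rejected(self, site):
        with pytest.raises(ValueError):
            canonicalize(site, site.cut, site.cut, "")


class TestApplyOutcome:
    def test_examples(self, site):
        seq = site.sequence
        o = OutcomeSpec(site.cut, site.cut, "T")
        assert len(apply_outcome(site, o)) == len(seq) + 1
        o = OutcomeSpec(site.cut - 1, site.cut + 1)
        assert len(apply_outcome(site, o)) == len(seq) - 2


class TestMicrohomology:
    def test_homopolymer(self):
        o = canonicalize("AAAAAA", 1, 3, check_window=False)
        assert microhomology_length("AAAAAA", o) == 4

    def test_no_repeat(self):
        o = canonicalize("ACGT", 1, 2, check_window=False)
        assert microhomology_length("ACGT", o) == 0

    def test_rejects_insertions(self, site):
        with pytest.raises(ValueError):
            microhomology_length(site, OutcomeSpec(site.cut, site.cut, "A"))


class TestClassify:
    @pytest.mark.parametrize(
        "del_left,del_right,expected_size_class",
        [(1, 0, OutcomeCategory.DEL_1), (1, 1, OutcomeCategory.DEL_2)],
    )
    def test_small_deletions(self, repeat_free_site, del_left, del_right, expected_size_class):
        t = repeat_free_site
        o = canonicalize(t, t.cut - del_left, t.cut + del_right)
        assert classify(t, o) is expected_size_class

    def test_medium_deletion_with_mh(self):
        # embed TAGCAGC across the cut: deleting one AGC copy slides freely
        seq = list(make_site(seed=5).sequence)
        seq[CUT - 5 : CUT + 2] = "TAGCAGC"
        t = TargetSite("mh", "".join(seq), 13, 33)
        o = canonicalize(t, t.cut - 1, t.cut + 2)  # one AGC copy, in window
        assert microhomology_length(t, o) >= 2
        assert classify(t, o) is OutcomeCategory.DEL_MED_MH

    def test_medium_and_long_without_mh(self, repeat_free_site):
        t = repeat_free_site
        assert classify(t, canonicalize(t, t.cut - 2, t.cut + 3)) is OutcomeCategory.DEL_MED_NOMH
        assert classify(t, canonicalize(t, t.cut - 5, t.cut + 7)) is OutcomeCategory.DEL_LONG_NOMH

    def test_insertions_by_flank(self):
        t = make_site(distal="T", proximal="G")
        ins = lambda b: canonicalize(t, t.cut, t.cut, b)
        assert classify(t, ins("T")) is OutcomeCategory.INS_DIST
        assert classify(t, ins("G")) is OutcomeCategory.INS_PROX
        assert classify(t, ins("C")) in (
            OutcomeCategory.OTHER_I_MH, OutcomeCategory.OTHER_I_NOMH,
        )
        both = make_site(distal="T", proximal="T", seed=3)
        o = canonicalize(both, both.cut, both.cut, "T")
        assert classify(both, o) is OutcomeCategory.INS_DIST
        assert classify(both, o, both_as_distal=False) is OutcomeCategory.INS_PROX

    def test_mixed_outcome_with_flank_match_is_other_mh(self, site):
        left = site.sequence[site.cut - 3 : site.cut]
        o = canonicalize(site, site.cut - 1, site.cut + 1, left)
        assert classify(site, o) is OutcomeCategory.OTHER_I_MH

    def test_totality_on_enumeration(self, site):
        outcomes = enumerate_outcomes(site)
        labels = [classify(site, o) for o in outcomes]
        assert all(l.value in CATEGORIES for l in labels)
        assert len(labels) == len(outcomes)


class TestFlankMatch:
    @pytest.mark.parametrize(
        "distal,proximal,ins,expected",
        [
            ("T", "G", "T", FlankMatch.DISTAL_ONLY),
            ("T", "G", "G", FlankMatch.PROXIMAL_ONLY),
            ("T", "T", "T", FlankMatch.BOTH),
            ("T", "G", "C", FlankMatch.NEITHER),
        ],
    )
    def test_single_base(self, distal, proximal, ins, expected):
        t = make_site(distal=distal, proximal=proximal, seed=11)
        o = canonicalize(t, t.cut, t.cut, ins)
        assert insertion_flank_match(t, o) is expected

    def test_dinucleotide_templates_read_outward(self):
        t = make_site(seed=2)
        distal2 = t.sequence[t.cut - 2 : t.cut]
        o = canonicalize(t, t.cut, t.cut, distal2)
        proximal2 = t.sequence[t.cut : t.cut + 2]
        expected = FlankMatch.BOTH if distal2 == proximal2 else FlankMatch.DISTAL_ONLY
        assert insertion_flank_match(t, o) is expected

    def test_rejects_off_cut_and_deletions(self, repeat_free_site):
        t = repeat_free_site
        with pytest.raises(ValueError):
            insertion_flank_match(t, canonicalize(t, t.cut + 3, t.cut + 3, "C"))
        with pytest.raises(ValueError):
            insertion_flank_match(t, canonicalize(t, t.cut - 1, t.cut))


class TestDirectionality:
    def test_examples(self, repeat_free_site):
        t = repeat_free_site
        assert directionality(t, canonicalize(t, t.cut - 1, t.cut)) == 1.0
        assert directionality(t, canonicalize(t, t.cut - 4, t.cut + 4)) == 0.5
        assert directionality(t, canonicalize(t, t.cut - 3, t.cut + 1)) == 0.75
        assert directionality(t, canonicalize(t, t.cut, t.cut + 4)) == 1.0

    def test_invariant_under_recanonicalization(self, site):
        for o in enumerate_outcomes(site):
            if not o.is_pure_deletion:
                continue
            d1 = directionality(site, o)
            o2 = canonicalize(site, o.del_start, o.del_end)
            assert directionality(site, o2) == d1
            left, right = deletion_split(site, o)
            assert left + right == o.del_size

    def test_rejects_insertions(self, site):
        with pytest.raises(ValueError):
            directionality(site, OutcomeSpec(site.cut, site.cut, "A"))


class TestFrame:
    def test_examples(self, repeat_free_site):
        t = repeat_free_site
        assert is_in_frame(canonicalize(t, t.cut - 1, t.cut + 2))
        assert not is_in_frame(canonicalize(t, t.cut, t.cut, "A"))
        assert is_in_frame(canonicalize(t, t.cut - 2, t.cut + 2, "C"))


class TestDescriptorGrammar:
    def test_round_trip_canonical(self, site):
        for o in enumerate_outcomes(site):
            desc = format_descriptor(o)
            assert parse_descriptor(site, desc) == o
            assert format_descriptor(parse_descriptor(site, desc)) == desc

    def test_non_canonical_normalized_on_read(self):
        t = TargetSite("mh", "C" * 26 + "TAGCAGC" + "G" * 46, 13, 33)
        # the two AGC copies sit at 27..30 and 30..33; deleting either is equivalent
        o_left = parse_descriptor(t, "D:27-30")
        o_right = parse_descriptor(t, "D:30-33")
        assert o_left == o_right
        assert o_left.del_start == 27

    @pytest.mark.parametrize("bad", ["", "X:1-2", "D:5", "I:3:", "D:1-2+D:3-4", "I:1:A+I:2:C"])
    def test_malformed_rejected(self, site, bad):
        with pytest.raises(ValueError):
            parse_descriptor(site, bad)

    def test_combined_outcome_gap_must_match(self, site):
        with pytest.raises(ValueError):
            parse_descriptor(site, f"D:{site.cut - 1}-{site.cut}+I:{site.cut}:A")
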