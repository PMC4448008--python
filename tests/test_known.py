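"""Known-miRNA matching, isomiR descriptors, and the naming grammar."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpipe.known import (
    VariantDescriptor,
    annotate_known,
    apply_descriptor,
    classify_match,
    match_to_precursor,
    name_variant,
    PrecursorPlacement,
)
from mirpipe.preprocess import UniqueTag


def _brute_placements(tag, prec):
    out = []
    for start in range(len(prec) - len(tag) + 1):
        mism = [(k, prec[start + k], tag[k]) for k in range(len(tag)) if tag[k] != prec[start + k]]
        if len(mism) <= 1:
            out.append((start, len(mism)))
    return out


class TestMatchToPrecursor:
    def test_exact_substring_placement(self, tiny_reference):
        prec = tiny_reference.precursors[0]
        tag = prec.seq[12:33]
        pls = match_to_precursor(tag, prec.seq)
        assert any(p.start == 12 and p.mismatches == 0 for p in pls)

    def test_single_internal_substitution_recorded(self, tiny_reference):
        prec = tiny_reference.precursors[0]
        tag = list(prec.seq[0:21])
        orig = tag[10]
        tag[10] = {"A": "G", "G": "A", "C": "T", "T": "C"}[tag[10]]
        pls = [p for p in match_to_precursor("".join(tag), prec.seq) if p.start == 0]
        assert pls[0].mismatches == 1
        assert pls[0].substitution == (11, orig, tag[10])

    def test_two_substitutions_rejected(self, tiny_reference):
        prec = tiny_reference.precursors[0]
        tag = list(prec.seq[0:21])
        tag[5] = "A" if tag[5] != "A" else "C"
        tag[15] = "A" if tag[15] != "A" else "C"
        assert all(p.start != 0 for p in match_to_precursor("".join(tag), prec.seq))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        prec = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 121))))
        if rng.random() < 0.5:  # planted with 0-1 mutations
            start = int(rng.integers(0, len(prec) - 21))
            tag = list(prec[start : start + 21])
            if rng.random() < 0.5:
                i = int(rng.integers(21))
                tag[i] = "ACGT"[int(rng.integers(4))]
            tag = "".join(tag)
        else:
            tag = "".join(rng.choice(list("ACGT"), size=21))
        got = sorted((p.start, p.mismatches) for p in match_to_precursor(tag, prec))
        assert got == sorted(_brute_placements(tag, prec))


class TestClassify:
    def test_exact_mature_is_documented_zero_descriptor(self, tiny_reference):
        pl = PrecursorPlacement("syn-MIR1", 0, 0, None)
        kind, arm, desc, mpl = classify_match(
            tiny_reference.matures[0].seq, pl, tiny_reference, "syn-MIR1"
        )
        assert (kind, arm) == ("documented", "5p") and desc.is_zero

    def test_opposite_arm_is_p5p3(self, tiny_reference):
        prec = tiny_reference.precursors[0]
        tag = prec.seq[29:50]  # 3p arm; documented mature is 5p
        pl = PrecursorPlacement("syn-MIR1", 29, 0, None)
        kind, arm, desc, _ = classify_match(tag, pl, tiny_reference, "syn-MIR1")
        assert (kind, arm) == ("p5p3", "3p")

    def test_one_extra_3prime_base_gives_right_plus_1(self, tiny_reference):
        prec = tiny_reference.precursors[0]
        tag = prec.seq[0:22]
        pl = PrecursorPlacement("syn-MIR1", 0, 0, None)
        kind, _, desc, mpl = classify_match(tag, pl, tiny_reference, "syn-MIR1")
        assert kind == "documented"
        assert (desc.left_offset, desc.right_offset) == (0, 1)
        assert name_variant(mpl.mature_id, desc) == "syn-miR1-5p_R+1"


class TestNaming:
    @pytest.mark.parametrize(
        "base,desc,expected",
        [
            ("osa-miR530-5p", VariantDescriptor(0, 1, None), "osa-miR530-5p_R+1"),
            ("bdi-miR156b-5p", VariantDescriptor(1, 0, (15, "T", "G")),
             "bdi-miR156b-5p_L+1_1ss15TG"),
            ("sbi-miR166a", VariantDescriptor(0, 1, (1, "T", "G")),
             "sbi-miR166a_R+1_1ss1TG"),
            ("osa-miR172a", VariantDescriptor(), "osa-miR172a"),
            ("x", VariantDescriptor(-2, 0, None), "x_L-2"),
        ],
    )
    def test_grammar(self, base, desc, expected):
        assert name_variant(base, desc) == expected

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(
        st.integers(-3, 3), st.integers(-3, 3),
        st.one_of(st.none(), st.tuples(st.integers(1, 25),
                                       st.sampled_from("ACGT"), st.sampled_from("ACGT"))),
        st.integers(-3, 3), st.integers(-3, 3),
        st.one_of(st.none(), st.tuples(st.integers(1, 25),
                                       st.sampled_from("ACGT"), st.sampled_from("ACGT"))),
    )
    def test_injective_for_fixed_base(self, l1, r1, s1, l2, r2, s2):
        d1, d2 = VariantDescriptor(l1, r1, s1), VariantDescriptor(l2, r2, s2)
        if d1 != d2:
            assert name_variant("osa-miR1", d1) != name_variant("osa-miR1", d2)


class TestAnnotateKnown:
    def _tags(self, seqs):
        return [UniqueTag(s, np.array([3, 2])) for s in seqs]

    def test_exact_mature_documented_and_descriptor_round_trip(self, tiny_reference):
        prec = tiny_reference.precursors[0]
        tags = self._tags([
            tiny_reference.matures[0].seq,   # exact documented
            prec.seq[1:23],                  # L-1, R+2 variant
            prec.seq[29:50],                 # opposite arm -> p5p3
        ])
        records, unmatched, consumed = annotate_known(tags, tiny_reference)
        assert not unmatched
        by_class = {r.mirna_class for r in records}
        assert by_class == {"documented", "p5p3"}
        for r in records:
            if r.mirna_class == "documented":
                mpl = next(p for p in tiny_reference.placements
                           if p.precursor_id == r.precursor_id and p.arm == r.arm)
                assert apply_descriptor(tiny_reference, mpl, r.descriptor) == r.seq

    def test_zero_mismatch_precursor_preferred(self, tiny_reference):
        # tag equals MIR1[0:21] exactly; also matches a mutated copy of itself
        # on a second precursor with 1 mismatch
        from mirpipe.io import MirnaReference, Placement, SequenceRecord

        m1 = tiny_reference.matures[0].seq
        mut = "G" + m1[1:] if m1[0] != "G" else "C" + m1[1:]
        prec2 = mut + "CTCACAAC" + tiny_reference.precursors[0].seq[29:]
        ref = MirnaReference(
            tiny_reference.precursors + [SequenceRecord("syn-MIR9", prec2)],
            tiny_reference.matures + [SequenceRecord("syn-miR9-5p", mut)],
            tiny_reference.placements + [Placement("syn-miR9-5p", "syn-MIR9", 0, 21, "5p")],
        )
        records, _, _ = annotate_known(self._tags([m1]), ref)
        assert records[0].precursor_id == "syn-MIR1" and records[0].mirna_class == "documented"

    def test_unmatched_tag_forwarded(self, tiny_reference):
        tags = self._tags(["ACACACACACACACACACACA"])
        records, unmatched, _ = annotate_known(tags, tiny_reference)
        assert not records and len(unmatched) == 1
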