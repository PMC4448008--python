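"""Degradome profiles, pairing scores, cleavage positions, and t-plot categories."""

import numpy as np
import pytest

from mirpipe.degradome import (
    DegradomeProfile,
    TranscriptIndex,
    align_mirna_target,
    anchored_score,
    categorize_site,
    cleavage_position,
    find_targets,
    map_degradome,
    penalty_matrix,
    preprocess_degradome,
    tpb,
    DegradomeLibrary,
    _ENC,
)
from mirpipe.io import SequenceRecord, revcomp

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
MIR = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def _reads(seqs):
    return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]


class TestPreprocess:
    def test_length_gate_and_adapter_only(self):
        tags, raw, removed = preprocess_degradome(
            _reads(["ACGTACGTACGTAC" + ADAPTER,   # 14 nt -> removed
                    "ACGTACGTACGTACGTACGT" + ADAPTER,  # 20 nt -> kept
                    ADAPTER]),                     # adapter only -> removed
            ADAPTER,
        )
        assert raw == 3 and removed == 2
        assert tags == {"ACGTACGTACGTACGTACGT": 1}


class TestMapping:
    def test_unique_and_split_weights(self):
        site = "ACGTACGTACGTACGTACGTA"
        t1 = SequenceRecord("T1", "C" * 100 + site + "G" * 100)
        t2 = SequenceRecord("T2", "C" * 50 + site + "G" * 30)
        index = TranscriptIndex([t1, t2])
        lib = map_degradome({site: 1, "TTTTTTTTTTGGGGGGGGGG": 2}, index, "A", 1000)
        assert lib.profiles["T1"].weights[101] == pytest.approx(0.5)
        assert lib.profiles["T2"].weights[51] == pytest.approx(0.5)
        assert lib.profiles["T1"].raw[101] == 1  # raw counts are not split
        assert lib.unmapped_reads == 2 and lib.mapped_reads == 1


class TestAlignmentScore:
    def test_perfect_complement_scores_zero(self):
        window = "CCCC" + revcomp(MIR) + "GGGG"
        al = align_mirna_target(MIR, window)
        assert al.score == 0.0 and al.pairing == "|" * 21

    def test_gu_outside_core_scores_half(self):
        # miRNA position 15 is G (pairs C); give the transcript T -> G:U wobble
        assert MIR[14] == "G"
        site = list(revcomp(MIR))
        site[21 - 15] = "T"
        al = align_mirna_target(MIR, "CCCC" + "".join(site) + "GGGG")
        assert al.score == 0.5 and al.pairing.count("o") == 1

    def test_mismatch_in_core_scores_two(self):
        site = list(revcomp(MIR))
        site[21 - 5] = MIR[4]  # identity base: mismatch at miRNA position 5
        al = align_mirna_target(MIR, "CCCC" + "".join(site) + "GGGG")
        assert al.score == 2.0

    def test_three_core_mismatches_fail_score_gate(self):
        site = list(revcomp(MIR))
        for pos in (3, 6, 9):
            site[21 - pos] = MIR[pos - 1]
        al = align_mirna_target(MIR, "CCCC" + "".join(site) + "GGGG")
        assert al.score == 6.0

    def test_single_bulge_rescues_frameshifted_site(self):
        # transcript carries an extra base inside the complementary site
        site = revcomp(MIR)
        window = "CCCC" + site[:6] + "A" + site[6:] + "GGGG"
        al = align_mirna_target(MIR, window)
        assert al.config[0] == "tbulge"
        assert al.score <= 2.0

    def test_equals_brute_force_scorer_on_random_pairs(self):
        """Independent enumeration of every <=1-bulge duplex placement."""
        rng = np.random.default_rng(1234)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

        def pen(m, t, pos):
            if t is None:
                base = 1.0
            elif t == comp[m]:
                base = 0.0
            elif (m, t) in (("G", "T"), ("T", "G")):
                base = 0.5
            else:
                base = 1.0
            return base * (2.0 if 2 <= pos <= 13 else 1.0)

        def brute(mir, win):
            L, n = len(mir), len(win)
            best = np.inf
            # anchor = 0-based t index facing miRNA position 1, constrained so
            # that position 10 faces a real window position
            for anchor in range(9, n + 9):
                # no bulge
                s = sum(
                    pen(mir[i - 1], win[anchor - (i - 1)] if 0 <= anchor - (i - 1) < n else "X", i)
                    for i in range(1, L + 1)
                )
                best = min(best, s)
                # miRNA bulge at k (not position 10)
                for k in range(1, L + 1):
                    if k == 10:
                        continue
                    s = 0.0
                    t = anchor
                    for i in range(1, L + 1):
                        if i == k:
                            s += pen(mir[i - 1], None, i)
                            continue
                        s += pen(mir[i - 1], win[t] if 0 <= t < n else "X", i)
                        t -= 1
                    best = min(best, s)
                # transcript bulge between k and k+1
                for k in range(1, L):
                    s = 0.0
                    t = anchor
                    for i in range(1, L + 1):
                        s += pen(mir[i - 1], win[t] if 0 <= t < n else "X", i)
                        t -= 1
                        if i == k:
                            s += 1.0 * (2.0 if 2 <= k + 1 <= 13 else 1.0)
                            t -= 1
                    best = min(best, s)
            return best

        for trial in range(60):
            mir = "".join(rng.choice(list("ACGT"), size=21))
            if trial % 2 == 0:
                win = "".join(rng.choice(list("ACGT"), size=30))
            else:  # seeded with a mutated complementary site
                site = list(revcomp(mir))
                for _ in range(int(rng.integers(0, 4))):
                    j = int(rng.integers(21))
                    site[j] = "ACGT"[int(rng.integers(4))]
                win = "CCCC" + "".join(site) + "GGGGG"
            got = align_mirna_target(mir, win).score
            assert got == pytest.approx(brute(mir, win), abs=1e-9), (mir, win)


class TestCleavagePosition:
    def test_coordinate_arithmetic_on_constructed_duplex(self):
        # place a perfect site so miRNA position 1 pairs transcript position 630
        t = ["C"] * 700
        site = revcomp(MIR)  # occupies 1-based positions 610..630
        t[609:630] = list(site)
        transcript = "".join(t)
        mir_enc = np.array([_ENC[c] for c in MIR], dtype=np.int8)
        t_enc = np.array([_ENC[c] for c in transcript], dtype=np.int8)
        score, config = anchored_score(mir_enc, penalty_matrix(MIR), t_enc, 621)
        assert score == 0.0 and config == ("none",)

    def test_translation_equivariance(self):
        for shift in (0, 1, 5):
            window = "C" * (4 + shift) + revcomp(MIR) + "G" * 4
            al = align_mirna_target(MIR, window)
            assert cleavage_position(al) == 16 + shift  # pos10 pairs site start + 11


class TestCategories:
    def _profile(self, raw):
        prof = DegradomeProfile("T", 500)
        for pos, n in raw.items():
            prof.add(pos, n, 1.0)
        return prof

    @pytest.mark.parametrize(
        "raw,site,expected",
        [
            ({100: 5}, 100, 0),                           # unique maximum
            ({100: 1, 200: 10}, 100, 4),                  # single raw read
            ({100: 3, 200: 10, 300: 1, 400: 1}, 100, 2),  # < max, > median (median 2)
            ({100: 7, 200: 7}, 100, 1),                   # two maxima
            ({100: 2, 200: 10, 300: 4}, 100, 3),          # <= median (median 4)
            ({200: 10}, 100, None),                       # absent
        ],
    )
    def test_spec_examples(self, raw, site, expected):
        assert categorize_site(self._profile(raw), site) == expected

    def test_every_supported_site_gets_exactly_one_category(self):
        # exhaustive over small profiles (acceptance suite runs the full grid)
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    prof = self._profile({p: n for p, n in zip((1, 2, 3), (a, b, c)) if n})
                    for pos, n in ((1, a), (2, b), (3, c)):
                        cat = categorize_site(prof, pos) if n else None
                        if n >= 1:
                            assert cat in (0, 1, 2, 3, 4)

    def test_doubling_raw_counts_preserves_categories_above_one_read(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            raw = {int(p): int(n) for p, n in
                   zip(rng.integers(1, 400, size=6), rng.integers(2, 9, size=6))}
            prof1 = self._profile(raw)
            prof2 = self._profile({p: 2 * n for p, n in raw.items()})
            for pos in raw:
                assert categorize_site(prof1, pos) == categorize_site(prof2, pos)


class TestTpb:
    def test_worked_examples(self):
        assert round(tpb(1.0, 8_853_077), 2) == 112.96
        assert round(tpb(1.0, 15_733_668), 2) == 63.56
        assert round(tpb(0.5, 8_853_077), 2) == 56.48
        assert tpb(0.0, 123) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpb(1.0, 0)


class TestFindTargets:
    def _setup(self, site_mutator=None, peak=3):
        site = list(revcomp(MIR))
        if site_mutator:
            site_mutator(site)
        seq = "C" * 100 + "".join(site) + "G" * 100
        transcript = SequenceRecord("T1", seq)
        cleavage = 100 + (21 - 10) + 1
        lib = DegradomeLibrary("A", 1_000_000)
        prof = DegradomeProfile("T1", len(seq))
        if peak:
            prof.add(cleavage, peak, 1.0)
        lib.profiles["T1"] = prof
        return transcript, lib, cleavage

    def test_planted_duplex_and_peak_reported_once(self):
        transcript, lib, cleavage = self._setup()
        hits = find_targets([("m1", MIR)], [lib], [transcript])
        assert len(hits) == 1
        h = hits[0]
        assert (h.transcript_id, h.cleavage_site, h.score) == ("T1", cleavage, 0.0)
        assert h.category["A"] == 0
        assert h.tpb["A"] == pytest.approx(3 * 1e9 / 1_000_000, abs=0.01)

    def test_no_reads_at_site_no_hit(self):
        transcript, lib, _ = self._setup(peak=0)
        assert find_targets([("m1", MIR)], [lib], [transcript]) == []

    def test_score_above_gate_not_reported(self):
        def spoil(site):  # 2 core + 1 non-core mismatch = 5.0
            for pos in (3, 6, 16):
                site[21 - pos] = MIR[pos - 1]
        transcript, lib, _ = self._setup(site_mutator=spoil)
        assert find_targets([("m1", MIR)], [lib], [transcript]) == []
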