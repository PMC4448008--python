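"""Generator guarantees: determinism, planted hairpins/decoys, read accounting."""

import json

import numpy as np
import pytest

from mirpipe.fold import fold
from mirpipe.hairpin import CRITERIA_ORDER, evaluate_hairpin
from mirpipe.io import read_fastq
from mirpipe.preprocess import is_junk
from mirpipe.simulate import (
    DECOY_PLANS,
    SimConfig,
    build_dataset,
    design_decoy,
    design_hairpin,
    make_genome,
    make_reference,
    plant_mir_loci,
)

SMALL = dict(
    genome_length=50_000, n_known=10, n_novel=6, n_decoy=11,
    srna_depth=20_000, degradome_depth=20_000, n_sirna_loci=30,
    n_targets=6, n_decoy_targets=2, n_decoy_transcripts=4,
)


class TestGenome:
    def test_deterministic_per_seed(self):
        assert make_genome(5, 10_000).seq == make_genome(5, 10_000).seq
        assert make_genome(5, 10_000).seq != make_genome(6, 10_000).seq

    def test_gc_fraction_within_binomial_bound(self):
        g = make_genome(1, 100_000, gc_fraction=0.5)
        gc = (g.seq.count("G") + g.seq.count("C")) / len(g.seq)
        assert abs(gc - 0.5) < 0.01

    def test_gc_zero_gives_at_only(self):
        g = make_genome(2, 10_000, gc_fraction=0.0)
        assert set(g.seq) <= {"A", "T"}


class TestDesigns:
    def test_designed_hairpin_passes_all_criteria_on_both_arms(self):
        rng = np.random.default_rng(17)
        for arm in ("5p", "3p"):
            seq, (ms, me) = design_hairpin(rng, arm=arm)
            pf = fold(seq)
            pf.mature_span = (ms, me)
            assert evaluate_hairpin(pf).overall
            assert not is_junk(seq[ms:me])[0]

    def test_forced_first_base(self):
        rng = np.random.default_rng(23)
        seq, (ms, _) = design_hairpin(rng, mature_first_base="A")
        assert seq[ms] == "A"

    @pytest.mark.parametrize("criterion", list(DECOY_PLANS))
    def test_decoy_fails_exactly_its_criterion(self, criterion):
        rng = np.random.default_rng(31)
        seq, span = design_decoy(rng, criterion)
        pf = fold(seq)
        pf.mature_span = span
        ev = evaluate_hairpin(pf)
        assert ev.failed() == [criterion]


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(41)
    ref = make_reference(rng, 8)
    cfg = SimConfig(**{**SMALL, "n_known": 8})
    genome = make_genome(77, cfg.genome_length)
    return plant_mir_loci(genome, ref, cfg, rng)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    truth = build_dataset(SimConfig(seed=3, **SMALL), out)
    return out, truth


class TestPlanting:

    def test_loci_do_not_overlap(self, planted):
        _, truth = planted
        spans = sorted((l.start, l.end) for l in truth.loci)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_planted_sequences_retrievable_at_coordinates(self, planted):
        genome, truth = planted
        for l in truth.loci:
            assert genome.seq[l.start : l.end] == l.precursor_seq
            assert genome.seq[l.mature_start : l.mature_end] == l.mature_seq

    def test_one_decoy_per_criterion_each_failing_it(self, planted):
        _, truth = planted
        decoys = [l for l in truth.loci if l.kind == "decoy"]
        assert sorted(l.criterion for l in decoys) == sorted(CRITERIA_ORDER)
        for l in decoys:
            pf = fold(l.precursor_seq)
            pf.mature_span = (l.mature_start - l.start, l.mature_end - l.start)
            assert evaluate_hairpin(pf).failed() == [l.criterion]


class TestDataset:
    def test_manifest_totals_equal_fastq_record_counts(self, dataset):
        out, truth = dataset
        for lib in ("A", "B"):
            n = sum(1 for _ in read_fastq(out / f"srna_{lib}.fastq"))
            assert n == truth.srna_read_totals[lib] == truth.config.srna_depth
            nd = sum(1 for _ in read_fastq(out / f"degradome_{lib}.fastq"))
            assert nd == truth.degradome_read_totals[lib]

    def test_truth_manifest_is_valid_json(self, dataset):
        out, truth = dataset
        tj = json.loads((out / "truth.json").read_text())
        assert len(tj["loci"]) == len(truth.loci)
        assert {l["kind"] for l in tj["loci"]} == {"known", "novel", "decoy"}

    def test_full_determinism_across_rebuilds(self, dataset, tmp_path):
        out, _ = dataset
        build_dataset(SimConfig(seed=3, **SMALL), tmp_path / "again")
        for name in ("genome.fa", "srna_A.fastq", "degradome_B.fastq", "truth.json"):
            assert (tmp_path / "again" / name).read_bytes() == (out / name).read_bytes()

    def test_planted_degradome_peaks_present(self, dataset):
        out, truth = dataset
        from mirpipe.degradome import TranscriptIndex, map_degradome, preprocess_degradome
        from mirpipe.io import read_fasta

        transcripts = read_fasta(out / "transcriptome.fa")
        index = TranscriptIndex(transcripts)
        tags, raw, removed = preprocess_degradome(
            read_fastq(out / "degradome_A.fastq"), truth.config.adapter
        )
        assert removed >= int(truth.config.degradome_depth * truth.config.deg_short_fraction)
        lib = map_degradome(tags, index, "A", raw)
        for tgt in truth.targets:
            if tgt.peak_a >= 1:
                prof = lib.profiles[tgt.transcript_id]
                assert prof.raw.get(tgt.cleavage_site, 0) >= tgt.peak_a
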