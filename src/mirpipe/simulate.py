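"""Synthetic two-condition sRNA + degradome datasets with planted truth.

The generator emulates the statistical structure of a two-library plant
small-RNA experiment: a random genome carrying planted MIR hairpin loci
(copies of a bundled-style reference for "known" miRNAs, de-novo designed
hairpins satisfying all 11 criteria for "novel" ones, and decoy loci each
violating exactly one named criterion), two sequencing libraries with
21/24-nt size peaks, 5'-nucleotide bias (U-rich known, A-rich novel
matures), isomiR end variation and substitution errors, junk reads
triggering every junk rule, annotation-excludable fragments, and planted
fold-change effects between the libraries; plus a transcriptome carrying
miRNA complementary sites at controlled pairing scores and two degradome
libraries with read peaks at the planted cleavage positions over a uniform
degradation background. A machine-readable truth manifest records every
planted fact so each pipeline stage can be scored without external data.

One master seed fixes every output byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .degradome import penalty_matrix, _ENC as _DEG_ENC
from .fold import PrecursorFold, fold
from .hairpin import CRITERIA_ORDER, HairpinCriteria, evaluate_hairpin
from .io import MirnaReference, Placement, SequenceRecord, revcomp, write_fasta, write_fastq
from .preprocess import is_junk

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "make_genome",
    "design_hairpin",
    "design_decoy",
    "make_reference",
    "build_dataset",
    "simulate_srna_libraries",
    "simulate_degradome",
    "DECOY_PLANS",
]

_BASES = np.array(list("ACGT"))
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the shipped study conditions."""

    seed: int = 1
    genome_length: int = 200_000
    gc_fraction: float = 0.44
    n_known: int = 60
    n_novel: int = 30
    n_decoy: int = 11
    srna_depth: int = 200_000
    degradome_depth: int = 200_000
    de_fraction: float = 0.2
    fold_effect: float = 4.0
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    isomir_rate: float = 0.12
    error_rate: float = 0.02
    star_ratio: float = 0.15  # star-arm expression relative to the mature
    # background composition of the sRNA libraries (fractions of depth)
    junk_fraction: float = 0.04
    no_insert_fraction: float = 0.02
    excluded_fraction: float = 0.10
    sirna_fraction: float = 0.28
    singleton_fraction: float = 0.015
    n_sirna_loci: int = 250
    # degradome
    n_targets: int = 24
    n_decoy_targets: int = 6
    n_decoy_transcripts: int = 20
    transcript_length: int = 600
    deg_background_rate: float = 0.30
    deg_short_fraction: float = 0.02
    peak_heights: tuple = (1, 3, 5, 8)


# ---------------------------------------------------------------------------
# hairpin design


@dataclass
class _Segment:
    kind: str  # pair | bulge5 | bulge3 | int | loop
    n: int = 0
    n3: int = 0
    style: str = "mixed"  # pair style: mixed | strong | weak
    mature: bool = False
    mature_ext: int = 0  # nt of the loop start belonging to the mature


def _pair_for(style: str, rng: np.random.Generator, first_base: str | None = None) -> tuple[str, str]:
    if first_base is not None:
        return first_base, _WC[first_base]
    if style == "strong":
        return ("G", "C") if rng.random() < 0.5 else ("C", "G")
    if style == "weak":  # G:U wobble
        return ("G", "T") if rng.random() < 0.5 else ("T", "G")
    a = str(rng.choice(_BASES))
    return a, _WC[a]


def _filler(n: int, rng: np.random.Generator) -> str:
    # A/C filler cannot pair with itself (no T/G): inert in loops and bulges
    return "".join(rng.choice(["A", "C"], size=n))


def build_hairpin(
    plan: Sequence[_Segment], rng: np.random.Generator, mature_first_base: str | None = None
) -> tuple[str, tuple[int, int]]:
    """Assemble a precursor sequence from a structural plan.

    The mature spans the 5'-arm positions of segments flagged ``mature``
    (plus ``mature_ext`` nt into the loop). Returns (sequence, mature span).
    """
    five: list[str] = []
    three_rev: list[str] = []  # per-segment 3'-side strings, innermost last
    mature_ranges: list[tuple[int, int]] = []
    pos5 = 0
    loop_seq = ""
    loop_ext = 0
    first_mature = True
    for seg in plan:
        if seg.kind == "pair":
            s5 = []
            s3 = []
            for k in range(seg.n):
                force = None
                if seg.mature and first_mature and k == 0 and mature_first_base:
                    force = mature_first_base
                a, b = _pair_for(seg.style, rng, force)
                s5.append(a)
                s3.append(b)
            five.append("".join(s5))
            three_rev.append("".join(reversed(s3)))
            if seg.mature:
                mature_ranges.append((pos5, pos5 + seg.n))
                first_mature = False
            pos5 += seg.n
        elif seg.kind == "bulge5":
            s = _filler(seg.n, rng)
            five.append(s)
            three_rev.append("")
            if seg.mature:
                mature_ranges.append((pos5, pos5 + seg.n))
            pos5 += seg.n
        elif seg.kind == "bulge3":
            five.append("")
            three_rev.append(_filler(seg.n, rng))
        elif seg.kind == "int":
            s = _filler(seg.n, rng)
            five.append(s)
            three_rev.append(_filler(seg.n3, rng))
            if seg.mature:
                mature_ranges.append((pos5, pos5 + seg.n))
            pos5 += seg.n
        elif seg.kind == "loop":
            loop_seq = _filler(seg.n, rng)
            loop_ext = seg.mature_ext
        else:
            raise ValueError(f"unknown segment kind {seg.kind!r}")
    seq = "".join(five) + loop_seq + "".join(reversed(three_rev))
    if not mature_ranges:
        raise ValueError("plan marks no mature segment")
    ms = mature_ranges[0][0]
    me = mature_ranges[-1][1] + loop_ext if loop_ext else mature_ranges[-1][1]
    # mature segments must be contiguous
    for (a, b), (c, d) in zip(mature_ranges, mature_ranges[1:]):
        if b != c:
            raise ValueError("mature segments are not contiguous")
    return seq, (ms, me)


def _canonical_plan(rng: np.random.Generator, mature_len: int = 21) -> list[_Segment]:
    outer = int(rng.integers(2, 5))
    loop = int(rng.integers(8, 13))
    return [
        _Segment("pair", outer),
        _Segment("pair", mature_len, mature=True),
        _Segment("loop", loop),
    ]


DECOY_PLANS: dict[str, list[_Segment]] = {
    "max_stem_bulge": [
        _Segment("pair", 6), _Segment("bulge5", 13),
        _Segment("pair", 21, mature=True), _Segment("loop", 8),
    ],
    "stem_pairs": [
        _Segment("pair", 15, style="strong", mature=True),
        _Segment("loop", 20, mature_ext=2),
    ],
    "energy": [
        _Segment("pair", 16, style="weak", mature=True),
        _Segment("loop", 18, mature_ext=1),
    ],
    "hairpin_len": [
        _Segment("pair", 16, style="strong", mature=True),
        _Segment("loop", 3, mature_ext=1),
    ],
    "loop_len": [
        _Segment("pair", 17, style="strong", mature=True),
        _Segment("loop", 201),
    ],
    "max_mature_bulge": [
        _Segment("pair", 8, mature=True), _Segment("int", 3, 2, mature=True),
        _Segment("pair", 10, mature=True), _Segment("pair", 3), _Segment("loop", 8),
    ],
    "max_biased_errors_in_bulge": [
        _Segment("pair", 8, mature=True), _Segment("bulge5", 3, mature=True),
        _Segment("pair", 10, mature=True), _Segment("pair", 3), _Segment("loop", 8),
    ],
    "biased_bulges_mature": [
        _Segment("pair", 5, mature=True), _Segment("bulge5", 1, mature=True),
        _Segment("pair", 5, mature=True), _Segment("bulge5", 1, mature=True),
        _Segment("pair", 5, mature=True), _Segment("bulge5", 1, mature=True),
        _Segment("pair", 3, mature=True), _Segment("pair", 5), _Segment("loop", 8),
    ],
    "mature_errors": [
        _Segment("pair", 4, mature=True), _Segment("int", 1, 1, mature=True),
        _Segment("pair", 4, mature=True), _Segment("int", 1, 1, mature=True),
        _Segment("pair", 3, mature=True), _Segment("int", 1, 1, mature=True),
        _Segment("pair", 3, mature=True), _Segment("int", 1, 1, mature=True),
        _Segment("pair", 2, mature=True), _Segment("int", 1, 1, mature=True),
        _Segment("pair", 5), _Segment("loop", 8),
    ],
    "mature_pairs": [
        _Segment("pair", 8), _Segment("pair", 4, mature=True),
        _Segment("int", 2, 2, mature=True), _Segment("pair", 3, mature=True),
        _Segment("int", 2, 2, mature=True), _Segment("pair", 3, mature=True),
        _Segment("loop", 8, mature_ext=3),
    ],
    "pct_mature_in_stem": [
        _Segment("pair", 4), _Segment("pair", 16, mature=True),
        _Segment("loop", 12, mature_ext=5),
    ],
}


def design_hairpin(
    rng: np.random.Generator,
    mature_len: int = 21,
    arm: str = "5p",
    mature_first_base: str | None = None,
    criteria: HairpinCriteria = HairpinCriteria(),
    max_tries: int = 200,
) -> tuple[str, tuple[int, int]]:
    """Design a precursor whose fold passes all 11 criteria.

    The mature sits on *arm*; for 3p the 5p design is reverse-complemented
    (plans use Watson-Crick pairs only, which survive that mirror).
    Sequence draws are rejected until the shipped folder reproduces a
    passing structure and the mature is not junk-like.
    """
    for _ in range(max_tries):
        seq, (ms, me) = build_hairpin(_canonical_plan(rng, mature_len), rng, mature_first_base)
        if arm == "3p":
            seq = revcomp(seq)
            ms, me = len(seq) - me, len(seq) - ms
        mature = seq[ms:me]
        if is_junk(mature)[0]:
            continue
        pf = fold(seq)
        pf.mature_span = (ms, me)
        if evaluate_hairpin(pf, criteria).overall:
            return seq, (ms, me)
    raise RuntimeError("failed to design a passing hairpin")


def design_decoy(
    rng: np.random.Generator,
    criterion: str,
    criteria: HairpinCriteria = HairpinCriteria(),
    max_tries: int = 500,
) -> tuple[str, tuple[int, int]]:
    """Design a precursor whose fold fails exactly the named criterion."""
    plan = DECOY_PLANS[criterion]
    for _ in range(max_tries):
        seq, span = build_hairpin(plan, rng)
        if is_junk(seq[span[0] : span[1]])[0]:
            continue
        pf = fold(seq)
        pf.mature_span = span
        ev = evaluate_hairpin(pf, criteria)
        if ev.is_hairpin and ev.failed() == [criterion]:
            return seq, span
    raise RuntimeError(f"failed to design a decoy for criterion {criterion!r}")


# ---------------------------------------------------------------------------
# genome, reference, loci


def make_genome(seed: int, length: int, gc_fraction: float = 0.44) -> SequenceRecord:
    """I.i.d. random chromosome at the requested GC content."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10,000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return SequenceRecord("chr1", seq)


def make_reference(
    rng: np.random.Generator, n: int, prefix: str = "syn", start_index: int = 101
) -> MirnaReference:
    """A synthetic miRBase-style reference of designed hairpin precursors."""
    precursors, matures, placements = [], [], []
    for i in range(n):
        arm = "5p" if rng.random() < 0.6 else "3p"
        first = "T" if rng.random() < 0.7 else None  # known matures biased to 5'-U
        mlen = int(rng.choice([20, 21, 21, 21, 22]))
        seq, (ms, me) = design_hairpin(rng, mlen, arm, first)
        pid = f"{prefix}-MIR{start_index + i}"
        mid = f"{prefix}-miR{start_index + i}-{arm}"
        precursors.append(SequenceRecord(pid, seq))
        matures.append(SequenceRecord(mid, seq[ms:me]))
        placements.append(Placement(mid, pid, ms, me, arm))
    return MirnaReference(precursors, matures, placements)


@dataclass
class PlantedLocus:
    """One planted MIR locus on the synthetic genome (always + strand)."""

    name: str
    kind: str  # known | novel | decoy
    chrom: str
    start: int
    end: int
    precursor_seq: str
    mature_seq: str
    mature_start: int  # genome coords
    mature_end: int
    arm: str
    criterion: str | None = None  # decoys: the designated failing criterion


@dataclass
class SimSpecies:
    """One expressed small-RNA species with its planted expression model."""

    name: str
    seq: str
    kind: str  # known_mature | star | novel | decoy_mature
    locus: str
    weight_a: float
    weight_b: float
    de_label: str  # none | up-in-B | down-in-B
    expected_a: float = 0.0
    expected_b: float = 0.0
    realized_a: int = 0  # exact-sequence (canonical) reads emitted
    realized_b: int = 0


@dataclass
class PlantedTarget:
    """A planted miRNA cleavage site on a synthetic transcript."""

    mirna_name: str
    mirna_seq: str
    transcript_id: str
    cleavage_site: int  # 1-based, pairs miRNA position 10
    score: float
    peak_a: int
    peak_b: int
    decoy: bool = False


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream scoring."""

    config: SimConfig
    loci: list[PlantedLocus] = field(default_factory=list)
    species: list[SimSpecies] = field(default_factory=list)
    targets: list[PlantedTarget] = field(default_factory=list)
    srna_read_totals: dict = field(default_factory=dict)
    degradome_read_totals: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {
            "config": asdict(self.config),
            "loci": [asdict(x) for x in self.loci],
            "species": [asdict(x) for x in self.species],
            "targets": [asdict(x) for x in self.targets],
            "srna_read_totals": self.srna_read_totals,
            "degradome_read_totals": self.degradome_read_totals,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def plant_mir_loci(
    genome: SequenceRecord,
    reference: MirnaReference,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Insert known/novel/decoy loci into the genome, validated in context.

    Novel loci must pass all 11 criteria when folded exactly as the
    pipeline will fold them (flanking windows 20/200 and 200/20 around the
    mature); decoys must fail, with their designated criterion failing on
    the standalone precursor fold. Loci never overlap.
    """
    truth = SyntheticTruth(config)
    g = list(genome.seq)
    n_loci = config.n_known + config.n_novel + config.n_decoy
    spacing = len(g) // (n_loci + 1)
    if spacing < 700:
        raise ValueError("genome too small for the requested number of loci")
    slots = [(i + 1) * spacing for i in range(n_loci)]
    rng.shuffle(slots)
    si = 0

    def insert(seq: str, slot: int) -> int:
        start = slot + int(rng.integers(0, 50))
        g[start : start + len(seq)] = list(seq)
        return start

    # known loci: copies of reference precursors
    known_n = min(config.n_known, len(reference.precursors))
    for i in range(known_n):
        prec = reference.precursors[i]
        pl = reference.placements_on(prec.id)[0]
        start = insert(prec.seq, slots[si]); si += 1
        truth.loci.append(PlantedLocus(
            prec.id, "known", genome.id, start, start + len(prec.seq), prec.seq,
            prec.seq[pl.start : pl.end], start + pl.start, start + pl.end, pl.arm,
        ))

    def _site_passes(chrom: str, s: int, e: int, strand: str) -> bool:
        for up, down in ((20, 200), (200, 20)):
            if strand == "+":
                lo, hi = max(0, s - up), min(len(chrom), e + down)
                window = chrom[lo:hi]
                ms = s - lo
            else:
                lo, hi = max(0, s - down), min(len(chrom), e + up)
                window = revcomp(chrom[lo:hi])
                ms = hi - e
            pf = fold(window)
            pf.mature_span = (ms, ms + (e - s))
            if evaluate_hairpin(pf).overall:
                return True
        return False

    def recoverable(mature: str) -> bool:
        """Mimic the prediction stage: scan every genome occurrence of the
        mature (both strands) in coordinate order with locus absorption;
        True iff some unabsorbed occurrence folds into a passing hairpin."""
        chrom = "".join(g)
        occ: list[tuple[int, int, str]] = []
        for strand, q in (("+", mature), ("-", revcomp(mature))):
            pos = chrom.find(q)
            while pos != -1:
                occ.append((pos, pos + len(q), strand))
                pos = chrom.find(q, pos + 1)
        occ.sort()
        claimed: dict[str, list[int]] = {"+": [], "-": []}
        for s, e, strand in occ:
            center = (s + e) // 2
            if any(abs(center - c) <= 220 for c in claimed[strand]):
                continue
            claimed[strand].append(center)
            if _site_passes(chrom, s, e, strand):
                return True
        return False

    # novel loci: designed hairpins, validated through the pipeline windows
    for i in range(config.n_novel):
        slot = slots[si]; si += 1
        for _ in range(60):
            mlen = int(rng.choice([24, 24, 24, 21, 21, 22], p=[0.45, 0.15, 0.12, 0.14, 0.1, 0.04]))
            arm = "5p" if rng.random() < 0.5 else "3p"
            first = "A" if rng.random() < 0.65 else None  # novel matures biased to 5'-A
            seq, (ms, me) = design_hairpin(rng, mlen, arm, first)
            saved = g[slot : slot + len(seq) + 60]
            start = insert(seq, slot)
            if recoverable(seq[ms:me]):
                truth.loci.append(PlantedLocus(
                    f"novel-{i + 1}", "novel", genome.id, start, start + len(seq), seq,
                    seq[ms:me], start + ms, start + me, arm,
                ))
                break
            g[slot : slot + len(saved)] = saved
        else:
            raise RuntimeError("could not place a validated novel locus")

    # decoy loci: one per criterion, cycling
    crits = list(DECOY_PLANS)
    for i in range(config.n_decoy):
        crit = crits[i % len(crits)]
        slot = slots[si]; si += 1
        for _ in range(60):
            seq, (ms, me) = design_decoy(rng, crit)
            saved = g[slot : slot + len(seq) + 60]
            start = insert(seq, slot)
            if not recoverable(seq[ms:me]):
                truth.loci.append(PlantedLocus(
                    f"decoy-{i + 1}", "decoy", genome.id, start, start + len(seq), seq,
                    seq[ms:me], start + ms, start + me, "5p", criterion=crit,
                ))
                break
            g[slot : slot + len(saved)] = saved
        else:
            raise RuntimeError(f"could not place a decoy locus for {crit!r}")

    return SequenceRecord(genome.id, "".join(g)), truth


# ---------------------------------------------------------------------------
# sRNA library simulation


def _assign_expression(truth: SyntheticTruth, rng: np.random.Generator) -> None:
    cfg = truth.config
    species: list[SimSpecies] = []
    de_pool: list[SimSpecies] = []
    for locus in truth.loci:
        if locus.kind == "known":
            base = float(rng.lognormal(mean=np.log(30.0), sigma=1.1))
        else:
            # novel (and decoy) loci sit an order of magnitude lower,
            # mirroring the low expression of recently evolved MIR genes
            base = float(rng.lognormal(mean=np.log(3.0), sigma=1.0))
        if locus.kind == "decoy":
            base = max(base, 1.5)  # decoys must reach prediction, so keep them expressed
        sp = SimSpecies(locus.name, locus.mature_seq, {
            "known": "known_mature", "novel": "novel", "decoy": "decoy_mature"
        }[locus.kind], locus.name, base, base, "none")
        species.append(sp)
        if locus.kind in ("known", "novel"):
            de_pool.append(sp)
    rng.shuffle(de_pool)
    n_de = int(round(len(de_pool) * cfg.de_fraction))
    for j, sp in enumerate(de_pool[:n_de]):
        if j % 2 == 0:
            sp.weight_b = sp.weight_a * cfg.fold_effect
            sp.de_label = "up-in-B"
        else:
            sp.weight_b = sp.weight_a / cfg.fold_effect
            sp.de_label = "down-in-B"
    # star species share their precursor's transcription, so they inherit
    # the mature's fold effect
    for locus in truth.loci:
        if locus.kind != "known":
            continue
        sp = next(s for s in species if s.locus == locus.name)
        species.append(SimSpecies(
            locus.name + "*", revcomp(locus.mature_seq), "star", locus.name,
            sp.weight_a * cfg.star_ratio, sp.weight_b * cfg.star_ratio, sp.de_label))
    truth.species = species


def _junk_read(rng: np.random.Generator, i: int) -> str:
    kind = i % 5
    rand = lambda n: "".join(rng.choice(_BASES, size=n))
    if kind == 0:
        return rand(6) + "A" * 7 + rand(7)
    if kind == 1:
        return rand(5) + "C" * 8 + rand(6)
    if kind == 2:
        return rand(7) + "G" * 6 + rand(7)
    if kind == 3:
        return rand(6) + "T" * 7 + rand(6)
    return rand(8) + "NNN" + rand(8)


def simulate_srna_libraries(
    truth: SyntheticTruth,
    genome: SequenceRecord,
    exclusion_sets: dict[str, list[SequenceRecord]],
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Emit the two sRNA read sets (inserts + adapter), updating the truth.

    Reads are drawn multinomially per library over miRNA species and
    background pools; miRNA reads carry configurable isomiR end variation
    and single-substitution errors, using genomic context for extensions.
    """
    cfg = truth.config
    _assign_expression(truth, rng)
    loci = {l.name: l for l in truth.loci}
    gseq = genome.seq

    # background pools
    sirna_pool = []
    for _ in range(cfg.n_sirna_loci):
        while True:
            pos = int(rng.integers(0, len(gseq) - 24))
            s = gseq[pos : pos + 24]
            if "N" not in s and not is_junk(s)[0]:
                sirna_pool.append(s)
                break
    sirna_w = rng.lognormal(np.log(3.0), 1.0, size=cfg.n_sirna_loci)
    excl_seqs = [s for seqs in exclusion_sets.values() for s in seqs]

    mirna_total = sum(sp.weight_a for sp in truth.species)
    bg_frac = (cfg.junk_fraction + cfg.no_insert_fraction + cfg.excluded_fraction
               + cfg.sirna_fraction + cfg.singleton_fraction)
    mirna_frac = 1.0 - bg_frac

    libs_reads: list[list[SequenceRecord]] = []
    for lib_i, lib in enumerate(("A", "B")):
        weights = []
        emitters = []
        for sp in truth.species:
            w = sp.weight_a if lib_i == 0 else sp.weight_b
            weights.append(mirna_frac * w / mirna_total)
            emitters.append(("species", sp))
        for s, w in zip(sirna_pool, sirna_w):
            weights.append(cfg.sirna_fraction * w / sirna_w.sum())
            emitters.append(("fixed", s))
        weights += [cfg.junk_fraction, cfg.no_insert_fraction,
                    cfg.excluded_fraction, cfg.singleton_fraction]
        emitters += [("junk", None), ("no_insert", None), ("excl", None), ("singleton", None)]
        p = np.array(weights)
        p = p / p.sum()
        counts = rng.multinomial(cfg.srna_depth, p)
        reads: list[str] = []
        for (kind, payload), n in zip(emitters, counts):
            if n == 0:
                continue
            if kind == "fixed":
                reads.extend([payload] * n)
            elif kind == "species":
                reads.extend(_emit_species(payload, n, lib_i, loci, gseq, cfg, rng))
            elif kind == "junk":
                reads.extend(_junk_read(rng, i) for i in range(n))
            elif kind == "no_insert":
                reads.extend([""] * n)
            elif kind == "excl":
                for _ in range(n):
                    src = excl_seqs[int(rng.integers(len(excl_seqs)))]
                    ln = int(rng.integers(18, 25))
                    pos = int(rng.integers(0, max(1, len(src.seq) - ln)))
                    reads.append(src.seq[pos : pos + ln])
            else:  # singleton genomic fragments
                for _ in range(n):
                    ln = int(rng.integers(20, 25))
                    pos = int(rng.integers(0, len(gseq) - ln))
                    reads.append(gseq[pos : pos + ln])
        rng.shuffle(reads)
        recs = [
            SequenceRecord(f"{lib}_{i + 1}", (r + cfg.adapter)[:40] if r else cfg.adapter)
            for i, r in enumerate(reads)
        ]
        truth.srna_read_totals[lib] = len(recs)
        libs_reads.append(recs)
    return libs_reads[0], libs_reads[1]


def _emit_species(
    sp: SimSpecies,
    n: int,
    lib_i: int,
    loci: dict[str, PlantedLocus],
    gseq: str,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[str]:
    locus = loci[sp.locus]
    if sp.kind == "star":
        # star of a perfect stem = exact reverse complement of the mature
        canonical = sp.seq
        ctx_start = None
    else:
        canonical = sp.seq
        ctx_start = locus.mature_start
    reads = []
    n_canon = 0
    for _ in range(n):
        r = canonical
        u = rng.random()
        if u < cfg.isomir_rate and ctx_start is not None:
            d5 = int(rng.choice([-1, 0, 1]))
            d3 = int(rng.choice([-1, 0, 1])) if d5 == 0 else 0
            if d5 == 0 and d3 == 0:
                d3 = 1
            s = ctx_start - d5
            e = ctx_start + len(canonical) + d3
            r = gseq[s:e]
        elif u < cfg.isomir_rate + cfg.error_rate:
            pos = int(rng.integers(len(r)))
            alt = str(rng.choice([b for b in "ACGT" if b != r[pos]]))
            r = r[:pos] + alt + r[pos + 1 :]
        else:
            n_canon += 1
        reads.append(r)
    if lib_i == 0:
        sp.expected_a = float(n)
        sp.realized_a = n_canon
    else:
        sp.expected_b = float(n)
        sp.realized_b = n_canon
    return reads


def make_exclusion_sets(rng: np.random.Generator) -> dict[str, list[SequenceRecord]]:
    """Random stand-ins for rRNA/tRNA/snoRNA/repeat exclusion databases (synthetic)."""
    out: dict[str, list[SequenceRecord]] = {}
    for cls, n, ln in (("rRNA", 4, 400), ("tRNA", 6, 80), ("snoRNA", 4, 120), ("repeat", 3, 300)):
        out[cls] = [
            SequenceRecord(f"{cls}-{i + 1}", "".join(rng.choice(_BASES, size=ln)))
            for i in range(n)
        ]
    return out


# ---------------------------------------------------------------------------
# transcriptome + degradome simulation


def _planted_site(mirna: str, score: float, rng: np.random.Generator) -> str:
    """Transcript subsequence complementary to the miRNA at a chosen score.

    The site is written 5'->3' on the transcript; miRNA position i pairs
    site position L-i+1 (site = revcomp of the miRNA, then mutated).
    Mismatches use the identity base (never Watson-Crick nor wobble).
    """
    site = list(revcomp(mirna))
    L = len(mirna)
    # mutate at miRNA positions: core (x2/mismatch) first, then non-core (x1)
    plans = {0.0: [], 2.0: [5], 4.0: [5, 8], 5.0: [5, 8, 16]}
    for mir_pos in plans[float(score)]:
        site[L - mir_pos] = mirna[mir_pos - 1]  # identity base = guaranteed mismatch
    return "".join(site)


def build_transcriptome(
    truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Transcripts carrying planted cleavage sites, plus decoy transcripts."""
    cfg = truth.config
    expressed = [sp for sp in truth.species if sp.kind in ("known_mature", "novel")]
    expressed.sort(key=lambda s: -max(s.weight_a, s.weight_b))
    chosen = expressed[: cfg.n_targets + cfg.n_decoy_targets]
    transcripts: list[SequenceRecord] = []
    annotations: dict[str, str] = {}
    heights = cfg.peak_heights
    for i, sp in enumerate(chosen):
        decoy = i >= cfg.n_targets
        score = 5.0 if decoy else float((0, 2, 4)[i % 3])
        site = _planted_site(sp.seq, score, rng)
        tlen = cfg.transcript_length
        ins = int(rng.integers(100, tlen - 100 - len(site)))
        seq = "".join(rng.choice(_BASES, size=tlen))
        seq = seq[:ins] + site + seq[ins + len(site) :]
        tid = f"TX{i + 1:04d}.1"
        transcripts.append(SequenceRecord(tid, seq))
        annotations[tid] = ("decoy site of " if decoy else "synthetic target of ") + sp.name
        # cleavage pairs miRNA position 10: site position L-10+1 within the site
        cleave = ins + (len(sp.seq) - 10) + 1  # 1-based transcript coordinate
        h = heights[i % len(heights)]
        peak_a = h if sp.realized_a > 0 else 0
        peak_b = h if sp.realized_b > 0 else 0
        truth.targets.append(PlantedTarget(
            sp.name, sp.seq, tid, cleave, score, peak_a, peak_b, decoy=decoy))
    for j in range(cfg.n_decoy_transcripts):
        tid = f"TXD{j + 1:04d}.1"
        transcripts.append(SequenceRecord(
            tid, "".join(rng.choice(_BASES, size=cfg.transcript_length))))
        annotations[tid] = "expressed protein"
    return transcripts, annotations


def simulate_degradome(
    transcripts: list[SequenceRecord],
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two degradome read sets: planted cleavage peaks + uniform background."""
    cfg = truth.config
    tx = {t.id: t.seq for t in transcripts}
    tids = list(tx)
    libs: list[list[SequenceRecord]] = []
    for lib_i, lib in enumerate(("A", "B")):
        reads: list[str] = []
        for tgt in truth.targets:
            peak = tgt.peak_a if lib_i == 0 else tgt.peak_b
            seq = tx[tgt.transcript_id]
            frag = seq[tgt.cleavage_site - 1 : tgt.cleavage_site - 1 + 20]
            reads.extend([frag] * peak)
        n_bg = int(cfg.degradome_depth * cfg.deg_background_rate)
        n_short = int(cfg.degradome_depth * cfg.deg_short_fraction)
        for _ in range(n_bg):
            tid = tids[int(rng.integers(len(tids)))]
            seq = tx[tid]
            pos = int(rng.integers(0, len(seq) - 20))
            reads.append(seq[pos : pos + 20])
        for _ in range(n_short):
            tid = tids[int(rng.integers(len(tids)))]
            seq = tx[tid]
            pos = int(rng.integers(0, len(seq) - 14))
            reads.append(seq[pos : pos + int(rng.integers(8, 15))])
        rng.shuffle(reads)
        recs = [
            SequenceRecord(f"D{lib}_{i + 1}", (r + cfg.adapter)[:40])
            for i, r in enumerate(reads)
        ]
        truth.degradome_read_totals[lib] = len(recs)
        libs.append(recs)
    return libs[0], libs[1]


# ---------------------------------------------------------------------------
# top-level dataset assembly


def build_dataset(config: SimConfig, out_dir: str | Path) -> SyntheticTruth:
    """Generate the full synthetic dataset into *out_dir* and return its truth.

    Files written: genome.fa, transcriptome.fa, reference precursor/mature
    FASTA + placements TSV, other-species reference, exclusion-set FASTAs,
    srna_A/B.fastq, degradome_A/B.fastq, annotations.tsv, truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reference = make_reference(rng, config.n_known, prefix="syn")
    genome0 = make_genome(int(rng.integers(2**31)), config.genome_length, config.gc_fraction)
    genome, truth = plant_mir_loci(genome0, reference, config, rng)
    exclusion = make_exclusion_sets(rng)
    srna_a, srna_b = simulate_srna_libraries(truth, genome, exclusion, rng)

    # other-species reference: orthologs of a few planted novel hairpins
    novel_loci = [l for l in truth.loci if l.kind == "novel"]
    sps_prec, sps_mat, sps_pl = [], [], []
    for k, locus in enumerate(novel_loci[:5]):
        pid = f"sps-MIR{901 + k}"
        arm = locus.arm
        mid = f"sps-miR{901 + k}-{arm}"
        ms = locus.mature_start - locus.start
        me = locus.mature_end - locus.start
        sps_prec.append(SequenceRecord(pid, locus.precursor_seq))
        sps_mat.append(SequenceRecord(mid, locus.mature_seq))
        sps_pl.append(Placement(mid, pid, ms, me, arm))
    other_ref = MirnaReference(sps_prec, sps_mat, sps_pl)

    transcripts, annotations = build_transcriptome(truth, rng)
    deg_a, deg_b = simulate_degradome(transcripts, truth, rng)

    write_fasta([genome], out / "genome.fa")
    write_fasta(transcripts, out / "transcriptome.fa")
    write_fasta(reference.precursors, out / "ref_precursors.fa")
    write_fasta(reference.matures, out / "ref_matures.fa")
    with open(out / "ref_placements.tsv", "w") as fh:
        fh.write("mature_id\tprecursor_id\tstart\tend\tarm\n")
        for p in reference.placements:
            fh.write(f"{p.mature_id}\t{p.precursor_id}\t{p.start}\t{p.end}\t{p.arm}\n")
    write_fasta(other_ref.precursors, out / "other_precursors.fa")
    write_fasta(other_ref.matures, out / "other_matures.fa")
    with open(out / "other_placements.tsv", "w") as fh:
        fh.write("mature_id\tprecursor_id\tstart\tend\tarm\n")
        for p in other_ref.placements:
            fh.write(f"{p.mature_id}\t{p.precursor_id}\t{p.start}\t{p.end}\t{p.arm}\n")
    for cls, seqs in exclusion.items():
        write_fasta(seqs, out / f"exclusion_{cls}.fa")
    write_fastq(srna_a, out / "srna_A.fastq")
    write_fastq(srna_b, out / "srna_B.fastq")
    write_fastq(deg_a, out / "degradome_A.fastq")
    write_fastq(deg_b, out / "degradome_B.fastq")
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("transcript_id\tannotation\n")
        for tid, ann in annotations.items():
            fh.write(f"{tid}\t{ann}\n")
    truth.to_json(out / "truth.json")
    return truth
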