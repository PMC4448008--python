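"""End-to-end orchestration: preprocess -> map -> known -> novel -> DE -> degradome.

`run_pipeline` wires the stages together on configured input files, writes
every result table into the output directory (each header carries the
config hash and seed for provenance), and returns the in-memory results so
stages can also be inspected programmatically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import degradome as deg
from .diffexpr import DETestResult, call_de
from .genome import GenomeIndex, MappedTag, map_tags
from .hairpin import HairpinCriteria
from .io import (
    MirnaReference,
    SequenceRecord,
    load_reference,
    read_fasta,
    read_fastq,
    read_structures,
    write_table,
)
from .known import MiRNARecord, annotate_known
from .novel import EXPRESSION_GATE, NovelCandidate, predict_novel
from .preprocess import LibraryAccounting, UniqueTag, clean_library

log = logging.getLogger("mirpipe")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report_composition"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    srna_fastqs: list[str]
    genome_fasta: str
    precursor_fasta: str
    mature_fasta: str
    out_dir: str
    placement_table: str | None = None
    degradome_fastqs: list[str] = field(default_factory=list)
    transcriptome_fasta: str | None = None
    other_precursor_fasta: str | None = None
    other_mature_fasta: str | None = None
    other_placement_table: str | None = None
    exclusion_fastas: dict[str, str] = field(default_factory=dict)
    structures_file: str | None = None
    annotations_table: str | None = None
    lib_names: list[str] = field(default_factory=lambda: ["A", "B"])
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 17
    max_len: int = 25
    max_hits: int = 100
    criteria: HairpinCriteria = field(default_factory=HairpinCriteria)
    expression_gate: float = EXPRESSION_GATE
    fc_min: float = 2.0
    q_max: float = 0.01
    min_raw: int = 10
    score_max: float = 4.0
    deg_min_len: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"min length {self.min_len} exceeds max length {self.max_len}")
        missing = [
            p for p in (
                *self.srna_fastqs, self.genome_fasta, self.precursor_fasta,
                self.mature_fasta, *self.degradome_fastqs,
                *(x for x in (self.transcriptome_fasta, self.placement_table,
                              self.structures_file) if x),
                *self.exclusion_fastas.values(),
            )
            if p and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("missing input files: " + ", ".join(map(str, missing)))

    def digest(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # parameters only: identical runs hash identically
        return hashlib.sha1(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tags: list[UniqueTag]
    accounting: list[LibraryAccounting]
    mapped: list[MappedTag]
    unmapped: list[UniqueTag]
    known_records: list[MiRNARecord]
    novel_records: list[MiRNARecord]
    candidates: list[NovelCandidate]
    de_results: list[DETestResult]
    target_hits: list[deg.TargetHit]
    clean_totals: list[int]


def _header(cfg: PipelineConfig) -> str:
    return f"mirpipe config={cfg.digest()} seed={cfg.seed}"


def report_composition(
    tags: list[UniqueTag],
    known: list[MiRNARecord],
    novel: list[MiRNARecord],
    lib_names: list[str],
) -> tuple[list[dict], list[dict]]:
    """Length histograms (redundant + unique per library) and 5'-nt bias tables."""
    lengths = sorted({len(t) for t in tags})
    total_reads = np.zeros(len(lib_names))
    for t in tags:
        total_reads += t.counts
    size_rows = []
    for L in lengths:
        row: dict = {"length": L}
        sub = [t for t in tags if len(t) == L]
        for i, lib in enumerate(lib_names):
            reads = sum(int(t.counts[i]) for t in sub)
            uniq = sum(1 for t in sub if t.counts[i] > 0)
            row[f"reads_{lib}"] = reads
            row[f"frac_{lib}"] = round(reads / total_reads[i], 4) if total_reads[i] else 0.0
            row[f"unique_{lib}"] = uniq
        size_rows.append(row)
    nt_rows = []
    for group, records in (("known", known), ("novel", novel)):
        counts = {b: 0 for b in "ACGT"}
        for r in records:
            counts[r.seq[0]] += 1
        tot = sum(counts.values())
        for b in "ACGT":
            nt_rows.append({
                "set": group, "first_nt": "U" if b == "T" else b,
                "mirnas": counts[b],
                "fraction": round(counts[b] / tot, 4) if tot else 0.0,
            })
    return size_rows, nt_rows


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, default=str)

    # --- preprocess ------------------------------------------------------
    exclusion = {
        cls: read_fasta(path) for cls, path in config.exclusion_fastas.items()
    }
    reads = [read_fastq(p) for p in config.srna_fastqs]
    tags, accounting = clean_library(
        reads, config.adapter, exclusion, config.lib_names,
        config.min_len, config.max_len,
    )
    clean_totals = [a.clean for a in accounting]
    for a in accounting:
        log.info("library %s: raw=%d no_insert=%d junk=%d length=%d excluded=%d clean=%d",
                 a.library, a.raw, a.no_insert, a.junk, a.length_removed,
                 a.excluded_total, a.clean)
    acct_rows = []
    for a in accounting:
        for row in a.as_rows():
            acct_rows.append({"library": a.library, **row})
    write_table(acct_rows, out / "accounting.tsv", ["library", "fate", "reads", "unique"],
                header_comment=_header(config))

    # --- genome mapping --------------------------------------------------
    genome = read_fasta(config.genome_fasta)
    index = GenomeIndex(genome)
    mapped, unmapped = map_tags(tags, index, config.max_hits)
    log.info("genome mapping: %d tags mapped, %d unmapped, %d multi-mapped",
             len(mapped), len(unmapped), sum(1 for m in mapped if m.multi_mapped))

    # --- known miRNAs ----------------------------------------------------
    reference = load_reference(
        config.precursor_fasta, config.mature_fasta, config.placement_table
    )
    known_records, unmatched_tags, consumed = annotate_known(
        [m.tag for m in mapped], reference
    )
    log.info("known miRNAs: %d records (%d documented, %d p5/p3), %d tags unmatched",
             len(known_records),
             sum(1 for r in known_records if r.mirna_class == "documented"),
             sum(1 for r in known_records if r.mirna_class == "p5p3"),
             len(unmatched_tags))

    # --- novel miRNAs ----------------------------------------------------
    other_ref: MirnaReference | None = None
    if config.other_precursor_fasta and config.other_mature_fasta:
        other_ref = load_reference(
            config.other_precursor_fasta, config.other_mature_fasta,
            config.other_placement_table,
        )
    structures = read_structures(config.structures_file) if config.structures_file else None
    unmatched_seqs = {t.seq for t in unmatched_tags}
    novel_input = [m for m in mapped if m.tag.seq in unmatched_seqs]
    novel_records, candidates = predict_novel(
        novel_input, index, config.criteria, other_ref, structures,
        config.expression_gate,
    )
    log.info("novel miRNAs: %d reported from %d evaluated loci (%d group1, %d group2)",
             len(novel_records), len(candidates),
             sum(1 for r in novel_records if r.mirna_class == "novel_group1"),
             sum(1 for r in novel_records if r.mirna_class == "novel_group2"))

    all_records = known_records + novel_records
    cat_rows = [
        {
            "name": r.name, "class": r.mirna_class, "precursor": r.precursor_id,
            "arm": r.arm, "sequence": r.seq,
            **{f"count_{lib}": int(r.counts[i]) for i, lib in enumerate(config.lib_names)},
            **{f"norm_{lib}": round(float(r.norm[i]), 2)
               for i, lib in enumerate(config.lib_names)},
        }
        for r in all_records
    ]
    write_table(
        cat_rows, out / "mirna_catalog.tsv",
        ["name", "class", "precursor", "arm", "sequence"]
        + [f"count_{lib}" for lib in config.lib_names]
        + [f"norm_{lib}" for lib in config.lib_names],
        header_comment=_header(config),
    )

    # --- differential expression ----------------------------------------
    de_results = call_de(
        [r.name for r in all_records],
        [int(r.counts[0]) for r in all_records],
        [int(r.counts[1]) for r in all_records],
        clean_totals[0], clean_totals[1],
        config.fc_min, config.q_max, config.min_raw,
    )
    n_de = sum(1 for r in de_results if r.call in ("up-in-B", "down-in-B"))
    log.info("differential expression: %d tested, %d DE",
             sum(1 for r in de_results if r.call != "excluded-low-abundance"), n_de)
    lib_b = config.lib_names[1]
    de_rows = [
        {
            "name": r.name, "count_a": r.a, "count_b": r.b,
            "norm_a": round(r.na, 2), "norm_b": round(r.nb, 2),
            "fold_change": round(r.fold_change, 3),
            "p_fisher": "" if r.p_fisher is None else f"{r.p_fisher:.3e}",
            "p_chi2": "" if r.p_chi2 is None else f"{r.p_chi2:.3e}",
            "q": "" if r.q is None else f"{r.q:.3e}",
            "call": r.call.replace("-in-B", f"-in-{lib_b}"),
        }
        for r in de_results
    ]
    write_table(de_rows, out / "de_table.tsv",
                ["name", "count_a", "count_b", "norm_a", "norm_b", "fold_change",
                 "p_fisher", "p_chi2", "q", "call"],
                header_comment=_header(config))

    # --- degradome -------------------------------------------------------
    target_hits: list[deg.TargetHit] = []
    if config.degradome_fastqs and config.transcriptome_fasta:
        transcripts = read_fasta(config.transcriptome_fasta)
        tindex = deg.TranscriptIndex(transcripts)
        libs = []
        for path, lib in zip(config.degradome_fastqs, config.lib_names):
            tag_counts, raw, removed = deg.preprocess_degradome(
                read_fastq(path), config.adapter, config.deg_min_len
            )
            library = deg.map_degradome(tag_counts, tindex, lib, raw)
            log.info("degradome %s: raw=%d short=%d mapped=%d unmapped=%d",
                     lib, raw, removed, library.mapped_reads, library.unmapped_reads)
            libs.append(library)
        annotations: dict[str, str] = {}
        if config.annotations_table:
            with open(config.annotations_table) as fh:
                next(fh)
                for line in fh:
                    tid, ann = line.rstrip("\n").split("\t")
                    annotations[tid] = ann
        target_hits = deg.find_targets(
            [(r.name, r.seq) for r in all_records], libs, transcripts, config.score_max
        )
        log.info("degradome targets: %d hits", len(target_hits))
        tgt_rows = [
            {
                "miR_name": h.mirna_name, "target": h.transcript_id,
                "annotation": annotations.get(h.transcript_id, ""),
                "score": h.score, "cleavage_site": h.cleavage_site,
                **{f"tpb_{lib}": h.tpb[lib] for lib in config.lib_names},
                **{f"reads_{lib}": h.reads_at_site[lib] for lib in config.lib_names},
                **{f"category_{lib}": "" if h.category[lib] is None else h.category[lib]
                   for lib in config.lib_names},
            }
            for h in target_hits
        ]
        write_table(
            tgt_rows, out / "targets.tsv",
            ["miR_name", "target", "annotation", "score", "cleavage_site"]
            + [f"tpb_{lib}" for lib in config.lib_names]
            + [f"reads_{lib}" for lib in config.lib_names]
            + [f"category_{lib}" for lib in config.lib_names],
            float_cols=[f"tpb_{lib}" for lib in config.lib_names],
            header_comment=_header(config),
        )

    # --- composition reports --------------------------------------------
    size_rows, nt_rows = report_composition(
        tags, known_records, novel_records, config.lib_names
    )
    write_table(size_rows, out / "size_distribution.tsv",
                list(size_rows[0].keys()) if size_rows else ["length"],
                header_comment=_header(config))
    write_table(nt_rows, out / "first_nucleotide.tsv",
                ["set", "first_nt", "mirnas", "fraction"],
                header_comment=_header(config))

    return PipelineResult(
        config, tags, accounting, mapped, unmapped, known_records,
        novel_records, candidates, de_results, target_hits, clean_totals,
    )
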