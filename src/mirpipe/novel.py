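"""Novel miRNA prediction from unmatched genome-mapped tags.

Tags that match no reference precursor seed candidate loci: the flanking
genomic windows (20 nt up / 200 nt down, and 200 nt up / 20 nt down, so
the mature can sit on either arm) are folded and screened against the 11
hairpin criteria; candidates passing all criteria with normalized
expression >= 10 in at least one library become novel miRNAs. Candidates
whose sequence matches another species' precursor (same <=1-substitution
rules as known-miRNA matching) are conserved orthologs (group 1) and adopt
the ortholog's name plus isomiR suffixes; the remainder are
species-specific (group 2) and get provisional ``PC-{arm}-{serial}_{count}``
names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .fold import PrecursorFold, fold, pair_table
from .genome import GenomeIndex, MappedTag, extract_flank
from .hairpin import HairpinCriteria, HairpinEvaluation, evaluate_hairpin
from .io import MirnaReference
from .known import MiRNARecord, VariantDescriptor, classify_match, match_to_precursor, name_variant

__all__ = [
    "expression_gate",
    "classify_conservation",
    "name_novel",
    "predict_novel",
    "NovelCandidate",
    "EXPRESSION_GATE",
    "WINDOWS",
]

EXPRESSION_GATE = 10.0  # normalized (per-million) expression in >=1 library
WINDOWS = ((20, 200), (200, 20))  # (upstream, downstream) folding windows
LOCUS_RADIUS = 220  # tags landing this close to a stronger tag share its locus


def expression_gate(norm_values: Sequence[float], threshold: float = EXPRESSION_GATE) -> bool:
    """Pass iff normalized expression reaches the threshold in >=1 library."""
    return bool(len(norm_values)) and max(norm_values) >= threshold


def classify_conservation(
    seq: str, other_species: MirnaReference | None
) -> tuple[str, str | None, VariantDescriptor | None]:
    """Group a novel sequence by conservation.

    Returns (class, ortholog base name or None, descriptor or None):
    group 1 iff the sequence places on any other-species precursor under
    the usual <=1-substitution, bounded-end-variation rules.
    """
    if other_species is None:
        return "novel_group2", None, None
    for prec in other_species.precursors:
        for pl in match_to_precursor(seq, prec.seq):
            pl = type(pl)(prec.id, pl.start, pl.mismatches, pl.substitution)
            try:
                cls = classify_match(seq, pl, other_species, prec.id)
            except ValueError:
                continue
            if cls is None:
                # on the precursor but past the end-offset bound: still conserved
                return "novel_group1", None, None
            kind, arm, desc, mature_pl = cls
            if kind == "documented":
                return "novel_group1", mature_pl.mature_id, desc
            return "novel_group1", f"{prec.id}-p{arm[0]}", desc
    return "novel_group2", None, None


def name_novel(arm: str, serial: int, count: int) -> str:
    """Provisional-candidate name, e.g. ``PC-5p-180057_8``."""
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    return f"PC-{arm}-{serial}_{count}"


@dataclass
class NovelCandidate:
    """A candidate locus: tag, window fold, and its criteria evaluation."""

    record: MiRNARecord | None
    window_seq: str
    fold: PrecursorFold
    evaluation: HairpinEvaluation
    chrom: str
    start: int
    strand: str


def _mature_arm(pf: PrecursorFold) -> str:
    """Arm of the mature within its stem-loop: 5' of the terminal loop -> 5p."""
    pt = pair_table(pf.structure)
    n = len(pf.structure)
    ms, me = pf.mature_span
    comps: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = pt[i]
        if j > i:
            comps.append((i, j))
            i = j + 1
        else:
            i += 1
    best, ov_best = None, 0
    for a, b in comps:
        ov = max(0, min(me, b + 1) - max(ms, a))
        if ov > ov_best:
            best, ov_best = (a, b), ov
    if best is None:
        return "5p"
    a, b = best
    inner = max(((i, pt[i]) for i in range(a, b + 1) if pt[i] > i), key=lambda x: x[0])
    return "5p" if (ms + me) / 2 < sum(inner) / 2 else "3p"


def predict_novel(
    mapped_tags: Sequence[MappedTag],
    index: GenomeIndex,
    criteria: HairpinCriteria = HairpinCriteria(),
    other_species: MirnaReference | None = None,
    structures: Mapping[str, tuple[str, float]] | None = None,
    gate: float = EXPRESSION_GATE,
    serials: Mapping[str, int] | None = None,
) -> tuple[list[MiRNARecord], list[NovelCandidate]]:
    """Predict novel miRNAs from tags that matched no reference precursor.

    Multi-mapped tags never seed loci. Tags are visited in decreasing
    abundance; a tag whose hit falls inside the window of a stronger tag
    is absorbed into that locus (the most abundant tag defines the mature).
    Returns (novel records, all evaluated candidates incl. failures).
    """
    records: list[MiRNARecord] = []
    candidates: list[NovelCandidate] = []
    claimed: dict[tuple[str, str], list[int]] = {}
    fold_cache: dict[str, PrecursorFold] = {}
    order = sorted(
        mapped_tags, key=lambda m: (-int(m.tag.counts.sum()), m.tag.seq)
    )
    serial_counter = 0
    for m in order:
        if m.multi_mapped:
            continue
        if m.tag.norm is None or not expression_gate(list(m.tag.norm), gate):
            continue
        for hit in m.hits:
            key = (hit.chrom, hit.strand)
            center = (hit.start + hit.end) // 2
            spots = claimed.setdefault(key, [])
            if any(abs(center - c) <= LOCUS_RADIUS for c in spots):
                continue
            spots.append(center)
            best: NovelCandidate | None = None
            for up, down in WINDOWS:
                window, ws, we = extract_flank(hit, index, up, down)
                cached = fold_cache.get(window)
                if cached is None:
                    sid = f"{hit.chrom}:{hit.start}-{hit.end}({hit.strand})u{up}"
                    cached = fold(window, structures=structures, name=sid)
                    fold_cache[window] = cached
                pf = PrecursorFold(
                    cached.seq, cached.structure, cached.energy, mature_span=(ws, we)
                )
                ev = evaluate_hairpin(pf, criteria)
                cand = NovelCandidate(None, window, pf, ev, hit.chrom, hit.start, hit.strand)
                if best is None or (ev.overall and not best.evaluation.overall):
                    best = cand
                if ev.overall:
                    break
            assert best is not None
            candidates.append(best)
            if not best.evaluation.overall:
                continue
            arm = _mature_arm(best.fold)
            group, base, desc = classify_conservation(m.tag.seq, other_species)
            serial_counter += 1
            serial = serials.get(m.tag.seq, serial_counter) if serials else serial_counter
            if group == "novel_group1" and base is not None:
                name = name_variant(base, desc or VariantDescriptor())
            else:
                name = name_novel(arm, serial, int(m.tag.counts.sum()))
            rec = MiRNARecord(
                name, m.tag.seq, group, f"{hit.chrom}:{hit.start}", arm,
                desc or VariantDescriptor(), counts=m.tag.counts, norm=m.tag.norm,
                extras={"evaluation": best.evaluation, "window": best.window_seq,
                        "structure": best.fold.structure, "energy": best.fold.energy},
            )
            records.append(rec)
            best.record = rec
            break  # one locus per tag
    return records, candidates
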