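"""Known-miRNA identification against a miRBase-style reference.

A unique tag is compared to every reference precursor as an ungapped,
full-length placement with at most one substitution; total tag length must
stay within 17-25 nt. A placement overlapping a documented mature on its
own arm makes the tag a documented miRNA (possibly an isomiR, described by
5'/3' end offsets and the substitution); a placement on the arm opposite
all documented matures makes it a 5p-/3p-derived (p5/p3) species. IsomiR
variants are kept as separate records and named with the
``_L±n`` / ``_R±n`` / ``_1ss{pos}{from}{to}`` grammar, e.g.
``osa-miR530-5p_R+1`` (one extra 3' base) or
``sbi-miR166a_R+1_1ss1TG`` (plus a T→G substitution at position 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io import MirnaReference, Placement
from .preprocess import UniqueTag, MIN_TAG_LEN, MAX_TAG_LEN

__all__ = [
    "VariantDescriptor",
    "MiRNARecord",
    "PrecursorPlacement",
    "match_to_precursor",
    "classify_match",
    "name_variant",
    "annotate_known",
    "MAX_END_OFFSET",
]

MAX_END_OFFSET = 3  # |5'/3' end variation| allowed against a documented mature


@dataclass(frozen=True)
class VariantDescriptor:
    """End offsets and optional substitution relating a tag to a reference mature.

    Positive offsets extend the variant beyond the mature's end (using
    precursor context); negative offsets trim. The substitution position is
    1-based on the variant sequence, 5'→3'.
    """

    left_offset: int = 0
    right_offset: int = 0
    substitution: tuple[int, str, str] | None = None  # (pos, from, to)

    @property
    def is_zero(self) -> bool:
        return self.left_offset == 0 and self.right_offset == 0 and self.substitution is None


@dataclass(frozen=True)
class PrecursorPlacement:
    """Ungapped placement of a tag on a precursor with <=1 substitution."""

    precursor_id: str
    start: int  # 0-based on precursor
    mismatches: int
    substitution: tuple[int, str, str] | None  # 1-based on tag


@dataclass
class MiRNARecord:
    """A named mature miRNA species with its class and expression."""

    name: str
    seq: str
    mirna_class: str  # documented | p5p3 | novel_group1 | novel_group2
    precursor_id: str
    arm: str
    descriptor: VariantDescriptor
    counts: "object" = None  # per-library raw counts (np.ndarray)
    norm: "object" = None  # per-library normalized expression
    extras: dict = field(default_factory=dict)


def match_to_precursor(tag_seq: str, precursor_seq: str) -> list[PrecursorPlacement]:
    """All ungapped full-length placements of the tag with <=1 substitution."""
    L, P = len(tag_seq), len(precursor_seq)
    if not (MIN_TAG_LEN <= L <= MAX_TAG_LEN):
        return []
    out: list[PrecursorPlacement] = []
    for start in range(P - L + 1):
        sub = None
        mism = 0
        for k in range(L):
            if tag_seq[k] != precursor_seq[start + k]:
                mism += 1
                if mism > 1:
                    break
                sub = (k + 1, precursor_seq[start + k], tag_seq[k])
        if mism <= 1:
            out.append(PrecursorPlacement("", start, mism, sub if mism else None))
    return out


def _arm_of_span(prec_len: int, start: int, end: int) -> str | None:
    """Arm by position of the span center relative to the precursor midpoint."""
    center = (start + end) / 2
    mid = prec_len / 2
    if center == mid:
        return None  # exact tie: ambiguous
    return "5p" if center < mid else "3p"


def classify_match(
    tag_seq: str,
    placement: PrecursorPlacement,
    reference: MirnaReference,
    precursor_id: str,
    max_end_offset: int = MAX_END_OFFSET,
) -> tuple[str, str, VariantDescriptor, Placement | None] | None:
    """Classify one placement as documented / p5p3.

    Returns (class, arm, descriptor, matched mature placement or None), or
    ``None`` when the placement overlaps a documented mature but exceeds
    the end-offset bound (tag stays tied to the precursor but unnamed).
    Raises ValueError for an exact arm tie.
    """
    prec = reference.precursor(precursor_id)
    L = len(tag_seq)
    start, end = placement.start, placement.start + L
    arm = _arm_of_span(len(prec.seq), start, end)
    if arm is None:
        raise ValueError(
            f"ambiguous arm: placement [{start},{end}) centered on the midpoint "
            f"of precursor {precursor_id!r}"
        )
    same_arm = [p for p in reference.placements_on(precursor_id) if p.arm == arm]
    if same_arm:
        # documented mature on this arm: describe the tag as its variant
        best = min(
            same_arm,
            key=lambda p: (abs(start - p.start) + abs(end - p.end), p.mature_id),
        )
        left = best.start - start  # + = extension at 5'
        right = end - best.end  # + = extension at 3'
        if abs(left) > max_end_offset or abs(right) > max_end_offset:
            return None
        desc = VariantDescriptor(left, right, placement.substitution)
        return "documented", arm, desc, best
    return "p5p3", arm, VariantDescriptor(0, 0, placement.substitution), None


def name_variant(base_name: str, desc: VariantDescriptor) -> str:
    """Apply the isomiR naming grammar to a base miRNA name."""
    name = base_name
    if desc.left_offset:
        name += f"_L{desc.left_offset:+d}"
    if desc.right_offset:
        name += f"_R{desc.right_offset:+d}"
    if desc.substitution:
        pos, frm, to = desc.substitution
        name += f"_1ss{pos}{frm}{to}"
    return name


def apply_descriptor(reference: MirnaReference, mature_pl: Placement, desc: VariantDescriptor) -> str:
    """Reconstruct the variant sequence a descriptor denotes (round-trip check)."""
    prec = reference.precursor(mature_pl.precursor_id)
    start = mature_pl.start - desc.left_offset
    end = mature_pl.end + desc.right_offset
    if start < 0 or end > len(prec.seq):
        raise ValueError("descriptor extends beyond the precursor")
    seq = prec.seq[start:end]
    if desc.substitution:
        pos, frm, to = desc.substitution
        if seq[pos - 1] != frm:
            raise ValueError("substitution from-base does not match the precursor")
        seq = seq[: pos - 1] + to + seq[pos:]
    return seq


def annotate_known(
    tags: Sequence[UniqueTag],
    reference: MirnaReference,
    max_end_offset: int = MAX_END_OFFSET,
) -> tuple[list[MiRNARecord], list[UniqueTag], set[str]]:
    """Assign tags to reference precursors.

    Returns (records, unmatched tags, consumed tag sequences). Each tag is
    assigned to at most one precursor: fewest mismatches, then smallest
    total end offset, then lexicographically smallest precursor id.
    Unmatched tags flow on to novel-miRNA prediction. Tags that match a
    precursor but cannot be classified (offset bound) are consumed without
    a record. p5/p3 species on one arm are named after the most abundant
    tag on that arm; rarer tags on the same arm become its isomiR variants.
    """
    seed_k = 8
    seed_index: dict[str, list[tuple[str, int]]] = {}
    for prec in reference.precursors:
        s = prec.seq
        for i in range(len(s) - seed_k + 1):
            seed_index.setdefault(s[i : i + seed_k], []).append((prec.id, i))

    # gather candidate assignments per tag
    assigned: list[tuple[UniqueTag, str, PrecursorPlacement]] = []
    unmatched: list[UniqueTag] = []
    for tag in tags:
        L = len(tag.seq)
        cand_positions: set[tuple[str, int]] = set()
        # a <=1-mismatch placement matches exactly in the first or last half
        for off, seed in ((0, tag.seq[:seed_k]), (L - seed_k, tag.seq[-seed_k:])):
            for pid, pos in seed_index.get(seed, ()):
                start = pos - off
                if start >= 0:
                    cand_positions.add((pid, start))
        best: tuple[int, int, str, PrecursorPlacement] | None = None
        for pid, start in cand_positions:
            prec_seq = reference.precursor(pid).seq
            if start + L > len(prec_seq):
                continue
            sub = None
            mism = 0
            for k in range(L):
                if tag.seq[k] != prec_seq[start + k]:
                    mism += 1
                    if mism > 1:
                        break
                    sub = (k + 1, prec_seq[start + k], tag.seq[k])
            if mism > 1:
                continue
            pl = PrecursorPlacement(pid, start, mism, sub if mism else None)
            offset_cost = _offset_cost(tag.seq, pl, reference, pid)
            key = (mism, offset_cost, pid, pl)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is None:
            unmatched.append(tag)
        else:
            assigned.append((tag, best[2], best[3]))

    # group p5p3 tags by (precursor, arm); most abundant defines the species
    records: list[MiRNARecord] = []
    consumed: set[str] = set()
    p5p3_groups: dict[tuple[str, str], list[tuple[UniqueTag, PrecursorPlacement]]] = {}
    for tag, pid, pl in assigned:
        consumed.add(tag.seq)
        try:
            cls = classify_match(tag.seq, pl, reference, pid, max_end_offset)
        except ValueError:
            continue  # exact arm tie: precursor-matched but unnameable
        if cls is None:
            continue
        kind, arm, desc, mature_pl = cls
        if kind == "documented":
            name = name_variant(mature_pl.mature_id, desc)
            records.append(
                MiRNARecord(name, tag.seq, "documented", pid, arm, desc,
                            counts=tag.counts, norm=tag.norm)
            )
        else:
            p5p3_groups.setdefault((pid, arm), []).append((tag, pl))
    for (pid, arm), members in p5p3_groups.items():
        members.sort(key=lambda m: (-int(m[0].counts.sum()), m[0].seq))
        canon_tag, canon_pl = members[0]
        base = f"{pid}-p{arm[0]}"
        canon_start, canon_end = canon_pl.start, canon_pl.start + len(canon_tag.seq)
        for tag, pl in members:
            left = canon_start - pl.start
            right = (pl.start + len(tag.seq)) - canon_end
            desc = VariantDescriptor(left, right, pl.substitution)
            records.append(
                MiRNARecord(name_variant(base, desc), tag.seq, "p5p3", pid, arm, desc,
                            counts=tag.counts, norm=tag.norm)
            )
    return records, unmatched, consumed


def _offset_cost(tag_seq: str, pl: PrecursorPlacement, reference: MirnaReference, pid: str) -> int:
    """|left|+|right| against the nearest same-arm mature (tie-break key)."""
    prec = reference.precursor(pid)
    start, end = pl.start, pl.start + len(tag_seq)
    arm = _arm_of_span(len(prec.seq), start, end)
    same_arm = [p for p in reference.placements_on(pid) if p.arm == arm]
    if not same_arm:
        return 0
    return min(abs(start - p.start) + abs(end - p.end) for p in same_arm)
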