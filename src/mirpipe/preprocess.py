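"""Raw small-RNA read cleanup and collapsing to unique tags.

Cleanup follows the junk-read conventions used for plant sRNA libraries:
reads that are adapter-only, dominated (>80%) by a single nucleotide,
carry more than two Ns, or contain homopolymer runs of A7/C8/G6/T7 are
discarded. Surviving inserts are collapsed to unique tags, length-filtered
to 17–25 nt, screened against user-supplied exclusion sets (rRNA, tRNA,
snRNA, snoRNA, repeats, mRNA, ...), and assigned per-library normalized
expression in reads per million clean reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SequenceRecord, revcomp

__all__ = [
    "UniqueTag",
    "LibraryAccounting",
    "trim_adapter",
    "is_junk",
    "length_filter",
    "exclude_by_annotation",
    "collapse_unique",
    "clean_library",
    "MIN_TAG_LEN",
    "MAX_TAG_LEN",
]

MIN_TAG_LEN = 17
MAX_TAG_LEN = 25
MIN_ADAPTER_OVERLAP = 6

_HOMOPOLYMER = re.compile("A{7}|C{8}|G{6}|T{7}")


@dataclass
class UniqueTag:
    """A collapsed distinct read sequence with per-library counts.

    ``counts[i]`` is the raw read count in library *i*; ``norm[i]`` the
    normalized expression (reads per million clean reads of that library).
    """

    seq: str
    counts: np.ndarray
    norm: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LibraryAccounting:
    """Read-fate counters for one library; every raw read gets exactly one fate."""

    library: str
    raw: int = 0
    no_insert: int = 0
    length_removed: int = 0
    junk: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    clean: int = 0
    unique_clean: int = 0
    # unique-tag variants of the tag-level fates
    unique_length_removed: int = 0
    unique_excluded: dict[str, int] = field(default_factory=dict)

    @property
    def excluded_total(self) -> int:
        return sum(self.excluded.values())

    def check(self) -> None:
        total = self.no_insert + self.junk + self.length_removed + self.excluded_total + self.clean
        if total != self.raw:
            raise AssertionError(
                f"{self.library}: fates sum to {total}, raw is {self.raw}"
            )

    def as_rows(self) -> list[dict]:
        rows = [
            {"fate": "raw", "reads": self.raw, "unique": ""},
            {"fate": "no_insert", "reads": self.no_insert, "unique": ""},
            {"fate": "junk", "reads": self.junk, "unique": ""},
            {"fate": "length_filter", "reads": self.length_removed,
             "unique": self.unique_length_removed},
        ]
        for cls in sorted(self.excluded):
            rows.append({"fate": f"excluded:{cls}", "reads": self.excluded[cls],
                         "unique": self.unique_excluded.get(cls, "")})
        rows.append({"fate": "clean", "reads": self.clean, "unique": self.unique_clean})
        return rows


def trim_adapter(seq: str, adapter: str) -> str | None:
    """Trim the 3' adapter from a read sequence.

    The insert ends at the leftmost position where a prefix of the adapter
    (minimum overlap 6 nt, exact match) begins. Returns ``None`` for
    adapter-only reads (no insert); reads without any adapter occurrence
    pass through unchanged.
    """
    if len(adapter) < MIN_ADAPTER_OVERLAP:
        raise ValueError("adapter must be at least 6 nt")
    n = len(seq)
    probe = adapter[:MIN_ADAPTER_OVERLAP]
    pos = seq.find(probe)
    while pos != -1:
        k = min(len(adapter), n - pos)
        if seq[pos : pos + k] == adapter[:k]:
            return None if pos == 0 else seq[:pos]
        pos = seq.find(probe, pos + 1)
    # tail shorter than the minimum overlap is not trimmed
    return seq


def is_junk(seq: str) -> tuple[bool, str | None]:
    """Classify a read insert as junk.

    Junk if any single base exceeds 80% of the length, more than two Ns,
    or a homopolymer run of A×7, C×8, G×6 or T×7. Returns (verdict, reason)
    with the first triggered rule.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    for base in "ACGT":
        if seq.count(base) / n > 0.8:
            return True, f"composition>{80}%{base}"
    if seq.count("N") > 2:
        return True, "N>2"
    m = _HOMOPOLYMER.search(seq)
    if m:
        return True, f"homopolymer:{m.group(0)}"
    return False, None


def length_filter(
    tags: Sequence[UniqueTag],
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> tuple[list[UniqueTag], list[UniqueTag]]:
    """Partition tags into (retained, removed) by inclusive length bounds."""
    if min_len > max_len:
        raise ValueError(f"min length {min_len} exceeds max length {max_len}")
    kept = [t for t in tags if min_len <= len(t) <= max_len]
    removed = [t for t in tags if not (min_len <= len(t) <= max_len)]
    return kept, removed


def exclude_by_annotation(
    tags: Sequence[UniqueTag],
    exclusion_sets: Mapping[str, Sequence[SequenceRecord]],
) -> tuple[list[UniqueTag], list[tuple[UniqueTag, str]]]:
    """Screen tags against named exclusion sequence sets.

    A tag is excluded iff it occurs as an exact substring (either strand)
    of any sequence in any set; the class of the first matching set (in
    mapping order) is recorded.
    """
    haystacks = {
        cls: "\n".join(
            s.seq + "\n" + revcomp(s.seq) for s in seqs
        )
        for cls, seqs in exclusion_sets.items()
    }
    retained: list[UniqueTag] = []
    excluded: list[tuple[UniqueTag, str]] = []
    for tag in tags:
        hit = None
        for cls, hay in haystacks.items():
            if tag.seq in hay:
                hit = cls
                break
        if hit is None:
            retained.append(tag)
        else:
            excluded.append((tag, hit))
    return retained, excluded


def collapse_unique(libraries: Sequence[Iterable[str]]) -> list[UniqueTag]:
    """Collapse per-library read sequences to unique tags with count vectors."""
    n_lib = len(libraries)
    counts: dict[str, np.ndarray] = {}
    for i, reads in enumerate(libraries):
        for seq in reads:
            vec = counts.get(seq)
            if vec is None:
                vec = np.zeros(n_lib, dtype=np.int64)
                counts[seq] = vec
            vec[i] += 1
    return [UniqueTag(seq, vec) for seq, vec in counts.items()]


def clean_library(
    reads_per_lib: Sequence[Iterable[SequenceRecord]],
    adapter: str,
    exclusion_sets: Mapping[str, Sequence[SequenceRecord]] | None = None,
    lib_names: Sequence[str] | None = None,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> tuple[list[UniqueTag], list[LibraryAccounting]]:
    """Full cleanup for a set of libraries.

    Per read: adapter trim (adapter-only reads dropped), junk filter on the
    trimmed insert; then collapse to unique tags, length filter, exclusion
    screen, and per-million normalization against each library's clean
    read total. Every raw read lands in exactly one accounting bucket.
    """
    names = list(lib_names) if lib_names else [f"lib{i+1}" for i in range(len(reads_per_lib))]
    acct = [LibraryAccounting(name) for name in names]
    surviving: list[list[str]] = []
    for i, reads in enumerate(reads_per_lib):
        keep: list[str] = []
        for rec in reads:
            acct[i].raw += 1
            insert = trim_adapter(rec.seq, adapter)
            if insert is None:
                acct[i].no_insert += 1
                continue
            junk, _reason = is_junk(insert)
            if junk:
                acct[i].junk += 1
                continue
            keep.append(insert)
        surviving.append(keep)

    tags = collapse_unique(surviving)
    kept, removed = length_filter(tags, min_len, max_len)
    for t in removed:
        for i in range(len(acct)):
            acct[i].length_removed += int(t.counts[i])
            acct[i].unique_length_removed += int(t.counts[i] > 0)

    if exclusion_sets:
        kept, excluded = exclude_by_annotation(kept, exclusion_sets)
        for t, cls in excluded:
            for i in range(len(acct)):
                acct[i].excluded[cls] = acct[i].excluded.get(cls, 0) + int(t.counts[i])
                if t.counts[i] > 0:
                    acct[i].unique_excluded[cls] = acct[i].unique_excluded.get(cls, 0) + 1

    totals = np.zeros(len(acct), dtype=np.int64)
    for t in kept:
        totals += t.counts
    for i, a in enumerate(acct):
        a.clean = int(totals[i])
        a.unique_clean = sum(1 for t in kept if t.counts[i] > 0)
        a.check()
    safe = np.where(totals > 0, totals, 1)
    for t in kept:
        t.norm = t.counts * 1e6 / safe
    return kept, acct
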