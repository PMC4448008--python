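"""Exact mapping of unique tags to the genome on both strands.

Mapping is exact (no mismatches): mismatch tolerance in this pipeline
applies only to matching against reference precursors, never the genome.
The index is a seed dictionary of fixed-length k-mers; a query is located
by seed lookup followed by full-length verification, which for 17–25-nt
queries is equivalent to a brute-force scan of both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import SequenceRecord, revcomp
from .preprocess import UniqueTag, MIN_TAG_LEN

__all__ = ["GenomeHit", "GenomeIndex", "map_tags", "extract_flank", "MappedTag"]

DEFAULT_MAX_HITS = 100


@dataclass(frozen=True)
class GenomeHit:
    """Exact occurrence of a tag on one genome strand, 0-based half-open.

    Coordinates are always on the forward strand of the chromosome; for
    ``strand == "-"`` the tag equals the reverse complement of the forward
    substring at [start, end).
    """

    seq: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class MappedTag:
    """A unique tag together with its genome hits and a multi-mapping flag."""

    tag: UniqueTag
    hits: list[GenomeHit]
    multi_mapped: bool


class GenomeIndex:
    """Seed-and-verify exact-match index over a set of chromosomes."""

    def __init__(self, genome: Sequence[SequenceRecord], k: int = MIN_TAG_LEN):
        if k > MIN_TAG_LEN:
            raise ValueError(f"seed length {k} exceeds the minimum tag length {MIN_TAG_LEN}")
        self.k = k
        self.chroms = {rec.id: rec.seq for rec in genome}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in self.chroms.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i : i + k], []).append((cid, i))

    def find(self, query: str) -> list[GenomeHit]:
        """All exact full-length occurrences of *query* on both strands."""
        if len(query) < self.k:
            raise ValueError(f"query shorter than seed length {self.k}")
        hits: list[GenomeHit] = []
        n = len(query)
        for strand, q in (("+", query), ("-", revcomp(query))):
            for cid, pos in self._seeds.get(q[: self.k], ()):
                if self.chroms[cid][pos : pos + n] == q:
                    hits.append(GenomeHit(query, cid, pos, pos + n, strand))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def map_tags(
    tags: Sequence[UniqueTag],
    index: GenomeIndex,
    max_hits: int = DEFAULT_MAX_HITS,
) -> tuple[list[MappedTag], list[UniqueTag]]:
    """Map tags; returns (mapped, unmapped).

    Tags with more than *max_hits* genomic occurrences are flagged
    multi-mapped (kept for expression, excluded from hairpin prediction);
    tags with no exact hit are dropped from miRNA analysis.
    """
    mapped: list[MappedTag] = []
    unmapped: list[UniqueTag] = []
    for tag in tags:
        hits = index.find(tag.seq)
        if not hits:
            unmapped.append(tag)
        else:
            mapped.append(MappedTag(tag, hits, len(hits) > max_hits))
    return mapped, unmapped


def extract_flank(
    hit: GenomeHit,
    genome: GenomeIndex | Sequence[SequenceRecord],
    upstream: int,
    downstream: int,
) -> tuple[str, int, int]:
    """Genomic window around a hit, on the hit's strand.

    Upstream/downstream are relative to the tag's 5'→3' orientation;
    windows are clipped at chromosome bounds. Returns
    (window sequence, mature start, mature end) with the mature span given
    0-based within the window.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window sizes must be non-negative")
    chroms = genome.chroms if isinstance(genome, GenomeIndex) else {
        r.id: r.seq for r in genome
    }
    chrom = chroms[hit.chrom]
    if hit.strand == "+":
        lo = max(0, hit.start - upstream)
        hi = min(len(chrom), hit.end + downstream)
        window = chrom[lo:hi]
        m_start = hit.start - lo
    else:
        lo = max(0, hit.start - downstream)
        hi = min(len(chrom), hit.end + upstream)
        window = revcomp(chrom[lo:hi])
        m_start = hi - hit.end
    return window, m_start, m_start + (hit.end - hit.start)
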