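"""Degradome (PARE) target identification for miRNAs.

Degradome tags mark uncapped 5' ends of mRNA fragments. miRNA-guided
cleavage leaves a 5' end opposite miRNA position 10, so mapping tags by
their 5' ends produces a peak at the cleavage site. The module builds
per-transcript 5'-end profiles, scores miRNA:mRNA complementarity with the
plant pairing scheme (mismatch 1.0, G:U wobble 0.5, bulge 1.0, all doubled
at miRNA positions 2-13), keeps sites with score <= 4 and at least one raw
read at the predicted cleavage position, and grades each site into t-plot
categories 0-4 from the site's abundance relative to the transcript
profile. Site abundance is reported as tags per billion (tpb): weighted
reads x 10^9 / total raw reads of the library; a tag matching k positions
contributes weight 1/k to each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SequenceRecord
from .preprocess import trim_adapter

__all__ = [
    "DegradomeProfile",
    "DegradomeLibrary",
    "TranscriptIndex",
    "TargetAlignment",
    "TargetHit",
    "preprocess_degradome",
    "map_degradome",
    "align_mirna_target",
    "anchored_score",
    "cleavage_position",
    "categorize_site",
    "tpb",
    "find_targets",
    "MIN_DEG_TAG_LEN",
    "SCORE_MAX",
]

MIN_DEG_TAG_LEN = 15
SCORE_MAX = 4.0
CORE_START, CORE_END = 2, 13  # miRNA positions with doubled penalties

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}  # A-T, C-G


def _penalty_row(mir_base: int) -> np.ndarray:
    """Penalty of pairing one miRNA base against each transcript base."""
    row = np.ones(5)
    if mir_base < 4:
        row[_COMP[mir_base]] = 0.0
        if mir_base == 2:  # G pairs U(T) as wobble
            row[3] = 0.5
        elif mir_base == 3:  # U(T) pairs G as wobble
            row[2] = 0.5
    return row


def penalty_matrix(mirna_seq: str) -> np.ndarray:
    """(L, 5) penalty lookup with positional doubling at positions 2-13."""
    L = len(mirna_seq)
    M = np.empty((L, 5))
    for i, c in enumerate(mirna_seq):
        M[i] = _penalty_row(_ENC[c])
        if CORE_START <= i + 1 <= CORE_END:
            M[i] *= 2.0
    return M


def _bulge_penalty(mir_pos: int) -> float:
    """Penalty of one bulged nucleotide attributed to miRNA position *mir_pos*."""
    return 2.0 if CORE_START <= mir_pos <= CORE_END else 1.0


@dataclass
class DegradomeProfile:
    """Per-transcript 5'-end read profile for one library (positions 1-based)."""

    transcript_id: str
    length: int
    weights: dict[int, float] = field(default_factory=dict)
    raw: dict[int, int] = field(default_factory=dict)

    def add(self, pos: int, count: int, share: float) -> None:
        if not (1 <= pos <= self.length):
            raise ValueError(f"position {pos} outside transcript of length {self.length}")
        self.weights[pos] = self.weights.get(pos, 0.0) + count * share
        self.raw[pos] = self.raw.get(pos, 0) + count


@dataclass
class DegradomeLibrary:
    """All transcript profiles of one degradome library."""

    name: str
    raw_total: int  # raw sequenced reads (the tpb denominator)
    profiles: dict[str, DegradomeProfile] = field(default_factory=dict)
    mapped_reads: int = 0
    unmapped_reads: int = 0


def preprocess_degradome(
    reads: Iterable[SequenceRecord], adapter: str, min_len: int = MIN_DEG_TAG_LEN
) -> tuple[dict[str, int], int, int]:
    """Trim 3' adapters and drop tags shorter than *min_len*.

    Returns (tag -> count, raw read count, removed read count).
    """
    tags: dict[str, int] = {}
    raw = removed = 0
    for rec in reads:
        raw += 1
        insert = trim_adapter(rec.seq, adapter)
        if insert is None or len(insert) < min_len:
            removed += 1
            continue
        tags[insert] = tags.get(insert, 0) + 1
    return tags, raw, removed


class TranscriptIndex:
    """Exact sense-strand substring index over a transcriptome."""

    def __init__(self, transcripts: Sequence[SequenceRecord], k: int = MIN_DEG_TAG_LEN):
        self.k = k
        self.transcripts = {t.id: t.seq for t in transcripts}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.transcripts.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i : i + k], []).append((tid, i))

    def find(self, tag: str) -> list[tuple[str, int]]:
        """All (transcript, 0-based position) sense-strand occurrences."""
        hits = []
        for tid, pos in self._seeds.get(tag[: self.k], ()):
            if self.transcripts[tid][pos : pos + len(tag)] == tag:
                hits.append((tid, pos))
        return hits


def map_degradome(
    tag_counts: Mapping[str, int],
    index: TranscriptIndex,
    name: str,
    raw_total: int,
) -> DegradomeLibrary:
    """Map tags to the transcriptome and build 5'-end profiles.

    A tag matching k distinct positions contributes weight count/k at each
    5'-end position; the raw counter at each position gets the full count
    (category rules use raw reads, tpb uses weights).
    """
    lib = DegradomeLibrary(name, raw_total)
    for tag, count in tag_counts.items():
        hits = index.find(tag)
        if not hits:
            lib.unmapped_reads += count
            continue
        lib.mapped_reads += count
        share = 1.0 / len(hits)
        for tid, pos in hits:
            prof = lib.profiles.get(tid)
            if prof is None:
                prof = DegradomeProfile(tid, len(index.transcripts[tid]))
                lib.profiles[tid] = prof
            prof.add(pos + 1, count, share)
    return lib


@dataclass
class TargetAlignment:
    """A scored miRNA:transcript duplex anchored on the transcript."""

    mirna_name: str
    mirna_seq: str
    transcript_id: str
    score: float
    pairing: str  # per miRNA position: '|' pair, 'o' wobble, 'x' mismatch, '-' bulged
    config: tuple  # ("none",) | ("mbulge", k) | ("tbulge", k)
    t_anchor10: int  # 1-based transcript position paired with miRNA position 10


def anchored_score(mirna_enc: np.ndarray, M: np.ndarray, t_enc: np.ndarray, p: int) -> tuple[float, tuple]:
    """Best score of a duplex with miRNA position 10 opposite transcript position *p*.

    *p* is 1-based; configurations with <=1 bulge are enumerated (a bulge
    directly at position 10 is not considered — it would leave the cleavage
    site undefined). Returns (score, config).
    """
    L = len(mirna_enc)
    n = len(t_enc)

    def base(t: int) -> int:
        return int(t_enc[t - 1]) if 1 <= t <= n else 4

    # frames: A -> t = p+10-i ; C -> p+9-i ; D -> p+11-i
    A = np.array([M[i - 1, base(p + 10 - i)] for i in range(1, L + 1)])
    C = np.array([M[i - 1, base(p + 9 - i)] for i in range(1, L + 1)])
    D = np.array([M[i - 1, base(p + 11 - i)] for i in range(1, L + 1)])
    best = (float(A.sum()), ("none",))
    for k in range(1, L + 1):
        if k == 10:
            continue
        if k > 10:
            s = A[: k - 1].sum() + _bulge_penalty(k) + D[k:].sum()
        else:
            s = C[: k - 1].sum() + _bulge_penalty(k) + A[k:].sum()
        if s < best[0] - 1e-9:
            best = (float(s), ("mbulge", k))
    for k in range(1, L):
        if k >= 10:
            s = A[:k].sum() + _bulge_penalty(k + 1) + C[k:].sum()
        else:
            s = D[:k].sum() + _bulge_penalty(k + 1) + A[k:].sum()
        if s < best[0] - 1e-9:
            best = (float(s), ("tbulge", k))
    return best


def _pairing_string(mirna_enc: np.ndarray, t_enc: np.ndarray, p: int, config: tuple) -> str:
    L = len(mirna_enc)
    n = len(t_enc)
    sym = []
    for i in range(1, L + 1):
        t = _t_coord(i, p, config)
        if t is None:
            sym.append("-")
            continue
        if not (1 <= t <= n):
            sym.append("x")
            continue
        m, b = int(mirna_enc[i - 1]), int(t_enc[t - 1])
        if m < 4 and b == _COMP[m]:
            sym.append("|")
        elif (m, b) in ((2, 3), (3, 2)):
            sym.append("o")
        else:
            sym.append("x")
    return "".join(sym)


def _t_coord(i: int, p: int, config: tuple) -> int | None:
    """Transcript coordinate paired with miRNA position *i* (1-based), or None if bulged."""
    kind = config[0]
    if kind == "none":
        return p + 10 - i
    if kind == "mbulge":
        k = config[1]
        if i == k:
            return None
        if k > 10:
            return p + 10 - i if i < k else p + 11 - i
        return p + 9 - i if i < k else p + 10 - i
    k = config[1]  # tbulge between k and k+1
    if k >= 10:
        return p + 10 - i if i <= k else p + 9 - i
    return p + 11 - i if i <= k else p + 10 - i


def align_mirna_target(
    mirna_seq: str,
    window_seq: str,
    mirna_name: str = "",
    transcript_id: str = "",
) -> TargetAlignment:
    """Best-scoring duplex of a miRNA against a transcript window.

    All anchorings of the duplex within the window and all <=1-bulge
    configurations are searched; ties resolve to the leftmost transcript
    site (smallest position paired with miRNA position 10).
    """
    mir = np.array([_ENC[c] for c in mirna_seq], dtype=np.int8)
    t = np.array([_ENC[c] for c in window_seq], dtype=np.int8)
    M = penalty_matrix(mirna_seq)
    L = len(mir)
    best: tuple[float, int, tuple] | None = None
    # p = window position opposite miRNA position 10; every anchoring with
    # that position inside the window is searched (overhangs score as
    # mismatches)
    for p in range(1, len(t) + 1):
        score, config = anchored_score(mir, M, t, p)
        if best is None or score < best[0] - 1e-9:
            best = (score, p, config)
    if best is None:
        raise ValueError("window too short for any duplex placement")
    score, p, config = best
    return TargetAlignment(
        mirna_name, mirna_seq, transcript_id, round(score, 2),
        _pairing_string(mir, t, p, config), config, p,
    )


def cleavage_position(alignment: TargetAlignment) -> int:
    """1-based transcript position opposite miRNA position 10."""
    return alignment.t_anchor10


@dataclass
class TargetHit:
    """A validated miRNA -> transcript cleavage record."""

    mirna_name: str
    transcript_id: str
    score: float
    cleavage_site: int  # 1-based
    reads_at_site: dict[str, int]  # per library, raw
    weight_at_site: dict[str, float]
    tpb: dict[str, float]
    category: dict[str, int | None]  # None = absent in that library
    pairing: str = ""


def categorize_site(profile: DegradomeProfile, position: int) -> int | None:
    """t-plot category 0-4 of one site, or None when no read supports it.

    Raw read counts drive all comparisons; the median is taken over
    positions with at least one read.
    """
    r = profile.raw.get(position, 0)
    if r == 0:
        return None
    if r == 1:
        return 4
    counts = np.array(list(profile.raw.values()))
    mx = counts.max()
    med = float(np.median(counts))
    if r == mx:
        return 0 if (counts == mx).sum() == 1 else 1
    return 2 if r > med else 3


def tpb(weighted_reads: float, library_raw_total: int) -> float:
    """Tags per billion: weighted reads x 10^9 / total raw library reads."""
    if library_raw_total <= 0:
        raise ValueError("library raw total must be positive")
    return weighted_reads * 1e9 / library_raw_total


def find_targets(
    mirnas: Sequence[tuple[str, str]],
    libraries: Sequence[DegradomeLibrary],
    transcripts: Sequence[SequenceRecord],
    score_max: float = SCORE_MAX,
) -> list[TargetHit]:
    """Scan degradome peaks for miRNA cleavage sites.

    *mirnas* is (name, sequence) pairs. For every transcript position with
    >=1 raw read in >=1 library, the duplex anchored with miRNA position 10
    at that site is scored (vectorized over peaks); sites with score <=
    *score_max* are emitted with per-library raw reads, tpb and category.
    Output sorted by (miRNA, transcript, position).
    """
    seqs = {t.id: np.array([_ENC[c] for c in t.seq], dtype=np.int8) for t in transcripts}
    peaks: dict[str, np.ndarray] = {}
    for tid in seqs:
        pos: set[int] = set()
        for lib in libraries:
            prof = lib.profiles.get(tid)
            if prof:
                pos.update(p for p, r in prof.raw.items() if r >= 1)
        if pos:
            peaks[tid] = np.array(sorted(pos))

    hits: list[TargetHit] = []
    for name, mseq in mirnas:
        mir = np.array([_ENC[c] for c in mseq], dtype=np.int8)
        M = penalty_matrix(mseq)
        L = len(mir)
        i_arr = np.arange(1, L + 1)
        bulge_pen = np.array([_bulge_penalty(k) for k in range(0, L + 2)])
        for tid, parr in peaks.items():
            t_enc = seqs[tid]
            n = len(t_enc)
            padded = np.full(n + 2 * (L + 12), 4, dtype=np.int8)
            off = L + 12
            padded[off : off + n] = t_enc
            # frames A/C/D: transcript base opposite miRNA position i
            idxA = parr[:, None] + (10 - i_arr)[None, :] - 1 + off
            A = M[i_arr - 1, padded[idxA]]
            Cf = M[i_arr - 1, padded[idxA - 1]]
            Df = M[i_arr - 1, padded[idxA + 1]]
            score0 = A.sum(axis=1)
            cumA = np.cumsum(A, axis=1)
            # miRNA bulge at k (k != 10)
            sufD = np.cumsum(Df[:, ::-1], axis=1)[:, ::-1]
            preC = np.cumsum(Cf, axis=1)
            m_scores = np.full((len(parr), L), np.inf)
            for k in range(1, L + 1):
                if k == 10:
                    continue
                if k > 10:
                    pre = cumA[:, k - 2] if k >= 2 else 0.0
                    suf = sufD[:, k] if k < L else 0.0
                else:
                    pre = preC[:, k - 2] if k >= 2 else 0.0
                    suf = cumA[:, L - 1] - cumA[:, k - 1]
                m_scores[:, k - 1] = pre + bulge_pen[k] + suf
            # transcript bulge between k and k+1
            sufC = np.cumsum(Cf[:, ::-1], axis=1)[:, ::-1]
            preD = np.cumsum(Df, axis=1)
            t_scores = np.full((len(parr), L), np.inf)
            for k in range(1, L):
                if k >= 10:
                    pre = cumA[:, k - 1]
                    suf = sufC[:, k]
                else:
                    pre = preD[:, k - 1]
                    suf = cumA[:, L - 1] - cumA[:, k - 1]
                t_scores[:, k - 1] = pre + bulge_pen[k + 1] + suf
            total = np.minimum(score0, np.minimum(m_scores.min(axis=1), t_scores.min(axis=1)))
            for pi in np.nonzero(total <= score_max + 1e-9)[0]:
                p = int(parr[pi])
                score, config = anchored_score(mir, M, t_enc, p)
                if score > score_max + 1e-9:
                    continue
                reads = {}
                weights = {}
                tpbs = {}
                cats: dict[str, int | None] = {}
                for lib in libraries:
                    prof = lib.profiles.get(tid)
                    r = prof.raw.get(p, 0) if prof else 0
                    w = prof.weights.get(p, 0.0) if prof else 0.0
                    reads[lib.name] = r
                    weights[lib.name] = w
                    tpbs[lib.name] = round(tpb(w, lib.raw_total), 2)
                    cats[lib.name] = categorize_site(prof, p) if prof else None
                if all(r == 0 for r in reads.values()):
                    continue
                hits.append(
                    TargetHit(
                        name, tid, round(float(score), 2), p, reads, weights, tpbs, cats,
                        pairing=_pairing_string(mir, t_enc, p, config),
                    )
                )
    hits.sort(key=lambda h: (h.mirna_name, h.transcript_id, h.cleavage_site))
    return hits
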