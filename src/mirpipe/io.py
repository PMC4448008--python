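"""Readers and writers for the standard formats the pipeline touches.

Sequences are held as plain uppercase DNA-alphabet strings: U is converted
to T on input so miRBase-style RNA references and genomic DNA live in one
alphabet. All internal coordinates are 0-based half-open; positions printed
in result tables (cleavage sites, substitution offsets) are 1-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Placement",
    "MirnaReference",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "load_reference",
    "read_structures",
    "write_table",
    "read_table",
    "write_bed",
    "revcomp",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file (message names the offending record/line)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str, where: str) -> str:
    s = seq.upper().replace("U", "T")
    if not s:
        raise ParseError(f"empty sequence for {where}")
    bad = set(s) - _VALID
    if bad:
        raise ParseError(f"invalid characters {sorted(bad)} in {where}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N} (U normalized to T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        object.__setattr__(self, "seq", _normalize(self.seq, f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Placement:
    """Location of a mature miRNA on its precursor, 0-based half-open."""

    mature_id: str
    precursor_id: str
    start: int
    end: int
    arm: str  # "5p" or "3p"


@dataclass
class MirnaReference:
    """miRBase-style reference: precursors, matures, and their placements."""

    precursors: list[SequenceRecord]
    matures: list[SequenceRecord]
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._prec = {r.id: r for r in self.precursors}
        self._mat = {r.id: r for r in self.matures}
        self._by_prec: dict[str, list[Placement]] = {}
        for p in self.placements:
            self._validate(p)
            self._by_prec.setdefault(p.precursor_id, []).append(p)

    def _validate(self, p: Placement) -> None:
        prec = self._prec.get(p.precursor_id)
        mat = self._mat.get(p.mature_id)
        if prec is None:
            raise ParseError(f"placement references unknown precursor {p.precursor_id!r}")
        if mat is None:
            raise ParseError(f"placement references unknown mature {p.mature_id!r}")
        if prec.seq[p.start : p.end] != mat.seq:
            raise ParseError(
                f"mature {p.mature_id!r} does not equal precursor "
                f"{p.precursor_id!r}[{p.start}:{p.end}]"
            )
        mid = len(prec.seq) / 2
        center = (p.start + p.end) / 2
        expected = "5p" if center < mid else "3p"
        if p.arm not in ("5p", "3p"):
            raise ParseError(f"placement arm {p.arm!r} must be 5p or 3p")
        if p.arm != expected:
            raise ParseError(
                f"placement of {p.mature_id!r} labelled {p.arm} but sits on the "
                f"{expected} side of precursor {p.precursor_id!r}"
            )

    def precursor(self, pid: str) -> SequenceRecord:
        return self._prec[pid]

    def mature(self, mid: str) -> SequenceRecord:
        return self._mat[mid]

    def placements_on(self, precursor_id: str) -> list[Placement]:
        return self._by_prec.get(precursor_id, [])


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file; duplicate ids are a hard error."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA header without an id")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line FASTQ file. Qualities are only format-checked."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            sep = fh.readline()
            qual = fh.readline()
            idx += 1
            if not qual:
                raise ParseError(f"{path}: truncated FASTQ record #{idx}")
            if not header.startswith("@"):
                raise ParseError(f"{path}: record #{idx} header does not start with '@'")
            if not sep.startswith("+"):
                raise ParseError(f"{path}: record #{idx} separator line is not '+'")
            seq = seq.strip()
            if len(seq) != len(qual.strip()):
                raise ParseError(f"{path}: record #{idx} sequence/quality length mismatch")
            name = header[1:].strip().split()[0] or f"read{idx}"
            yield SequenceRecord(name, seq)


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")


def load_reference(
    precursor_fasta: str | Path,
    mature_fasta: str | Path,
    placement_table: str | Path | None = None,
) -> MirnaReference:
    """Assemble a miRBase-style reference.

    The placement table is TSV with columns
    (mature_id, precursor_id, start, end[, arm]); coordinates 0-based
    half-open. Matures lacking a placement row are located by exact
    substring search over all precursors — a unique occurrence is adopted,
    ambiguity (or absence) is an error.
    """
    precursors = read_fasta(precursor_fasta)
    matures = read_fasta(mature_fasta)
    placements: list[Placement] = []
    placed: set[str] = set()
    if placement_table is not None:
        with open(placement_table) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "mature_id":
                    continue
                mid, pid, start, end = row[0], row[1], int(row[2]), int(row[3])
                arm = row[4] if len(row) > 4 and row[4] else _infer_arm(
                    precursors, pid, start, end
                )
                placements.append(Placement(mid, pid, start, end, arm))
                placed.add(mid)
    prec_by_id = {r.id: r for r in precursors}
    for mat in matures:
        if mat.id in placed:
            continue
        hits = []
        for prec in precursors:
            pos = prec.seq.find(mat.seq)
            while pos != -1:
                hits.append((prec.id, pos))
                pos = prec.seq.find(mat.seq, pos + 1)
        if not hits:
            raise ParseError(f"mature {mat.id!r} not found on any precursor")
        if len(hits) > 1:
            raise ParseError(
                f"mature {mat.id!r} occurs at {len(hits)} precursor positions; "
                "an explicit placement row is required"
            )
        pid, pos = hits[0]
        arm = _arm_of(len(prec_by_id[pid].seq), pos, pos + len(mat.seq))
        placements.append(Placement(mat.id, pid, pos, pos + len(mat.seq), arm))
    return MirnaReference(precursors, matures, placements)


def _arm_of(prec_len: int, start: int, end: int) -> str:
    return "5p" if (start + end) / 2 < prec_len / 2 else "3p"


def _infer_arm(precursors: list[SequenceRecord], pid: str, start: int, end: int) -> str:
    for p in precursors:
        if p.id == pid:
            return _arm_of(len(p.seq), start, end)
    raise ParseError(f"placement references unknown precursor {pid!r}")


def read_structures(path: str | Path) -> dict[str, tuple[str, float]]:
    """Read precomputed secondary structures.

    Format: three lines per entry — ``>id``, sequence (ignored beyond length
    checking), and a dot-bracket line ending with the free energy in
    parentheses, e.g. ``((((...)))) (-17.40)``.
    """
    out: dict[str, tuple[str, float]] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ParseError(f"{path}: expected '>' header at line {i + 1}")
        name = lines[i][1:].strip()
        seq = lines[i + 1].strip()
        struct_line = lines[i + 2].strip()
        try:
            struct, energy = struct_line.rsplit(None, 1)
            e = float(energy.strip("()"))
        except ValueError as exc:
            raise ParseError(f"{path}: malformed structure line {i + 3}") from exc
        if len(struct) != len(seq):
            raise ParseError(f"{path}: structure/sequence length mismatch for {name!r}")
        out[name] = (struct, e)
        i += 3
    return out


def write_table(
    records: Sequence[dict],
    path: str | Path,
    schema: Sequence[str],
    float_cols: Sequence[str] = (),
    header_comment: str | None = None,
) -> None:
    """Write dict records as TSV with a fixed column schema.

    Columns named in *float_cols* (tpb-style quantities) print with two
    decimals. A missing schema field in any record is an error.
    """
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(schema) + "\n")
        for i, rec in enumerate(records):
            vals = []
            for col in schema:
                if col not in rec:
                    raise ValueError(f"record #{i} missing schema field {col!r}")
                v = rec[col]
                if col in float_cols and v is not None and v != "":
                    vals.append(f"{float(v):.2f}")
                else:
                    vals.append("" if v is None else str(v))
            fh.write("\t".join(vals) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read back a TSV written by :func:`write_table` (values as strings)."""
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(dict(zip(header, line.split("\t"))))
    return rows


def write_bed(hits: Iterable, path: str | Path) -> None:
    """Export genome hits as 6-column BED (0-based half-open, strand column)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.seq}\t0\t{h.strand}\n")
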