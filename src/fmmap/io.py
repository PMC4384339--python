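"""Readers and writers: FASTA/FASTQ in, TSV and minimal SAM out.

Sequence parsing goes through Biopython's SeqIO with transparent gzip
support. Mapping output is TSV-first (read id, record, 0-based position,
strand, error count, compact edit grammar); SAM is a best-effort minimal
dialect (mandatory columns plus an NM tag, 1-based positions, CIGAR derived
from the edit list with M for matches and X for mismatches).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .index import FMIndex
from .tree import Mapping

TSV_HEADER = "#read_id\trecord\tposition\tstrand\tn_errors\tedits"

VALID_READ = set("ACGTN")


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        bad = set(self.sequence.upper()) - VALID_READ
        if bad:
            raise ValueError(f"read {self.id!r} has symbols outside ACGTN: {sorted(bad)}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[tuple[str, str]]:
    """All (name, sequence) pairs of a FASTA file (optionally gzipped)."""
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream reads from FASTQ (optionally gzipped); constant memory."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )


def read_sequences(path) -> Iterator[ReadRecord]:
    """Reads from FASTA or FASTQ, sniffed from the first character."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        yield from read_fastq(path)
    elif first == ">":
        for name, seq in read_fasta(path):
            yield ReadRecord(name, seq)
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ")


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = getattr(r, "quality", None) or "I" * len(r.sequence)
            fh.write(f"@{r.read_id if hasattr(r, 'read_id') else r.id}\n"
                     f"{r.sequence}\n+\n{qual}\n")


def cigar_from_edits(read_length: int, edits: tuple) -> str:
    """CIGAR string for a canonical edit list.

    Conventions follow the read-vs-reference view: a mapper insertion (extra
    reference base) consumes reference only -> CIGAR D; a mapper deletion
    (skipped read base) consumes read only -> CIGAR I; mismatches are X,
    matches M. The M/I/X counts sum to the read length.
    """
    by_pos: dict[int, list] = {}
    for pos, kind, base in edits:
        by_pos.setdefault(pos, []).append(kind)
    ops: list[str] = []
    for pos in range(read_length + 1):
        kinds = by_pos.get(pos, [])
        ops.extend("D" for k in kinds if k == "I")  # inserted ref base(s) first
        if pos == read_length:
            break
        point = [k for k in kinds if k != "I"]
        if not point:
            ops.append("M")
        elif point[0] == "M":
            ops.append("X")
        else:  # read base skipped
            ops.append("I")
    # run-length encode
    out = []
    run, count = ops[0], 1
    for o in ops[1:]:
        if o == run:
            count += 1
        else:
            out.append(f"{count}{run}")
            run, count = o, 1
    out.append(f"{count}{run}")
    return "".join(out)


def parse_edit_string(s: str) -> tuple:
    """Inverse of the compact edit grammar (for round-tripping TSV output)."""
    from .index import _CODE

    if s == ".":
        return ()
    ops = []
    for part in s.split(","):
        pos, rest = part.split(":")
        kind = rest[0]
        base = _CODE[rest[2]] if kind != "D" else 0
        ops.append((int(pos), kind, base))
    return tuple(ops)


def _resolved(index: FMIndex, mappings: Iterable[Mapping]):
    for m in mappings:
        rec = index.record_at(m.position, m.ref_span)
        if rec is not None:
            yield rec[0], rec[1], m


def write_mappings_tsv(index: FMIndex, mappings, path, reads=None) -> None:
    rows = sorted(
        _resolved(index, mappings),
        key=lambda t: (t[2].n_errors, t[0], t[1], t[2].read_id, t[2].edits),
    )
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for rname, offset, m in rows:
            fh.write(
                f"{m.read_id}\t{rname}\t{offset}\t{m.strand}\t{m.n_errors}\t{m.edit_string}\n"
            )


def write_mappings_sam(index: FMIndex, mappings, path, reads: dict | None = None) -> None:
    """Minimal SAM: mandatory columns, NM tag. ``reads`` maps read id to a
    ReadRecord so SEQ/QUAL can be filled; otherwise placeholders are used."""
    reads = reads or {}
    rows = sorted(
        _resolved(index, mappings),
        key=lambda t: (t[2].n_errors, t[0], t[1], t[2].read_id, t[2].edits),
    )
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rec in index.records:
            fh.write(f"@SQ\tSN:{rec.name}\tLN:{rec.length}\n")
        fh.write("@PG\tID:fmmap\tPN:fmmap\n")
        for rname, offset, m in rows:
            rr = reads.get(m.read_id)
            seq = rr.sequence if rr else "*"
            qual = (rr.quality or "*") if rr else "*"
            read_len = len(rr.sequence) if rr else m.ref_span + sum(
                1 for _, k, _ in m.edits if k == "D"
            ) - sum(1 for _, k, _ in m.edits if k == "I")
            cigar = cigar_from_edits(read_len, m.edits)
            flag = 16 if m.strand == "-" else 0
            fh.write(
                f"{m.read_id}\t{flag}\t{rname}\t{offset + 1}\t255\t{cigar}"
                f"\t*\t0\t0\t{seq}\t{qual}\tNM:i:{m.n_errors}\n"
            )


def write_mappings(index: FMIndex, mappings, path, format: str = "tsv", reads=None) -> None:
    if format == "tsv":
        write_mappings_tsv(index, mappings, path, reads)
    elif format == "sam":
        write_mappings_sam(index, mappings, path, reads)
    else:
        raise ValueError(f"unknown mapping format {format!r}")


def write_truth_table(truths, path) -> None:
    """Truth TSV mirroring the mapper's output grammar for direct diffing."""
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\tref\t{t.position}\t{t.strand}\t{t.n_errors}\t{t.edit_string}\n"
            )
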