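"""Readers and writers for the plain-text formats the pipeline speaks:
FASTQ (Phred+33, optionally gzipped), FASTA, SAM text and a minimal VCF.

All coordinates are 0-based half-open in memory and converted to 1-based
only when SAM or VCF lines are emitted.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .dna import revcomp, validate_iupac_sequence, validate_read_sequence

GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class Read:
    """A sequencing read with Phred qualities.

    ``mate`` is one of ``"R1"``, ``"R2"`` or ``"unpaired"``.
    """

    id: str
    sequence: str
    qualities: list[int]
    mate: str = "unpaired"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        validate_read_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SeqRecord:
    """A named sequence over the IUPAC alphabet (gaps allowed)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        validate_iupac_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MappedRead:
    """A read placed on a reference locus.

    ``start`` is the 0-based leftmost reference coordinate; SAM emission
    adds 1. ``cigar`` uses M/I/D/S operations against the reference
    orientation; ``sequence``/``qualities`` are stored in original read
    orientation and flipped on output for reverse-strand placements.
    """

    read_id: str
    locus_id: str
    start: int
    strand: str  # '+' or '-'
    cigar: str
    edit_distance: int
    sequence: str
    qualities: list[int]
    is_duplicate: bool = False
    mate: str = "unpaired"
    fragment_id: str = ""  # shared by the two mates of a pair

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("mapped read start must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.fragment_id:
            self.fragment_id = self.read_id

    def reference_span(self) -> int:
        """Reference bases consumed by the CIGAR (M and D ops)."""
        return sum(n for n, op in iter_cigar(self.cigar) if op in "MD")

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (reference position, read offset) for every M column.

        Read offsets refer to the reference-oriented read sequence
        (i.e. reverse-complemented when strand is '-').
        """
        rpos = self.start
        qpos = 0
        for n, op in iter_cigar(self.cigar):
            if op == "M":
                for i in range(n):
                    yield rpos + i, qpos + i
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            elif op in "IS":
                qpos += n

    def oriented_sequence(self) -> str:
        return self.sequence if self.strand == "+" else revcomp(self.sequence)

    def oriented_qualities(self) -> list[int]:
        return self.qualities if self.strand == "+" else self.qualities[::-1]


def iter_cigar(cigar: str) -> Iterator[tuple[int, str]]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            yield int(num), ch
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")


def _open_text_read(path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _open_text_write(path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        # mtime=0 keeps gzip output byte-stable across reruns
        return _io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))
    return open(path, "wt")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path, mate: str = "unpaired") -> Iterator[Read]:
    """Stream Reads from a (possibly gzipped) Phred+33 FASTQ file.

    Malformed records raise ValueError naming the 1-based record index.
    """
    handle = _open_text_read(path)
    index = 0
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record {index + 1}: {exc}") from exc
            index += 1
            read_id = title.split()[0] if title else ""
            quals = [ord(c) - 33 for c in qual]
            if any(q < 0 or q > 93 for q in quals):
                raise ValueError(
                    f"{path}: record {index}: quality character outside Phred+33 range"
                )
            try:
                yield Read(read_id, seq.upper(), quals, mate)
            except ValueError as exc:
                raise ValueError(f"{path}: record {index}: {exc}") from exc
    finally:
        handle.close()


def write_fastq(reads: Iterable[Read], path) -> None:
    with _open_text_write(path) as out:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            out.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Iterator[SeqRecord]:
    """Stream SeqRecords; duplicate ids within one file are an error."""
    seen: set[str] = set()
    handle = _open_text_read(path)
    try:
        header: str | None = None
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield _fasta_record(header, chunks, seen, path)
                header = line[1:].split()[0]
                chunks = []
            elif line:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first '>' header")
                chunks.append(line)
        if header is not None:
            yield _fasta_record(header, chunks, seen, path)
    finally:
        handle.close()


def _fasta_record(header: str, chunks: list[str], seen: set[str], path) -> SeqRecord:
    if header in seen:
        raise ValueError(f"{path}: duplicate FASTA id {header!r}")
    seen.add(header)
    try:
        return SeqRecord(header, "".join(chunks).upper())
    except ValueError as exc:
        raise ValueError(f"{path}: record {header!r}: {exc}") from exc


FASTA_WRAP = 80


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    with _open_text_write(path) as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, max(len(seq), 1), FASTA_WRAP):
                out.write(seq[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# SAM

FLAG_REVERSE = 0x10
FLAG_DUPLICATE = 0x400


def write_sam(records: Iterable[MappedRead], locus_lengths: dict[str, int], path) -> None:
    """Emit SAM 1.6 text, coordinate-sorted within each locus.

    Every record's locus must appear in ``locus_lengths``; strand and
    duplicate status are encoded in FLAG, edit distance in the NM tag.
    """
    records = list(records)
    for rec in records:
        if rec.locus_id not in locus_lengths:
            raise ValueError(f"mapped read {rec.read_id!r} references undeclared locus {rec.locus_id!r}")
        if rec.start + rec.reference_span() > locus_lengths[rec.locus_id]:
            raise ValueError(
                f"read {rec.read_id!r} overhangs locus {rec.locus_id!r} "
                f"({rec.start} + {rec.reference_span()} > {locus_lengths[rec.locus_id]})"
            )
    records.sort(key=lambda r: (r.locus_id, r.start, r.read_id))
    with _open_text_write(path) as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for locus in sorted(locus_lengths):
            out.write(f"@SQ\tSN:{locus}\tLN:{locus_lengths[locus]}\n")
        for rec in records:
            flag = 0
            if rec.strand == "-":
                flag |= FLAG_REVERSE
            if rec.is_duplicate:
                flag |= FLAG_DUPLICATE
            seq = rec.oriented_sequence()
            qual = "".join(chr(q + 33) for q in rec.oriented_qualities())
            out.write(
                f"{rec.read_id}\t{flag}\t{rec.locus_id}\t{rec.start + 1}\t60\t"
                f"{rec.cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{rec.edit_distance}\n"
            )


def read_sam(path) -> tuple[dict[str, int], list[MappedRead]]:
    """Parse SAM text written by :func:`write_sam` back into records."""
    lengths: dict[str, int] = {}
    records: list[MappedRead] = []
    with _open_text_read(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("@SQ"):
                fields = dict(f.split(":", 1) for f in line.split("\t")[1:])
                lengths[fields["SN"]] = int(fields["LN"])
                continue
            if line.startswith("@") or not line:
                continue
            cols = line.split("\t")
            flag = int(cols[1])
            strand = "-" if flag & FLAG_REVERSE else "+"
            nm = 0
            for tag in cols[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            seq = cols[9]
            quals = [ord(c) - 33 for c in cols[10]]
            if strand == "-":
                seq = revcomp(seq)
                quals = quals[::-1]
            records.append(
                MappedRead(
                    read_id=cols[0],
                    locus_id=cols[2],
                    start=int(cols[3]) - 1,
                    strand=strand,
                    cigar=cols[5],
                    edit_distance=nm,
                    sequence=seq,
                    qualities=quals,
                    is_duplicate=bool(flag & FLAG_DUPLICATE),
                )
            )
    return lengths, records


# ---------------------------------------------------------------------------
# VCF


def write_vcf(sites, path) -> None:
    """Write variant sites as minimal VCF 4.2.

    ``sites`` is an iterable of objects with attributes ``locus_id``,
    ``position`` (0-based; emitted 1-based), ``ref_base`` and ``alleles``
    (ordered list of (base, depth) with the reference allele first when
    present).
    """
    sites = sorted(sites, key=lambda s: (s.locus_id, s.position))
    with _open_text_write(path) as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        out.write('##INFO=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref first)">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site in sites:
            alts = [(b, d) for b, d in site.alleles if b != site.ref_base]
            ref_depth = sum(d for b, d in site.alleles if b == site.ref_base)
            depth = sum(d for _, d in site.alleles)
            alt_field = ",".join(b for b, _ in alts) if alts else "."
            ad = ",".join(str(d) for d in [ref_depth] + [d for _, d in alts])
            out.write(
                f"{site.locus_id}\t{site.position + 1}\t.\t{site.ref_base}\t"
                f"{alt_field}\t.\tPASS\tDP={depth};AD={ad}\n"
            )


def validate_sam_line(line: str, locus_lengths: dict[str, int]) -> bool:
    """Field-count and coordinate-range check for one alignment line."""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 11:
        return False
    pos = int(cols[3])
    locus = cols[2]
    if locus not in locus_lengths or pos < 1:
        return False
    span = sum(n for n, op in iter_cigar(cols[5]) if op in "MD")
    return pos - 1 + span <= locus_lengths[locus]
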