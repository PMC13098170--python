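"""Readers for read-mapping output against a multi-contig reference genome.

Two input dialects are supported: the 12-column tabular alignment format
written by ``blastn -outfmt 6`` (and compatible mappers) and SAM. Both are
normalized into :class:`AlignmentRecord` objects using a single internal
coordinate convention — 0-based, half-open intervals on the reference — so
that downstream depth/breadth arithmetic never has to reason about strand
or 1-based inclusiveness again.

The genome (possibly many contigs) is the unit of analysis: records from all
contigs of one reference are pooled, and :class:`ReferenceIndex` carries the
contig lengths whose sum is the denominator of depth and breadth.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import pysam
from Bio import SeqIO

__all__ = [
    "AlignmentRecord",
    "ReferenceIndex",
    "AlignmentParseError",
    "parse_blast_tabular",
    "parse_sam",
    "write_blast_tabular",
    "best_hit_per_read",
    "load_reference_index",
    "DEFAULT_IDENTITY_FLOOR",
]

#: Alignments below this percent identity are discarded on input. Typical
#: recruitment plots span 70–100% identity; hits below that range carry no
#: signal about the target population.
DEFAULT_IDENTITY_FLOOR = 70.0


class AlignmentParseError(ValueError):
    """Raised for malformed alignment input (with line/record context)."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's best alignment to the reference.

    Coordinates are 0-based, half-open on the reference contig. ``bitscore``
    is in the score units of the source format (bit score for tabular BLAST,
    alignment score ``AS`` for SAM, 0 when absent).
    """

    read_id: str
    contig_id: str
    identity: float  # percent in [0, 100]
    aln_length: int  # alignment columns (including indel columns)
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"empty reference interval [{self.ref_start}, {self.ref_end}) "
                f"for read {self.read_id!r}"
            )
        if self.aln_length <= 0:
            raise ValueError(f"non-positive alignment length for {self.read_id!r}")


@dataclass(frozen=True)
class ReferenceIndex:
    """Contig lengths of one reference genome (MAG or isolate assembly)."""

    genome_id: str
    contig_lengths: dict[str, int]

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths.values())

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.contig_lengths

    def validate_record(self, record: AlignmentRecord, context: str = "") -> None:
        """Check a record's interval against the contig bounds."""
        length = self.contig_lengths.get(record.contig_id)
        if length is None:
            raise AlignmentParseError(
                f"{context}contig {record.contig_id!r} not present in reference "
                f"{self.genome_id!r}"
            )
        if record.ref_end > length:
            raise AlignmentParseError(
                f"{context}alignment [{record.ref_start}, {record.ref_end}) exceeds "
                f"length {length} of contig {record.contig_id!r}"
            )


def load_reference_index(
    source: Union[str, Path, TextIO], genome_id: str | None = None
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from a FASTA file or handle."""
    if isinstance(source, (str, Path)):
        name = Path(source).stem
        handle: TextIO = open(source)
        close = True
    else:
        name = getattr(source, "name", "reference")
        handle, close = source, False
    lengths: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in lengths:
                raise AlignmentParseError(f"duplicate contig id {rec.id!r} in FASTA")
            lengths[rec.id] = len(rec.seq)
    finally:
        if close:
            handle.close()
    if not lengths:
        raise AlignmentParseError("reference FASTA contains no sequences")
    return ReferenceIndex(genome_id=genome_id or str(name), contig_lengths=lengths)


def _iter_lines(source: Union[str, Path, TextIO, Iterable[str]]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            yield from handle
    else:
        yield from source


def parse_blast_tabular(
    source: Union[str, Path, TextIO, Iterable[str]],
    reference: ReferenceIndex | None = None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> list[AlignmentRecord]:
    """Parse 12-column tabular alignments (``blastn -outfmt 6`` dialect).

    Column order is query, subject, pident, length, mismatch, gapopen,
    qstart, qend, sstart, send, evalue, bitscore. Lines starting with ``#``
    and blank lines are ignored. Subject coordinates are 1-based inclusive;
    minus-strand hits (sstart > send) are normalized by swapping before the
    conversion to 0-based half-open. Hits below ``identity_floor`` are
    dropped. When ``reference`` is given, every interval is checked against
    the contig bounds.
    """
    records: list[AlignmentRecord] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            fields = line.split()
        if len(fields) < 12:
            raise AlignmentParseError(
                f"line {lineno}: expected >=12 tab-separated fields, got {len(fields)}"
            )
        try:
            identity = float(fields[2])
            aln_length = int(fields[3])
            sstart = int(fields[8])
            send = int(fields[9])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise AlignmentParseError(f"line {lineno}: non-numeric field ({exc})") from exc
        if sstart > send:  # minus strand: normalize, strand is not retained
            sstart, send = send, sstart
        if identity < identity_floor:
            continue
        record = AlignmentRecord(
            read_id=fields[0],
            contig_id=fields[1],
            identity=identity,
            aln_length=aln_length,
            ref_start=sstart - 1,
            ref_end=send,
            bitscore=bitscore,
        )
        if reference is not None:
            reference.validate_record(record, context=f"line {lineno}: ")
        records.append(record)
    return records


def write_blast_tabular(
    records: Iterable[AlignmentRecord], dest: Union[str, Path, TextIO]
) -> None:
    """Write records back to the 12-column tabular dialect.

    Mismatch, gap and query columns are reconstructed to be internally
    consistent with the identity and alignment length; coordinates are
    emitted on the plus strand.
    """
    if isinstance(dest, (str, Path)):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        for r in records:
            mismatch = round((1.0 - r.identity / 100.0) * r.aln_length)
            handle.write(
                "\t".join(
                    [
                        r.read_id,
                        r.contig_id,
                        f"{r.identity:.2f}",
                        str(r.aln_length),
                        str(mismatch),
                        "0",
                        "1",
                        str(r.aln_length),
                        str(r.ref_start + 1),
                        str(r.ref_end),
                        "1e-99",
                        f"{r.bitscore:g}",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# CIGAR operation codes that consume alignment columns: M, I, D, =, X
_ALIGNED_COLUMN_OPS = {0, 1, 2, 7, 8}


def parse_sam(
    source: Union[str, Path],
    reference: ReferenceIndex | None = None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> list[AlignmentRecord]:
    """Parse mapped primary alignments from a SAM (or BAM) file.

    Percent identity is computed from the edit distance (``NM`` tag) over all
    aligned columns (CIGAR M/=/X/I/D): ``100 * (columns - NM) / columns``.
    Unmapped, secondary and supplementary records are skipped. Mapped records
    lacking ``NM`` are skipped with a warning tally; the parse fails only if
    every mapped record lacks it.
    """
    records: list[AlignmentRecord] = []
    n_mapped = 0
    n_missing_nm = 0
    save = pysam.set_verbosity(0)  # silence missing-index chatter
    try:
        with pysam.AlignmentFile(str(source), check_sq=False) as sam:
            for aln in sam.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                n_mapped += 1
                if not aln.has_tag("NM"):
                    n_missing_nm += 1
                    continue
                columns = sum(
                    length
                    for op, length in (aln.cigartuples or [])
                    if op in _ALIGNED_COLUMN_OPS
                )
                if columns <= 0:
                    n_missing_nm += 1
                    continue
                nm = int(aln.get_tag("NM"))
                identity = 100.0 * (columns - nm) / columns
                if identity < identity_floor:
                    continue
                record = AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    identity=identity,
                    aln_length=columns,
                    ref_start=aln.reference_start,
                    ref_end=aln.reference_end,
                    bitscore=float(aln.get_tag("AS")) if aln.has_tag("AS") else 0.0,
                )
                if reference is not None:
                    reference.validate_record(record, context=f"read {aln.query_name!r}: ")
                records.append(record)
    finally:
        pysam.set_verbosity(save)
    if n_missing_nm:
        if n_mapped == n_missing_nm:
            raise AlignmentParseError(
                "every mapped SAM record lacks the NM edit-distance tag; "
                "identity cannot be computed"
            )
        warnings.warn(
            f"{n_missing_nm} of {n_mapped} mapped records lacked an NM tag "
            "and were skipped",
            stacklevel=2,
        )
    return records


def best_hit_per_read(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep exactly one alignment per read id.

    Selection is by highest bitscore, ties broken by higher identity, then
    longer alignment, then first seen (stable). Output order follows the
    first occurrence of each read id.
    """
    best: dict[str, AlignmentRecord] = {}
    for record in records:
        incumbent = best.get(record.read_id)
        if incumbent is None:
            best[record.read_id] = record
            continue
        challenger_key = (record.bitscore, record.identity, record.aln_length)
        incumbent_key = (incumbent.bitscore, incumbent.identity, incumbent.aln_length)
        if challenger_key > incumbent_key:
            best[record.read_id] = record
    return list(best.values())
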