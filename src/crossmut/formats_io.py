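"""Readers and writers for FASTA assemblies and samtools mpileup text.

This is the only module that touches raw text formats. FASTA parsing is
delegated to Bio.SeqIO; the mpileup read-base grammar is decoded by a small
character machine because no installed library parses mpileup *text* (pileup
objects in pysam are generated from BAM, which is out of scope here).

Coordinate convention: mpileup positions are 1-based and fully closed, and
every internal position in this package stays 1-based. Positions absent from
an mpileup file are depth 0 (samtools omits zero-depth positions by default).
Base-quality and mapping-quality strings are parsed but ignored: all
downstream filters operate on base counts only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, NamedTuple, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IntegrityError, ParseError, ValidationError

FASTA_WRAP = 80

#: counts-dict key for deleted bases ("*" in mpileup)
DELETION = "*"
#: counts-dict key for everything that is neither A/C/G/T nor a deletion
#: (reference skips ">"/"<", ambiguity codes such as N)
OTHER = ">"

_VALID_REF_CHARS = frozenset("ACGTNacgtn")
_ACGT = frozenset("ACGT")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ReferenceContig:
    """One contig of a repeat-masked wild-type assembly.

    Lowercase letters and N mark repeat-masked / ambiguous positions; SNV
    calling and all density denominators ignore them. ``gc_unmasked`` counts
    uppercase G/C only, which is the denominator of the per-G/C-site EMS
    mutation rate.
    """

    id: str
    sequence: str
    length: int = field(init=False)
    gc_unmasked: int = field(init=False)
    unmasked_bases: int = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence
        object.__setattr__(self, "length", len(seq))
        object.__setattr__(self, "gc_unmasked", seq.count("G") + seq.count("C"))
        object.__setattr__(
            self,
            "unmasked_bases",
            seq.count("A") + seq.count("C") + seq.count("G") + seq.count("T"),
        )


class PileupColumn(NamedTuple):
    """Per-position base-count summary of one mpileup column.

    ``counts`` maps A/C/G/T plus the DELETION and OTHER sentinels to
    non-negative read counts; the values sum to ``depth``. ``ref_base`` is
    uppercase-normalised.
    """

    contig_id: str
    position: int  # 1-based
    ref_base: str
    depth: int
    counts: dict


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[ReferenceContig]:
    """Read an assembly FASTA into ReferenceContig records, order preserved.

    Raises FormatError naming the offending line for malformed headers,
    illegal sequence characters, or duplicate record ids.
    """
    contigs: list[ReferenceContig] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq)
            bad = set(seq) - _VALID_REF_CHARS
            if bad:
                line = _locate_bad_character(path, record.id, bad)
                raise FormatError(
                    f"{path}: line {line}: illegal character(s) {sorted(bad)!r} "
                    f"in record {record.id!r}"
                )
            if record.id in seen:
                raise FormatError(f"{path}: duplicate record id {record.id!r}")
            seen.add(record.id)
            contigs.append(ReferenceContig(record.id, seq))
    return contigs


def _locate_bad_character(path: PathLike, record_id: str, bad: set) -> int:
    """Find the 1-based line number of the first illegal sequence character."""
    in_record = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and (set(line.rstrip("\n")) & bad):
                return lineno
    return 0  # unreachable for errors raised by read_fasta


def write_fasta(contigs: Iterable[ReferenceContig], path: PathLike) -> None:
    """Write contigs as FASTA at wrap width 80; ids must be unique."""
    contigs = list(contigs)
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate contig ids in FASTA output")
    records = (SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs)
    with _open_text(path, "wt") as handle:
        FastaWriter(handle, wrap=FASTA_WRAP).write_file(records)


def assembly_index(assembly: Union[Sequence[ReferenceContig], Mapping[str, ReferenceContig]]) -> dict:
    """Return a contig-id -> ReferenceContig mapping from either container."""
    if isinstance(assembly, Mapping):
        return dict(assembly)
    return {c.id: c for c in assembly}


# ---------------------------------------------------------------------------
# mpileup


def decode_read_bases(read_bases: str, ref_base: str) -> dict:
    """Decode one mpileup read-base string into per-base counts.

    Grammar handled: "."/"," count as the reference base; A/C/G/T in either
    case count as that base (strand is irrelevant to the filters, so case is
    folded); "*" is a deleted base; "^" consumes the following mapping-quality
    character; "$" marks a read end and is not counted; "+n<seq>"/"-n<seq>"
    indel suffixes annotate the *preceding* base and are consumed without
    counting; ">"/"<" (reference skips) and ambiguity codes count as OTHER.
    """
    counts: dict = {}
    ref = ref_base.upper()
    i = 0
    n = len(read_bases)
    while i < n:
        c = read_bases[i]
        if c == "^":
            i += 2  # next char is mapping quality, not a base
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and read_bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"indel marker {c!r} not followed by a length")
            i = j + int(read_bases[i + 1 : j])
            continue
        if c in ".,":
            key = ref if ref in _ACGT else OTHER
        elif c in "ACGTacgt":
            key = c.upper()
        elif c == "*":
            key = DELETION
        elif c in "><Nn":
            key = OTHER
        else:
            raise ParseError(f"unrecognised read-base character {c!r}")
        counts[key] = counts.get(key, 0) + 1
        i += 1
    return counts


def read_mpileup(
    path: PathLike,
    assembly: Union[Sequence[ReferenceContig], Mapping[str, ReferenceContig]],
) -> Iterator[PileupColumn]:
    """Stream PileupColumns from a samtools mpileup text file.

    Decoded counts must sum to the stated depth, otherwise a ParseError naming
    contig and position is raised; a contig id absent from the assembly raises
    IntegrityError.
    """
    index = assembly_index(assembly)
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 5:
                raise ParseError(f"{path}: line {lineno}: expected ≥5 mpileup columns")
            contig_id, pos_s, ref_base, depth_s = fields[:4]
            if contig_id not in index:
                raise IntegrityError(
                    f"{path}: line {lineno}: contig {contig_id!r} not in assembly"
                )
            try:
                position = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            ref_base = ref_base.upper()
            if depth == 0:
                yield PileupColumn(contig_id, position, ref_base, 0, {})
                continue
            try:
                counts = decode_read_bases(fields[4], ref_base)
            except ParseError as exc:
                raise ParseError(f"{path}: {contig_id}:{position}: {exc}") from None
            total = sum(counts.values())
            if total != depth:
                raise ParseError(
                    f"{path}: {contig_id}:{position}: decoded {total} bases "
                    f"but depth field says {depth}"
                )
            yield PileupColumn(contig_id, position, ref_base, depth, counts)


def write_mpileup(columns: Iterable[PileupColumn], path: PathLike) -> None:
    """Write columns in one canonical mpileup dialect.

    Reference-matching reads are emitted as ".", alternates as uppercase
    bases, deletions as "*", OTHER as ">"; base qualities are a constant "I".
    Columns must be sorted by (contig_id, position).
    """
    last_key = None
    with _open_text(path, "wt") as handle:
        for col in columns:
            key = (col.contig_id, col.position)
            if last_key is not None and key <= last_key:
                raise ValidationError(
                    f"mpileup columns not sorted: {key} after {last_key}"
                )
            last_key = key
            ref = col.ref_base.upper()
            parts = []
            for base, count in sorted(col.counts.items()):
                if base == ref:
                    parts.append("." * count)
                elif base in _ACGT:
                    parts.append(base * count)
                elif base == DELETION:
                    parts.append("*" * count)
                else:
                    parts.append(">" * count)
            bases = "".join(parts) or "*"
            quals = "I" * col.depth if col.depth else "*"
            handle.write(
                f"{col.contig_id}\t{col.position}\t{ref}\t{col.depth}\t{bases}\t{quals}\n"
            )
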