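"""Sequence, alignment and pair-table I/O.

Reads come in as FASTA/FASTQ, reference placements as SAM, and the
pairwise distance tables the rest of the package exchanges are plain TSV.
All coordinates are 0-based half-open internally; SAM's 1-based POS is
converted on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PAIR_COLUMNS = ("id1", "id2", "bt", "nw", "bl", "af")


class ParseError(ValueError):
    """A malformed input file."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """An identified nucleotide sequence.

    ``seq`` is uppercase over the alphabet {A,C,G,T,N}; ambiguous bases are
    kept (downstream consumers decide locally how to treat them).
    """

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, id: Optional[str] = None) -> "Read":
        return Read(id=id if id is not None else self.id,
                    seq=reverse_complement(self.seq))


@dataclass(frozen=True)
class Placement:
    """One placement of a read on a reference: 0-based half-open interval."""

    ref_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid placement interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """A read plus one or more reference placements.

    The placement list preserves input order so that averaging over
    multiple alignments is deterministic.
    """

    read: Read
    placements: tuple[Placement, ...]

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError(f"read {self.read.id!r} has no placements")

    @property
    def id(self) -> str:
        return self.read.id


@dataclass(frozen=True)
class PairRecord:
    """A pair of distinct reads and its four distances, each in [0,1].

    Any of the distances may be ``None`` before computation: ``bt`` is the
    overlap-based target distance, ``nw`` the global-alignment distance,
    ``bl`` the local-alignment distance and ``af`` the tetramer-frequency
    distance.
    """

    id1: str
    id2: str
    bt: Optional[float] = None
    nw: Optional[float] = None
    bl: Optional[float] = None
    af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.id1 == self.id2:
            raise ValueError(f"pair of identical reads {self.id1!r}")
        for name in ("bt", "nw", "bl", "af"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def with_distances(self, **kwargs: Optional[float]) -> "PairRecord":
        return replace(self, **kwargs)


def _validate_fasta_lines(path: Path) -> None:
    """Line-level checks that give better messages than the parser does."""
    header_line: Optional[int] = None
    seq_len = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and seq_len == 0:
                    raise ParseError(
                        f"{path}: record starting at line {header_line} "
                        "has an empty sequence")
                header_line = lineno
                seq_len = 0
            else:
                if header_line is None:
                    raise ParseError(
                        f"{path}: line {lineno}: sequence data before "
                        "the first '>' header")
                seq_len += len(line)
    if header_line is not None and seq_len == 0:
        raise ParseError(
            f"{path}: record starting at line {header_line} "
            "has an empty sequence")


def read_fasta(path: str | Path) -> list[Read]:
    """Parse a FASTA file into a list of :class:`Read`.

    Multi-line records are concatenated and lowercase bases are mapped to
    uppercase. Malformed input (text before the first header, a record
    with an empty sequence) raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    return [Read(id=rec.id, seq=str(rec.seq).upper())
            for rec in SeqIO.parse(path, "fasta")]


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a (Sanger) FASTQ file; qualities are checked but discarded."""
    path = Path(path)
    try:
        return [Read(id=rec.id, seq=str(rec.seq).upper())
                for rec in SeqIO.parse(path, "fastq")]
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


_UNSUPPORTED_CIGAR_OPS = {9}  # B (back) — reference semantics undefined here


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Parse mapped SAM records into :class:`AlignedRead` objects.

    One object is returned per distinct read id, carrying all its mapped
    placements in file order. Unmapped records are dropped (a count is
    logged). SAM's 1-based POS becomes a 0-based ``start``; ``end`` is
    start plus the reference-consumed length derived from the CIGAR.
    Reverse-strand SEQ fields are reverse complemented back so that
    ``Read.seq`` is always the sequence as read off the machine.

    Headerless SAM is accepted: a header is synthesized from the reference
    names seen in the records.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = [ln for ln in lines if ln and not ln.startswith("@")]
    has_sq = any(ln.startswith("@SQ") for ln in lines)

    if has_sq:
        header = pysam.AlignmentFile(str(path), "r", check_sq=False).header
    else:
        refs: list[str] = []
        for ln in body:
            fields = ln.split("\t")
            if len(fields) >= 3 and fields[2] != "*" and fields[2] not in refs:
                refs.append(fields[2])
        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": name, "LN": 2**29} for name in refs],
        })

    order: list[str] = []
    seqs: dict[str, str] = {}
    placements: dict[str, list[Placement]] = {}
    n_unmapped = 0
    for ln in body:
        try:
            seg = pysam.AlignedSegment.fromstring(ln, header)
        except ValueError as exc:
            raise ParseError(f"{path}: unparsable record: {exc}") from exc
        if seg.is_unmapped:
            n_unmapped += 1
            continue
        qname = seg.query_name
        if seg.reference_start < 0:
            raise ParseError(
                f"{path}: mapped record {qname!r} has POS=0")
        if seg.cigartuples is None:
            raise ParseError(
                f"{path}: mapped record {qname!r} has no CIGAR")
        if any(op in _UNSUPPORTED_CIGAR_OPS for op, _ in seg.cigartuples):
            raise ParseError(
                f"{path}: record {qname!r} has unsupported CIGAR opcode")
        start = seg.reference_start
        end = seg.reference_end
        strand = "-" if seg.is_reverse else "+"
        if qname not in placements:
            order.append(qname)
            placements[qname] = []
        placements[qname].append(
            Placement(seg.reference_name, start, end, strand))
        if qname not in seqs and seg.query_sequence:
            seq = seg.query_sequence.upper()
            seqs[qname] = reverse_complement(seq) if seg.is_reverse else seq
    if n_unmapped:
        logger.info("read_sam(%s): dropped %d unmapped records",
                    path, n_unmapped)
    out = []
    for qname in order:
        out.append(AlignedRead(read=Read(id=qname, seq=seqs.get(qname, "")),
                               placements=tuple(placements[qname])))
    return out


def write_pairs(records: Iterable[PairRecord], path: str | Path) -> None:
    """Write pair records as TSV with columns id1,id2,bt,nw,bl,af.

    Missing distances are serialized as ``NA``; floats keep full
    precision so the table round-trips exactly.
    """
    rows = [(r.id1, r.id2, r.bt, r.nw, r.bl, r.af) for r in records]
    df = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.17g")


def read_pairs(path: str | Path) -> list[PairRecord]:
    """Read a pair-distance TSV written by :func:`write_pairs`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"],
                         keep_default_na=False, float_precision="round_trip",
                         dtype={"id1": str, "id2": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if tuple(df.columns) != PAIR_COLUMNS:
        raise ParseError(
            f"{path}: expected columns {list(PAIR_COLUMNS)}, "
            f"got {list(df.columns)}")
    for col in ("bt", "nw", "bl", "af"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(
                f"{path}: non-numeric values in column {col!r}") from exc
    out = []
    for row in df.itertuples(index=False):
        vals = {c: (None if pd.isna(v) else float(v))
                for c, v in zip(("bt", "nw", "bl", "af"), row[2:])}
        out.append(PairRecord(id1=row.id1, id2=row.id2, **vals))
    return out
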