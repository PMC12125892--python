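"""Streaming parser for MAF (Multiple Alignment Format) files.

MAF stores whole-genome alignments as blocks: each block opens with an ``a``
line (optionally carrying an aligner score), followed by one ``s`` line per
aligned sequence and optional ``q`` (per-base quality), ``i`` and ``e`` lines.
The first ``s`` line of a block is the block's reference sequence.

This module parses plain or gzip-compressed MAF into :class:`AlignmentBlock`
objects, derives genome names from ``s``-line sources (the text before the
first ``.``, following the UCSC ``database.chromosome`` convention), and
assigns each genome a small integer ID that must fit in 8 bits downstream.

Gzip input is detected by magic bytes and decompressed as a stream; no
extracted copy is written anywhere.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

from .errors import CapacityError, ConsistencyError, MafParseError

#: quality symbol -> numeric level. 'F' (finished/complete) ranks above '9' so
#: a range filter can express "only finished bases". '.' (missing) and the gap
#: symbol '-' carry no value.
QUALITY_VALUES = {str(d): d for d in range(10)}
QUALITY_VALUES["F"] = 10

MAX_GENOMES = 256  # genome IDs are stored in an 8-bit field


@dataclass
class SequenceLine:
    """One MAF ``s`` line.

    ``start``/``size`` are 0-based, strand-local source coordinates of the
    ungapped sequence; ``aligned_text`` is the gapped alignment row.
    """

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    aligned_text: str


@dataclass
class QualityLine:
    """A ``q`` line paired with the preceding ``s`` line (same gapped length)."""

    src: str
    qualities: str


@dataclass
class AlignmentBlock:
    """One MAF alignment block (an ``a`` line and its sequence lines)."""

    score: Optional[float] = None
    sequences: list[SequenceLine] = field(default_factory=list)
    qualities: dict[int, QualityLine] = field(default_factory=dict)
    #: raw "i"/"e" lines, retained verbatim; they never contribute k-mers
    meta: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0].aligned_text) if self.sequences else 0


class GenomeTable:
    """Bijection between genome names and integer IDs in ``[0, 255]``.

    IDs are assigned in first-seen order, which makes them stable across
    re-parses of the same file.
    """

    def __init__(self, names: Iterable[str] = ()) -> None:
        self.names: list[str] = []
        self.ids: dict[str, int] = {}
        for name in names:
            self.get_or_add(name)

    def get_or_add(self, name: str) -> int:
        gid = self.ids.get(name)
        if gid is None:
            if len(self.names) >= MAX_GENOMES:
                raise CapacityError(
                    f"more than {MAX_GENOMES} distinct genomes; genome IDs "
                    "must fit the 8-bit field of packed records"
                )
            gid = len(self.names)
            self.names.append(name)
            self.ids[name] = gid
        return gid

    def id_of(self, name: str) -> int:
        return self.ids[name]

    def name_of(self, gid: int) -> str:
        return self.names[gid]

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.ids

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeTable) and self.names == other.names


def extract_genome_id(src: str) -> str:
    """Genome name of an ``s``-line source: the text before the first ``.``."""
    if not src:
        raise MafParseError("empty 's' line source field")
    return src.split(".", 1)[0]


def _open_maybe_gzip(path) -> IO[str]:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def open_maf_stream(path) -> Iterator[AlignmentBlock]:
    """Yield alignment blocks from a MAF file, gzip autodetected by magic bytes."""
    handle = _open_maybe_gzip(path)
    try:
        yield from read_blocks(handle)
    finally:
        handle.close()


def read_blocks(handle: IO[str]) -> Iterator[AlignmentBlock]:
    """Yield alignment blocks from an open text handle of MAF content."""
    block: Optional[AlignmentBlock] = None
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            if block is not None:
                yield block
                block = None
            continue
        if stripped.startswith("#") or stripped.startswith("track"):
            continue
        tag = stripped.split(None, 1)[0]
        if tag == "a":
            if block is not None:
                yield block
            block = AlignmentBlock(score=_parse_score(stripped, lineno))
        elif tag == "s":
            if block is None:
                raise MafParseError(f"line {lineno}: 's' line outside a block")
            block.sequences.append(_parse_s_line(stripped, lineno))
        elif tag == "q":
            if block is None or not block.sequences:
                raise MafParseError(f"line {lineno}: 'q' line without a preceding 's' line")
            parts = stripped.split()
            if len(parts) != 3:
                raise MafParseError(
                    f"line {lineno}: 'q' line has {len(parts)} fields, expected 3"
                )
            idx = len(block.sequences) - 1
            if len(parts[2]) != len(block.sequences[idx].aligned_text):
                raise MafParseError(
                    f"line {lineno}: quality string length differs from its 's' line"
                )
            block.qualities[idx] = QualityLine(src=parts[1], qualities=parts[2])
        elif tag in ("i", "e"):
            if block is None:
                raise MafParseError(f"line {lineno}: '{tag}' line outside a block")
            block.meta.append(stripped)
        else:
            raise MafParseError(f"line {lineno}: unrecognized line type {tag!r}; not MAF?")
    if block is not None:
        yield block


def _parse_score(a_line: str, lineno: int) -> Optional[float]:
    for token in a_line.split()[1:]:
        if token.startswith("score="):
            try:
                return float(token[6:])
            except ValueError as exc:
                raise MafParseError(f"line {lineno}: bad score value {token!r}") from exc
    return None


def _parse_s_line(line: str, lineno: int) -> SequenceLine:
    parts = line.split()
    if len(parts) != 7:
        raise MafParseError(f"line {lineno}: 's' line has {len(parts)} fields, expected 7")
    _, src, start, size, strand, src_size, text = parts
    if strand not in ("+", "-"):
        raise MafParseError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
    try:
        start_i, size_i, src_size_i = int(start), int(size), int(src_size)
    except ValueError as exc:
        raise MafParseError(f"line {lineno}: non-integer coordinate field") from exc
    seq = SequenceLine(src, start_i, size_i, strand, src_size_i, text)
    ungapped = sum(1 for c in text if c != "-")
    if ungapped != size_i:
        # Real-world MAFs contain such inconsistencies; the counter only uses
        # the aligned text, so this is a warning rather than a fatal error.
        warnings.warn(
            f"line {lineno}: 's' line size field {size_i} != "
            f"{ungapped} non-gap characters",
            stacklevel=2,
        )
    return seq


def format_block(block: AlignmentBlock) -> str:
    """Serialize a block back to MAF text (inverse of parsing, for round-trips)."""
    lines = []
    if block.score is not None:
        lines.append(f"a score={block.score:g}")
    else:
        lines.append("a")
    for idx, seq in enumerate(block.sequences):
        lines.append(
            f"s {seq.src} {seq.start} {seq.size} {seq.strand} "
            f"{seq.src_size} {seq.aligned_text}"
        )
        qline = block.qualities.get(idx)
        if qline is not None:
            lines.append(f"q {qline.src} {qline.qualities}")
    lines.extend(block.meta)
    return "\n".join(lines) + "\n"


def ungap(
    line: SequenceLine, quality: Optional[QualityLine] = None
) -> tuple[str, Optional[list[Optional[int]]]]:
    """Remove gaps from an aligned row, uppercasing the sequence.

    Returns ``(sequence, qualities)`` where ``qualities`` aligns
    index-for-index with the ungapped sequence ('0'-'9' -> 0-9, 'F' -> 10,
    '.' -> None for missing), or ``None`` when no quality line was given.
    """
    text = line.aligned_text
    if quality is None:
        return text.replace("-", "").upper(), None
    qtext = quality.qualities
    if len(qtext) != len(text):
        raise ConsistencyError(
            f"quality length {len(qtext)} != aligned length {len(text)} for {line.src}"
        )
    seq_chars: list[str] = []
    quals: list[Optional[int]] = []
    for base, q in zip(text, qtext):
        if base == "-":
            continue
        seq_chars.append(base)
        quals.append(QUALITY_VALUES.get(q))
    return "".join(seq_chars).upper(), quals


def build_genome_table(blocks: Iterable[AlignmentBlock]) -> GenomeTable:
    """Assign genome IDs in first-seen order over all ``s`` lines."""
    table = GenomeTable()
    for block in blocks:
        for seq in block.sequences:
            table.get_or_add(extract_genome_id(seq.src))
    return table
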