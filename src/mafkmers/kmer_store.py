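"""The binary k-mer database: on-disk layout, random access, and text dumps.

A database is a pair of files:

``NAME.mkc`` (data)
    5-byte header (magic ``MKCD``, 1 version byte) followed by the record
    section: fixed-width records grouped by Prefix in ascending Prefix order,
    strictly ascending by packed key within each Prefix.

``NAME.mkc.idx`` (metadata)
    Magic ``MKCI``, version byte, alphabet tag (0=dna, 1=protein), k, the
    number of Prefix sections (1024 for binned DNA k > 10, otherwise 1), the
    genome table as length-prefixed UTF-8 names in ID order, then one
    (byte offset, record count) pair per Prefix. Offsets are relative to the
    start of the record section, so a lookup seeks directly to its Prefix's
    byte range and touches nothing else.

Record layout (little-endian): ``ceil((R + 8) / 8)`` key bytes holding
``(remainder << 8) | genome_id`` where R is the remainder bit width
(``2*(k-5)`` for binned DNA, the full code width otherwise), then a 4-byte
unsigned count. Small-k and protein databases use a single Prefix section
with the same framing, so every downstream tool is format-agnostic.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import CapacityError, FormatError, QueryError
from .kmer_codec import (
    GENOME_ID_BITS,
    PREFIX_BITS,
    PREFIX_SPACE,
    check_k,
    decode,
    encode,
    remainder_bits,
)

MAGIC_DATA = b"MKCD"
MAGIC_IDX = b"MKCI"
VERSION = 1
COUNT_WIDTH = 4
COUNT_MAX = (1 << (8 * COUNT_WIDTH)) - 1
_ALPHABET_TAGS = {"dna": 0, "protein": 1}
_TAG_ALPHABETS = {v: k for k, v in _ALPHABET_TAGS.items()}


def is_binned(k: int, alphabet: str) -> bool:
    """Whether a database for (k, alphabet) uses 1024 Prefix sections."""
    return alphabet == "dna" and k > 10


def n_prefixes(k: int, alphabet: str) -> int:
    return PREFIX_SPACE if is_binned(k, alphabet) else 1


def key_width(k: int, alphabet: str) -> int:
    """Byte width of the packed (remainder, genome_id) key."""
    bits = remainder_bits(k, alphabet, is_binned(k, alphabet)) + GENOME_ID_BITS
    return (bits + 7) // 8


def record_width(k: int, alphabet: str) -> int:
    return key_width(k, alphabet) + COUNT_WIDTH


def database_paths(path) -> tuple[Path, Path]:
    """Resolve a user path (with or without .mkc) to (data, index) paths."""
    p = Path(path)
    data = p if p.suffix == ".mkc" else p.with_name(p.name + ".mkc")
    return data, data.with_name(data.name + ".idx")


def write_database(
    per_prefix_records: Iterable[tuple[int, Iterable[tuple[int, int]]]],
    path,
    k: int,
    alphabet: str,
    genome_names: list[str],
) -> Path:
    """Write sorted, aggregated records to a database.

    ``per_prefix_records`` yields ``(prefix, records)`` in ascending prefix
    order; prefixes may be omitted when empty. Records are ``(packed_key,
    count)`` strictly ascending by key.
    """
    check_k(k, alphabet)
    if len(genome_names) > (1 << GENOME_ID_BITS):
        raise CapacityError("genome table exceeds the 8-bit ID space")
    data_path, idx_path = database_paths(path)
    np = n_prefixes(k, alphabet)
    kw = key_width(k, alphabet)
    offsets = [0] * np
    counts = [0] * np
    with open(data_path, "wb") as fh:
        fh.write(MAGIC_DATA)
        fh.write(bytes([VERSION]))
        pos = 0
        last_prefix = -1
        for prefix, records in per_prefix_records:
            if not 0 <= prefix < np:
                raise FormatError(f"prefix {prefix} out of range for {np} sections")
            if prefix <= last_prefix:
                raise FormatError("per-prefix record stream not in ascending order")
            last_prefix = prefix
            offsets[prefix] = pos
            n = 0
            for key, count in records:
                if count > COUNT_MAX:
                    raise CapacityError(f"count {count} exceeds the 4-byte count field")
                fh.write(key.to_bytes(kw, "little"))
                fh.write(count.to_bytes(COUNT_WIDTH, "little"))
                n += 1
            counts[prefix] = n
            pos += n * (kw + COUNT_WIDTH)
    # empty prefixes point at the position where their (zero) records would sit
    pos = 0
    for p in range(np):
        offsets[p] = pos
        pos += counts[p] * (kw + COUNT_WIDTH)
    with open(idx_path, "wb") as fh:
        fh.write(MAGIC_IDX)
        fh.write(bytes([VERSION, _ALPHABET_TAGS[alphabet], k]))
        fh.write(struct.pack("<H", np if np < PREFIX_SPACE else 0))  # 0 means 1024
        fh.write(struct.pack("<H", len(genome_names)))
        for name in genome_names:
            raw = name.encode("utf-8")
            fh.write(struct.pack("<H", len(raw)))
            fh.write(raw)
        for p in range(np):
            fh.write(struct.pack("<QQ", offsets[p], counts[p]))
    return data_path


class KmerDatabase:
    """Read-only random-access view of a written database."""

    def __init__(self, data_path: Path, idx_path: Path) -> None:
        self.data_path = Path(data_path)
        self.idx_path = Path(idx_path)
        self._load_index()
        self._fh = open(self.data_path, "rb")
        header = self._fh.read(5)
        if header[:4] != MAGIC_DATA or header[4] != VERSION:
            raise FormatError(f"{self.data_path}: bad data-file magic or version")
        self._data_start = 5

    @classmethod
    def open(cls, path) -> "KmerDatabase":
        data_path, idx_path = database_paths(path)
        if not data_path.exists() or not idx_path.exists():
            raise FormatError(f"database files not found for {path}")
        return cls(data_path, idx_path)

    def _load_index(self) -> None:
        raw = self.idx_path.read_bytes()
        if raw[:4] != MAGIC_IDX or raw[4] != VERSION:
            raise FormatError(f"{self.idx_path}: bad index magic or version")
        tag, k = raw[5], raw[6]
        if tag not in _TAG_ALPHABETS:
            raise FormatError(f"{self.idx_path}: unknown alphabet tag {tag}")
        self.alphabet = _TAG_ALPHABETS[tag]
        self.k = k
        pos = 7
        (np_raw,) = struct.unpack_from("<H", raw, pos)
        pos += 2
        self.n_prefix = PREFIX_SPACE if np_raw == 0 else np_raw
        (n_genomes,) = struct.unpack_from("<H", raw, pos)
        pos += 2
        names = []
        for _ in range(n_genomes):
            (ln,) = struct.unpack_from("<H", raw, pos)
            pos += 2
            names.append(raw[pos : pos + ln].decode("utf-8"))
            pos += ln
        self.genome_names = names
        self.index: list[tuple[int, int]] = []
        expected = pos + 16 * self.n_prefix
        if len(raw) < expected:
            raise FormatError(f"{self.idx_path}: truncated prefix index")
        for _ in range(self.n_prefix):
            off, cnt = struct.unpack_from("<QQ", raw, pos)
            pos += 16
            self.index.append((off, cnt))
        self.key_width = key_width(self.k, self.alphabet)
        self.record_width = self.key_width + COUNT_WIDTH
        self.binned = self.n_prefix == PREFIX_SPACE

    # -- accessors ---------------------------------------------------------

    @property
    def total_records(self) -> int:
        return sum(c for _, c in self.index)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "KmerDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _read_record(self, offset: int, i: int) -> tuple[int, int]:
        self._fh.seek(self._data_start + offset + i * self.record_width)
        raw = self._fh.read(self.record_width)
        key = int.from_bytes(raw[: self.key_width], "little")
        count = int.from_bytes(raw[self.key_width :], "little")
        return key, count

    def _code_of(self, prefix: int, remainder: int) -> int:
        if self.binned:
            rb = remainder_bits(self.k, self.alphabet, True)
            return (prefix << rb) | remainder
        return remainder

    def iter_records(self) -> Iterator[tuple[int, int, int]]:
        """Yield (prefix, packed_key, count) in storage order, streaming."""
        with open(self.data_path, "rb") as fh:
            fh.seek(self._data_start)
            for prefix in range(self.n_prefix):
                _, cnt = self.index[prefix]
                for _ in range(cnt):
                    raw = fh.read(self.record_width)
                    key = int.from_bytes(raw[: self.key_width], "little")
                    count = int.from_bytes(raw[self.key_width :], "little")
                    yield prefix, key, count

    def iter_entries(self) -> Iterator[tuple[int, list[tuple[int, int]]]]:
        """Yield (full code, [(genome_id, count) ascending]) in code order."""
        current_code: Optional[int] = None
        pairs: list[tuple[int, int]] = []
        for prefix, key, count in self.iter_records():
            remainder = key >> GENOME_ID_BITS
            gid = key & ((1 << GENOME_ID_BITS) - 1)
            code = self._code_of(prefix, remainder)
            if code != current_code:
                if current_code is not None:
                    yield current_code, pairs
                current_code = code
                pairs = []
            pairs.append((gid, count))
        if current_code is not None:
            yield current_code, pairs

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (genome name, count) pairs for one k-mer via the Prefix index.

        Seeks into the k-mer's Prefix section only and binary-searches the
        fixed-width records with the genome-ID byte masked out.
        """
        if len(kmer) != self.k:
            raise QueryError(f"query length {len(kmer)} != database k {self.k}")
        code = encode(kmer.upper(), self.alphabet)
        if code is None:
            raise QueryError(f"query {kmer!r} contains symbols outside the alphabet")
        if self.binned:
            rb = remainder_bits(self.k, self.alphabet, True)
            prefix = code >> rb
            remainder = code & ((1 << rb) - 1)
        else:
            prefix, remainder = 0, code
        offset, cnt = self.index[prefix]
        lo_key = remainder << GENOME_ID_BITS
        # leftmost record with key >= remainder||0
        lo, hi = 0, cnt
        while lo < hi:
            mid = (lo + hi) // 2
            key, _ = self._read_record(offset, mid)
            if key < lo_key:
                lo = mid + 1
            else:
                hi = mid
        out: list[tuple[str, int]] = []
        i = lo
        while i < cnt:
            key, count = self._read_record(offset, i)
            if key >> GENOME_ID_BITS != remainder:
                break
            out.append((self.genome_names[key & 0xFF], count))
            i += 1
        return out


# -- conversions and dumps -------------------------------------------------


def records_from_table(table) -> Iterator[tuple[int, list[tuple[int, int]]]]:
    """Per-prefix sorted record lists from a CountTable-like object."""
    binned = is_binned(table.k, table.alphabet)
    rb = remainder_bits(table.k, table.alphabet, binned)
    per_prefix: dict[int, list[tuple[int, int]]] = {}
    for code, per_genome in table.counts.items():
        prefix = code >> rb if binned else 0
        remainder = code & ((1 << rb) - 1) if binned else code
        bucket = per_prefix.setdefault(prefix, [])
        for gid, count in per_genome.items():
            bucket.append(((remainder << GENOME_ID_BITS) | gid, count))
    for prefix in sorted(per_prefix):
        yield prefix, sorted(per_prefix[prefix])


def write_table(table, path) -> Path:
    """Write a CountTable to a binary database."""
    return write_database(
        records_from_table(table),
        path,
        table.k,
        table.alphabet,
        list(table.genome_table.names),
    )


def dump_combined(db: KmerDatabase, out_path) -> None:
    """One line per k-mer: the k-mer then space-separated NAME:COUNT pairs.

    K-mers appear in ascending code order (equal to lexicographic order) and
    genomes in ascending genome-ID order within a line.
    """
    names = db.genome_names
    with open(out_path, "w") as fh:
        for code, pairs in db.iter_entries():
            kmer = decode(code, db.k, db.alphabet)
            fields = " ".join(f"{names[gid]}:{count}" for gid, count in pairs)
            fh.write(f"{kmer} {fields}\n")


def dump_per_genome(db: KmerDatabase, out_dir) -> list[Path]:
    """One ``NAME.kmers`` file per genome with ``KMER COUNT`` lines.

    Every genome in the table gets a file, even if it holds no k-mers, so the
    output directory always reflects the full genome roster.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [out_dir / f"{name}.kmers" for name in db.genome_names]
    handles = [open(p, "w") for p in paths]
    try:
        for code, pairs in db.iter_entries():
            kmer = decode(code, db.k, db.alphabet)
            for gid, count in pairs:
                handles[gid].write(f"{kmer} {count}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths
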