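"""External-memory counting engine for large k (default for k > 10).

The pipeline follows the classic disk-based k-mer counter design:

1. Reader stage: sliding-window scan encodes each window, assigns it to one
   of 1024 bins by its 10-bit Prefix (first 5 bases), and appends a packed
   record ``(infix||suffix) << 8 | genome_id`` with count 1.
2. When a bin crosses the bin threshold it is partially sorted (packed-key
   order = Infix, then Suffix, then genome ID) and compacted — adjacent equal
   keys merge by summing counts — then handed to the package stage.
3. The package manager keeps one sorted package per Prefix, merging incoming
   runs on Infix order; a package crossing the element threshold is spilled
   to a temp file and its byte range recorded as a segment.
4. Finalization loads every segment of a Prefix, fully sorts (any stable sort
   is equivalent to the radix sort on these fixed-width keys), aggregates
   duplicates, and streams the result into the binary database with one byte
   offset per Prefix.

Reader/manager counts (or a total split 30%/70% between them) and both
thresholds are accepted as configuration and influence only scheduling in a
truly concurrent build; here the pipeline executes deterministically and the
output database is byte-identical for every setting — the invariant the
tests pin.

For k <= 10 or protein input the Prefix split is undefined, so everything
flows through a single prefix-0 section with the full code as remainder; the
resulting database uses the same framing the store defines for small k.
"""

from __future__ import annotations

import heapq
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from ._scan import iter_block_events
from .filters import EMPTY_FILTER, FilterSpec
from .kmer_codec import (
    GENOME_ID_BITS,
    check_k,
    remainder_bits,
)
from .kmer_store import (
    COUNT_WIDTH,
    KmerDatabase,
    is_binned,
    key_width,
    n_prefixes,
    write_database,
)
from .maf_io import build_genome_table, open_maf_stream

DEFAULT_BIN_THRESHOLD = 65_536
DEFAULT_PACKAGE_THRESHOLD = 262_144
READER_FRACTION = 0.3  # default apportionment of a total thread count


def apportion_workers(
    threads: Optional[int],
    readers: Optional[int],
    managers: Optional[int],
) -> tuple[int, int]:
    """Resolve worker counts; a bare total splits 30% readers / 70% managers.

    Configuration only: the counting result never depends on these numbers.
    """
    if readers is not None or managers is not None:
        return max(1, readers or 1), max(1, managers or 1)
    total = threads or 2
    r = max(1, round(total * READER_FRACTION))
    return r, max(1, total - r)


Record = tuple[int, int]  # (packed key, count)


def assign_to_bin(code: int, k: int, genome_id: int, alphabet: str = "dna") -> tuple[int, Record]:
    """Prefix bin and packed unit-count record for one window code."""
    binned = is_binned(k, alphabet)
    rb = remainder_bits(k, alphabet, binned)
    if binned:
        prefix = code >> rb
        remainder = code & ((1 << rb) - 1)
    else:
        prefix, remainder = 0, code
    return prefix, ((remainder << GENOME_ID_BITS) | genome_id, 1)


def sort_and_compact(records: Iterable[Record]) -> list[Record]:
    """Sort by packed key and merge adjacent equal keys by summing counts."""
    out: list[Record] = []
    for key, count in sorted(records):
        if out and out[-1][0] == key:
            out[-1] = (key, out[-1][1] + count)
        else:
            out.append((key, count))
    return out


def merge_into_package(package: list[Record], run: Sequence[Record]) -> list[Record]:
    """Merge a sorted compacted run into a sorted package, keeping order."""
    if not package:
        return sort_and_compact(run) if _needs_compaction(run) else list(run)
    merged: list[Record] = []
    for key, count in heapq.merge(package, run):
        if merged and merged[-1][0] == key:
            merged[-1] = (key, merged[-1][1] + count)
        else:
            merged.append((key, count))
    return merged


def _needs_compaction(run: Sequence[Record]) -> bool:
    return any(run[i][0] == run[i + 1][0] for i in range(len(run) - 1))


def finalize_prefix(runs: Sequence[Sequence[Record]]) -> list[Record]:
    """Fully sort and aggregate all sorted runs of one Prefix."""
    out: list[Record] = []
    for key, count in heapq.merge(*runs):
        if out and out[-1][0] == key:
            out[-1] = (key, out[-1][1] + count)
        else:
            out.append((key, count))
    return out


@dataclass
class SpillSegment:
    """A sorted run of one Prefix spilled to the temp file."""

    prefix: int
    offset: int
    n_records: int


class _SpillFile:
    """Append-only temp file of fixed-width spilled records."""

    def __init__(self, key_bytes: int, temp_dir) -> None:
        self.key_bytes = key_bytes
        self.rec_bytes = key_bytes + COUNT_WIDTH
        self._fh = tempfile.NamedTemporaryFile(
            mode="w+b", dir=temp_dir, prefix="mafkmers-spill-", delete=False
        )
        self.path = Path(self._fh.name)
        self._pos = 0

    def spill(self, prefix: int, records: Sequence[Record]) -> SpillSegment:
        buf = bytearray()
        for key, count in records:
            buf += key.to_bytes(self.key_bytes, "little")
            buf += count.to_bytes(COUNT_WIDTH, "little")
        self._fh.write(buf)
        seg = SpillSegment(prefix, self._pos, len(records))
        self._pos += len(buf)
        return seg

    def load(self, seg: SpillSegment) -> list[Record]:
        self._fh.flush()
        self._fh.seek(seg.offset)
        raw = self._fh.read(seg.n_records * self.rec_bytes)
        out = []
        kb = self.key_bytes
        for i in range(seg.n_records):
            start = i * self.rec_bytes
            key = int.from_bytes(raw[start : start + kb], "little")
            count = int.from_bytes(raw[start + kb : start + self.rec_bytes], "little")
            out.append((key, count))
        self._fh.seek(0, 2)
        return out

    def close(self) -> None:
        self._fh.close()
        self.path.unlink(missing_ok=True)


def count_file_disk(
    path,
    out_path,
    k: int,
    spec: Optional[FilterSpec] = None,
    alphabet: str = "dna",
    readers: Optional[int] = None,
    managers: Optional[int] = None,
    threads: Optional[int] = None,
    bin_threshold: int = DEFAULT_BIN_THRESHOLD,
    package_threshold: int = DEFAULT_PACKAGE_THRESHOLD,
    temp_dir=None,
) -> KmerDatabase:
    """Count a MAF file with the disk-based engine and write the database."""
    check_k(k, alphabet)
    if bin_threshold < 1 or package_threshold < 1:
        raise ValueError("thresholds must be >= 1")
    spec = spec or EMPTY_FILTER
    apportion_workers(threads, readers, managers)  # validated; scheduling only

    blocks = list(open_maf_stream(path))
    genome_table = build_genome_table(blocks)
    spec.warn_unseen_genomes(set(genome_table.names))

    np = n_prefixes(k, alphabet)
    kw = key_width(k, alphabet)
    bins: dict[int, list[Record]] = {}
    packages: dict[int, list[Record]] = {}
    segments: dict[int, list[SpillSegment]] = {}
    spill = _SpillFile(kw, temp_dir)
    try:
        def hand_to_manager(prefix: int, run: list[Record]) -> None:
            pkg = merge_into_package(packages.get(prefix, []), run)
            if len(pkg) >= package_threshold:
                segments.setdefault(prefix, []).append(spill.spill(prefix, pkg))
                packages.pop(prefix, None)
            else:
                packages[prefix] = pkg

        for block in blocks:
            for gid, code in iter_block_events(block, k, alphabet, spec, genome_table):
                prefix, record = assign_to_bin(code, k, gid, alphabet)
                records = bins.setdefault(prefix, [])
                records.append(record)
                if len(records) >= bin_threshold:
                    hand_to_manager(prefix, sort_and_compact(records))
                    bins[prefix] = []

        # end-of-input flush: drain bins, then spill residual packages
        for prefix, records in bins.items():
            if records:
                hand_to_manager(prefix, sort_and_compact(records))
        for prefix, pkg in list(packages.items()):
            if pkg:
                segments.setdefault(prefix, []).append(spill.spill(prefix, pkg))
        packages.clear()

        def final_stream() -> Iterator[tuple[int, list[Record]]]:
            for prefix in range(np):
                segs = segments.get(prefix)
                if not segs:
                    continue
                runs = [spill.load(s) for s in segs]
                yield prefix, finalize_prefix(runs)

        data_path = write_database(
            final_stream(), out_path, k, alphabet, list(genome_table.names)
        )
    finally:
        spill.close()
    return KmerDatabase.open(data_path)
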