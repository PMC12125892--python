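"""In-memory counting engine for small k (default cutoff k <= 10).

Each worker scans its chunk of alignment blocks with a sliding window and
accumulates counts in a local associative map keyed by k-mer code, with a
per-genome sub-map; the main path then merges the per-chunk maps pointwise.
The chunk count never changes the result — chunk boundaries always fall
between blocks, and merging is associative and commutative — so the W-chunk
outcome equals the single-pass outcome by construction.

The engine accepts any encodable k (the cutoff is a default, not a limit),
which makes cross-engine equivalence against the disk engine testable.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from ._scan import iter_block_events
from .errors import RangeError
from .filters import EMPTY_FILTER, FilterSpec
from .kmer_codec import check_k
from .maf_io import AlignmentBlock, GenomeTable, build_genome_table, open_maf_stream


class CountTable:
    """Per-genome k-mer counts: ``code -> {genome_id -> count}``.

    Zero counts are never stored; the total stored mass equals the number of
    accepted windows scanned.
    """

    def __init__(self, k: int, alphabet: str, genome_table: GenomeTable) -> None:
        check_k(k, alphabet)
        self.k = k
        self.alphabet = alphabet
        self.genome_table = genome_table
        self.counts: dict[int, dict[int, int]] = {}

    def add(self, code: int, genome_id: int, n: int = 1) -> None:
        per_genome = self.counts.setdefault(code, {})
        per_genome[genome_id] = per_genome.get(genome_id, 0) + n

    def total(self) -> int:
        return sum(c for per in self.counts.values() for c in per.values())

    def n_kmers(self) -> int:
        return len(self.counts)

    def sorted_items(self):
        """(code, [(genome_id, count) ascending]) in ascending code order."""
        for code in sorted(self.counts):
            yield code, sorted(self.counts[code].items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.k == other.k
            and self.alphabet == other.alphabet
            and self.genome_table == other.genome_table
            and self.counts == other.counts
        )

    def __repr__(self) -> str:
        return (
            f"CountTable(k={self.k}, alphabet={self.alphabet!r}, "
            f"kmers={self.n_kmers()}, total={self.total()})"
        )


def count_block(
    block: AlignmentBlock,
    k: int,
    spec: FilterSpec,
    table: CountTable,
) -> CountTable:
    """Count every accepted length-k window of a block into ``table``.

    All ``s`` lines contribute, including the block's reference sequence.
    """
    for gid, code in iter_block_events(block, k, table.alphabet, spec, table.genome_table):
        table.add(code, gid)
    return table


def merge_tables(tables: Sequence[CountTable]) -> CountTable:
    """Pointwise-additive merge; associative and commutative."""
    if not tables:
        raise ValueError("merge_tables requires at least one table")
    first = tables[0]
    for t in tables[1:]:
        if t.k != first.k or t.alphabet != first.alphabet:
            raise RangeError("cannot merge tables with differing k or alphabet")
        if t.genome_table != first.genome_table:
            raise ValueError("cannot merge tables with differing genome tables")
    out = CountTable(first.k, first.alphabet, first.genome_table)
    for t in tables:
        for code, per in t.counts.items():
            for gid, n in per.items():
                out.add(code, gid, n)
    return out


def split_chunks(blocks: Sequence[AlignmentBlock], w: int) -> list[list[AlignmentBlock]]:
    """Partition a block list into W contiguous chunks at block boundaries."""
    if w < 1:
        raise ValueError("chunk count must be >= 1")
    base, extra = divmod(len(blocks), w)
    chunks = []
    pos = 0
    for i in range(w):
        size = base + (1 if i < extra else 0)
        chunks.append(list(blocks[pos : pos + size]))
        pos += size
    return chunks


def count_blocks(
    blocks: Iterable[AlignmentBlock],
    k: int,
    alphabet: str = "dna",
    spec: Optional[FilterSpec] = None,
    partitions: int = 1,
    genome_table: Optional[GenomeTable] = None,
) -> CountTable:
    """Chunked map-merge counting over an in-memory block list."""
    spec = spec or EMPTY_FILTER
    blocks = list(blocks)
    if genome_table is None:
        genome_table = build_genome_table(blocks)
    tables = []
    for chunk in split_chunks(blocks, partitions):
        t = CountTable(k, alphabet, genome_table)
        for block in chunk:
            count_block(block, k, spec, t)
        tables.append(t)
    merged = merge_tables(tables)
    spec.warn_unseen_genomes(set(genome_table.names))
    return merged


def count_file_small(
    path,
    k: int,
    spec: Optional[FilterSpec] = None,
    partitions: int = 1,
    alphabet: str = "dna",
) -> CountTable:
    """Count a MAF file with the associative-map engine."""
    check_k(k, alphabet)
    blocks = list(open_maf_stream(path))
    return count_blocks(blocks, k, alphabet, spec, partitions)


def table_from_database(db) -> CountTable:
    """Materialize a binary database back into a CountTable (for comparisons)."""
    table = CountTable(db.k, db.alphabet, GenomeTable(db.genome_names))
    for code, pairs in db.iter_entries():
        for gid, count in pairs:
            table.add(code, gid, count)
    return table
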