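"""Shared sliding-window scan over ungapped alignment rows.

Both counting engines consume the same stream of (genome_id, code) events;
only what they do with an event differs. The rolling encoder keeps a window
code updated in O(1) per base and tracks the length of the current run of
valid symbols, so windows spanning ambiguous bases are skipped without
re-encoding.
"""

from __future__ import annotations

from typing import Iterator

from .filters import FilterSpec, block_passes, sequence_selected, window_quality_ok
from .kmer_codec import PROTEIN_ALPHABET, bits_per_symbol
from .maf_io import AlignmentBlock, GenomeTable, extract_genome_id, ungap

_DNA_TABLE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_PROTEIN_TABLE = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}


def symbol_bits_table(alphabet: str) -> dict[str, int]:
    return _DNA_TABLE if alphabet == "dna" else _PROTEIN_TABLE


def iter_window_codes(seq: str, k: int, alphabet: str) -> Iterator[tuple[int, int]]:
    """Yield (start_index, code) for every encodable length-k window of seq."""
    table = symbol_bits_table(alphabet)
    width = bits_per_symbol(alphabet)
    mask = (1 << (width * k)) - 1
    code = 0
    run = 0
    for i, ch in enumerate(seq):
        bits = table.get(ch)
        if bits is None:
            run = 0
            code = 0
            continue
        code = ((code << width) | bits) & mask
        run += 1
        if run >= k:
            yield i - k + 1, code


def iter_block_events(
    block: AlignmentBlock,
    k: int,
    alphabet: str,
    spec: FilterSpec,
    genome_table: GenomeTable,
) -> Iterator[tuple[int, int]]:
    """Yield (genome_id, code) for every counted window of a block.

    Registers every genome of the block in ``genome_table`` (first-seen order)
    before applying the genome-subset filter, so ID assignment never depends
    on the active filters.
    """
    gids = [genome_table.get_or_add(extract_genome_id(s.src)) for s in block.sequences]
    if not block_passes(block, spec):
        return
    for idx, line in enumerate(block.sequences):
        genome = genome_table.name_of(gids[idx])
        if not sequence_selected(genome, spec):
            continue
        seq, quals = ungap(line, block.qualities.get(idx))
        if len(seq) < k:
            continue
        check_q = spec.q_active and quals is not None
        for start, code in iter_window_codes(seq, k, alphabet):
            if check_q and not window_quality_ok(quals[start : start + k], spec):
                continue
            yield gids[idx], code
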