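"""Integer encoding of k-mers and the bit layout of packed count records.

DNA/RNA k-mers are packed 2 bits per base (A=00, C=01, G=10, T/U=11, most
significant bit-pair first) for k up to 64; protein k-mers use 5 bits per
residue over a fixed 25-symbol alphabet for k up to 25. Because the symbol
orders are alphabetical within each alphabet, integer order of codes equals
lexicographic order of the strings, so sorted codes dump in sorted text order.

For the disk-based engine a DNA code with k > 10 splits into a 10-bit Prefix
(first 5 bases, selecting one of 1024 bins), a 10-bit Infix (next 5 bases,
the partial-sort key) and a Suffix holding the remaining 2*(k-10) bits. Packed
records place the genome ID in the 8 least significant bits with the k-mer
remainder (Infix plus Suffix) above it, so integer record order is
(infix, suffix, genome_id).

No canonical (reverse-complement-minimum) representation is used anywhere:
alignment rows are counted exactly as written, which distinguishes strands —
unlike most FASTA k-mer counters.
"""

from __future__ import annotations

from typing import Optional

from .errors import CapacityError, RangeError

MAX_K_DNA = 64
MAX_K_PROTEIN = 25

PREFIX_BASES = 5
PREFIX_BITS = 10
PREFIX_SPACE = 1 << PREFIX_BITS  # 1024 bins

GENOME_ID_BITS = 8

DNA_ALPHABET = "ACGT"
_DNA_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

#: 20 standard residues plus ambiguity codes B, Z, X and the rare U, O.
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZXUO"
_PROTEIN_TO_BITS = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
PROTEIN_SYMBOL_BITS = 5


def bits_per_symbol(alphabet: str) -> int:
    if alphabet == "dna":
        return 2
    if alphabet == "protein":
        return PROTEIN_SYMBOL_BITS
    raise ValueError(f"unknown alphabet {alphabet!r}")


def max_k(alphabet: str) -> int:
    return MAX_K_DNA if alphabet == "dna" else MAX_K_PROTEIN


def check_k(k: int, alphabet: str) -> None:
    """Raise :class:`RangeError` unless k is valid for the alphabet."""
    limit = max_k(alphabet)
    if not 1 <= k <= limit:
        raise RangeError(f"k={k} outside supported range [1, {limit}] for {alphabet}")


def encode_dna(kmer: str) -> Optional[int]:
    """2-bit code of a DNA/RNA k-mer, or None if any symbol is ambiguous.

    A window containing N or any other non-ACGTU symbol contributes no count.
    """
    check_k(len(kmer), "dna")
    value = 0
    for base in kmer:
        bits = _DNA_TO_BITS.get(base)
        if bits is None:
            return None
        value = (value << 2) | bits
    return value


def decode_dna(code: int, k: int) -> str:
    check_k(k, "dna")
    bases = []
    for shift in range(2 * (k - 1), -1, -2):
        bases.append(DNA_ALPHABET[(code >> shift) & 3])
    return "".join(bases)


def encode_protein(kmer: str) -> Optional[int]:
    """5-bit-per-residue code of a peptide k-mer, or None on a foreign symbol."""
    check_k(len(kmer), "protein")
    value = 0
    for aa in kmer:
        bits = _PROTEIN_TO_BITS.get(aa)
        if bits is None:
            return None
        value = (value << PROTEIN_SYMBOL_BITS) | bits
    return value


def decode_protein(code: int, k: int) -> str:
    check_k(k, "protein")
    out = []
    for shift in range(PROTEIN_SYMBOL_BITS * (k - 1), -1, -PROTEIN_SYMBOL_BITS):
        out.append(PROTEIN_ALPHABET[(code >> shift) & 31])
    return "".join(out)


def encode(kmer: str, alphabet: str) -> Optional[int]:
    return encode_dna(kmer) if alphabet == "dna" else encode_protein(kmer)


def decode(code: int, k: int, alphabet: str) -> str:
    return decode_dna(code, k) if alphabet == "dna" else decode_protein(code, k)


def split_parts(code: int, k: int) -> tuple[int, int, int]:
    """Split a DNA code (k > 10) into (prefix, infix, suffix).

    Prefix = top 10 bits (first 5 bases), Infix = next 10 bits, Suffix = the
    remaining 2*(k-10) bits; concatenating them reproduces the code.
    """
    if k <= PREFIX_BASES * 2:
        raise RangeError(f"prefix/infix split requires k > 10, got k={k}")
    suffix_bits = 2 * (k - 2 * PREFIX_BASES)
    prefix = code >> (PREFIX_BITS + suffix_bits)
    infix = (code >> suffix_bits) & (PREFIX_SPACE - 1)
    suffix = code & ((1 << suffix_bits) - 1)
    return prefix, infix, suffix


def join_parts(prefix: int, infix: int, suffix: int, k: int) -> int:
    """Inverse of :func:`split_parts`."""
    suffix_bits = 2 * (k - 2 * PREFIX_BASES)
    return (prefix << (PREFIX_BITS + suffix_bits)) | (infix << suffix_bits) | suffix


def remainder_bits(k: int, alphabet: str, binned: bool) -> int:
    """Bit width of the stored k-mer remainder (code minus Prefix when binned)."""
    bits = bits_per_symbol(alphabet) * k
    return bits - PREFIX_BITS if binned else bits


def pack_record(remainder: int, genome_id: int, count: int) -> tuple[int, int]:
    """Pack (remainder, genome_id) into one key; the count rides alongside."""
    if not 0 <= genome_id < (1 << GENOME_ID_BITS):
        raise CapacityError(f"genome ID {genome_id} does not fit 8 bits")
    return (remainder << GENOME_ID_BITS) | genome_id, count


def unpack_record(key: int, count: int) -> tuple[int, int, int]:
    """Inverse of :func:`pack_record`: (remainder, genome_id, count)."""
    return key >> GENOME_ID_BITS, key & ((1 << GENOME_ID_BITS) - 1), count
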