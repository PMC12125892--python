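"""Deterministic synthetic-MAF generator and the brute-force counting oracle.

``generate_maf`` emits well-formed MAF text with a configurable number of
genomes and blocks, gap and ambiguity rates, optional quality lines and
alignment scores, and a mix of strands — everything the counting engines and
filters touch — fully reproducible from an integer seed. It makes no attempt
at biological realism (no substitution model, no phylogeny): its job is to
exercise the file format, not to imitate evolution.

``oracle_counts`` is the counting authority the engines are tested against:
a deliberately naive single pass using plain string slicing and nested dicts.
It shares only the MAF parser with the engines — filtering, ungapping,
quality mapping and window scanning are all reimplemented here from the
stated rules.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .counter_small import CountTable
from .filters import FilterSpec
from .kmer_codec import PROTEIN_ALPHABET
from .maf_io import GenomeTable, read_blocks


@dataclass
class FixtureConfig:
    """Knobs of the synthetic generator; every field has a sane default."""

    n_genomes: int = 4
    n_blocks: int = 10
    block_len: tuple[int, int] = (20, 60)  # alignment columns, inclusive range
    gap_prob: float = 0.10
    q_prob: float = 0.3  # probability a DNA s line gets a q line
    #: weights over quality symbols '0'..'9' then 'F'
    quality_weights: tuple = (1, 1, 1, 1, 1, 2, 3, 4, 5, 6, 4)
    score_missing_prob: float = 0.2
    score_range: tuple[float, float] = (-50.0, 150.0)
    minus_strand_prob: float = 0.3
    alphabet: str = "dna"
    ambig_prob: float = 0.02  # N for DNA, J (foreign symbol) for protein
    src_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_len[0] < 1 or self.block_len[0] > self.block_len[1]:
            raise ValueError("block_len must be a range with lower bound >= 1")
        if not 1 <= self.n_genomes <= 256:
            raise ValueError("n_genomes must be in [1, 256]")
        for p in (self.gap_prob, self.q_prob, self.score_missing_prob,
                  self.minus_strand_prob, self.ambig_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


_Q_SYMBOLS = "0123456789F"


def generate_maf(config: FixtureConfig) -> str:
    """Render a reproducible synthetic MAF file as text."""
    rng = random.Random(config.seed)
    dna = config.alphabet == "dna"
    symbols = "ACGT" if dna else PROTEIN_ALPHABET[:20]
    ambig = "N" if dna else "J"
    genomes = [f"g{i:03d}" for i in range(config.n_genomes)]
    out = ["##maf version=1 scoring=synthetic"]
    for b in range(config.n_blocks):
        ncols = rng.randint(*config.block_len)
        if rng.random() < config.score_missing_prob:
            out.append("a")
        else:
            out.append(f"a score={rng.uniform(*config.score_range):.1f}")
        for genome in genomes:
            chars = []
            for _ in range(ncols):
                if rng.random() < config.gap_prob:
                    chars.append("-")
                elif rng.random() < config.ambig_prob:
                    chars.append(ambig)
                else:
                    chars.append(rng.choice(symbols))
            text = "".join(chars)
            size = sum(1 for c in text if c != "-")
            strand = "-" if rng.random() < config.minus_strand_prob else "+"
            start = rng.randrange(0, config.src_size - ncols)
            out.append(
                f"s {genome}.chr{1 + b % 3} {start} {size} {strand} "
                f"{config.src_size} {text}"
            )
            if dna and rng.random() < config.q_prob:
                q = "".join(
                    "-" if c == "-" else rng.choices(_Q_SYMBOLS, config.quality_weights)[0]
                    for c in text
                )
                out.append(f"q {genome}.chr{1 + b % 3} {q}")
        out.append("")
    return "\n".join(out) + "\n"


def write_fixture(config: FixtureConfig, path) -> Path:
    path = Path(path)
    path.write_text(generate_maf(config))
    return path


# ---------------------------------------------------------------------------
# brute-force oracle

_Q_VALUE = {str(d): d for d in range(10)}
_Q_VALUE["F"] = 10


def _naive_code(window: str, alphabet: str) -> int:
    """Base-|alphabet| positional encoding, independent of the bit-packing codec.

    The symbol orders coincide with the codec's by construction (both are the
    alphabet's canonical order), so the integer values agree — computed here
    by plain arithmetic rather than shared code.
    """
    value = 0
    if alphabet == "dna":
        for c in window:
            value = value * 4 + "ACGT".index(c)
    else:
        for c in window:
            value = value * 32 + PROTEIN_ALPHABET.index(c)
    return value


def oracle_counts(
    maf_text: str,
    k: int,
    spec: Optional[FilterSpec] = None,
    alphabet: str = "dna",
) -> CountTable:
    """Naive reference counter: slice every window, check every rule inline."""
    spec = spec or FilterSpec()
    valid = set("ACGT") if alphabet == "dna" else set(PROTEIN_ALPHABET)
    blocks = list(read_blocks(io.StringIO(maf_text)))

    table = GenomeTable()
    for block in blocks:
        for seq in block.sequences:
            table.get_or_add(seq.src.split(".", 1)[0])

    counts = CountTable(k, alphabet, table)
    for block in blocks:
        score_ok = True
        if spec.min_a is not None or spec.max_a is not None:
            score_ok = (
                block.score is not None
                and (spec.min_a is None or block.score >= spec.min_a)
                and (spec.max_a is None or block.score <= spec.max_a)
            )
        if not score_ok:
            continue
        for idx, line in enumerate(block.sequences):
            genome = line.src.split(".", 1)[0]
            if spec.genome_subset is not None and genome not in spec.genome_subset:
                continue
            qline = block.qualities.get(idx)
            seq = ""
            quals = []
            for pos, c in enumerate(line.aligned_text):
                if c == "-":
                    continue
                seq += c.upper()
                quals.append(_Q_VALUE.get(qline.qualities[pos]) if qline else None)
            if alphabet == "dna":
                seq = seq.replace("U", "T")
            gid = table.id_of(genome)
            q_active = spec.min_q is not None or spec.max_q is not None
            lo = spec.min_q if spec.min_q is not None else 0
            hi = spec.max_q if spec.max_q is not None else 10
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if any(c not in valid for c in window):
                    continue
                if q_active and qline is not None:
                    window_q = quals[i : i + k]
                    if any(v is not None and not lo <= v <= hi for v in window_q):
                        continue
                counts.add(_naive_code(window, alphabet), gid)
    return counts


def oracle_counts_file(path, k: int, spec: Optional[FilterSpec] = None,
                       alphabet: str = "dna") -> CountTable:
    return oracle_counts(Path(path).read_text(), k, spec, alphabet)
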