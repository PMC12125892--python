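"""MAF-level inclusion rules applied before any k-mer is counted.

Three orthogonal filters: a genome subset (only selected genomes' rows are
scanned), a per-base quality range over ``q``-line levels (0-9 and F=10), and
a per-block alignment-score range over the ``a``-line score. All ranges are
inclusive at both ends.

Asymmetric missing-data policy, pinned by tests: a block *without* a score
fails an active score filter (unknown alignment quality), while a sequence
*without* a ``q`` line passes an active quality filter (missing q lines are
the norm in real MAFs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .maf_io import AlignmentBlock


@dataclass(frozen=True)
class FilterSpec:
    """The active MAF-level filters; ``None`` fields are inactive."""

    genome_subset: Optional[frozenset[str]] = None
    min_q: Optional[int] = None
    max_q: Optional[int] = None
    min_a: Optional[float] = None
    max_a: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_q is not None and self.max_q is not None and self.min_q > self.max_q:
            raise ValueError("min_q > max_q")
        if self.min_a is not None and self.max_a is not None and self.min_a > self.max_a:
            raise ValueError("min_a > max_a")
        if self.genome_subset is not None:
            object.__setattr__(self, "genome_subset", frozenset(self.genome_subset))

    @property
    def q_active(self) -> bool:
        return self.min_q is not None or self.max_q is not None

    @property
    def a_active(self) -> bool:
        return self.min_a is not None or self.max_a is not None

    def warn_unseen_genomes(self, seen: set[str]) -> None:
        if self.genome_subset is None:
            return
        missing = sorted(self.genome_subset - seen)
        if missing:
            warnings.warn(
                f"requested genomes never seen in the input: {', '.join(missing)}",
                stacklevel=2,
            )


EMPTY_FILTER = FilterSpec()


def block_passes(block: AlignmentBlock, spec: FilterSpec) -> bool:
    """Score-range check; score-less blocks fail an active score filter."""
    if not spec.a_active:
        return True
    if block.score is None:
        return False
    if spec.min_a is not None and block.score < spec.min_a:
        return False
    if spec.max_a is not None and block.score > spec.max_a:
        return False
    return True


def sequence_selected(genome: str, spec: FilterSpec) -> bool:
    return spec.genome_subset is None or genome in spec.genome_subset


def window_quality_ok(qualities: Optional[list[Optional[int]]], spec: FilterSpec) -> bool:
    """True iff every base quality in the window lies in the active range.

    ``qualities`` is one k-window of per-base levels; ``None`` entries
    ('.' = missing data) and a wholly absent q line pass unconditionally.
    """
    if not spec.q_active or qualities is None:
        return True
    lo = spec.min_q if spec.min_q is not None else 0
    hi = spec.max_q if spec.max_q is not None else 10
    return all(v is None or lo <= v <= hi for v in qualities)
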