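"""Downstream analysis over a binary k-mer database.

All tools are read-only streams over database entries:

* ``top_variance`` — rank k-mers by the sample standard deviation of their
  count vector taken over *all* genomes in the table (absent genome = count
  0), selected with a bounded min-heap of size T.
* ``genome_stats`` — summary statistics of the count distribution of k-mers
  *present* in one genome (min, max, mean, median, sample variance, moment
  skewness g1).
* ``filter_database`` — boolean expressions over per-genome counts with
  ``<``, ``>``, ``=`` atoms, ``&&``/``||`` connectives and parentheses
  (``&&`` binds tighter).
* ``query`` — exact lookups (comma list or file, index-backed) and regex
  scans over decoded k-mer strings, including the G-quadruplex consensus
  d(G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+).

The two count-vector conventions differ deliberately: cross-genome variance
is only meaningful on a common genome roster (absent = 0), while a genome's
own count distribution is over the k-mers it actually contains.
"""

from __future__ import annotations

import heapq
import math
import re
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

from .errors import ExpressionError, QueryError
from .kmer_codec import decode
from .kmer_store import KmerDatabase

# ---------------------------------------------------------------------------
# variance ranking


def top_variance(db: KmerDatabase, top: int, chunk_size: int = 4096) -> list[tuple[str, float]]:
    """Top-T k-mers by count standard deviation across genomes, descending.

    The count vector spans every genome in the table with absent genomes
    contributing 0; the spread is the sample standard deviation (n-1
    denominator, 0 for a single-genome table). Ties rank the lexicographically
    smaller k-mer first. Selection uses a bounded min-heap of size T, so
    memory is O(T) regardless of database size.
    """
    if top <= 0:
        raise ValueError("top must be a positive integer")
    g = len(db.genome_names)
    # rank on the exact integer g*ss - s^2 (proportional to the variance for
    # fixed g) so ties are broken exactly, free of float round-off
    heap: list[tuple[int, int]] = []
    for code, pairs in db.iter_entries():
        s = sum(c for _, c in pairs)
        ss = sum(c * c for _, c in pairs)
        nvar = g * ss - s * s if g > 1 else 0
        item = (nvar, -code)  # larger spread wins; equal spread keeps smaller code
        if len(heap) < top:
            heapq.heappush(heap, item)
        elif item > heap[0]:
            heapq.heapreplace(heap, item)
    ranked = sorted(heap, key=lambda t: (-t[0], -t[1]))
    scale = g * (g - 1) if g > 1 else 1
    return [
        (decode(-neg, db.k, db.alphabet), math.sqrt(nvar / scale))
        for nvar, neg in ranked
    ]


# ---------------------------------------------------------------------------
# per-genome statistics


@dataclass
class GenomeStats:
    """Summary of the count distribution of k-mers present in one genome."""

    genome: str
    n: int
    min: int
    max: int
    mean: float
    median: float
    variance: float
    skewness: float


def genome_stats(db: KmerDatabase, genome: str, chunk_size: int = 8192) -> GenomeStats:
    """Statistics over the counts of k-mers present in ``genome``.

    Median is the mean of the two middle values for even n; variance uses the
    n-1 denominator (0 for n = 1); skewness is the moment coefficient
    g1 = m3 / m2^(3/2) with population moments, defined as 0 when m2 = 0.
    Counts are gathered in chunks of ``chunk_size`` entries; the chunking
    never changes the result.
    """
    try:
        gid = db.genome_names.index(genome)
    except ValueError:
        raise KeyError(f"genome {genome!r} not in this database") from None
    counts: list[int] = []
    chunk: list[int] = []
    for _, pairs in db.iter_entries():
        for g, c in pairs:
            if g == gid:
                chunk.append(c)
        if len(chunk) >= chunk_size:
            counts.extend(chunk)
            chunk = []
    counts.extend(chunk)
    if not counts:
        return GenomeStats(genome, 0, 0, 0, 0.0, 0.0, 0.0, 0.0)
    n = len(counts)
    counts.sort()
    mean = sum(counts) / n
    mid = n // 2
    median = float(counts[mid]) if n % 2 else (counts[mid - 1] + counts[mid]) / 2
    m2 = sum((c - mean) ** 2 for c in counts) / n
    m3 = sum((c - mean) ** 3 for c in counts) / n
    variance = m2 * n / (n - 1) if n > 1 else 0.0
    skewness = m3 / m2**1.5 if m2 > 0 else 0.0
    return GenomeStats(genome, n, counts[0], counts[-1], mean, median, variance, skewness)


# ---------------------------------------------------------------------------
# boolean expression filtering


@dataclass(frozen=True)
class Atom:
    name: str
    op: str  # one of < > =
    value: int

    def evaluate(self, counts: dict[str, int]) -> bool:
        c = counts.get(self.name, 0)
        if self.op == "<":
            return c < self.value
        if self.op == ">":
            return c > self.value
        return c == self.value

    def names(self) -> set[str]:
        return {self.name}


@dataclass(frozen=True)
class And:
    terms: tuple

    def evaluate(self, counts: dict[str, int]) -> bool:
        return all(t.evaluate(counts) for t in self.terms)

    def names(self) -> set[str]:
        return set().union(*(t.names() for t in self.terms))


@dataclass(frozen=True)
class Or:
    terms: tuple

    def evaluate(self, counts: dict[str, int]) -> bool:
        return any(t.evaluate(counts) for t in self.terms)

    def names(self) -> set[str]:
        return set().union(*(t.names() for t in self.terms))


FilterExpr = Union[Atom, And, Or]

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<and>&&)|(?P<or>\|\|)|(?P<lp>\()|(?P<rp>\))"
    r"|(?P<op>[<>=])|(?P<int>-?\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_.\-]*))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ExpressionError(f"position {pos}: unexpected input {stripped[:10]!r}")
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


def parse_expr(text: str) -> FilterExpr:
    """Parse ``expr := term (|| term)*; term := factor (&& factor)*``.

    ``factor`` is a parenthesized expression or an atom ``NAME op INTEGER``;
    ``&&`` binds tighter than ``||``; whitespace is insignificant.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek() -> Optional[tuple[str, str, int]]:
        return tokens[pos] if pos < len(tokens) else None

    def take(kind: str) -> tuple[str, str, int]:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ExpressionError(f"position {len(text)}: unexpected end of expression")
        if tok[0] != kind:
            raise ExpressionError(f"position {tok[2]}: expected {kind}, got {tok[1]!r}")
        pos += 1
        return tok

    def parse_or() -> FilterExpr:
        terms = [parse_and()]
        while peek() and peek()[0] == "or":
            take("or")
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> FilterExpr:
        terms = [parse_factor()]
        while peek() and peek()[0] == "and":
            take("and")
            terms.append(parse_factor())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_factor() -> FilterExpr:
        tok = peek()
        if tok is None:
            raise ExpressionError(f"position {len(text)}: unexpected end of expression")
        if tok[0] == "lp":
            take("lp")
            inner = parse_or()
            take("rp")
            return inner
        name = take("name")
        op = take("op")
        value = take("int")
        return Atom(name[1], op[1], int(value[1]))

    expr = parse_or()
    if pos != len(tokens):
        tok = tokens[pos]
        raise ExpressionError(f"position {tok[2]}: unexpected token {tok[1]!r}")
    return expr


def filter_database(
    db: KmerDatabase, expr: Union[str, FilterExpr]
) -> Iterator[tuple[int, list[tuple[int, int]]]]:
    """Yield database entries whose count vector satisfies ``expr``.

    Genomes absent from a k-mer contribute count 0; every name in the
    expression must exist in the database's genome table.
    """
    if isinstance(expr, str):
        expr = parse_expr(expr)
    known = set(db.genome_names)
    unknown = sorted(expr.names() - known)
    if unknown:
        raise ExpressionError(f"unknown genome name(s) in expression: {', '.join(unknown)}")
    names = db.genome_names
    for code, pairs in db.iter_entries():
        counts = {names[g]: c for g, c in pairs}
        if expr.evaluate(counts):
            yield code, pairs


def write_filtered(db: KmerDatabase, expr: Union[str, FilterExpr], out_path):
    """Materialize :func:`filter_database` output as a new database."""
    from .kmer_codec import GENOME_ID_BITS, remainder_bits
    from .kmer_store import is_binned, write_database

    binned = is_binned(db.k, db.alphabet)
    rb = remainder_bits(db.k, db.alphabet, binned)

    def stream():
        current_prefix = -1
        records: list[tuple[int, int]] = []
        for code, pairs in filter_database(db, expr):
            prefix = code >> rb if binned else 0
            remainder = code & ((1 << rb) - 1) if binned else code
            if prefix != current_prefix:
                if records:
                    yield current_prefix, records
                current_prefix, records = prefix, []
            for gid, count in pairs:
                records.append(((remainder << GENOME_ID_BITS) | gid, count))
        if records:
            yield current_prefix, records

    return write_database(stream(), out_path, db.k, db.alphabet, list(db.genome_names))


# ---------------------------------------------------------------------------
# queries


def g4_pattern() -> str:
    """G-quadruplex consensus d(G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+), N = any base."""
    return r"G{3,}[ACGT]{1,7}G{3,}[ACGT]{1,7}G{3,}[ACGT]{1,7}G{3,}"


QueryResult = list[tuple[str, list[tuple[str, int]]]]


def query(
    db: KmerDatabase,
    kmers: Optional[Sequence[str]] = None,
    list_file=None,
    regex: Optional[str] = None,
) -> QueryResult:
    """Exact or regex query against the database.

    Exact queries (a k-mer list and/or a file of one k-mer per line) go
    through the Prefix index; a regex scans every decoded k-mer with
    substring-search semantics (``re.search``). Results keep query order for
    exact queries and code order for regex scans; absent exact queries are
    omitted.
    """
    wanted: list[str] = list(kmers or [])
    if list_file is not None:
        with open(list_file) as fh:
            wanted.extend(line.strip() for line in fh if line.strip())
    out: QueryResult = []
    for kmer in wanted:
        if len(kmer) != db.k:
            raise QueryError(f"query {kmer!r} has length {len(kmer)}, database k={db.k}")
        hits = db.lookup(kmer)
        if hits:
            out.append((kmer.upper(), hits))
    if regex is not None:
        try:
            pattern = re.compile(regex)
        except re.error as exc:
            raise QueryError(f"invalid regular expression: {exc}") from exc
        names = db.genome_names
        for code, pairs in db.iter_entries():
            kmer = decode(code, db.k, db.alphabet)
            if pattern.search(kmer):
                out.append((kmer, [(names[g], c) for g, c in pairs]))
    return out
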