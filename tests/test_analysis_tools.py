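"""Analysis tools: variance ranking, per-genome statistics, expression
filtering, queries, G-quadruplex consensus."""

import math
import random
import re

import pytest

from mafkmers.analysis_tools import (
    And,
    Atom,
    Or,
    filter_database,
    g4_pattern,
    genome_stats,
    parse_expr,
    query,
    top_variance,
    write_filtered,
)
from mafkmers.counter_small import CountTable, table_from_database
from mafkmers.errors import ExpressionError, QueryError
from mafkmers.kmer_codec import decode_dna
from mafkmers.kmer_store import KmerDatabase, write_table
from mafkmers.maf_io import GenomeTable


def _db(tmp_path, counts, k=4, genomes=("g1", "g2"), name="db"):
    """counts: {kmer_code: {gid: count}}"""
    table = CountTable(k, "dna", GenomeTable(list(genomes)))
    for code, per in counts.items():
        for gid, c in per.items():
            table.add(code, gid, c)
    return KmerDatabase.open(write_table(table, tmp_path / name))


# -- variance ----------------------------------------------------------------


def test_std_with_absent_genome_counted_as_zero(tmp_path):
    with _db(tmp_path, {7: {0: 4}}) as db:
        [(kmer, std)] = top_variance(db, 1)
    assert kmer == decode_dna(7, 4)
    assert std == pytest.approx(math.sqrt(8))  # vector (4,0), n-1 denominator


def test_equal_counts_have_zero_std(tmp_path):
    with _db(tmp_path, {7: {0: 3, 1: 3}}) as db:
        assert top_variance(db, 1)[0][1] == 0.0


def test_top_selection_matches_full_sort_oracle(tmp_path):
    rng = random.Random(19)
    counts = {}
    for code in rng.sample(range(256), 50):
        counts[code] = {g: rng.randrange(0, 9) for g in range(3) if rng.random() < 0.8}
    counts = {c: {g: n for g, n in per.items() if n} or {0: 1} for c, per in counts.items()}
    with _db(tmp_path, counts, genomes=("g1", "g2", "g3")) as db:
        got = top_variance(db, 3)
        full = top_variance(db, 50)

    def oracle_var(per):
        """Exact sample variance as a rational, so ties order exactly."""
        from fractions import Fraction

        vec = [per.get(g, 0) for g in range(3)]
        mean = Fraction(sum(vec), 3)
        return sum((v - mean) ** 2 for v in vec) / 2

    expected = sorted(
        ((oracle_var(per), code) for code, per in counts.items()),
        key=lambda t: (-t[0], t[1]),
    )
    expected = [(math.sqrt(var), code) for var, code in expected]
    assert [k for k, _ in got] == [decode_dna(c, 4) for _, c in expected[:3]]
    assert [s for _, s in got] == pytest.approx([s for s, _ in expected[:3]])
    # T = n gives the complete ordering
    assert [k for k, _ in full] == [decode_dna(c, 4) for _, c in expected]


def test_top_variance_rejects_nonpositive_t(tmp_path):
    with _db(tmp_path, {1: {0: 1}}) as db:
        with pytest.raises(ValueError):
            top_variance(db, 0)


# -- genome statistics -------------------------------------------------------


def test_degenerate_equal_counts(tmp_path):
    with _db(tmp_path, {1: {0: 2}, 2: {0: 2}, 3: {0: 2}}) as db:
        s = genome_stats(db, "g1")
    assert (s.n, s.min, s.max, s.mean, s.median) == (3, 2, 2, 2.0, 2.0)
    assert s.variance == 0.0 and s.skewness == 0.0


def test_moment_statistics_worked_case(tmp_path):
    """Counts [1, 2, 3, 10]: mean 4, median 2.5, var 50/3, g1 ~ 1.0183."""
    counts = {c: {0: v} for c, v in enumerate([1, 2, 3, 10])}
    with _db(tmp_path, counts) as db:
        s = genome_stats(db, "g1")
    # independent recomputation with the stated estimators
    data = [1, 2, 3, 10]
    mean = sum(data) / 4
    m2 = sum((x - mean) ** 2 for x in data) / 4
    m3 = sum((x - mean) ** 3 for x in data) / 4
    assert s.mean == pytest.approx(4.0, rel=1e-9)
    assert s.median == pytest.approx(2.5, rel=1e-9)
    assert s.variance == pytest.approx(50 / 3, rel=1e-9)
    assert s.skewness == pytest.approx(m3 / m2**1.5, rel=1e-9)
    assert s.skewness == pytest.approx(1.0183, abs=1e-4)


def test_chunk_size_never_changes_stats(tmp_path):
    rng = random.Random(23)
    counts = {c: {0: rng.randrange(1, 30)} for c in rng.sample(range(250), 40)}
    with _db(tmp_path, counts) as db:
        base = genome_stats(db, "g1", chunk_size=10**6)
        for chunk in (1, 7):
            assert genome_stats(db, "g1", chunk_size=chunk) == base


def test_stats_exclude_kmers_absent_from_the_genome(tmp_path):
    with _db(tmp_path, {1: {0: 5}, 2: {1: 7}}) as db:
        s = genome_stats(db, "g1")
    assert (s.n, s.mean) == (1, 5.0)


def test_unknown_genome_raises(tmp_path):
    with _db(tmp_path, {1: {0: 1}}) as db:
        with pytest.raises(KeyError):
            genome_stats(db, "nope")


# -- expression filter -------------------------------------------------------


def test_parse_parenthesized_expression():
    expr = parse_expr("hg38>2 && (mm10<1 || rn6=0)")
    assert expr == And((Atom("hg38", ">", 2), Or((Atom("mm10", "<", 1), Atom("rn6", "=", 0)))))


def test_and_binds_tighter_than_or():
    expr = parse_expr("a>1 || b>1 && c>1")
    assert expr == Or((Atom("a", ">", 1), And((Atom("b", ">", 1), Atom("c", ">", 1)))))


@pytest.mark.parametrize("bad", ["hg38 >> 2", "hg38>", "(a>1", "a>1 &&", "a ? 1"])
def test_malformed_expressions_report_position(bad):
    with pytest.raises(ExpressionError, match="position"):
        parse_expr(bad)


def test_filter_absent_genome_counts_as_zero(tmp_path):
    with _db(tmp_path, {7: {0: 3}}, genomes=("hg38", "mm10")) as db:
        kept = list(filter_database(db, "hg38>2 && mm10<1"))
        assert [code for code, _ in kept] == [7]
        assert list(filter_database(db, "hg38=0")) == []
        assert [c for c, _ in filter_database(db, "mm10=0")] == [7]


def test_filter_matches_per_record_oracle(tmp_path):
    rng = random.Random(3)
    counts = {}
    for code in rng.sample(range(200), 100):
        per = {g: rng.randrange(0, 5) for g in range(2)}
        per = {g: n for g, n in per.items() if n}
        if per:
            counts[code] = per
    expr_text = "g1>2 || g1=1 && g2<3"
    with _db(tmp_path, counts) as db:
        kept = [code for code, _ in filter_database(db, expr_text)]
    expected = [
        code
        for code in sorted(counts)
        if counts[code].get(0, 0) > 2
        or (counts[code].get(0, 0) == 1 and counts[code].get(1, 0) < 3)
    ]
    assert kept == expected


def test_always_true_filter_is_identity_and_roundtrips(tmp_path):
    counts = {c: {0: c % 5 + 1} for c in range(40)}
    with _db(tmp_path, counts) as db:
        kept = list(filter_database(db, "g1>-1"))
        assert [c for c, _ in kept] == sorted(counts)
        out = write_filtered(db, "g1>-1", tmp_path / "copy")
        original = table_from_database(db)
    with KmerDatabase.open(out) as copy:
        assert table_from_database(copy) == original


def test_unknown_name_in_expression_is_named(tmp_path):
    with _db(tmp_path, {1: {0: 1}}) as db:
        with pytest.raises(ExpressionError, match="zz9"):
            list(filter_database(db, "zz9>0"))


def test_tools_leave_database_bytes_unchanged(tmp_path):
    counts = {c: {0: 1 + c % 3, 1: 1} for c in range(30)}
    db = _db(tmp_path, counts)
    before = (db.data_path.read_bytes(), db.idx_path.read_bytes())
    top_variance(db, 5)
    genome_stats(db, "g1")
    list(filter_database(db, "g1>0"))
    query(db, regex="^AC")
    db.close()
    after = (db.data_path.read_bytes(), db.idx_path.read_bytes())
    assert after == before


# -- queries -----------------------------------------------------------------


def test_exact_query_composes_lookups(tmp_path):
    with _db(tmp_path, {27: {0: 3}, 255: {1: 1}}) as db:  # ACGT, TTTT
        res = query(db, kmers=["ACGT", "TTTT", "AAAA"])
    assert [(k, dict(h)) for k, h in res] == [
        ("ACGT", {"g1": 3}),
        ("TTTT", {"g2": 1}),
    ]
    # absent k-mers are omitted; empty input gives empty output
    assert res[0][0] == "ACGT"


def test_empty_query_returns_nothing(tmp_path):
    with _db(tmp_path, {27: {0: 3}}) as db:
        assert query(db, kmers=[]) == []


def test_query_length_guard(tmp_path):
    with _db(tmp_path, {27: {0: 3}}) as db:
        with pytest.raises(QueryError):
            query(db, kmers=["ACG"])


def test_regex_query_matches_linear_scan(tmp_path):
    rng = random.Random(8)
    counts = {c: {0: 1} for c in rng.sample(range(256), 60)}
    with _db(tmp_path, counts) as db:
        res = query(db, regex="^AC")
        all_kmers = [decode_dna(c, 4) for c in sorted(counts)]
    assert [k for k, _ in res] == [k for k in all_kmers if k.startswith("AC")]


def test_invalid_regex_rejected(tmp_path):
    with _db(tmp_path, {27: {0: 1}}) as db:
        with pytest.raises(QueryError):
            query(db, regex="([")


def test_query_from_file(tmp_path):
    listing = tmp_path / "list.txt"
    listing.write_text("ACGT\nTTTT\n")
    with _db(tmp_path, {27: {0: 2}}) as db:
        res = query(db, list_file=listing)
    assert res == [("ACGT", [("g1", 2)])]


# -- G-quadruplex ------------------------------------------------------------


def _oracle_g4(seq: str) -> bool:
    """Independent backtracking scanner for G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+.

    Loops (N) admit any base, including G, so a stem may donate trailing Gs
    to its loop; this matcher explores those splits explicitly instead of
    relying on a regex engine.
    """

    def stem_then_rest(i: int, stems_left: int) -> bool:
        run = 0
        while i + run < len(seq) and seq[i + run] == "G":
            run += 1
        if run < 3:
            return False
        if stems_left == 1:
            return True
        for used in range(3, run + 1):
            for loop in range(1, 8):
                j = i + used + loop
                if j < len(seq) and stem_then_rest(j, stems_left - 1):
                    return True
        return False

    return any(stem_then_rest(i, 4) for i in range(len(seq)))


def test_g4_minimal_instance_matches():
    assert re.search(g4_pattern(), "GGGAGGGAGGGAGGG")
    assert re.search(g4_pattern(), "GGGGTTAGGGTTAGGGTTAGGGG")


def test_three_g_runs_do_not_match():
    assert not re.search(g4_pattern(), "GGGAGGGAGGGA")


def test_loop_longer_than_seven_fails():
    assert not re.search(g4_pattern(), "GGG" + "A" * 8 + "GGGAGGGAGGG")


def test_g4_against_independent_scanner():
    rng = random.Random(99)
    pattern = re.compile(g4_pattern())
    disagreements = []
    for _ in range(2000):
        n = rng.randint(15, 25)
        # G-rich so matches actually occur
        seq = "".join(rng.choice("GGGACT") for _ in range(n))
        if bool(pattern.search(seq)) != _oracle_g4(seq):
            disagreements.append(seq)
    assert not disagreements
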