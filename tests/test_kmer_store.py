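"""Binary database: round-trips, random access, dump formats."""

import random

import pytest

from mafkmers.counter_small import CountTable, count_file_small, table_from_database
from mafkmers.errors import QueryError
from mafkmers.kmer_codec import decode, decode_dna
from mafkmers.kmer_store import (
    KmerDatabase,
    dump_combined,
    dump_per_genome,
    key_width,
    write_database,
    write_table,
)
from mafkmers.maf_io import GenomeTable


def _random_table(seed, k=12, n_genomes=4, n_kmers=200, alphabet="dna"):
    rng = random.Random(seed)
    gt = GenomeTable([f"g{i}" for i in range(n_genomes)])
    table = CountTable(k, alphabet, gt)
    space = 4**k if alphabet == "dna" else 32**k
    for _ in range(n_kmers):
        code = rng.randrange(space)
        for gid in range(n_genomes):
            if rng.random() < 0.5:
                table.add(code, gid, rng.randrange(1, 50))
    return table


@pytest.mark.parametrize("seed,k,alphabet", [(0, 12, "dna"), (1, 7, "dna"),
                                             (2, 33, "dna"), (3, 5, "protein")])
def test_write_read_round_trip(tmp_path, seed, k, alphabet):
    table = _random_table(seed, k=k, alphabet=alphabet)
    path = write_table(table, tmp_path / "db")
    with KmerDatabase.open(path) as db:
        assert db.k == k and db.alphabet == alphabet
        assert table_from_database(db) == table


def test_key_width_formula():
    # DNA k>10: ceil((2*(k-5) + 8) / 8) bytes of key
    assert key_width(12, "dna") == (2 * (12 - 5) + 8 + 7) // 8
    assert key_width(33, "dna") == (2 * (33 - 5) + 8 + 7) // 8
    # small k / protein store the full code
    assert key_width(5, "dna") == (2 * 5 + 8 + 7) // 8
    assert key_width(5, "protein") == (5 * 5 + 8 + 7) // 8


def test_empty_database_has_full_index(tmp_path):
    path = write_database([], tmp_path / "db", 12, "dna", ["g0"])
    with KmerDatabase.open(path) as db:
        assert db.n_prefix == 1024
        assert db.total_records == 0
        assert db.lookup("A" * 12) == []


def test_write_is_deterministic(tmp_path):
    table = _random_table(9)
    p1 = write_table(table, tmp_path / "a")
    p2 = write_table(table, tmp_path / "b")
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a.mkc.idx").read_bytes() == (tmp_path / "b.mkc.idx").read_bytes()


def test_lookup_matches_linear_scan(tmp_path):
    rng = random.Random(42)
    table = _random_table(42, k=12, n_kmers=300)
    path = write_table(table, tmp_path / "db")
    with KmerDatabase.open(path) as db:
        scan = {}
        for code, pairs in db.iter_entries():
            scan[decode_dna(code, 12)] = [(db.genome_names[g], c) for g, c in pairs]
        present = rng.sample(sorted(scan), 50)
        for kmer in present:
            assert db.lookup(kmer) == scan[kmer]
        misses = 0
        while misses < 50:
            kmer = "".join(rng.choice("ACGT") for _ in range(12))
            if kmer not in scan:
                assert db.lookup(kmer) == []
                misses += 1


def test_lookup_rejects_bad_queries(tmp_path):
    path = write_table(_random_table(1), tmp_path / "db")
    with KmerDatabase.open(path) as db:
        with pytest.raises(QueryError):
            db.lookup("ACGT")  # wrong length
        with pytest.raises(QueryError):
            db.lookup("N" * 12)  # unencodable


def test_combined_dump_format_and_order(tmp_path):
    gt = GenomeTable(["hg38", "mm10"])
    table = CountTable(4, "dna", gt)
    table.add(27, 0, 3)  # ACGT
    table.add(27, 1, 1)
    table.add(0, 1, 2)  # AAAA
    path = write_table(table, tmp_path / "db")
    with KmerDatabase.open(path) as db:
        dump_combined(db, tmp_path / "dump.txt")
    lines = (tmp_path / "dump.txt").read_text().splitlines()
    assert lines == ["AAAA mm10:2", "ACGT hg38:3 mm10:1"]


def test_dump_round_trips_to_the_same_table(tmp_path):
    table = _random_table(3, k=8, n_kmers=100)
    path = write_table(table, tmp_path / "db")
    with KmerDatabase.open(path) as db:
        dump_combined(db, tmp_path / "dump.txt")
        names = db.genome_names
    rebuilt = CountTable(8, "dna", GenomeTable(names))
    from mafkmers.kmer_codec import encode_dna

    for line in (tmp_path / "dump.txt").read_text().splitlines():
        kmer, *pairs = line.split(" ")
        for pair in pairs:
            name, count = pair.rsplit(":", 1)
            rebuilt.add(encode_dna(kmer), rebuilt.genome_table.id_of(name), int(count))
    assert rebuilt == table


def test_per_genome_dumps_conserve_mass_and_create_empty_files(tmp_path):
    gt = GenomeTable(["a", "b", "silent"])
    table = CountTable(3, "dna", gt)
    table.add(5, 0, 2)
    table.add(5, 1, 1)
    table.add(9, 0, 4)
    path = write_table(table, tmp_path / "db")
    with KmerDatabase.open(path) as db:
        paths = dump_per_genome(db, tmp_path / "per")
    assert sorted(p.name for p in paths) == ["a.kmers", "b.kmers", "silent.kmers"]
    total = 0
    for p in paths:
        for line in p.read_text().splitlines():
            total += int(line.split()[1])
        assert p.read_text() == "" or all(
            len(line.split()) == 2 for line in p.read_text().splitlines()
        )
    assert total == table.total()
    assert (tmp_path / "per" / "silent.kmers").read_text() == ""


def test_dump_lines_sorted_lexicographically(make_fixture, tmp_path):
    path = make_fixture(seed=6, n_genomes=3, n_blocks=6)
    table = count_file_small(path, 5)
    db_path = write_table(table, tmp_path / "db")
    with KmerDatabase.open(db_path) as db:
        dump_combined(db, tmp_path / "d.txt")
    kmers = [line.split()[0] for line in (tmp_path / "d.txt").read_text().splitlines()]
    assert kmers == sorted(kmers)
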