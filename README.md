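# mafkmers

Per-genome k-mer counting and analysis **directly on MAF multiple-alignment
files**.

Whole-genome alignments (UCSC Multiple Alignment Format) hold the sequences
of many genomes side by side, but conventional k-mer counters only accept
per-genome FASTA, so counting k-mers in an alignment normally means exploding
the MAF into one FASTA per genome and losing the per-genome association in a
post-processing join. `mafkmers` counts every length-k window of every
ungapped `s`-line row as it streams through the alignment, keyed by
*(k-mer, genome)*, and keeps the MAF-specific context available as filters:
per-block alignment scores (`a score=`), per-base quality levels (`q` lines,
levels 0–9 and F = finished), and genome subsets.

## Method

Genome names are derived from `s`-line sources (`hg38.chr1` → `hg38`) and
assigned IDs 0–255 in first-seen order; each ID must fit 8 bits. K-mers are
bit-packed — 2 bits/base for DNA/RNA (A=00, C=01, G=10, T=U=11; k ≤ 64),
5 bits/residue over a fixed 25-symbol alphabet for protein (k ≤ 25) — with
no reverse-complement canonicalization: alignment rows are counted exactly
as written. Windows containing N or any other foreign symbol are skipped.

Two engines share one result contract:

* **map engine** (default for k ≤ 10): per-chunk associative maps
  `code → {genome_id → count}`, merged pointwise.
* **disk engine** (default for k > 10): each code splits into a 10-bit
  **Prefix** (first 5 bases, choosing one of 1024 bins), a 10-bit **Infix**
  (partial-sort key) and a **Suffix**. Records pack
  `(infix‖suffix) << 8 | genome_id`; full bins are sorted and compacted,
  merged into per-Prefix packages, spilled to disk past a threshold, and
  finally each Prefix is fully sorted, aggregated and written at a
  precomputed byte offset.

The result is a binary database (`NAME.mkc` + `NAME.mkc.idx`) whose
per-Prefix byte-offset index supports random-access queries that touch only
one Prefix's byte range. Worker counts (or a total split 30 % readers / 70 %
package managers) and both spill thresholds are configuration only — the
output bytes are identical for every setting.

On top of the database: combined text dumps (one line per k-mer,
`KMER name:count name:count …`), per-genome dumps, ranking by the sample
standard deviation of the count vector across genomes (absent genome = 0),
per-genome summary statistics (min/max/mean/median/sample variance/moment
skewness g1), boolean count filters (`<, >, =, &&, ||`, parentheses), and
exact/regex queries including the G-quadruplex consensus
d(G₃₊N₁₋₇G₃₊N₁₋₇G₃₊N₁₋₇G₃₊).

## Worked example

```sh
mafkmers gen-fixture --seed 5 --genomes 3 --blocks 6 --out demo.maf
mafkmers count demo.maf --k 5 --out demo
head -3 demo.counts.txt
```

```
AAAAG g001:1
AAAGG g000:1 g001:2
AAATT g001:2
```

Each line is one 5-mer followed by `genome:count` pairs in genome-ID order —
e.g. `AAAGG` occurs once in `g000` and twice in `g001`, never in `g002`.
Query and analyze the binary database the same run produced:

```sh
mafkmers tools variance demo --top 3
```

```
kmer	stddev
ATTTA	1.73205
CTGGA	1.73205
AAATT	1.1547
```

`ATTTA` has count vector (0, 3, 0) across the three genomes: sample standard
deviation √3 ≈ 1.73205, the largest spread in this small fixture; ties are
listed in lexicographic order.

```sh
mafkmers tools filter demo --expr 'g000>0 && g001=0'   # k-mers private to g000 vs g001
mafkmers query demo --kmers AAAGG,AAATT               # exact, index-backed
mafkmers query demo --g4                               # G-quadruplex consensus scan
```

The same operations are available as a library (`mafkmers.count_file_small`,
`mafkmers.count_file_disk`, `mafkmers.KmerDatabase`, …).

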