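# Methods

## Problem and data model

A MAF file stores a whole-genome alignment as blocks: an `a` line (optionally
with an aligner score), one `s` line per aligned genome fragment, and
optional `q` (per-base quality), `i` and `e` lines. The first `s` line of a
block is its reference. `mafkmers` counts, for every genome, how often each
length-k substring occurs over the *ungapped* `s`-line rows — all rows,
including the reference — so the unit of observation is a (k-mer, genome)
pair, not a k-mer alone.

Decisions a MAF-aware counter has to make, and the ones taken here:

* **Genome identity.** The text before the first `.` of the `s`-line source
  (`hg38.chr1` → `hg38`), following the UCSC `database.chromosome`
  convention; per-genome outputs need genome-level keys. IDs 0–255 are
  assigned in first-seen order over *all* `s` lines (filters never shift ID
  assignment), and the 8-bit ID field makes >256 genomes a hard capacity
  error.
* **Strands and case.** Minus-strand rows are counted exactly as written in
  the alignment (MAF stores alignment-oriented text); nothing is
  reverse-complemented and no canonical k-mer representation is used —
  deliberately unlike FASTA k-mer counters, because alignment-context
  counting must distinguish strands. Soft-masked lowercase is uppercased and
  treated like ordinary sequence.
* **Ambiguity.** Windows containing a symbol outside the alphabet (N, IUPAC
  codes, `*`, J for protein) are dropped, not substituted.
* **Qualities.** `q`-line symbols map `'0'`–`'9'` → 0–9 and `'F'`
  (finished) → 10, so a quality range can express "finished bases only";
  `'.'` (missing) carries no value and never blocks a window.

## Alphabets and encoding

DNA/RNA uses 2 bits/base, A=00 C=01 G=10 T=11, U folded to T, k ≤ 64 (a
128-bit key budget). Protein uses 5 bits/residue over the fixed 25-symbol
alphabet `A C D E F G H I K L M N P Q R S T V W Y B Z X U O` (20 standard
residues plus ambiguity and rare codes), k ≤ 25. Both symbol orders are the
alphabet's canonical order, so integer code order equals lexicographic
string order and sorted databases dump in sorted text order.

## Filters

Three orthogonal, pre-counting filters: genome subset, per-base quality
range, per-block score range; all ranges inclusive. Missing data is handled
asymmetrically and pinned by tests: a block *without* a score fails an
active score filter (its alignment quality is unknown), while a row
*without* a `q` line passes an active quality filter (q lines are rare in
real MAFs; failing them would silently empty most files). Filters are pure
restrictions: filtered counts are pointwise ≤ unfiltered counts.

## Counting engines

**Map engine (default k ≤ 10).** Blocks are partitioned into W contiguous
chunks at block boundaries, each chunk counted into a local map
`code → {genome_id → count}`, and the maps merged pointwise. Merging is
associative and commutative, so the result is provably independent of W and
of chunk assignment — the property the parallelism contract requires.

**Disk engine (default k > 10).** The code splits into a 10-bit Prefix
(first 5 bases → 1024 bins), 10-bit Infix, and 2·(k−10)-bit Suffix. Records
pack `(infix‖suffix) << 8 | genome_id` so integer record order is (Infix,
Suffix, genome ID). Full bins (default threshold 65 536 records) are sorted
and compacted (adjacent equal keys merge by summing counts), merged into one
sorted package per Prefix, and packages past the element threshold (default
262 144) are spilled to a temp file as byte-offset segments. Finalization
merges all segments of a Prefix, aggregates duplicates, and streams the
sorted result into the database. Any stable sort is contract-equivalent to
the radix sort on these fixed-width keys. The stored remainder keeps the
Infix bits: stripping them irrecoverably would make k-mers unreconstructible
in dumps, so "removing" Prefix and Infix is interpreted as removing them
from the *sort key's* leading position, not from storage.

For k ≤ 10 or protein input the Prefix split is undefined; the same pipeline
runs with a single prefix-0 section and the full code as remainder, so both
engines cover every legal k and their outputs can be compared directly.

Reader/manager thread counts — or a single total, split 30 % readers / 70 %
managers — and both thresholds are accepted as configuration. The pipeline
here executes deterministically; in a truly concurrent build these knobs
affect scheduling only, and the binding contract (pinned byte-for-byte by
tests across worker counts and thresholds 1/16/default) is that they never
change the output.

## Binary database

`NAME.mkc` holds fixed-width little-endian records grouped by Prefix;
`NAME.mkc.idx` holds the alphabet tag, k, the genome table (names in ID
order) and one (byte offset, record count) pair per Prefix. Key width is
⌈(R+8)/8⌉ bytes with R the remainder bit width (2·(k−5) binned, the full
code width otherwise); counts are 4-byte unsigned (overflow raises rather
than wraps). Lookups seek to the query's Prefix range and binary-search with
the genome-ID byte masked, touching no other Prefix's bytes. Empty
databases still carry the full index. Writing is deterministic: equal
inputs give byte-identical files.

## Analysis tools

* **Variance ranking** uses the count vector over *all* genomes with absent
  = 0 (cross-genome spread is only meaningful on a common roster) and the
  sample standard deviation (n−1 denominator; 0 for one genome). Selection
  is a bounded min-heap of size T; ranking compares the exact integer
  G·Σc²−(Σc)² rather than floating-point variances so exact ties are broken
  purely by ascending code (lexicographic k-mer order).
* **Per-genome statistics** are computed over the counts of k-mers *present*
  in the genome — the complementary convention, matching the question "what
  does this genome's count distribution look like". Median is the midpoint
  average for even n, variance uses n−1 (0 for n = 1), and skewness is the
  moment coefficient g1 = m3/m2^(3/2) with population moments, 0 when
  m2 = 0.
* **Expression filter** grammar: `expr := term (|| term)*`,
  `term := factor (&& factor)*`, `factor := atom | ( expr )`,
  `atom := NAME op INTEGER` with op ∈ {<, >, =}; `&&` binds tighter than
  `||`, `=` is exact integer equality, absent genomes count 0, integers may
  be negative (so `name>-1` is the identity filter).
* **Queries**: exact lists/files go through the Prefix index; regex queries
  scan decoded k-mer strings with substring-search semantics (`re.search`),
  Python's `re` dialect. The bundled G-quadruplex consensus is
  `G{3,}[ACGT]{1,7}G{3,}[ACGT]{1,7}G{3,}[ACGT]{1,7}G{3,}` — four runs of
  ≥3 guanines separated by loops of 1–7 arbitrary bases.

All tools are read-only; tests assert the database bytes are unchanged after
every tool runs.

## Synthetic data and what it does (not) show

The generator emits structurally complete MAF: configurable genome and block
counts, per-column gap and ambiguity probabilities, optional `q` lines drawn
from a weighted quality distribution (F included), optional block scores
with a missing-score probability, and a strand mix — byte-reproducible from
a seed. Default shapes used throughout the tests (2–8 genomes, 5–50 blocks
of 15–60 columns, gap rate ≤ 0.2, ambiguity ≤ 0.05) keep oracle-vs-engine
comparisons exhaustive yet fast; the acceptance run uses 12 configurations
× k ∈ {3, 10, 11, 20, 33} and finishes in seconds on one core. Columns are
i.i.d.: there is no substitution model, no phylogeny, no realistic repeat
structure. Passing tests therefore demonstrate *counting correctness and
format handling*, not biological plausibility of the inputs; counting is
exact arithmetic, so correctness on these fixtures transfers to real MAFs
with the same structural features.

The brute-force oracle recounts everything with plain string slicing and
nested dicts, sharing only the MAF parser with the engines; its genome
naming, filtering, quality mapping and encoding are reimplemented
independently (positional base-|Σ| arithmetic rather than the bit codec).

## Numerical and degenerate-input choices

Exact integer arithmetic everywhere in counting; floats appear only in
reported statistics. Empty files yield empty tables and valid empty
databases. Sequences shorter than k contribute nothing. Score-less blocks
and q-less rows follow the asymmetric rule above. `s`-line size fields that
disagree with the gapped text are warnings, not errors (such files exist in
the wild); malformed field counts are hard parse errors naming the line.

## Known limitations

No interval indexing of MAF, no bgzf, no `e`-line gap semantics beyond
pass-through, no canonical k-mers or minimizers, no approximate counting,
no compression of the record section, and single-writer databases only.
Counts are capped at 2³²−1 per (k-mer, genome). The deterministic pipeline
trades wall-clock parallelism for reproducibility; the format and contracts
are designed so a concurrent implementation must produce the same bytes.
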