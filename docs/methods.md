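# Methods

## Scope and pipeline shape

srnapipe implements the computational core of a miRNA-seq identification
workflow for single-end short reads: raw data reading → adapter removal →
sequence alignment → read counting, plus the sample management, parallel
scheduling and QC statistics needed to run it over many samples. Genome
mapping of mRNA libraries, differential expression, and novel-miRNA
discovery are out of scope; the count matrix this package produces is the
natural input to downstream tools for those analyses.

## Sequence IO

FASTQ is parsed as strict 4-line records (gzip by `.gz` suffix); malformed
records abort with their 1-based record number. Internally all coordinates
are 0-based half-open; the SAM writer is the single conversion point to
1-based POS. Reads may contain `N`; references must be over {A,C,G,T} —
references are curated sequences, and a read position against anything is
then a plain character comparison (`N` never matches).

**Phred encoding detection.** With `encoding="auto"` the whole file's
quality characters are scanned before any record is emitted. Any character
below `;` (ASCII 59) is impossible under offset 64, so the file is
Phred+33. Otherwise, a maximum character at or above `K` (ASCII 75 — a
Phred+33 score of 42, above the realistic base-call range) indicates
Phred+64. Files whose characters all fall in `[;..J]` are consistent with
both offsets and are rejected with a request for an explicit encoding:
never silently misinterpret. Offset-64 characters below `@` are Solexa-era
negative scores and are clamped to 0 on decode so quality values always
lie in [0, 62].

## Adapter trimming

Small-RNA inserts are shorter than the read, so informative reads run into
the 3' adapter. For each read the trimmer scans positions left to right
and accepts the first position *p* whose overlap with the adapter prefix
(`overlap = min(adapter length, read length − p)`, required ≥ `min_overlap`)
has at most `floor(max_error_rate × overlap)` substitutions. The insert
`read[:p]` is kept if its length lies in `[min_len, max_len]`; otherwise
the read is classified `too_short`/`too_long` (carrying the untouched read
for audit). No qualifying position means `untrimmed`.

Choices: leftmost qualifying position (not best-scoring) wins — it
maximizes adapter removal and is deterministic; substitutions only, no
indels — this keeps the exhaustive per-position scorer an exact oracle and
matches the mismatch-count alignment model downstream. Defaults
(`min_overlap=5`, `max_error_rate=0.1`, `min_len=16`, `max_len=28`,
TruSeq small-RNA adapter `TGGAATTCTCGGGTGCCAAGG`) reflect standard
small-RNA practice around 21–23 nt mature miRNAs.

## Alignment

Ungapped, substitution-only alignment with the reporting semantics of a
`-v`-mode short-read aligner:

1. enumerate every placement (reference, offset, strand) of the read with
   mismatches ≤ *v* (reverse strand = reverse complement of the read
   against the forward reference; `forward_only` disables it);
2. if `best_strata`, keep only the minimal-mismatch stratum;
3. if the kept set exceeds *m*, the read is **suppressed** (status
   `suppressed`, nothing reported); otherwise it is `aligned` with all
   kept placements, sorted by (reference input order, offset, strand with
   `+` before `-`); no placements at all means `unaligned`.

*m* applies to the kept (reportable) set — i.e. after best-stratum
filtering — so two identical references suppress an exact read under
`m=1` even though each placement individually is perfect.

**Candidate generation.** An exact k-mer index (seed length 8 by default)
over the reference sequences supports pigeonhole search: the read is split
into *v*+1 contiguous, near-equal partitions; any ≤ *v*-mismatch placement
leaves at least one partition mismatch-free, so looking up each
partition's leading seed k-mer finds a superset of all true placements,
each then verified by direct mismatch counting. References shorter than
the seed, and reads whose partitions are shorter than the seed, fall back
to full enumeration, which is exact by construction. This favors
correctness and testability over genome-scale throughput (an FM-index is a
non-goal); references here are miRNA-scale sequences and genome slices.

## Cascade

A cascade is an ordered list of (stage name, reference set, policy). In
**separate** mode every read is evaluated at every stage. In **iterative**
mode stage *i* receives exactly the reads neither aligned nor suppressed
at stages < *i*; `Alignment.round` records the stage position. Suppressed
reads are terminal by default — they were reportable, just not reported,
which is different from unmapped — but `suppressed_continue=True`
implements the alternative reading where they flow on like unmapped reads.
Stage order is the user's choice; assigning to the most specific reference
first (mature → precursor → genome) is the conservative default
recommendation, since mature sequences are embedded in precursors and
order visibly shifts per-stage totals.

## Counting

For each aligned read, *k* is the number of distinct references in its
reported stratum (multiple placements on one reference count once: the
feature, not the placement, is what is quantified). `fractional` (default)
assigns 1/*k* to each — totals are conserved exactly, which is why counts
are `fractions.Fraction` internally and the TSV writer emits both a
4-decimal rendering and an exact `num/den` sidecar. `all` assigns 1 to
each; `unique_only` drops multi-mappers. The m-suppression path remains
available through the alignment policy for users who want the aligner
itself to discard ambiguous reads. Features are keyed
(stage, reference id) and ordered by stage then reference input order.

## Sample management and scheduling

Auto mode groups a directory's FASTQ files (`.fastq/.fq[.gz]`) into
samples by stripping trailing lane/read/part suffixes (`_L<d>`, `_R1`,
`_<d>`) from the basename; files sharing the stripped name are one
sample's replicates, merged by concatenation in sorted-file order. A file
fitting no rule becomes its own sample with a warning. Program mode loads
a TSV sheet (`sample_id`, `file`, arbitrary trait columns); rows sharing a
sample id merge their files, and their trait values must agree. The
filename-stripping patterns are this package's own convention and are
deliberately explicit so the behavior is testable; trait/group
relationships always come from the sheet, never from filenames.

Work is partitioned at sample granularity: samples sorted by total bytes
descending, each assigned to the currently lightest bin (ties to the
lowest bin index) — the classic LPT greedy, whose makespan is within
(4/3 − 1/(3·workers)) of optimal. Each bin runs in its own process with no
shared state, so outputs are bitwise independent of the worker count.

## QC statistics

Per-cycle quality summarizes cycle *i* over every read at least *i*+1
bases long (count, mean, min/max, quartiles by linear interpolation
between order statistics — fixed because quartile conventions vary and
tests need one). Depth adds 1 over `[offset, offset + read length)` per
alignment, strand-blind, and is reported raw (no library-size
normalization). Insert lengths histogram the retained inserts of trimmed
reads, optionally including untrimmed full lengths. All three are emitted
as tables; plots are rendered from the tables.

## Synthetic data generator

`simulate_library` emulates a single-end small-RNA library: each read is a
mature-miRNA insert drawn from an abundance vector, with iid substitution
errors, the 3' adapter appended, and random filler out to the fixed read
length; per-cycle Phred scores are Gaussian (mean 34, sd 3, clamped to
[2, 40]). Defaults fix the study conditions used throughout the tests: 20
references of 20–23 nt, Dirichlet(1) abundances, 50,000 reads, 1%
substitution rate, TruSeq small-RNA adapter, 36 cycles. A single seeded
numpy generator threads through every draw, so outputs are
byte-reproducible and the recorded `GroundTruth` (per-read source, insert,
error positions; per-feature totals) reconciles with the emitted files
exactly.

What the generator does **not** emulate — position-dependent Illumina
error profiles, indels, adapter dimers, quality/error correlation,
ligation bias — bounds what passing tests show: they demonstrate the
pipeline's bookkeeping, reporting semantics and estimator are correct
under the stated error model, not that real-library artifacts are
handled. `make_homolog_pair` provides the canonical identical-sequence
pair (two ids, one synthetic 22-nt sequence) for the suppression and
fractional-counting cases.

## Pipeline runs, caching, parallelism

`run_mirna` writes every parameter to `variables.txt` in the result
directory (replayable via `--params`). Each per-sample step stores a
SHA-256 content hash of its inputs and parameters
(`<sample>.hashes.json`); a refreshed run re-executes only steps whose
hash changed. Changing only the counting policy re-derives counts from
the cached per-stage SAM files (read back through pysam) and leaves
alignment outputs untouched; changing *v* invalidates alignment and
everything downstream while the trim cache is reused. Per-sample failures
are caught and reported; other samples complete.

## Numerical and edge-case choices

- Exact rational counting; floats appear only in rendered TSVs (4 dp).
- Alignment output order is fully deterministic (reference input order,
  offset, `+` before `-`), making SAM output reproducible.
- Empty read streams are valid everywhere (empty results, all-zero
  summaries, header-only SAM).
- An all-`N` read is `unaligned`, never an error.
- A read longer than a reference simply has no placements there.
- Problem sizes in the test suite (for example a 20-reference × 2,000-read
  policy-grid sweep, a 10⁴-pair trimmer comparison, and one 50,000-read
  recovery experiment) were chosen as the smallest instances that exercise
  every reporting path while keeping the full suite fast to run.

## Known limitations

- No quality-aware (`-n`-style) alignment mode, no gapped alignment, no
  BAM/CRAM, no paired-end support (small-RNA libraries are single-end).
- The aligner's index targets miRNA-scale references and genome slices,
  not whole-genome memory footprints.
- Trimming models substitutions only; adapters sequenced with indels will
  be missed (rare in small-RNA data at these overlap lengths).
- Auto-mode filename association follows this package's documented
  suffix rules; sheets are authoritative whenever filenames deviate.
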