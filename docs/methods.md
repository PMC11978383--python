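# Methods

## The canonical model

All operations run over a single in-memory representation of a pairwise
alignment block, `PairwiseBlock`.  Its conventions were genuinely open
choices, fixed once:

* **Coordinates** are 0-based half-open on the forward strand
  everywhere inside the package.  Strand-relative offsets (MAF `s`-line
  starts, Chain `-`-strand headers) exist only in the format readers
  and writers.  For a `-` row the forward interval is
  `[src_size - start - size, src_size - start)`; applying the transform
  twice is the identity, which the tests assert.
* **The target is always `+`.**  A MAF block whose first row is on `-`
  is normalised by reverse-complementing both row texts and flipping the
  query strand — the forward intervals are unchanged.  PAF and Chain
  tooling already keep the target forward, so this removes a case
  explosion from every conversion.
* **CIGAR** is run-length normalised (no two adjacent ops share a kind)
  over `{=, X, I, D, M}`.  `M` is kept as an opaque match-or-mismatch op
  until base strings are available to split it; operations that need the
  distinction without bases (`stat`, `call`) raise rather than guess.
* **Base comparison** is case-insensitive and `N` matches nothing, so a
  CIGAR derived from aligned strings is deterministic.

## Conversions

The six conversions are single passes through the canonical block; no
intermediate text is generated, and `maf2chain` is by construction the
composition `paf2chain ∘ maf2paf`.  Chain is the only lossy edge:

* `=`/`X` runs coarsen to ungapped chain blocks; `D` gaps fill `dt`, `I`
  gaps fill `dq`, and an adjacent `I`+`D` run becomes one triple with
  both gaps set (either spelling is accepted on input).
* Chains must start and end with an ungapped block, so boundary indels
  are trimmed into the coordinates with a warning.
* Chain has no mismatch detail, so `chain2paf` emits `M` CIGARs;
  `chain2maf` (with FASTAs) re-derives `=`/`X` from the bases exactly.
* **Scores.** MAF scores are aligner-specific and are not propagated.
  When a block carries no score the chain writer stores the
  match-column count (`=` columns for an exact CIGAR, all `M` columns
  for an opaque one).  `chain2paf` uses that convention in reverse: a
  score that is a plausible match count (`0 < score ≤ Σ block sizes`)
  becomes `nmatch`, anything else falls back to `Σ block sizes`.  This
  makes PAF→Chain→PAF round trips value-identical for chains this
  package wrote while staying sane on foreign chains.
* Unknown mandatory fields are written with fixed conventions: PAF mapq
  60 (255 accepted on read), MAF score 0.

## Indexing, extraction, chunking

The MAF index sidecar (`<maf>.idx`) is a TSV of
`name, target_start, target_end, byte_offset` — one line per block,
per-block granularity.  Blocks are few and large; sub-block slicing is
computed on demand by column projection, keeping the sidecar tiny.
CLI regions are 1-based inclusive (samtools convention); BED input is
0-based half-open.  With `--slice`, the retained column range covers
every column whose projected target position falls in the region;
insertion columns anchored at the last in-region target base are
retained.  Chunking splits at column boundaries and recomputes row
starts/sizes; a window in which one row is entirely gapped keeps that
row with size 0 for coordinate continuity (legal MAF).  Concatenating
chunk row texts reproduces the input exactly for every chunk size.

## Statistics

* Gap-compressed identity `matches/(matches+mismatches)`; overall
  identity `matches/columns`.  Aggregates are recomputed from summed
  counts, hence length-weighted.
* Coverage merges intervals per sequence (union), so it is invariant
  under block reordering and duplication.
* **Gap divergence** has no universal definition; here it is
  `(mismatch_cols + indel_cols) / all columns assigned to the window`,
  with a mismatch-only variant exposed alongside.  Every column is
  assigned to exactly one target window — insertion columns anchor to
  the last consumed target base (a leading insertion to the block's
  first base) — so window sums equal whole-alignment totals for any
  window size, a property the tests check at 100 bp, 1 kb and 1 Mb.
  The default window is 1 Mb.
* **Pseudo-MAF** projects per-sample pairwise alignments onto the
  reference: one character per reference base per sample — the aligned
  query base, `-` where the reference base is deleted in that sample,
  `*` where unaligned.  Insertions relative to the reference are
  dropped.  Overlapping blocks are resolved most-matches-wins (matches
  counted inside the region), ties by input order — deterministic.
* **Conservation** counts, per position, the non-reference samples whose
  base matches the reference; the default denominator is the number of
  samples (unaligned counts against conservation), `--aligned-only`
  switches it to the aligned count.  Both readings are useful; the
  choice is exposed rather than hidden.

## Variant calling

A left-to-right column walk: `X` → SNP; a maximal `I` run → INS
anchored on the last consumed target base (REF = anchor, ALT = anchor +
inserted bases); a maximal `D` run → DEL (REF = anchor + deleted bases,
ALT = anchor).  Indel runs of ≥ 50 bp (configurable `--sv-len`;
community convention) are additionally tagged SVTYPE/SVLEN/END.
Adjacent `I` and `D` runs become two records, consecutive `X` columns
individual SNPs — the simplest VCF-valid representations.  A leading
indel with no left anchor uses the VCF position-1 fallback (anchor on
the following base) with a warning.  QUAL is `.`, FILTER `PASS`, GT
`1/1` (haploid assembly-vs-assembly semantics).  Minus-strand blocks
are called in target coordinates; the canonical frame already holds the
reverse-complemented query bases, and the reported query positions are
mapped back to the forward strand.

Left-normalization follows the vt/bcftools rotation invariant: while
the anchor base equals the last varied base, rotate the event one base
left.  The result matches `bcftools norm` (verified on repeat-context
cases) and is idempotent.

## The simulator

The generator edits a uniform-random target into a query; the editing
trace *is* the alignment, so the emitted block, the three format files
and the truth variants are exact by construction.  Defaults — 100 kb,
SNP rate 0.01, insertion and deletion event rates 0.002, geometric
indel lengths with p = 0.5 (mean 2 bp) — describe a ~1%-divergent
assembly pair, the regime the toolkit targets; optional fixed-length
SVs exercise the SV threshold.  Two properties are engineered in:
planted events are ≥ 2 bp apart (so truth comparison needs only
left-normalization, never haplotype realignment), and the first and
last target bases are always match columns (so every emitted alignment
is representable as a chain without boundary trimming).  Identical
configs give byte-identical outputs.

What the simulator does **not** emulate: repeats and segmental
duplications (so no ambiguous alignments), rearrangements, GC bias, or
aligner error.  Passing the recovery tests therefore shows the calling
and normalization machinery is exact on unambiguous alignments; it says
nothing about upstream aligner quality on repetitive real genomes.

## Numerical and scale choices

Round-trip and recovery checks run at deliberately desk-scale sizes
chosen to exercise every code path many times over: 1000 randomized
blocks of 120–300 bp (half on the `-` strand) for the round-trip suite,
twenty 100 kb pairs for variant recovery, 500 random regions against a
brute-force scan for extraction.  All randomness is seeded; the test
suite runs hypothesis in derandomised mode.

## CLI conventions

Data to stdout unless `-o`; diagnostics to stderr; `-` for stdio; gzip
and BGZF input auto-detected by magic bytes; exit status 0/1/2 for
success/usage/data errors.  `--threads` is accepted on block-parallel
commands for interface stability, but processing is a deterministic
sequential pass — the work is pure-Python and output order must equal
input order regardless of worker count, so a thread pool would buy
nothing but nondeterministic buffering.  Shell completion and the
interactive viewers are out of scope; the exported TSV/SVG dotplot
geometry is consumable by any downstream viewer.

## Known limitations

* Only pairwise (2-row) MAF blocks are converted; `e`/`i`/`q` lines are
  skipped with a warning.
* No random access into plain-gzip MAF (an index offset requires
  decompressing from the start; BGZF files work but are not
  block-seeked).
* Inversions, translocations and duplications are not inferred from
  multi-block signatures; calling is per block.
* `nmatch` recovery from chain scores is a heuristic for foreign chains
  (see Conversions); the `cg` tag remains `M`-coarse until bases are
  supplied.
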