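# alnkit

A toolkit for manipulating **pairwise whole-genome alignments**.  Modern
assembly-vs-assembly comparisons arrive in three incompatible text
formats — UCSC **MAF** (gapped aligned rows, strand-relative starts),
**PAF** (12 columns plus a `cg:Z:` CIGAR, forward-strand query
coordinates) and UCSC **Chain** (ungapped block triples `size dt dq`,
strand-relative coordinates, no base detail).  `alnkit` converts
losslessly among them and provides the downstream operations
comparative-genomics pipelines need: indexing and region extraction,
chunking, statistics and filtering, alignment-based variant calling to
VCF, reference-projected pseudo-MAF matrices with per-base conservation
scores, and dotplot export.  A deterministic genome-pair simulator with
planted variants ships as a first-class module and powers the test
suite.

## The model in brief

Every format is parsed into one canonical in-memory record, a
`PairwiseBlock`: 0-based half-open forward-strand coordinates, target
always on `+`, plus a normalised CIGAR over `{=, X, I, D, M}`.  All six
conversions, slicing, statistics and calling are defined as walks over
that record's alignment columns:

* columns consuming both rows are matches (`=`) or mismatches (`X`);
* `I` columns exist only in the query (insertion), `D` only in the
  target (deletion);
* gap-compressed identity = `matches / (matches + mismatches)`;
* per-window **gap divergence** = `(mismatch + indel columns) / all
  columns assigned to the window` (1 Mb windows by default);
* a mismatch column calls a SNP; maximal `I`/`D` runs call INS/DEL
  anchored at the preceding target base, tagged as SVs at ≥ 50 bp;
  indels are left-normalised exactly as `bcftools norm` would.

Chain is the one lossy edge (`=`/`X` coarsen to `M`); converting back to
MAF with the FASTAs restores full base-level detail.

## Worked example

```sh
$ alnkit simulate --length 100000 --seed 1 --out-prefix sim
$ alnkit stat sim.maf | cut -f8-16
columns	matches	mismatches	ins_events	ins_bases	del_events	del_bases	identity_gap_compressed	identity_overall
100406	98617	989	196	406	189	394	0.990071	0.982182
100406	98617	989	196	406	189	394	0.990071	0.982182
$ alnkit call sim.maf -n qry.chr1 | grep -vc '^#'
1374
$ alnkit maf2chain sim.maf | head -2
chain 98617 ref.chr1 100000 + 0 100000 qry.chr1 100012 + 0 100012 1
118	1	0
```

The simulated pair is 100 kb with ~1% planted SNPs and 0.2% indel
events: the `stat` row shows 989 mismatch columns and 406 + 394 indel
bases across 100 406 alignment columns (gap-compressed identity 0.9901),
`call` emits 1374 VCF records — exactly the planted truth set — and the
chain header carries the match count with the first ungapped block of
118 columns.  The identical second row is the aggregate footer (one
block in this file).

The same operations are available as a library:

```python
from alnkit.synthetic import SimConfig, simulate_pair
from alnkit.varcall import call_variants

sim = simulate_pair(SimConfig(length=100_000, seed=1))
calls = call_variants([sim.block])          # 1374 records
assert [(v.pos, v.ref, v.alt) for v in calls] == \
       [(v.pos, v.ref, v.alt) for v in sorted(sim.truth, key=lambda v: v.sort_key)]
```

## Layout

| module | contents |
| --- | --- |
| `alnkit.core` | `PairwiseBlock`, `Cigar`, CIGAR parsing/derivation, column projection |
| `alnkit.io` | MAF / PAF / Chain / FASTA / VCF readers and writers |
| `alnkit.convert` | the six conversions over the canonical model |
| `alnkit.indexing` | MAF index sidecar, region extraction, chunking |
| `alnkit.stats` | identity/coverage stats, gap divergence, pseudo-MAF, conservation, filtering |
| `alnkit.varcall` | variant calling and VCF left-normalization |
| `alnkit.viz` | dotplot segments, TSV and SVG export |
| `alnkit.synthetic` | planted-variant genome-pair simulator |
| `alnkit.cli` | the `alnkit` command |
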