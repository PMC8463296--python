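# Methods

## Model

`dualmap` treats long-read mapping as a routing problem over two aligners
with different gap models. The fast backend (minimap2-style, two-piece
affine gap penalty) maps everything; the sensitive backend (NGMLR-style,
convex gap penalty) remaps only the reads whose fast alignments look
suspect. The suspicion score is the normalized edit distance of the read's
primary alignment,

```
E = e / l
```

where `e` is the alignment's edit distance — substitutions plus inserted
plus deleted bases, as reported by the SAM `NM` tag — and `l` is the
aligned query length, i.e. the read bases consumed by CIGAR `M`, `I`, `=`
and `X` operations. The underlying assumption is that a read forced into a
continuous alignment across an SV breakpoint accumulates excess edits, so
the upper tail of the `E` distribution is enriched for exactly the reads
a convex gap model would place better.

### Why the aligned length as denominator

Normalizing by the aligned length rather than the full read length makes
`E` a well-defined error *rate*: `NM` counts edits only within the aligned
region, so dividing by a length that includes soft/hard-clipped bases would
deflate `E` for heavily clipped reads — the very reads most likely to need
realignment. The full-read-length alternative is still available via the
`denominator="read"` option (CLI: `--denominator read`), and the choice is
recorded in the stats report so results are auditable.

### Which records count

Only primary mapped records enter the profile: secondary placements
typically carry larger edit distances by construction (they lost the
primary contest) and would thicken the tail artificially; supplementary
records describe split-read segments rather than whole-read quality, so
they are likewise excluded. Unmapped reads have no `E`; they pass through
to the final BAM unchanged by default, or are routed to the sensitive
mapper with `--realign-unmapped`.

If `NM` is absent, it is reconstructed as (MD-encoded mismatches) +
(CIGAR `I` bases) + (CIGAR `D` bases), with the MD tag validated
structurally against the CIGAR (deletion run lengths and aligned-span
coverage must agree); a record carrying neither tag is an error, not a
silent zero.

## The percentile cut-off

The threshold is the **nearest-rank** `p`-th percentile of the profiled
`E` values: sort ascending, take rank `k = ceil(p·n/100)`. A read is
flagged iff `E` is *strictly greater* than the threshold. Two properties
follow:

* the threshold is always an observed `E` value, so "strictly greater"
  is unambiguous even with heavy ties;
* the flagged fraction never exceeds `(100 − p)/100` — at the default
  `p = 90`, at most 10% of reads are realigned.

`p = 0` maps to a sentinel strictly below every `E` (all reads realigned);
`p = 100` yields the maximum (no read realigned, pipeline is an identity).
Interpolated percentile estimators were rejected because an interpolated
threshold can fall between observed values, making tie behavior and the
fraction bound estimator-dependent.

The default `p = 90` is the shipped pipeline default; lower cut-offs
realign more reads, buying recall for CPU time. No automatic per-dataset
tuning is attempted: the recall/precision optimum moves with platform and
coverage, and choosing it requires a truth set the user may not have.

## Partitioning and extraction

Partitioning is by read, not by record: all records of a flagged read
(primary, secondary, supplementary) leave the keep set, because the
sensitive mapper regenerates its own placements and mixing two mappers'
secondary records for one read would be incoherent. Kept reads retain all
their records, including secondaries — downstream callers filter by flag
as they see fit, and the stats report discloses the counts.

Flagged reads are re-extracted as FASTQ from their primary record, reverse
complemented (with reversed qualities) when the reverse flag is set, so
the sensitive mapper sees reads in original sequencing orientation. A
primary with hard clips or a `*` sequence cannot be reconstructed; such
reads are reported, dropped from realignment, and retained in the keep set
(fail-soft), since hard-clipping of primaries is a mapper-dialect issue
that should not abort a run.

## Merge semantics

The final BAM is the disjoint union of keep-set records and the sensitive
mapper's output, coordinate-sorted (Sniffles and most SV callers require
it) and indexed. Sorting happens once, at merge time. Invariants enforced:
identical `@SQ` dictionaries, no read name present in both inputs, at most
one primary per read. Flagged reads the sensitive mapper dropped entirely
are emitted as unmapped records rather than vanishing, so primary-read
counts are conserved end to end. `verify_merge` re-checks sortedness,
index presence, primary uniqueness and name-set equality after every run
and its (ideally empty) violation list lands in the stats report.

## Mapper backends

Backends satisfy a small contract: FASTQ + FASTA in, BAM out, read-name
set a subset of the input, `NM` (or reconstructible `MD`) on mapped
records, exit status checked. Platform presets map to documented argument
sets (`minimap2 -ax map-ont|map-pb|map-hifi --MD`; `ngmlr -x ont|pacbio`).
Versions and command lines of both backends are recorded in the stats
report and the `@PG` chain.

The mock backend is manifest-driven: read name → list of (position, CIGAR,
NM, strand, flags). It writes exactly the prescribed records, storing
reverse-strand reads the way SAM does (reverse-complemented sequence,
reversed qualities and CIGAR). Because it is scripted rather than seeded,
end-to-end tests can assert byte-level equalities instead of statistical
ones.

## Synthetic data generator

The fixtures module emulates, at desk scale, a simulation study design:
a random reference contig (default GC 0.38, matching a yeast-like
composition), an alternative haplotype with implanted SVs of all five
classes (DEL/INS/INV/DUP/TRA, each ≥ 50 bp, non-overlapping), and long
reads sampled uniformly from either haplotype with i.i.d. substitutions
and geometric(0.5)-length indels. Each read carries a truth record with
its origin interval, strand, reference-orientation CIGAR and exact edit
count; the generator is self-consistent (realized edit counts equal the
truth), which is what enables parameter-recovery tests of the profiler.

What the model deliberately omits: homopolymer-conditioned ONT error
profiles, read-length distributions trained on real flow cells, chimeras,
and base-quality structure. Passing tests therefore demonstrate pipeline
mechanics — profiling, thresholding, routing, conservation, merge
validity — not mapper accuracy on real signal; the optional
`external_stack_smoke.sh` script exists for the latter.

Default desk-scale problem sizes were chosen to keep the whole suite and
the acceptance script fast while leaving no quantity degenerate: 1,000
reads for percentile/fraction identities (so 10% is an exact integer
count), 400 reads × 1,500 bp at 5% substitution rate for rate recovery
(standard error of the mean `E` ≈ 0.0003, giving a sharp 3σ test), and
20–60 kb references.

## Numerical choices

* Nearest-rank percentile; ties at the threshold stay in the keep set.
* Median/quartiles in summaries use linear interpolation (numpy default);
  histograms are equal-width over `[0, max E]`, half-open with the last
  bin closed, so counts always sum to n.
* `E` is unbounded above (NM may exceed the aligned length on pathological
  alignments); no clamping is applied.
* An all-zero profile gets a unit-width histogram range to avoid
  zero-width bins.
* Seeds: every generator takes an explicit integer seed; regeneration is
  byte-identical.

## Known limitations

* Single-end semantics only (long reads); no CRAM; no MAPQ-based
  filtering — MAPQ measures placement confidence within a region, not
  alignment-model misfit, so it is the wrong signal for this routing
  decision.
* An alternative edit-counting scheme that counts each indel *event* once
  (so one long deletion costs 1, not its length) would penalize
  misalignment-style noise more specifically, but requires reconstructing
  every alignment and is not implemented.
* The profile is held in memory (two numbers per read), and flagged reads'
  records are buffered during extraction; both are comfortably within
  memory for realistic long-read datasets but the implementation is not
  streaming-optimal.
* Mock-backend tests cannot detect contract violations peculiar to real
  mapper output (tag dialects, split-read conventions); the minimap2 smoke
  tests cover the fast path, while the NGMLR invocation path is exercised
  only through its command construction.
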