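# Methods

## Model and assumptions

A CRISPR spacer is a copy of a protospacer from a past invader, so a
near-exact, ungapped match of a spacer against a viral contig is evidence
that the spacer's carrier was (recently) infected by that virus. The method
assumes protospacers are preserved well enough that ≤ 2 substitutions
separate spacer and contig; more divergent pairings are treated as noise.
It also assumes the array annotation's 5′→3′ orientation call is correct,
since spacer acquisition order (leader-proximal = most recent) is what
justifies the criterion-3 tie-break.

## Coordinates and orientation

GFF3 coordinates (1-based inclusive) are used across the public API;
conversions to 0-based half-open slices happen only inside sequence
accessors. For reverse-oriented arrays, spacer sequences are
reverse-complemented from the forward genome slice and the relative
position is computed on mirrored coordinates,
`(array_end − spacer_end) / (array_end − array_start)`, so 0 always means
the biological leader end. Arrays without a strand are treated as forward
with a warning. Spacer features are attached to their parent array by the
GFF `Parent` attribute when present, by coordinate containment otherwise;
feature-type names are configurable (defaults `repeat_region` /
`binding_site`) because annotation dialects vary across tool versions.
When a `Note`/`sequence` attribute holds plain nucleotides it is taken
verbatim as the (locus-oriented) spacer sequence; otherwise the genome is
sliced. Both paths are supported because annotation tools differ in
whether they embed sequences.

## Matching

The native matcher emits every full-length, ungapped placement of each
spacer on either contig strand with Hamming distance ≤ the threshold
(default 2). `N` matches nothing, including another `N`, so every `N`
counts as a mismatch. Placements overhanging contig ends are not emitted:
any truncated placement that would pass the true-mismatch filter is
dominated by a full-length placement except at contig ends, where evidence
is inherently partial. The scan is vectorised (numpy sliding windows over
byte-encoded sequences with distinct sentinels for spacer-`N` and
contig-non-ACGT); an independent per-offset character scan serves as the
test oracle. Ingested BLAST hits may be gapped or truncated — the
`true_mismatches = spacer_length − alignment_length + mismatches` formula
charges unaligned spacer bases as mismatches, and the filter drops any hit
with gap openings. The contig-span/alignment-length consistency check is
enforced only for ungapped hits, because gapped alignment lengths count
gap columns. Multiple hits of one spacer on one contig are all retained;
the assignment stage consumes them for interval counting. Output order is
fixed at (contig, start, strand, spacer id) for reproducibility.

## Host assignment

"Spacers matching non-overlapping regions" (criterion 2) is formalized as
the maximum cardinality of a pairwise non-overlapping subset of the match
intervals per candidate host, computed greedily by earliest interval end
(optimal for this objective; verified against exhaustive enumeration).
Overlap is defined on closed intervals: `[a,b]` and `[c,d]` overlap iff
`a ≤ d` and `c ≤ b` — intervals sharing a single base overlap. For
criterion 3, each tied host's statistic is the **minimum** relative
position over all of its matching spacers; the host with the smallest
value wins. A residual exact tie is broken by lexicographically smallest
host id and logged as unresolved — determinism over a silent arbitrary
choice. Criteria are strictly ordered: the criterion-2/3 statistics are
computed only when needed and never influence an earlier criterion.
Assignment never re-filters; it trusts the matches given to it.

Simple mode (`--mode simple`) reproduces the bare approach of keeping hits
with ≤ 2 aligner-reported mismatches and listing every candidate host per
contig, with no gap/truncation logic and no assignment criteria.

## Benchmark semantics

Scoring is per gold pair, not per virus: a virus with k gold hosts
contributes k outcomes, so one call can be simultaneously a TP (against
the matching pair) and an FP (against the other pairs). This is the only
interpretation under which the published count identities
`predicted = TP + FP` and `FN = FP + NA` close over multi-host viruses,
and it makes sensitivity collapse algebraically to `TP / actual_pairs`.
Rank comparison is string equality of the taxon name at the evaluation
rank after case-folding and whitespace trimming; no synonym resolution. A
prediction whose lineage does not reach the evaluation rank is scored NA
(no call at that rank). Undefined ratios (0/0) are reported as 0 with an
explicit flag so report tables stay numeric.

## Agreement and environment consistency

Two lineages agree when the deepest rank present in both with equal names
is at least as deep as the minimum rank (default **order**, chosen because
order-level concordance is the typical granularity at which independent
methods corroborate each other on novel taxa). Per contig, the predicting
tools are searched for the best pairwise-agreeing clique — largest first,
then deepest internal agreement, then alphabetical tool-set name (logged
when non-transitivity makes the choice non-obvious); tools outside the
clique count the contig in their exclusive sets. Per-tool counts across
combinations therefore partition each tool's prediction set, which is the
property that makes the counts plottable as an upset diagram.

A prediction is environment-consistent iff its predicted taxon or any
named ancestor carries at least one accepted trait; taxa absent from the
trait table are inconsistent by default and logged. The accepted-trait
profile for a hypersaline, alkaline, oligotrophic pond (nine trait
classes) ships as an editable TSV in `spacerhost/data/`; nothing is
hard-coded. Percentages are half-up rounded to 2 decimal places.

## Synthetic data

The generator emulates the real inputs' structure, not their biology:
uniform-ACGT genomes (default 20 kb) carrying repeat-spacer arrays (30 bp
repeats; spacer lengths uniform in 28–43 bp, the range observed in real
custom databases; default 6 spacers/array) with random orientation, and
5 kb contigs carrying protospacers implanted at scheduled substitution
counts, reverse-complemented with probability 0.5, at non-overlapping
positions. With i.i.d. uniform background, a chance full-length ≤ 2-
mismatch match of a 28-mer is astronomically unlikely (~4·10⁻¹³ per
placement), so tests assert zero spurious matches rather than modelling
them. Substitutions always change the base, never leave ACGT and never
reuse a position, so the implanted Hamming distance is exact. What passing
tests do **not** show about real data: repeat families, low-complexity
sequence and inter-genome homology can create ambiguous spacer hits that
the uniform background cannot produce; array mis-annotation and wrong
orientation calls upstream are likewise out of scope.

Confusion fixtures (`realize_confusion`) give every virus its own genus
and realize an exact (TP, FP, NA) triple; the shuffle seed only permutes
which virus receives which outcome, so scored counts are seed-invariant by
construction.

## Numerical and scale choices

All generators are deterministic given the configured seed (byte-identical
outputs). The acceptance script scores the ten published confusion rows at
their real size (1,046 pairs) — that computation is exact counting, not
simulation — and exercises the sequence pipeline on a 24-contig,
8-host community with implants at 0/1/2 substitutions plus an 8-contig
over-budget community, sizes at which every code path (both strands, all
three criteria, the NA path) is reached while the whole run stays in
seconds. Metric cells are reported at 4 decimal places, percentage shares
at 2, matching the precision at which such tables are conventionally
printed.

## Known limitations

* The native matcher is exhaustive (O(contig × spacers)); it is meant for
  custom databases of 10²–10⁴ spacers, not for multi-million-spacer
  reference databases, which should be searched with an external aligner
  and ingested as tabular hits.
* Whether duplicate hits of one spacer should be deduplicated before
  criterion-2 counting is unknowable from the published description; we
  retain all hits, and the maximum non-overlapping count is insensitive to
  exact duplicates, but near-duplicate stacked hits could differ from the
  original scripts' behaviour.
* Rank comparison has no taxonomy-aware synonym or rank-inheritance
  resolution; lineages must use consistent naming.
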