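# Methods

## Coordinate frame and conventions

All statistics use a single frame: the circular plastome linearized at the
conventional origin (start of the LSC), 1-based inclusive coordinates, and
regions in LSC → IRb → SSC → IRa order with IRa ending at the last base.
Features and repeat runs are never traced across the origin; inputs rotated
to another origin are rejected with an explicit error rather than silently
re-rotated.  `N` is allowed in sequences: it is excluded from the GC
denominator, breaks SSR runs, and is excluded (like a gap) from alignment
comparisons.

Every printed number is a `ReportValue`: the raw double plus a half-up
rounding at the declared precision (half-up, not banker's, because that is
how comparative-genomics tables are conventionally typeset).  Raw values are
retained everywhere; rounding happens only at the reporting surface.

## SSR scanning

A locus is a maximal perfect run of a *primitive* 1–6 bp motif meeting a
per-unit-size minimum repeat count (defaults 10, 6, 4, 4, 3, 3).  Key
decisions, all of which change the counts if made differently:

- **One run, one SSR.**  A periodic run is reported once, at its leftmost
  start, truncated to whole units.  Character-level maximality (the base
  immediately left/right cannot continue the period) is used rather than
  unit-level maximality — otherwise every cyclic rotation of the motif
  would count as a separate "maximal" locus inside the same run.
- **Primitive motifs only.**  A run qualifies at its smallest period
  (AT × 6 is never also A-mononucleotide), keeping the p1..p6 classes
  disjoint.
- **No canonicalization.**  Motifs are reported as observed on the given
  strand: A- and T-homopolymers are distinct (the T/A ratio depends on it),
  and cyclic variants (TAA/ATA/AAT) are distinct matrix columns.
- **No compound merging.**  Adjacent qualifying runs are reported
  independently; interruption-distance merging would add structure the
  downstream statistics never use.
- **Region by start coordinate.**  A junction-spanning locus belongs to the
  region containing its first base — deterministic and consistent with a
  "region of origin" reading of per-region count tables.

The scanner is validated against an exhaustive brute-force oracle (every
(start, unit size) pair tested independently) on 200 random sequences of
200–5,000 bp.

## cpSSR comparison

- **Balance index** `min(n_present, n_absent) / n_species` per motif: 0.5
  means the motif bisects the species set (maximally informative for
  clustering); symmetric under complementing the column.  This is the only
  formula consistent with all published per-motif values we reproduce
  (5/10 → 0.5, 7/10 → 0.3, 9/10 → 0.1); it is documented here as a balance
  index even though source tables sometimes label the column "Sørensen-Dice".
- **Sørensen dissimilarity** on presence sets; equals the Dice distance on
  boolean vectors (cross-checked against `scipy.spatial.distance.dice`).
- **Ward.D2** is implemented directly (Lance–Williams recurrence on squared
  dissimilarities, heights reported as square roots) so that tie-breaking
  is fully deterministic: among equally close pairs, the pair whose
  smallest leaf labels sort first merges first.  Heights match
  `scipy.cluster.hierarchy.linkage(..., "ward")` and the merge order matches
  an independent closed-form oracle (centroid-gap formula from the original
  squared distances, no recursion).
- **Mantel test**: Pearson r over upper triangles, one-sided (greater),
  null generated by joint row/column permutation of the second matrix,
  p-value with the +1 correction, explicit seed required.  Calibrated
  against exhaustive enumeration of all 24 permutations at n = 4, and for
  null uniformity over 500 replicate pairs of independent matrices.

## Junction analysis

The IR pair is detected as the longest pair of disjoint, exact
reverse-complement substrings (binary search on length over a rolling-hash
index; hash hits verified by direct comparison), with `min_ir_length`
defaulting to 1,000 bp.  Exact matching is a deliberate limitation: when the
two IR copies differ internally the detector returns the longest exact core,
which is appropriate for taxa whose IRs are annotated as identical in
length.  The longer intervening single-copy stretch is labelled LSC; a tie
goes to the stretch containing position 1, with a warning.

Junction spans report the bp split of a gene across the one boundary it
crosses (genes crossing ≥ 2 boundaries indicate a broken annotation and
raise).  The across-species "junction shift" is defined as the range
(max − min) of each region class's length — the only definition that yields
one number per region class.

## Nucleotide diversity

π is the mean pairwise difference proportion.  The default site filter is
complete deletion (a gap or N anywhere removes the column for all pairs),
the convention of sliding-window diversity scanners; pairwise deletion is an
option.  Windows start at column 1 and advance by `step` while a full
window fits; trailing partial windows are dropped, and a window with no
valid column reports NaN rather than failing so scans over gappy alignments
stay contiguous.  Conservation classes use half-open cuts at π = 0.012,
0.024 and 0.038 (the variable / highly-variable boundary is placed at 0.038,
consistent with both adjacent published range labels), and "variable or
above" means π ≥ 0.024.

Per-gene π is computed over a user-supplied gene-to-column map; the package
never re-aligns.  Whether per-gene diversity should come from gene-level
alignments or from gene-spanning columns of a whole-plastome alignment is
left to the caller — both entry points exist.

## SNP diagnostics

SNPs are alignment columns with ≥ 2 distinct non-gap bases, polarised
against an explicit reference taxon (default: first row) because reference
polarity decides the "gains" vs "loses" direction of the A/T-effect labels.
Columns with three bases, or a gapped reference, are retained as
multiallelic but excluded from Ts/Tv and A/T-effect summaries.  Percent
identity divides matches by columns where both rows are unambiguous bases
(gaps and N excluded), so self-identity is always 100.00.  Indels are
maximal contiguous gap blocks grouped by identical gapped-taxon set, with
the retained string read from a non-gapped row.

The built-in four-taxon marker fixture realises the published variant
structure — ten substitution columns with their per-taxon bases, and a 3 bp
AGC block retained only by the reference taxon — on a synthetic invariant
background of 426 columns.  The gap block is placed in an invariant stretch
(columns 150–152), away from the substitution columns, so gap and SNP
columns never interact; everything outside the variable columns is
generated, not the deposited sequence.

## Synthetic data: what it does and does not emulate

`synth_plastome` draws i.i.d. background bases at a target GC (default
0.35, typical for plastomes), writes planted SSRs with one guard base on
each side (so planted coordinates are exactly maximal), mirrors IRb into
IRa as an exact reverse complement, and then re-scans the assembled genome,
resampling any window that produced an unplanned qualifying SSR (bounded at
1,000 passes).  The emitted truth set is therefore exhaustive: the
brute-force oracle finds exactly the planted loci.  Junction-extension is
also guarded (the first and last SSC bases are kept non-complementary so
the exact reverse-complement match cannot creep across a junction).

`synth_alignment` plants biallelic SNPs (chosen carriers and ref/alt bases)
and gap blocks exactly, then adds background substitutions independently
per taxon and site at probability θ outside planted/adjacent columns.  Two
taxa then differ at a background site with probability
`1 − ((1−θ)² + θ²/3)`, the moment used for parameter-recovery tests.

Neither generator models phylogenetic correlation (no tree), indel length
distributions, rate heterogeneity, or the gene-density and codon structure
of real plastomes.  Passing tests therefore demonstrate algorithmic
correctness (exact recovery, calibrated statistics) — not robustness to
alignment error, annotation noise, or IR boundary SNPs in real data.

## Problem sizes and determinism

All stochastic components are pure functions of an explicit seed; the test
suite runs synthetic genomes of 6–20 kb (scaled-down quadripartite layouts
with the same structural proportions), 200-sequence oracle sweeps for the
SSR scanner, 500-replicate calibrations for the Mantel null and for π
parameter recovery, and 100-seed truth-recovery sweeps — sizes chosen so
the full suite completes in well under a minute while keeping every
statistical check at ≥ 3σ resolution.

## Known limitations

- Exact-match IR detection under-reports IRs containing internal SNPs
  (longest exact core only).
- Inputs must be linearized at the LSC start; no rotation search is
  attempted.
- Mean read-coverage accounting for assemblies is out of scope: the
  package computes no coverage statistic.
- Dendrograms carry no bootstrap support; tree inference is out of scope.
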