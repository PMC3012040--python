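# Methods

## Scope and model

`methkit` analyses single-locus bisulfite sequencing of cloned molecules.
The underlying measurement model: bisulfite converts unmethylated C to U
(read T); methylated C survives. A clone's base at a reference CpG cytosine
is therefore a direct readout of that molecule's methylation state, provided
the clone is correctly oriented and the treatment converted essentially all
unmethylated cytosines. Non-CpG cytosines in vertebrate DNA are almost never
methylated, so they serve as built-in conversion controls.

## Alignment

Global alignment uses Needleman–Wunsch with Gotoh's affine-gap recurrence.
The substitution scheme is directional: clone T against reference C scores
`bisulfite_tc_score` (default: the full match score, i.e. conversion is not
penalised at all), while clone C against reference T is an ordinary mismatch
— conversion happens on the clone strand only. N scores 0 against anything;
other IUPAC ambiguity codes score a match when the two codes' base sets
intersect. Defaults: match +1, mismatch −1, gap open −2, gap extend −1
(a length-L gap costs open + (L−1)·extend). There is no canonical published
matrix for this task; all parameters are configurable and echoed into the
run manifest, since gap penalties measurably shift calls near indels.

Traceback tie-breaking is fixed (diagonal over gap-in-clone over
gap-in-reference; among matrices, match state first), so alignments are
deterministic. Because global alignment runs end-to-end, a short clone
accrues reference-only overhang columns; these are trimmed and
`ref_start`/`ref_end` record the reference span under the clone's first and
last aligned base, which is what "covered" means for missing calls.

**Orientation control.** Sequencer output may be reversed, complemented or
reverse-complemented. All four candidates (including the untransformed clone)
are scored and the best kept, so correctly oriented input is never
transformed; ties resolve in favour of `identity` first. If all four scores
coincide at or below a floor (default 0) the clone is flagged unalignable
rather than silently returned.

## Quality control

*Conversion ratio* = unconverted non-CpG Cs / all non-CpG Cs, counted on the
**reference**: a reference C is a CpG-C iff it heads a CG dinucleotide on the
forward strand; every other reference C covered by the alignment enters the
denominator, and a clone C in such a column is unconverted. The clone's own
CpG context is distorted by conversion, which is why the reference defines
context. Gap and clone-N columns are excluded from both counts. The ratio is
a failure rate (lower is better); reports also print 1 − ratio as
"conversion success" to prevent misreading. A clone covering no non-CpG C
has an undefined ratio and fails the gate — it cannot demonstrate quality.

*Identity rate* = matches / (matches + mismatches) from a Smith–Waterman
local alignment, tallied only over columns whose reference base is A, G or T
(and whose clone base is a concrete A/C/G/T): reference-C columns are
legitimately rewritten by conversion and carry no identity signal. Note the
tally runs over the *optimal* local alignment, so a terminal mismatch that
the optimum excludes is not counted.

Default gates: conversion ratio ≤ 0.1, identity ≥ 0.8; both configurable.
There is no community-standard threshold; these defaults reject clones with
>10% treatment failure or visibly poor base agreement while passing any
clean read.

## Methylation calls

CpG sites are all forward-strand CG dinucleotides (1-based position of the
C). At a covered CpG column: clone C → methylated (1), T → unmethylated (0),
anything else (gap, N, A, G) → missing — a non-C/T base evidences sequencing
error, not methylation state, and contaminating a binary matrix with error
calls biases every downstream statistic. Sites outside the clone's aligned
span are missing. Orientation is normalised before calling, so calls are
always made on the forward-oriented transformed clone. Missing is a
first-class third state throughout; it is excluded pairwise from
correlations and distances and listwise within a Fisher table.

The dataset serialises to a versioned JSON container (clone ids, positions,
spans, matrix with nulls for missing) and a TSV matrix; JSON round-trips
field-for-field.

## Statistics

- **Co-occurrence.** Two readings are exposed because "correlation" between
  binary columns is ambiguous in the literature: the phi coefficient
  (Pearson on the two binary columns over pairwise-complete clones) and the
  shared fraction (= 1 − normalised Hamming distance). Pairs with fewer than
  two complete clones, or zero variance in correlation mode, are flagged as
  undefined (NaN) rather than propagated.
- **Fisher exact test** per site on the 2×2 group × state table, two-sided
  by summing hypergeometric point probabilities ≤ the observed table's
  (scipy's convention). A zero margin makes the table uninformative: p = 1
  with a degenerate flag. No multiple-testing correction by default;
  Benjamini–Hochberg available behind a flag.
- **Mann–Whitney U** compares per-site percent-methylation vectors between
  two clone groups (sampling unit = site; a per-clone aggregate is available
  behind a flag — the choice of unit is a genuinely open design point and
  the site reading matches how set-level comparisons are usually run).
  For combined n ≤ 20 the p-value is exact by full enumeration of group
  assignments, two-sided as P(min(U_A, U_B) ≤ observed min), which remains
  valid under ties; above that, the tie-corrected normal approximation.
- **Biclustering.** Pairwise-complete normalised Hamming distance on clones
  and, independently, on sites; agglomerative clustering with complete
  linkage by default (binary data make single linkage chain badly). If any
  pair shares no complete position the distance matrix is undefined and
  clustering refuses rather than guessing.
- **Correspondence analysis** on the raw 0/1 matrix (clones × CpGs), not a
  doubled indicator matrix; duplicated identical clones are retained — they
  carry mass and the demonstration result depends on them. Missing cells
  contribute zero mass; all-zero rows/columns are dropped with a warning.
  Principal inertias λ_k = σ_k² from the SVD of the standardised residuals;
  total inertia equals χ²/n (verified against an independent chi-square
  computation in the tests). Dimensions with σ² < 10⁻¹² × max(λ_max, 1) are
  treated as null, so a table at the independence model reports zero
  inertia; at most min(rows, cols) − 1 dimensions are kept.

## Visualisation

Every display is computed as a layout object first (glyph states,
coordinates, fills, line weights) and rendered in a thin final step; tests
assert the layout, never pixels, so results are backend-independent. The
lollipop summary row's fill fractions equal the per-site methylation
percentages exactly; connecting-line thickness is an affine map of |phi|
(0.5–4 pt) — any monotone map would do, this one keeps zero correlation
visible. Biplot markers: red triangles for CpG sites, black bullets for
clones; axis labels carry percent inertia to two decimals. Heatmap colours:
light = methylated, red = unmethylated, grey = missing.

## Synthetic data

The simulator generates the study conditions end-to-end: a reference of
length 100 (default) over an A/G/T background — so the only cytosines are
the planted ones — with CG dinucleotides exactly at the requested positions
(default: the demonstration geometry 7, 32, 48, 55, 73) and 10 planted
non-CpG cytosines as conversion-control denominators; clones then apply a
known methylation pattern (default: the demonstration pattern), leave each
non-CpG C unconverted with probability `conversion_failure_p` (default 0),
plant substitutions at rate `seq_error_p` (default 0) and finally apply a
per-clone orientation transform. All draws come from one seeded numpy
Generator and are logged to the ground-truth record, so tests compare
against what was actually planted, not the nominal rate. In `clean_calls`
mode (default) errors avoid CpG and planted-C positions, isolating
methylation-call tests from error handling.

What the simulator does **not** emulate: chromatogram-level base quality,
PCR duplicates and chimeras, read-length truncation, indel sequencing
errors, and non-CpG methylation. Passing tests therefore demonstrate the
pipeline's logic (orientation recovery, conversion accounting, call
extraction, statistics) under idealised reads; they do not certify
performance on noisy trace data.

## Problem sizes and numerical choices

Property tests run the alignment oracle on sequences ≤ 12 bp (where an
independent memoised recursion is exact and fast) and orientation recovery
on 200 clones of 100 bp at 1% substitution error — sizes representative of
a single-locus clone panel. The dynamic programming is pure Python; a
100 bp × 100 bp orientation resolution takes well under 0.1 s, and the full
demonstration pipeline a few seconds. Exact-test enumerations are bounded
(Fisher tables ≤ 30 total, Mann–Whitney combined n ≤ 20) with the standard
asymptotic fallback above.

Degenerate inputs are handled explicitly rather than by NaN propagation:
empty sequences, all-missing sites, constant columns, undefined distances,
zero-margin tables and zero-mass CA inputs each produce a flagged value, a
warning or a refusal as documented above.

## Known limitations

- Single reference per run; no multiple sequence alignment.
- No modelling of incomplete-conversion bias in downstream statistics: QC
  gates remove bad clones, but passing clones' residual failures are taken
  at face value.
- CHG/CHH (non-CpG) methylation is out of scope.
- The alignment is quadratic-time Python: adequate for clone panels (tens of
  sequences, hundreds of bp), not for high-throughput read sets.
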