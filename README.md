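# methkit

Exploratory analysis of DNA methylation profiles from bisulfite-sequenced
clones: alignment, quality control, methylation calling, statistics and
visualisation.

## The problem

Bisulfite treatment converts unmethylated cytosine to uracil (read as T after
amplification) while methylated cytosines survive as C. Sequencing individual
cloned molecules of a treated locus therefore encodes each molecule's
methylation pattern in its C/T states at CpG sites. Before that pattern can
be read off, each clone must be aligned to the reference — tolerating the
expected C→T changes and resolving clones that arrive reversed, complemented
or reverse-complemented — and screened for incomplete bisulfite conversion
and poor sequence quality. `methkit` performs this whole workflow for
single-locus (cloning-and-Sanger style) experiments and provides the field's
standard exploratory views of the resulting binary matrix.

## What it computes

- **Orientation-aware alignment.** Global Needleman–Wunsch alignment with an
  affine gap model and a *directional* bisulfite-tolerant substitution
  scheme: clone T vs reference C scores as a match (conversion), while clone
  C vs reference T is an ordinary mismatch. Each clone is scored in all four
  orientations (identity, reverse, complement, reverse-complement) and the
  best is kept.
- **Quality control.** Per clone: the *conversion ratio*
  (unconverted non-CpG Cs) / (all non-CpG Cs) — a treatment failure rate,
  lower is better — and the *identity rate* from a local alignment restricted
  to A/G/T (reference-C columns carry no identity information after
  conversion). Configurable pass/fail gates.
- **Methylation matrix.** A clone × CpG ternary matrix: 1 = methylated (C),
  0 = unmethylated (T), missing = not covered / gap / other base. JSON and
  TSV serialisation.
- **Statistics.** Per-site methylation percentages; neighbouring and distant
  co-occurrence as the phi coefficient (Pearson correlation of two binary
  columns) or as shared fraction (1 − normalised Hamming distance); Fisher's
  exact test per site between two groups; Mann–Whitney U test on entire site
  sets (exact by enumeration for small samples); hierarchical biclustering
  with pairwise-complete Hamming distance; correspondence analysis (CA).
- **Displays.** Lollipop plots (genomic-proportional or equidistant),
  colour-coded co-occurrence matrices, CA biplots, clustered heatmaps.

Correspondence analysis decomposes the table X under the chi-square metric:
with P = X/n, row masses r and column masses c, the SVD of
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} = UΣVᵀ yields principal inertias
λ_k = σ_k², which partition the total inertia χ²/n; percent inertia of
component k is 100·λ_k/Σλ. Clones and CpG sites with similar profiles plot
at small angles in the biplot.

## Worked example

The built-in simulator generates a 100 bp reference with five CpG sites at
positions 7, 32, 48, 55 and 73 and four clones: clones 1–2 methylated at
sites 1–2 only, clone 3 at sites 3–4, clone 4 at sites 3–5.

```sh
methkit simulate --outdir demo/sim --seed 1
methkit run --reference demo/sim/reference.fasta \
            --clones demo/sim/clones.fasta --outdir demo/out
```

The run prints the stage counts:

```json
{
 "n_clones_in": 4,
 "n_cpg_sites": 5,
 "n_passed_qc": 4,
 "matrix_shape": [4, 5],
 "ca_percent_inertia": [85.71, 14.29]
}
```

All four clones pass QC (perfect conversion, identity 1.0, orientation
`identity`). The per-site summary (`demo/out/stats/summary.tsv`):

```
position  percent_methylated  n_methylated  n_unmethylated  n_missing
7         50.0                2             2               0
32        50.0                2             2               0
48        50.0                2             2               0
55        50.0                2             2               0
73        25.0                1             3               0
```

Half the clones are methylated at each of the first four sites and one in
four at the last. Sites 1 and 2 are perfectly correlated (phi = +1: always
both methylated or both not) and sites 2 and 3 perfectly anti-correlated
(phi = −1). The first two CA components carry 85.71% and 14.29% of the total
inertia (χ²/n = 7/6), so the biplot captures the full structure: clones 1–2
cluster with sites 1–2, clones 3–4 with sites 3–5. Plots are written under
`demo/out/plots/`.

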