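# Methods

## Model and assumptions

`karyodelim` treats a sample set as draws from K unknown species, each
characterized by (i) a haploid chromosome-number range and a marker-bivalent
structure signature, and (ii) a mitochondrial COI haplotype cloud. The two
marker systems are physically unlinked (nuclear vs mitochondrial), which is
what gives the sympatric criterion its force: within one panmictic population
the joint distribution of karyotype class and haplogroup factorizes (linkage
equilibrium), whereas two coexisting reproductively isolated species produce
a block-diagonal table (mimicked linkage disequilibrium). The allopatric
criteria rest on the empirical generalization that fixed chromosomal
rearrangements between groups normally entail hybrid meiotic problems and
hence non-conspecificity, while barcode differentiation alone marks
phylogeographic sublineages (subspecies grade).

Bivalent sizes are deliberately modelled qualitatively. Measured bivalent
areas are unreliable in squash preparations (blurred boundaries, stain
swelling, projection effects), so a karyotype structure is reduced to the
counts of "large" and "medium" marker bivalents, serialized as e.g. `2L+2M`.
Two structures are equal iff both counts are equal.

## Grouping

* **Karyotype classes.** Samples are chained into connected components when
  they share a structure signature and their counts differ by less than Δ.
  Chaining (rather than fixed-width binning) matches how intraspecific
  variability presents in real data: a species can span a 29–34 range through
  consecutive counts while remaining separated from its neighbor by a clean
  gap. On the packaged 62-sample table this yields exactly one class per
  species-level taxon (six classes).
* **Haplogroups.** Single-linkage connected components of the p-distance
  matrix at threshold θ. Single linkage is the natural dual of the chaining
  rule above and is order-invariant up to deterministic relabelling (ids
  assigned by first member). The clustering stands in for reading clusters
  off a phylogenetic tree; the package intentionally contains no Bayesian
  tree inference.
* **Final groups** are the observed (karyotype class, haplogroup)
  combinations. Samples with only one data type are attached to a combination
  group when it is unambiguous (unique haplogroup for their class, preferring
  same-locality evidence; unique class for their haplogroup), otherwise they
  form a karyotype-only group and verdicts touching them are annotated.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| Δ (`delta`) | species-level haploid-count gap, integer | 3 | separates observed subspecies-grade gaps (1, e.g. 73–75 vs 67–72) from species-grade gaps (≥ 4, e.g. 86 vs 90) with a margin of one on either side; configurable |
| θ (`theta`) | haplogroup distance threshold, proportion | 0.02 | conventional barcode-gap figure for COI; also the distance bound in the "barcode differentiated" disjunction |
| α (`alpha`) | association-test significance | 0.05 | conventional; configurable |
| `n_permutations` | sampled permutations when enumeration is infeasible | 9999 | add-one estimator resolution ~1e-4 |
| `radius_km` | locality merge radius (great-circle) | 0 | source data use named localities; merging is offered for coordinate-based datasets |

Δ and θ are formalizations of criteria the underlying methodology states
qualitatively; they are exposed as configuration precisely because they are
judgment calls, not measured constants.

## Association test

The observed class × haplogroup table is scored with the likelihood-ratio
G statistic (robust for sparse tables; cross-checked against
`scipy.stats.chi2_contingency(lambda_="log-likelihood")` in the tests). The
null distribution permutes haplogroup labels against karyotype labels. When
the number of distinct label arrangements (a multinomial coefficient) is at
most 10,000 the full set is enumerated and p = b/m is exact; otherwise m
arrangements are sampled with a seeded generator and p = (b+1)/(m+1). The
permutation comparison uses a 1e-9 tolerance on G to make ties robust to
floating-point noise. Degenerate tables (one class and one haplogroup) return
p = 1 with a warning. Significance alone is not the species criterion: the
engine additionally requires the table to be one-to-one (each class maps to
exactly one haplogroup and vice versa), because the biological claim is
stability of combinations, not mere non-independence.

## Decision rules

Rules fire in a fixed order; exactly one fires per pair:

1. **R1** sympatric ∧ p < α ∧ one-to-one ∧ no multivalents → distinct species.
2. **R2** sympatric ∧ (multivalents ∨ not significant) → single polymorphic
   species.
3. **R3** allopatric ∧ fixed karyotype difference (structure mismatch or gap
   ≥ Δ) → distinct species; when barcodes are *not* differentiated the
   verdict carries an introgression flag, since chromosome numbers evolve too
   slowly for deep karyotype divergence to coexist with barcode identity by
   descent.
4. **R4** allopatric ∧ conspecific-grade karyotype ∧ barcodes differentiated
   → conspecific subspecies.
5. **R5** allopatric ∧ indistinguishable karyotype ∧ barcodes not
   differentiated → synonym.
6. **R6** anything else → unresolved (e.g. a minor count gap without barcode
   evidence, or missing barcode data where R4/R5 would need it).

"Barcode differentiated" is a disjunction: ≥ 1 diagnostic fixed site, or
minimum between-group p-distance > θ. The distance clause stands in for
sublineage monophyly, which the package does not infer. Comparisons in which
a side has only approximate ("ca") counts are marked low-confidence but still
adjudicated — approximate counts are evidence, not noise.

Sympatric pairs that cannot be tested (no sequenced individuals at the shared
site) fall back to the allopatric comparison rather than erroring; calling
`decide` directly with a sympatric evidence record lacking a p-value is an
error.

## Numerical and algorithmic choices

* **p-distance**: mismatches over comparable sites, a site being comparable
  when both sequences carry unambiguous A/C/G/T (pairwise deletion). Zero
  comparable sites yields NaN — an undefined distance, never 0 — and
  undefined entries are refused by clustering and tree building rather than
  silently imputed.
* **Diagnostic sites**: a column qualifies when each group shows at least one
  unambiguous base and the two observed state sets are disjoint. N/gap/
  ambiguity codes are ignored by default (maximizing use of short barcodes);
  a strict mode disqualifies any column containing them. Positions are
  1-based.
* **Neighbor joining** is implemented directly because its determinism
  contract matters here: Q-criterion ties (within 1e-12) are broken by
  joining the pair whose sorted representative leaf labels are
  lexicographically smallest, and negative branch lengths are clamped to
  zero with the deficit moved to the sister branch. The implementation is
  cross-checked in the tests against closed-form three-taxon lengths,
  exhaustive four-taxon topology fitting, and scikit-bio's NJ on random
  matrices.
* **Modal counts** break frequency ties toward the smaller value.

## Synthetic data

The simulator emulates the statistical structure of a karyotype + barcode
study, not its evolutionary history: species counts are drawn uniformly from
`base_n ± count_spread` (data of this kind report ranges, not a fission/
fusion process), and barcodes descend from per-species consensus sequences on
a star phylogeny. Fixed differences are implemented as `n_fixed_diffs` shared
columns at which every species carries a distinct base, which makes two
invariants exact: every pair differs at exactly `n_fixed_diffs` columns, and
the between-species minimum p-distance under zero within-species mutation is
exactly `n_fixed_diffs / seq_length`. With four nucleotides this caps the
species count at 4 when fixed differences are requested (a per-species
private-site scheme cannot give pairwise-equal counts and is not offered).
Introgression is whole-barcode replacement of the recipient's consensus by
the donor's — complete haplotype capture, the regime that actually defeats
barcode-only identification.

Defaults are chosen to mirror a realistic study: 3 species × 8 samples,
658 bp barcodes, 20 fixed differences (~3% divergence, a typical congener
separation and safely above θ = 2%), within-species per-site mutation rate
0.002 (shallow intraspecific clouds of a few substitutions), 30% of counts
emitted as approximate (about the fraction seen in real karyotype tables of
this kind), one two-species sympatric site plus one allopatric site. What the
simulator does *not* emulate: nested clade structure, recombination,
selection, codon structure, partial introgression, uneven sampling. Passing
recovery tests on this generator therefore demonstrates the pipeline's logic
and determinism, not robustness to phylogenetic signal conflict in real data.

## Problem sizes

The validity check for the association test uses 1,000 simulated independent
10-sample tables with exact enumeration; truth-recovery runs the full
pipeline on 100 simulated datasets (plus 25 with introgression) with 999
sampled permutations where enumeration would exceed the 10,000-arrangement
cutoff. These sizes give stable 0/1 recovery rates and a type-I error
estimate with standard error ≈ 0.007 while keeping the whole suite fast.

## Known limitations

* Subspecies retained on phenotype despite identical karyotypes and
  undifferentiated barcodes cannot be reproduced: morphology is outside the
  package's evidence model, so such pairs come out as synonym or unresolved.
* The Δ rule is a step function; a biologically gradual quantity (count
  divergence) is dichotomized, and intraspecific variability does not widen
  Δ adaptively.
* Haplogroup clustering at a fixed θ inherits the usual barcode-gap caveats;
  it is a stand-in for tree-based cluster reading, not a replacement for
  phylogenetic inference.
* Sympatry is binary co-occurrence at (optionally merged) collecting sites;
  no range interpolation is attempted.
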