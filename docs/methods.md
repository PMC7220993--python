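# Methods

This note documents the models and estimators geotypekit implements, the
conventions it pins where the field's tools differ, what the synthetic
generators do and do not emulate, and the numerical choices that affect
results.

## k-mer genome similarity

An assembly is reduced to the set of its distinct k-mers (default k = 31,
2-bit-encoded integers; exact set membership, no sketching). Windows
containing a non-ACGT letter are skipped, which is equivalent to splitting
scaffolds at ambiguous bases. Scaffolds shorter than 1,000 bp are removed
before extraction, matching the assembly-filtering step of the survey
workflow this package reproduces.

The similarity of assemblies *i* and *j* is
`K'_ij = |A_i ∩ A_j| / (|A_i| · |A_j|)` — the *product* denominator is
implemented verbatim, so self-similarity is `1/|A_i|`, not 1. A `cosine`
flag offers the square-root (geometric-mean) denominator for users who
want a [0, 1] scale; nothing in the package's own pipelines uses it.
Distances are Euclidean norms between rows of the full similarity matrix
(diagonal included); they satisfy the triangle inequality by construction
and feed UPGMA.

Whether the original comparison folded reverse complements is not
documented; assemblies have arbitrary scaffold orientation, so canonical
(strand-folded) k-mers are the default and a `--no-canonical` flag
preserves literal-strand comparison.

## MLST typing

In-silico PCR scans both strands of every scaffold for the forward primer
and the reverse complement of the reverse primer, allowing at most 2
mismatches per primer and none in the 3′-terminal 3 bases (mismatches
there abolish extension in real PCR). A pairing is valid when the product
length is within ±20% of the scheme's locus size; the nearest valid
pairing is taken, and multiple non-overlapping pairings raise an
ambiguity error listing all of them. Amplicons are reported 5′→3′ on the
locus strand with 0-based half-open forward-strand coordinates.

Per-locus frame offsets are not published, so trim specifications are
per-locus configuration; the default trims from offset 0 to the largest
codon multiple of the expected amplicon size. Allele identity is exact
string equality of the trimmed region — one SNP is a new allele — and
numbering follows order of discovery, so allele and ST labels are a pure
function of presentation order while the induced partition of strains is
order-invariant (tested by permutation).

A known bookkeeping quirk of the source survey: the six locus sizes sum
to 2,858 bp while the concatenate is reported as 2,859 bp. The package
carries the per-locus sizes and takes no position on the extra base.

## Per-locus diversity

Segregating sites are alignment columns with ≥2 A/C/G/T states; columns
containing any gap or ambiguity letter are excluded wholly (complete
deletion, the DnaSP convention) rather than pairwise. dN/dS follows
Nei–Gojobori (1986): per-codon synonymous site fractions (changes to stop
codons count as nonsynonymous), substitutions classified by exhaustive
enumeration of mutational pathways with stop-containing pathways excluded,
pN = Nd/N and pS = Sd/S averaged over all unordered pairs of *distinct
alleles* — the summary describes allele diversity, so duplicated isolates
carry no weight; a flag switches to per-isolate pairs. The ratio is 0 when
Nd = 0 and undefined (None) when Sd = 0 with Nd > 0. A Jukes–Cantor
correction is available behind a flag and off by default; the uncorrected
proportions are what small MLST distances warrant, and the implementation
is cross-checked against Biopython's NG86 with the correction on.

Report rounding is decimal half-up to 2 places; internal values keep full
precision. One published cell is arithmetically irreproducible: alleles
per variable site for *GLN4* prints 0.23 where 4/18 = 0.22; the package
returns 0.22.

## Index of Association

For n haplotypes over l loci, the mismatch distribution is the number of
differing loci for each of the n(n−1)/2 pairs; `V_D` is its variance and
`V_e = Σ_j h_j(1 − h_j)` with `h_j` the per-locus heterozygosity. Then
`IA = V_D/V_e − 1` and `IAS = IA/(l − 1)` (an exact identity, asserted for
every input). Monte-Carlo significance permutes each locus column
independently — allele frequencies are preserved exactly, inter-locus
association is destroyed — with a +1-smoothed upper-tail p-value on V_D.
The permutation null is exact, and the test's type-I error at α = 0.05 is
verified to sit inside the binomial 95% band over 100 null replicates.

Estimator choices differ across LIAN-family implementations, so both are
exposed: naive vs unbiased (`n/(n−1)`) heterozygosity, population (N) vs
sample (N−1) mismatch variance, and all-isolate vs unique-ST rows. The
library default is the classical definition — rows as given, population
variance — but the *paper-reproduction path pins* unique STs, unbiased
heterozygosity and N−1 variance (`PAPER_PINNED_CONVENTION`): under that
convention the published pooled A–B–C row (0.36/0.07) and the GeoC row
(−0.63/−0.13) reproduce exactly at printed precision, and GeoB lands
within 0.03 (−0.30 vs −0.33). No convention combination examined
(including permutation-mean expected variances and mixed-source variants)
reproduces the published GeoA (0.21) or pooled GeoA–C (1.9) values from
the allelic profiles; those two cells appear not to be derivable from the
printed profile table and are reported as computed.

## Phi recombination test

Parsimony-informative sites (≥2 states each carried by ≥2 sequences) are
extracted after dropping gap/ambiguity columns. Pair incompatibility uses
joint-state counting — `max(0, joint − (a + b − 1))` for sites with a and
b states — which equals the four-gamete indicator for binary sites; full
chordality checking for multi-allelic sites is deliberately not attempted,
and this counting rule is the implemented definition. The statistic is the
mean score over informative-site pairs within `w` ranks of each other in
the site ordering (default w = 100, the convention of the original phi
software; configurable). Significance is by site-order permutation only —
the normal approximation of the original method is not implemented, to
keep a single well-defined null — with a +1-smoothed lower-tail p-value.
When fewer than two informative sites exist the result is "not testable"
(p absent) rather than an error, mirroring how small groups are reported
in practice. When every site pair falls within the window the statistic is
permutation-invariant and p is 1 by construction; meaningful testing needs
w below the informative-site count (the calibration and power tests use
w = 10 with ~40–60 informative sites).

## Synthetic data

All generators are pure functions of their configuration, seed included,
and emit ground truth (genealogy, breakpoints, planted coordinates).

* **Clonal populations**: a random binary coalescent genealogy shared by
  all loci; per-branch mutation counts are Poisson(rate × length ×
  branch), applied at uniform positions with stop-codon-creating changes
  redrawn so alignments stay open reading frames. Defaults (41 strains,
  six loci, 477 bp — the mean scheme locus size rounded to a codon
  multiple — rate 0.003/site) put the expected polymorphic-site count in
  the 60–75 range over the ~2.9 kb concatenate, the scale of the real
  data. Mutation is finite-sites, so recurrent hits create homoplasy;
  that is what makes clonal data a valid phi null (sites are i.i.d. given
  the tree, hence exchangeable under site-order permutation).
* **Equilibrium populations**: per-locus allele frequencies from a flat
  Dirichlet, strains drawn i.i.d.; inter-locus independence holds by
  construction, giving the IA ≈ 0 reference point.
* **Recombinant alignments**: two parents differing i.i.d. per site at
  the configured divergence (default 8%), two clades of lightly mutated
  parent copies, and — when crossovers are requested — one *reciprocal*
  pair of recombinants (both crossover products, as a physical crossover
  yields; a single product alone creates no four-gamete violation against
  two clean clades).
* **Genomes**: random scaffolds (default 6 × 20 kb — scaled down three
  orders of magnitude from real assemblies, which the size-invariant K′
  normalization permits), an optional shared core occupying a configured
  fraction of every genome (controlling pairwise k-mer overlap to within
  ~±1 point of the target; boundary effects cost k−1 k-mers per scaffold
  junction), and optional planted MLST amplicons built from the real
  primer sequences at random scaffolds, positions and strands.

What the generators do *not* emulate: real base composition and repeat
structure, assembly artefacts (chimeric scaffolds, collapsed repeats),
within-primer polymorphism, indels, and selection. Passing the synthetic
end-to-end tests therefore demonstrates correctness of the computational
chain, not robustness to sequencing or assembly error.

## Numerical choices

* UPGMA is implemented directly so tie-breaking is deterministic (the
  candidate pair with the smallest (row, column) position wins), making
  dendrograms bit-stable; heights are half the merge distance and the
  output is ultrametric to 1e-9 (cross-checked against scipy average
  linkage). Neighbor joining delegates to scikit-bio with negative branch
  lengths clamped to zero under a warning.
* Monte-Carlo p-values use +1 smoothing on numerator and denominator and
  mandatory seeds; defaults are 10,000 resamples (IA) and 1,000
  permutations (phi). Tests use 200–999 to stay fast; the calibration
  experiments use 100 replicates per test.
* Fixture integrity is enforced by pinned SHA-256 checksums plus
  structural invariants (41 strains, 15 STs, complex sizes 31/6/4) on
  every load.

## Known limitations

* The two published linkage cells discussed above (GeoA, GeoA–C) cannot
  be recomputed from the profile table under any examined convention.
* dN/dS for the real loci cannot be recomputed offline because not every
  allele sequence of the survey was deposited; the implementation is
  validated against an independent NG86 implementation and hand-worked
  examples instead.
* The phi test here is the permutation form only, and the refined
  incompatibility for >2 states is the joint-state counting rule, which
  can under-count incompatibility relative to full chordality analysis.
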