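# Methods

## The data shape and the analysis chain

Reference-free RADseq genotyping produces a multi-sample VCF whose
sites group into thousands of short contigs (RAD loci, here 595–1,140
bp) carrying 0–8 SNPs each. Contig order along chromosomes is unknown,
which drives two design choices throughout the package: resampling
units are contigs (or sites) rather than genomic windows, and the usual
block jackknife over linkage groups is replaced, for the D-statistic,
by random subsampling of the data.

The chain is: hard filtering → per-individual QC → one-SNP-per-contig
thinning → allele-count statistics (F_ST, D), distances (p-distance,
haversine, Mantel), PCA, and EBSP locus export. The pipeline module
runs these in that order with stage isolation and a config-hash
manifest.

## Hard-filter cascade

Rules run in a fixed order: (1) biallelic only; (2) site QUAL < 30
dropped; (3) mapping quality < 20 dropped; (4) genotypes with GQ < 20
set missing; (5) genotypes with DP < 5 set missing; (6) sites in the
upper 5% of the post-(1–5) total-called-depth distribution dropped (a
guard against collapsed repeats and transposon pile-ups); (7) sites
called in fewer than 2 individuals dropped.

Decisions where the rule statement alone underdetermines behaviour:

- *Depth rule level.* "Coverage under five" is applied per genotype
  (DP < 5 ⇒ missing), so the ≥ 2-individual presence rule remains
  meaningful; a site-level mode (mean called depth) is available via
  `FilterConfig(site_level_depth=True)`.
- *Coverage distribution.* The excess-coverage quantile is computed
  over sites surviving rules 1–5, on the total depth of genotypes still
  called. This is the simplest reproducible reading; the 6↔7 order
  matters and is pinned by a regression fixture.
- *Absent annotations.* A missing QUAL/MQ/DP/GQ is recorded as absent
  and passes the corresponding rule — absence of evidence does not fail
  a call.
- *Per-individual QC.* Individuals whose called-site count falls below
  a fraction (default 0.25) of the cohort median are flagged (and, in
  the pipeline, excluded), capturing the failed-library pattern where
  one sample retains almost no sites.
- *Thinning.* One SNP per contig keeps the first SNP by position —
  deterministic and idempotent; a seeded random mode exists.

## Reich–Patterson F_ST

Per site, with alternate-allele count `a_i` of `n_i` called chromosomes
in population *i*:

    h_i = a_i (n_i − a_i) / (n_i (n_i − 1))
    N   = (a_1/n_1 − a_2/n_2)² − h_1/n_1 − h_2/n_2
    D   = N + h_1 + h_2
    F_ST = ΣN / ΣD   over usable sites

Both N and D are unbiased for their population quantities at any sample
size, which is why this estimator is preferred with ~8 diploids per
population; its denominator simplifies algebraically to the classical
Hudson form `p₁(1−p₂) + p₂(1−p₁)` (the test suite verifies exact
agreement with an independently coded Hudson estimator). Sites with
n < 2 in either population, or monomorphic across the pair, are skipped
and counted. Estimates can be negative under panmixia; that is a
feature of the bias correction, not an error.

Uncertainty: delete-one jackknife with the **contig** as the block, so
linked SNPs leave together. Both the normal-approximation interval
(θ̂ ± z·SE, the default) and the percentile interval of the delete-one
estimates are reported; blocks whose removal makes the denominator
non-positive are skipped with a warning. Calibration (built into the
acceptance tests): with true F_ST = 0.1, 8 diploids per population and
~20k SNPs, the mean estimate lands within ±0.015 and the 95% CI covers
the truth at nominal rate.

## ABBA-BABA D-statistic

For topology (((P1,P2),P3),O) with per-group alternate-allele
frequencies `p_i = a_i/n_i`, the symmetric frequency forms

    ABBA = (1−p₁)p₂p₃(1−p₄) + p₁(1−p₂)(1−p₃)p₄
    BABA = p₁(1−p₂)p₃(1−p₄) + (1−p₁)p₂(1−p₃)p₄
    D = Σ(ABBA−BABA) / Σ(ABBA+BABA)

include the outgroup frequency in both orientations, making D exactly
invariant to REF/ALT labeling — dosages are used directly with no prior
polarization step. Swapping P1 and P2 negates D exactly.

*Reliability.* D is recomputed on random subsets of the informative
sites at retention levels 99/95/90/80/70% (1,000 replicates each,
without replacement; a per-contig unit is available since sites within
a contig are linked). The SD of the subsampled D at level ℓ measures
leave-out noise only, which is `sqrt((1−ℓ)/ℓ)` times the sampling
standard error of D over the full site set (≈ 0.1× at ℓ = 0.99).
`call_significance` therefore rescales the 99%-level SD by
`sqrt(ℓ/(1−ℓ))` to estimate the full-data SE before applying the
|D|/SE > 3 rule. Without this finite-population correction the raw
subsampling SD would overstate certainty roughly tenfold and flag
nearly every non-zero D; with it, null simulations produce |Z| < 3 at
the expected rate while a 20% admixture pulse at ~20k SNPs is detected
essentially always. The spread is labeled SD (it is the SD of the
subsampled-D distribution, not an analytic standard error), and the
z-threshold is configurable because no universal cutoff exists.

## Distances and Mantel tests

- *Geographic*: haversine great-circle distance, Earth radius 6371 km.
  Along-shore (network) distances are accepted only as a user-supplied
  labeled matrix — GIS routing is out of scope.
- *Genetic*: uncorrected p-distance on dosages, per-site difference
  `|d₁−d₂|/2` (het vs hom counts one half), pairwise deletion by
  default (complete deletion available). For biallelic sites this is
  equivalent, up to a constant, to the p-distance on concatenated
  sequence characters.
- *Pseudoreplication*: samples from one locality are averaged into a
  locality × locality matrix before testing.
- *Mantel*: Pearson correlation of upper triangles; null from
  simultaneous row/column permutation; `p = (1 + #{r* ≥ r}) / (1 + B)`
  with B = 999 by default, so p is never 0. One-tailed "greater" is the
  default (the isolation-by-distance hypothesis is directional);
  two-sided is available. The permutation routine is in-package so the
  RNG is explicit and seedable; the test suite cross-checks r and p
  against scikit-bio's independent implementation and against full
  enumeration at n = 4.

## PCA

Dosage matrix, complete cases only (enforced), mean-centered per site
without variance scaling (the common genotype-PCA default; a scaling
flag exists). Eigendecomposition via full SVD; per-axis variance
fractions are reported. Axis signs are fixed by making each axis's
largest-magnitude loading positive, so results are bit-reproducible.
Monomorphic-only input raises an error (a matrix with zero variance has
no principal axes; this also covers degenerate inputs such as two
identical samples).

## EBSP locus selection

Candidates are contigs with exactly `snps_per_locus` (default 4) SNPs
at positions within the forward read — default 95 bp, the usable length
of a 100-bp read after barcode/overhang — each called in at least
`min_individuals` samples (default: all; relaxations to ≥7 or ≥6 are
the expected escape hatch when 4-SNP loci are scarce). Three replicate
sets of 50 loci are drawn without replacement, independently (sets may
overlap). Genotypes export as IUPAC-coded per-locus FASTA plus a NEXUS
with per-locus charsets for external skyline-plot software; model
fitting itself is out of scope.

## The synthetic-data generator

Two engines share one output contract (dataset + popmap + truth record):

- **beta** (default): per site an ancestral alternate frequency
  ~ U(0.05, 0.95); deme frequencies drift along a deme tree with
  per-branch Balding–Nichols variance `F = 1 − exp(−t)` for branch
  length `t` in units of 2N generations. Topologies: a two-basin
  hierarchy (two demes per basin) or a stepping-stone chain (for
  isolation by distance). An admixture edge mixes fraction `f` of the
  source deme's frequencies into the target. Under this model expected
  pairwise F_ST has a closed form — for demes i, j with total drifts
  `C_ii, C_jj` and shared drift `C_ij`,
  `F_ST = (C_ii + C_jj − 2C_ij) / (2 − C_ii − C_jj + C_ii + C_jj − 2C_ij)` —
  which the truth record reports exactly (admixture handled through the
  mixture's second moments).
- **coalescent**: msprime ancestry over the same two-basin demography
  (population splits at the scaled depths, an admixture pulse as a
  recent mass migration, outgroup split at depth 1.0), one independent
  ancestry per contig, finite-sites mutations capped at 8 SNPs/contig.
  Slower, but generates genuine within-contig linkage; truth F_ST uses
  the same drift approximation and is labeled approximate.

Defaults encode the study system the package is shaped around: 4 demes
× 8 diploids + 7 outgroup samples; 33,833 contigs of 595–1,140 bp with
0–8 SNPs (mean 2/contig); between-basin F_ST ≈ 0.19 and within-basin
≈ 0.035 (split depths 0.2107 / 0.0356); an admixture pulse deme3→deme2
with f = 0.2, chosen so the nominal D (~0.045–0.05) matches the
magnitude at which admixture is reported in this kind of system; deme
coordinates on a bulged lake-like arc (so along-arc and straight-line
distances differ measurably). `target_fst_between_basins` rescales the
depth profile to hit a requested between-basin F_ST exactly.

Annotations are our construct (no published per-genotype depth model
exists for such data): depth ~ negative binomial (mean 20, dispersion
3); 5% of contigs are "repeat-like" with 6× depth and depressed MQ
(~30), feeding the excess-coverage and MQ rules with predictable pass
rates; GQ ≈ 4×DP + noise so the GQ ≥ 20 and DP ≥ 5 rules overlap
sensibly; QUAL ≈ 2× mean site depth + noise. Raw missingness is 2% per
genotype, which combined with depth/GQ masking yields ~7% post-filter
missingness — calibrated to the study-scale complete-case yield of
one-SNP-per-contig datasets ((1−m)^33 ≈ 0.087 ⇒ m ≈ 0.07). The
outgroup is held at 1% derived-allele frequency (near-fixed ancestral).

What the generator does **not** emulate: reads, assembly and genotype
-calling error modes (allele dropout correlated with divergence, PCR
duplicates), within-contig linkage in the beta engine (sites are
independent draws there), selection, and spatially continuous sampling.
Passing calibration tests therefore demonstrates correctness of the
statistics under their own sampling assumptions, not robustness to
assembly artefacts.

## Problem sizes and numerical choices

Simulation-based tests run at reduced but statistically meaningful
sizes chosen once: ~20k SNPs × 8 diploids/population for F_ST and D
calibration (20–100 seeds), 2,000 contigs for jackknife coverage,
6-deme stepping-stone chains with 999-permutation Mantel tests (50
seeds), and the acceptance script's end-to-end system at 6,000 contigs.
Tolerances: exact oracles at 1e−12; stochastic checks use binomial
margins at their stated seed counts. Ties in the Mantel permutation
null are counted in favour of the null (≥). Degenerate cases raise
explicit errors rather than returning NaN: no usable sites (F_ST), no
informative sites (D), constant matrices (Mantel), monomorphic-only
input (PCA), zero-candidate shortfalls (EBSP, reporting the candidate
count).

## Known limitations

- The beta engine's truth F_ST is exact only for the drift model it
  samples from; the coalescent engine's truth is an approximation.
- The D significance call assumes informative sites are exchangeable
  when converting subsampling SD to a standard error; with strong
  within-contig linkage the per-contig subsampling unit is the safer
  choice.
- p-distance on dosages ignores which haplotype carries which allele
  (no phasing), as does the whole chain.
- The filter cascade's excess-coverage rule is quantile-based and so
  always removes ~5% of sites even from clean data; this mirrors the
  blunt instrument it implements rather than a model-based repeat
  detector.
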