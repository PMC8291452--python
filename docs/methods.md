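# Methods

This note documents the models implemented in `altadapt`, the choices
made where the underlying procedures leave latitude, what the synthetic
generator does and does not emulate, and the problem sizes used by the
test suite and the acceptance script.

## Composite selection scan

Four per-variant statistics feed the scan, computed on phased biallelic
SNVs with pooled minor allele frequency > 0.05 and known ancestral state:

* **Weir–Cockerham F_ST** (two-population, 1984 variance components
  a/b/c including observed heterozygosity, θ = a/(a+b+c)). Sites
  monomorphic in both populations, or with fewer than two genotyped
  individuals in either population, return missing — never 0.
* **ΔAF** = derived-allele frequency in the highland population minus
  the lowland population.
* **iHS**: ln(iHH_ancestral / iHH_derived) at the core site, where iHH
  is the trapezoid integral of EHH over physical distance (base pairs),
  truncated at the first marker where EHH < 0.05. Scores are
  standardized to mean 0 / sd 1 within 2% derived-allele-frequency bins;
  bins with fewer than 10 scores merge with their neighbour. EHH treats
  a missing allele as matching nothing, including another missing
  allele (conservative: missingness can only break haplotype identity).
* **XP-EHH**: ln(iHH_pop1 / iHH_pop2) with EHH computed over all
  haplotypes of each population; standardized genome-wide. Positive
  values mean longer haplotypes (a harder sweep) in the highland
  population.

Integration is in base pairs rather than genetic distance: the scan
assumes a flat recombination map (1 cM/Mb), under which the two are
proportional and the standardization absorbs the constant.

**Edge policy.** An integral clipped by the region boundary (EHH still
≥ 0.05 at the last marker) is flagged. The library default excludes
flagged scores from standardization, which is the right behaviour on
genome-scale input where edge effects are rare. The bundled pipeline
instead *keeps* flagged scores: on the short (hundreds-of-kb) regions
the generator produces, nearly every integral touches an edge, and
excluding them would empty the scan. This is a deliberate small-region
accommodation, exposed as `exclude_truncated`.

**Empirical p-values and CMS.** Each statistic maps to an empirical
p-value p = (#values at least as extreme)/N with ties sharing the larger
p (so p ∈ [1/N, 1]); extremeness directions are F_ST high, ΔAF high,
|iHS| high, XP-EHH high, all configurable. CMS = −Σ log₁₀ pᵢ; a missing
component makes CMS missing rather than silently shrinking the product.
Log base 10 is used throughout; with four components each bounded by
1/N, CMS is bounded by 4·log₁₀N.

**Windows and regions.** Windows of 30 kb advance by 15 kb anchored at
coordinate 0 (0-based half-open). A window is flagged when *strictly
more than* 30% of its variants carry top-tier CMS (top fraction
genome-wide, ties at the threshold value included); overlapping flagged
windows merge into maximal regions. Merging is idempotent and the scan
is invariant to variant input order.

**Desk-scale significance tier.** The published tier (top 1% of the
genome) presumes millions of variants; on a 200-kb synthetic region with
~150 variants the top 1% is two variants, which can never exceed 30% of
a 30-kb window. Desk-scale experiments therefore size the tier to the
phenomenon being implanted: top fraction = sweep span / region length =
30 kb / 200 kb = 0.15. The pipeline configuration default remains the
published 0.01; the 0.15 tier is passed explicitly by the tests and the
acceptance script.

**Candidate criteria.** Inside candidate regions a variant is kept when
it (1) is top-tier by CMS, (2) has F_ST strictly above 5× the
genome-wide mean and |ΔAF| above a margin (default 0.1 — the source
procedure requires the frequencies to "differ" without quantifying it),
also applied against an East-Asian reference frequency when supplied,
and (3) has a non-empty effect class. Effect classes apply in funnel
order: CPS for protein-changing sequence-ontology terms, then RGE for
eQTL-flagged variants, then UCE for GERP > 2 or CADD > 15 (both strict).
The adaptive allele is the one more frequent in the highland population.

## Functional importance and gene ranking

FIS_i = CS_i × |ΔAF| per annotation method (CADD and GERP by default;
SIFT/PolyPhen accepted when supplied). Negative GERP scores denote
neutrality and floor to 0; CPS and RGE variants receive the maximum CS
observed *within the candidate set* for that method (the set over which
the maximum is taken is a choice; the candidate set keeps the weighting
self-contained). Within each method variants are ranked by FIS
descending (rank 1 = strongest, ties averaged) and ranks are averaged
over methods. "Priority" here is the lowest mean numeric rank — i.e.
the greatest functional importance; the phrase "highest rank" in common
usage refers to the same thing, and the numeric inversion is documented
to avoid ambiguity. Ties break by (mean rank, CMS descending, genomic
position), making the output deterministic. Each gene is represented by
its best-priority candidate ("key" variant) and genes are ordered by
their key variants.

## Association models

All phenotype models are OLS under additive dosage coding with sex and
five principal components as covariates; expression models use a batch
factor instead. Complete-case analysis per trait. p-values for the
dosage coefficient are two-sided; families (all variant × trait pairs;
all cis variant × gene pairs) are each corrected once by
Benjamini–Hochberg. The cis window is ±100 kb between variant and gene
position. Epistasis uses the nested triple — single-variant, additive
two-variant, and interaction models — compared by ANOVA F-tests;
perfectly collinear dosages mark the larger models unidentifiable.
Enrichment is OR = (A1/A2)/(N1/N2) with a one-sided (greater) Fisher
exact test, BH-adjusted across categories. Tissue specificity requires
the median in the focal tissue to be at least twice every other tissue's
median *and* its lower quartile to exceed every other tissue's upper
quartile. The allele-frequency–altitude relation is a Pearson
correlation of per-group adaptive-allele frequencies against group
altitude (≥ 3 groups; empty groups dropped).

## Archaic local ancestry

The copy-probability tensor P is indexed (run, donor, haplotype, site)
and must close to 1 over donors. Per (haplotype, site), runs with
P > 0.8 are counted per donor; with R runs, the modern quorum is
floor(0.10·R) and the African ceiling floor(0.01·R) (421 and 42 at the
published R = 4,212 — ceil would give 422 and break the printed
constant). A modern donor (Han, Ust'-Ishim, or Yoruba → African-like)
is called when it holds the overall maximum count strictly above the
quorum. An archaic donor (Denisovan/Neanderthal, larger count wins) is
called when its count is strictly above the quorum while the Yoruba
count is at or below the ceiling and the combined modern count at or
below the quorum; the African ceiling vetoes signals explainable by
deep shared ancestry. Everything else is Uncertain. The six printed
case conditions overlap as stated in the source; this reading preserves
all three printed constants while making the cases disjoint. Calls are
order-free in runs. Segments are maximal same-label runs per haplotype,
reported as half-open base-pair intervals.

## Dating and selection coefficients

TMRCA = π̄/(2 μ_ab l_ab) with π̄ the mean pairwise difference count over
all haplotype pairs of the class and μ_ab = d/(l_ab · T), T = 13 My
human–chimp divergence. The dispersion reported alongside is the
standard deviation of per-pair estimates π_ij/(2 μ_ab l_ab) — the "±"
convention chosen here, since pairwise ages are the natural resampling
unit. μ_ab = 0 yields an undefined (NaN) age, flagged rather than
raised. The estimator targets the mean pairwise coalescent time; the
tests validate it against branch-mode diversity/2 of simulated
genealogies.

The sweep model is deterministic additive selection in log₁₀-odds form:
odds(p_g) = odds(p₀)·10^(s·g), inverted as
s = (1/t)·log₁₀[p_t(1−p₀)/(p₀(1−p_t))]. Base 10 reproduces all four
published endpoint values from the published frequencies (natural log
does not). Frequencies of exactly 0 or 1 are rejected (infinite odds).
The introgression-timing scenario sets p₀ = 1/(2N_e) and t from the
haplotype-class TMRCA; it is exposed but no validation value is pinned
to it, because the published 0.013–0.033 range for that scenario is not
derivable from main-text quantities with this formula.

## Synthetic data generator

The generator emulates the study design: two populations split t
generations ago (default 480, the middle of the 360–600 window at 25
years/generation), diploid effective size 3,000, mutation rate
1.25 × 10⁻⁸ per site per generation, one focal sweep locus whose
highland frequency follows the deterministic log₁₀-odds trajectory from
p₀ = 0.03 with s = 0.0042 — reaching ≈ 0.76, the published
highland/lowland frequencies of the key missense variant — with
optional binomial drift (lost/fixed alleles retried a bounded number of
times). Neutral variation comes from an msprime two-population-split
coalescent (200-kb region, recombination 10⁻⁸) or from a built-in
Wright–Fisher forward model (shared ancestral frequency Uniform(0.05,
0.95), per-population binomial resampling) behind the same interface;
the forward model is deliberately simple enough to re-derive in a test
oracle. Sweep hitchhiking is emulated by copying a founder haplotype
across carriers within 30 kb of the focal site. Archaic introgression
is implanted as a divergent founder segment (extra-mutation density
0.3) shared by a configurable carrier fraction, recorded in a truth
painting. Phenotypes are α + Σβ·dosage + γ·sex + Σδ·PC + ε; expression
adds batch offsets; copy-probability tensors give the true donor
probability > 0.8 in a configurable fraction of runs (support), with
symmetric-Dirichlet noise elsewhere, and probabilities always close to
1 over donors.

What the generator does **not** emulate: realistic human demography
(bottlenecks, expansions), recombination-map structure, linked
background selection, genotyping error, X chromosomes, or a generative
model of introgressed-tract lengths. Passing tests therefore show that
the estimators recover the structure they assume, at desk scale — not
that the thresholds transfer to real cohort data.

## Numerical choices and degenerate inputs

* Empirical p-values never reach 0 (bounded by 1/N); analytic OLS
  p-values of exactly 0 (noiseless fits) are clamped to the smallest
  positive float before FDR.
* Monomorphic sites: F_ST and LD r² return missing; constant dosages
  skip association with a log message.
* The exact Hardy–Weinberg test (conditional enumeration over
  heterozygote counts, two-sided) is used for QC rather than chi-square
  — robust at the small per-population sample sizes (~40 individuals)
  the design targets; variants fail QC at p < 10⁻⁶ in any single
  population or missingness > 20%.
* Coordinates: VCF 1-based on disk, 0-based internally, BED half-open;
  the ancestral allele comes from the AA INFO field, with sites
  repolarized when AA equals ALT and flagged unpolarized when absent.
* All randomness flows from explicit seeds; identical configuration and
  seed give byte-identical outputs.

## Problem sizes

Test and acceptance experiments use: 80 + 80 haplotypes × ~150 variants
per simulation; 50 simulations for sweep sensitivity; 50 seeds × 100
runs for noisy ancestry recovery; 200 coalescent replicates (8
haplotypes, 50 kb, N_e = 2,000) for TMRCA recovery; 2,000 null
regressions (150 individuals) for type-I calibration; 1,000 random
vectors for the FDR cross-check and 100 random genotype-count fixtures
for the F_ST cross-check. The whole suite runs in well under a minute
on one CPU.

## Known limitations

Two-population F_ST only; no genetic-map-aware EHH integration; the
archaic caller consumes painting output and does not infer it; gene
ranking reproduces the procedure, not the restricted-data gene list;
and the desk-scale significance tier (above) means absolute region
counts are not comparable to genome-scale scans.
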