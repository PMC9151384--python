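# Methods

## Copy-number pseudo-marker model

A whole-gene CYP2D6 copy number CN ∈ {0, 1, 2, 3, 4} is re-encoded as two
biallelic pseudo-markers placed at chr22:42522500 (`CYP2D6_DEL`) and
chr22:42522501 (`CYP2D6_DUP`) on GRCh37, inside the gene and clear of real
chip markers:

    DEL allele count = max(0, 2 − CN)
    DUP allele count = max(0, CN − 2)

CN = 2 is the double-reference state; the encoding forbids DEL and DUP on
the same haplotype by construction and is exactly invertible,
CN = 2 − DEL + DUP. CN > 4 is not representable as a biallelic dosage and is
rejected rather than truncated. Decoding a fractional imputed dosage takes
the nearest integer to 2 − d_DEL + d_DUP, with exact half-way ties resolved
toward CN = 2 (prior mass on the unrearranged gene). Best-guess integer
classes, not dosages, feed the validation cross-tabulations, mirroring how
the imputation panel was originally scored; expected dosage and a full CN
class posterior are reported alongside.

## Panel QC

Filters run in a fixed order — marker missingness (> 3%), sample
missingness (> 3%), MAF (< 0.5%), exact Hardy–Weinberg p < 1e-6,
heterozygosity outliers beyond mean ± 3 SD — each step operating on the
survivors of the previous one, and the QC report conserves counts per axis
(excluded + retained = input). The HWE threshold is configurable because
panel building and cohort QC legitimately use different stringencies (1e-6
vs 1e-8). The HWE test is the exact conditional test: conditioned on the
observed minor-allele count, heterozygote counts are weighted by their
hypergeometric-style probabilities and the two-sided p sums all
configurations no more probable than the observed one.

Relatedness uses the classic method-of-moments IBD estimator on observed
IBS counts with finite-sample corrections to the expected IBS-given-IBD
proportions (allele counts sampled without replacement); π̂ = P(IBD=1)/2 +
P(IBD=2). Estimates are deliberately not clamped at zero — with few
markers the estimator is noisy and clamping would bias the unrelated-pair
mean upward — only capped at 1. For a pair above the cutoff (default 0.15)
the member with higher missingness is excluded, ties to the later sample
index; the cut-off is the established convention, the exclusion rule is
this package's choice.

## Haplotype-copying HMM

Imputation is a Li–Stephens copying model: a target haplotype is an
imperfect mosaic of the K reference haplotypes. Transitions switch to a
uniformly chosen haplotype with probability ρ_m = 1 − exp(−s·d_m/K) per
interval (d_m = 1 when distances are unused); emissions match the copied
allele with probability 1 − θ; untyped sites (the pseudo-markers in every
target) emit uniformly. Defaults: θ = 0.01, s chosen so ρ ≈ 0.05 at unit
distance. The scaled forward–backward recursions are O(M·K) per haplotype
thanks to the uniform-switch structure, and a batched variant keeps state
only at the sites being imputed so whole cohorts run in bounded memory.
Posterior allele probabilities at the pseudo-markers sum over the two
haplotypes of a sample into DEL/DUP dosages; the CN class posterior treats
the two haplotypes as independent (standard diploid factorization) with
DEL/DUP mutually exclusive within a haplotype.

This in-repo engine replaces the external phase-and-impute toolchain the
original workflow shelled out to; the claim being exercised — that CNVs
tagged by local haplotypes are imputable by standard haplotype machinery —
is method-agnostic, and a transparent engine is testable against exhaustive
path enumeration (the suite verifies equality for M ≤ 6, K ≤ 4). Targets
may be supplied pre-phased (the simulator's truth haplotypes — used for all
reported concordance figures) or unphased, in which case a constrained
Viterbi heuristic phases them first: haplotype one follows the Viterbi
copying path with homozygous sites forced, haplotype two is the complement,
so the pair always sums to the genotype. The pipeline manifest records
which path was used.

## Synthetic study generator

`simdata` emulates the real reference/target cohorts, which are not
distributable. Founder haplotypes (40 by default) get per-site allele
frequencies uniform in (0.05, 0.5); panel haplotypes are founder mosaics
with per-interval switch probability 0.01, giving block-like LD with
segments of ~100 markers. Defaults: 1804 panel haplotypes (902 diploids),
2000 markers spanning ~0.44 Mb around the locus — marker count is
desk-scale rather than genome-wide because the copying model's behaviour at
a locus depends only on local haplotype structure — DEL haplotype frequency
0.0135 and DUP 0.044, so diploid carrier fractions track the ~2.7% and
~8.5% of the emulated cohort; 100 target samples; SNP genotype error 2e-3.

CNV alleles are planted on haplotypes sharing a 10-site core haplotype
adjacent to the pseudo-marker coordinates (greedy Hamming-distance match to
a randomly seeded core, DUP carriers blocked from DEL selection), then one
window site is repaired into a tag: carriers set to allele 1, non-carrier
1s cleared one at a time until the realized r² with the carrier indicator
reaches the requested `tag_strength` floor (1.0 ⇒ a perfect tag exists by
construction). Infeasible requests (expected carrier count < 1 at a nonzero
frequency) raise instead of silently degrading. The emitted truth set
reports per-site r² recomputed from the final matrix by the textbook
formula, per-haplotype CNV labels, and per-sample true CN; CN = 2 − DEL +
DUP holds identically.

What the simulation does *not* model: coalescent genealogy, recombination
hotspots, allele-frequency spectra of real chips, population structure,
array-specific genotyping artifacts, and hybrid/tandem CYP2D6
rearrangements. Passing the concordance tests therefore shows the engine
recovers tag-encoded CNVs under controlled LD; it does not certify
performance on any particular real cohort.

## Star alleles and phenotypes

The caller is entirely table-driven. A reconstructed subset of the CPIC
allele definitions ships as `data/cpic_allele_definitions_subset.csv`
(clearly marked as reconstructed — it is not the authoritative catalogue):
the CYP2D6 alleles covered by the validation genotyping assay (*2, *3, *4,
*6, *9, *10, *17, *29, *35, *41, *59) plus the variants driving the other
seven genes, with UGT1A1*28 represented through its perfect proxy SNP
rs887829 because the underlying TA-repeat is absent from imputation
panels. Haplotype matching returns the candidate with the largest fully
matched defining set (so *4, which carries the *10 variant plus its own,
beats *10); no match defaults to *1; two distinct maximal candidates raise
an ambiguity error rather than guessing — as does an unphased heterozygote
at defining sites, since the upstream pipeline provides phase.

Copy number folds in at diplotype level: CN = 0 → \*5/\*5, CN = 1 →
hemizygote (two distinct observed alleles at CN = 1 is an inconsistency
error), CN = 3 with distinct alleles enumerates both duplication
assignments, CN = 4 enumerates the 2+2 and 3+1 splits. Activity scores are
Σ activity × copies with *5 contributing 0. Phenotype bins live in
`data/phenotype_bins.json`; the CYP2D6 bin edges (PM = 0, IM (0, 1.25),
NM [1.25, 2.25], UM > 2.25) are configuration, not code. Each call reports
the primary, pessimistic and optimistic categories over its ambiguity
branches on the gene's ordered scale; cohort prevalence summaries use the
pessimistic assignment, matching how ambiguous duplication carriers were
scored in the validation.

## Validation statistics

Contingency tables match imputed and genotyped calls by sample id,
excluding (and counting) unmatched samples. Binary metrics are computed
from arbitrary predicates over row/column classes; a metric with an empty
denominator is reported as undefined, never as 0. Fisher's two-sided p
uses probability-mass ordering (the convention of mainstream statistics
environments — stated because two-sided conventions differ), with the
sample odds ratio ad/bc and the conditional-MLE odds ratio both reported;
scipy provides the test and the conditional MLE, and the suite checks both
against exact-rational enumeration over all margin-preserving tables.
Confidence intervals: Woolf log-OR by default (zero cells suggest the
+0.5 continuity option), exact conditional interval available — published
intervals at these counts are consistent with the exact form. Regional
comparisons report nominal p-values, with Bonferroni across region pairs
optional, because the original analysis applied no correction.

## Numerical and scale choices

Forward–backward uses per-site normalization (no underflow to M ~ 1e5);
posterior rows are renormalized after the forward–backward product. The
acceptance workload (one full simulated study plus the published-table
statistics) runs in well under a minute; the test suite's heaviest item is
the 3-seed × 3-tag-strength concordance grid (~1.5 min). Concordance
figures use 100 target samples per run; the monotonicity check compares
mean concordance across seeds at tag strengths 1.0 ≥ 0.8 ≥ 0.5.

## Known limitations

* The star-allele table is a reconstructed subset; real deployments should
  drop in the full CPIC/PharmVar definitions (the engine is data-driven).
* CYP2D6 hybrid and tandem arrangements (*36+*10 and kin) are out of scope,
  as are dosing recommendations and drug–gene interaction logic.
* Naive Viterbi phasing is a heuristic stand-in for a full phasing model;
  pre-phased input is preferred and used for all reported numbers.
* Imputed-class extremes: the validation tables use classes CN 1–3; CN 0
  and 4 are representable and decoded when dosages support them, but rare
  homozygous rearrangements carry little tag information at panel sizes
  like these.
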