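# Methods

This note documents the models, conventions and design choices behind
`thioburden`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Gene-wise variant burden (GVB)

For one individual and one gene, the qualifying set contains every InDel
and every SNV with a SIFT score strictly below the cutoff (default 0.7;
SIFT is in [0, 1], lower = more deleterious). Each qualifying variant
contributes a zygosity-adjusted score — the square root of its base score
when heterozygous, the base score when homozygous — and the gene's GVB is
the geometric mean of those adjusted scores, computed in log space with an
explicit zero short-circuit (a homozygous SIFT-0 variant yields GVB 0
rather than a −∞ log). A gene with an empty qualifying set scores exactly
1. Multi-gene burdens are geometric means of per-gene GVBs, so the
combined score stays in [0, 1] and between the per-gene extremes. The
high-risk decision rule is combined GVB ≤ 0.3, boundary inclusive.

Conventions where the scoring definition is silent:

* **Heterozygous InDels.** The InDel substitute score (default 10⁻⁸) is
  treated as the *base* score and the zygosity rule is applied on top, so
  a heterozygous deletion contributes 10⁻⁴. The alternative — pinning all
  InDels at 10⁻⁸ regardless of zygosity — is available via
  `zygosity_adjust_indels=False`.
* **SNVs without a SIFT score** cannot be scored; they are excluded from
  the qualifying set with a logged warning (configurable to a hard
  error). They never silently pass as benign.
* **Multiple transcripts / multi-allelic records.** Readers split
  multi-allelic VCF records into biallelic calls before scoring; if a
  caller supplies several SIFT values per variant, the minimum (most
  deleterious) should be pre-selected upstream — the in-memory model
  stores one score per variant.
* **MNVs** (equal-length multi-base substitutions) are treated as
  SNV-like and require a score; this is a documented limitation rather
  than a modeling claim.

A structural property worth knowing: the geometric mean makes GVB
insensitive to *how many* variants share the same adjusted score (one
heterozygous variant at s and two heterozygous variants at s give the
same gene score), and a single extreme InDel dominates the mean. Both
follow directly from the definition.

## Star-allele diplotyping

Allele definitions are data: a TSV mapping each star allele to its exact
defining-variant set (chrom:pos:ref:alt, 1-based, left-aligned minimal
representation) and a function category. The shipped default covers the
ten alleles observed in the study population — *NUDT15* \*1–\*6 and
*TPMT* \*1, \*1S, \*3C, \*6 — with \*2–\*6 of *NUDT15* and *TPMT* \*3C as
no-function, *TPMT* \*6 as decreased, and the rest normal. The table is
taken as ground truth; nomenclature disputes are resolved by editing the
table, not the code.

Matching is deterministic and exact: a haplotype's variant set must equal
an allele's defining set; the empty set is the reference allele; anything
else is labeled `novel`. Phased genotypes are matched per haplotype.
Unphased genotypes are resolved by enumerating all 2^h assignments of the
h heterozygous sites to the two haplotypes (homozygous sites sit on both)
and choosing the partition that maximizes, in order: the number of
non-novel alleles, the number of variants explained by defined alleles,
and finally the lowest star-number pair. The second rule prevents a
genotype of {one defining variant het, one unknown variant het} from
collapsing to reference/novel when defined-allele/novel explains more.
With ≤ 2 defining heterozygous sites per gene in this allele set the
search is exact; a cap (12 het sites) guards against pathological input.
Probabilistic population-frequency-weighted phasing is deliberately out
of scope.

Phenotype translation uses per-allele activity (normal 1, decreased 0.5,
no function 0): summed activity 2 → NM, 0 → PM, anything between → IM.
Uncertain-function and novel alleles count as normal by default
(configurable to an indeterminate phenotype), mirroring how star
nomenclature treats variants it does not recognize. When combining genes,
the highest-risk per-gene phenotype (PM > IM > NM) is used.

## DIP endpoint and diagnostics

DIP = 100 × actual / planned dose; the event "intolerant at threshold t"
is DIP ≤ t (boundary inclusive), with t scanned over
{5, 10, 15, 25, 35, 45, 60, 80, 100} and 25 as the primary threshold.
Accuracy metrics are reported as percents rounded half-even to two
decimals; a metric with a zero denominator is reported as missing, never
as 0.

AUROC uses the rank (Mann–Whitney) estimator with midranks for ties;
variance, 95% normal-approximation confidence intervals and the paired
two-sided test for correlated AUROCs follow DeLong's structural-components
method. Identical paired classifiers return p = 1 by convention (zero
difference over zero variance). The star predictor enters ROC analysis as
the ordinal PM = 2, IM = 1, NM = 0 (three-level coding; a two-level
non-NM/NM coding is a trivial re-binning of the same calls); GVB enters
with lower scores meaning higher risk.

The Youden cutpoint maximizes sensitivity + specificity − 1 over the
observed score values and returns the inclusive boundary of the optimal
high-risk bin, breaking ties toward the more specific (smaller) bin. The
returned value is therefore always an observed score — a bin edge like
0.283 — rather than a midpoint of a gap; one convention is kept
everywhere so decision rules quoted from reports ("score ≤ c") apply
verbatim to the data that produced them.

Group association tests are the standard nonparametric set — pairwise
Mann–Whitney U, Kruskal–Wallis, Spearman and Kendall rank correlations
against ordinal group codes, all two-sided — via scipy. For small samples
an `exact=True` mode replaces asymptotic p-values with exhaustive
permutation enumeration (in-house for Kruskal–Wallis, scipy's exact
method for Mann–Whitney). Paired predictor accuracy is compared with the
exact binomial McNemar test on discordant pairs (statsmodels), overall
and restricted to events (sensitivity) and non-events (specificity).

## Synthetic cohort generator

The generator emulates the statistical structure of a 244-patient ALL
cohort; it is the package's stand-in for patient-level exome data that
cannot be redistributed.

* **Alleles.** Per gene, two alleles are drawn independently from the
  configured frequencies (Hardy–Weinberg pairing). Defaults are the
  observed allele counts over 488 chromosomes: *NUDT15* \*1 438, \*2 6,
  \*3 35, \*4 4, \*5 4, \*6 1; *TPMT* \*1 127, \*1S 354, \*3C 6, \*6 1.
  Counts (not rounded percentages) are used so frequencies sum to 1
  exactly. Genes are linked independently; dual-gene carriers arise by
  chance at about the observed rate.
* **Variant annotations.** Each defining variant carries a synthetic SIFT
  score (`sift_map`): severe no-function SNVs 0.0064 (*NUDT15* p.Arg139Cys,
  \*5's p.Val18Ile at 0.0025, *TPMT* p.Tyr240Cys), the mild *NUDT15*
  p.Arg139His 0.35, the *TPMT* \*1S synonymous tag 1.0 and *TPMT* \*6's
  p.Tyr180Phe 0.8 (both above the 0.7 cutoff, hence invisible to GVB),
  and the \*2/\*6 in-frame insertion as an unscored InDel. These values
  are chosen so that heterozygous severe-allele carriers land at combined
  GVB ≈ 0.28–0.30 (inside the ≤ 0.3 high-risk bin), the mild allele
  lands outside it (0.77), and the decreased *TPMT* allele splits the
  wild-type/variant GVB groups as observed. Distinct scores per allele
  avoid artificial ties the geometric mean cannot break. Note that no
  single score map can simultaneously reproduce every published
  group-mean GVB and the published risk-bin memberships — the score is
  nonlinear in zygosity — so the map prioritizes the classification
  structure of the accuracy tables.
* **DIP model.** DIP is drawn per patient from a truncated normal on
  [0, 150] (doses above protocol occur) conditioned on the patient's
  **DIP group**: NM mean 67.608, IM 56.452 (SD 28.2), PM 5.712 (SD 5.0 —
  a stated default; the source population contained a single PM, so no
  empirical SD exists). The truncation *location* is solved numerically
  so each group's realized mean equals the configured mean; otherwise
  truncation at 0 inflates the PM and IM means by up to +1.4. The DIP
  group equals the star phenotype except for two deliberate
  discordances: carriers of `mild_dip_alleles` (default *NUDT15* \*4)
  draw from the group obtained by treating that allele as normal
  function (clinically mild despite its no-function label), and carriers
  of an injected novel deleterious variant (a heterozygous in-frame
  *NUDT15* deletion no star allele defines, per-patient probability
  1/244) are downgraded to at least IM. These give the burden score
  something the star method cannot see, and vice versa — the decreased
  *TPMT* \*6 allele is visible only to the star method.
* **Burden–DIP gradient.** Within the IM and PM DIP groups, DIP is
  rank-correlated with the combined burden (default 0.3) through a
  Gaussian copula on within-group normal scores: the group's truncated
  normal marginal is applied through its quantile function, so group
  means are preserved exactly while more burdened carriers tolerate
  slightly lower doses. The default produces a cohort-level Spearman
  correlation of ≈ 0.21 between GVB^NUDT15 and DIP, the magnitude
  reported for the source cohort. The NM group is excluded: its only
  burden variation comes from mild alleles, which are NM-like by
  construction. A side effect of the copula is a small (≈ 2–5%)
  shrinkage of realized within-group SDs.
* **Outputs.** A phased, SIFT/GENE-annotated multi-sample VCF (written
  and read with pysam; INFO floats are float32 in htslib, so scores are
  rounded to six decimals on read), a dose TSV (actual dose backed out
  of DIP against a fixed planned dose of 50 mg/m²/day — only the ratio
  matters downstream) and a truth TSV recording diplotypes, phenotypes,
  the DIP group actually sampled from, and the combined GVB. Everything
  is reproducible byte-for-byte from the seed.

What the generator does **not** emulate: exome-scale variant background,
linkage between the two genes, realistic DIP distribution shape (real
last-cycle dose intensities are bounded, likely multimodal and
protocol-driven; the truncated normal is a stated stand-in), sequencing
or annotation errors, and population structure. Passing tests therefore
demonstrate correctness of the pipeline's computations and the internal
consistency of the modeled effect structure — not clinical performance on
real cohorts.

## Problem sizes and tolerances

The test suite checks the numeric kernels against independent oracles:
GVB against a product-then-root computation on 1,000 random variant sets
(relative tolerance 10⁻¹²), AUROC against all-pairs concordance counting
on 200 instances of n ≤ 50, exact rank-test p-values against exhaustive
permutation enumeration at n = 8 (10⁻⁶), and the DeLong test against a
paired bootstrap's rejection decision. Generator recovery uses one
n = 5,000 cohort (group DIP means within ±1.5, phenotype counts inside
99% Hardy–Weinberg binomial bands, exact diplotype recovery without novel
variants) and the comparative star-vs-GVB property uses 100 replicates of
n = 244, the study's size. These sizes keep the full suite and the
acceptance script fast while leaving Monte-Carlo margins comfortably
inside the asserted bounds.

## Known limitations

* No CADD-based scoring (CADD values are carried as metadata only), no
  variant calling/annotation, no CNV or hybrid alleles, no
  dose-recommendation logic.
* The unphased diplotype search assumes the defining-variant sets are
  small; it is exact here but would need real phasing for genes with
  many common defining variants.
* The exact-permutation mode of the group tests is exponential and
  intended for n ≲ 10 only.
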