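# Methods

## Problem setting

A tumor-informed liquid biopsy tracks somatic variants discovered in a
patient's tumor tissue into plasma cell-free DNA (cfDNA). The pipeline
implements the full desk-side analysis for a small gastric-cancer
cohort design: whole-exome tissue calls are filtered to credible,
rare, damaging somatic variants; the recurrently mutated genes define a
targeted capture panel; deep plasma sequencing over that panel is then
matched back to the tissue calls per patient; and cfDNA yield,
fragment-size structure and the matched-variant counts are related to
clinical covariates and survival.

## Filter cascade

A tissue call is retained iff all five predicates hold:
population allele frequency < 0.01 (strict), protein-coding
non-synonymous consequence AND HIGH impact, CADD Phred > 30 (strict),
cohort presence < 100 % of tissue samples, and ≥ 2 alt reads per
strand (inclusive). Boundary semantics are exactly as stated; a CADD of
30.0 fails. The "protein-coding non-synonymous" vocabulary is the set
{missense, nonsense, frameshift-ins, frameshift-del, splice-site,
in-frame-indel} and is configurable, since annotation vocabularies
differ between annotators. Cohort presence is evaluated per normalized
variant key over the *unfiltered* cohort, before any per-variant
decision. Any annotation needed by a criterion that is absent fails the
variant with reason `missing_annotation`: unknowns never pass.

Decisions are values, not exceptions (`FilterDecision` with the list of
failed criteria), so the cascade is auditable and the monotonicity
property — relaxing any threshold never shrinks a retained set — is
directly testable.

## Variant matching

Matching is exact on normalized keys: alleles uppercased, shared
trailing then leading bases of indels trimmed with the position shifted
accordingly. No fuzzy or windowed matching: plasma sequencing is
panel-restricted and deep, so a candidate either is or is not the
tissue variant. Cohort concordance reports each fraction with its
numerator and denominator; percentages are never reported bare.

## Fragmentomics

Profiles are concentration densities (pg/mL per bp) on a strictly
increasing size grid. Total yield is the trapezoidal integral over the
analysis range (default 100–1,000 bp), converted to ng/mL. Nucleosomal
regions default to mono [100,250), di [250,450), tri [450,700) bp —
chosen to bracket the ~170 bp mononucleosomal peak and its multiples;
the instrument's own region bounds are not published, so the bounds are
explicit configuration. The per-region "size" statistic is the modal
size (argmax, ties to the smallest size); a concentration-weighted mean
size is also computed because published instrument "average size"
statistics are ambiguous between the two. The published mono/di modal
sizes (73/125 bp and 349/259 bp) are inconsistent with a ~170 bp main
peak and with the stated shortening direction, cannot be reproduced
without the instrument's size definition, and are deliberately not
targeted.

## Exact Mann–Whitney

The number of group labelings with statistic exactly *u* equals the
number of integer partitions of *u* fitting in an *n₁ × n₂* box, i.e.
the coefficient of *qᵘ* in the Gaussian binomial coefficient
[n₁+n₂ choose n₁]_q. The implementation builds this polynomial by exact
integer multiplication/division (equivalent to the counting recurrence
N(u; n₁, n₂) = N(u; n₁−1, n₂) + N(u−n₂; n₁, n₂−1)) and is
cross-checked in the tests against exhaustive enumeration of all
C(n₁+n₂, n₁) labelings for small sizes. Two-sided p = 2·min(lower,
upper tail), capped at 1; tail sums are exact rationals converted to
float at the end. From raw samples, mid-ranks are used; the exact path
requires no ties, otherwise a normal approximation with tie-corrected
variance and continuity correction applies. The reported U is oriented
to the smaller group.

Note: at (n₁, n₂) = (20, 29), U = 1 the exact two-sided value is
4/C(49,20) = 1.4146×10⁻¹³; a printed value of 1.42×10⁻¹³ reflects
rounding of the last digit.

## 2×2 tables, correlation, survival

The Pearson χ² statistic is uncorrected — N(ad−bc)²/(product of
margins) — because the detection-rate tables this pipeline produces are
analyzed without Yates correction (the corrected statistic would not
match the uncorrected values the uncorrected convention reproduces,
e.g. 5.59 for [[1,9],[10,8]]). Fisher's exact test is two-sided
hypergeometric tail summation (scipy). Spearman correlation uses exact
permutation p for n ≤ 9 and the t-approximation otherwise; constant
input yields NaN sentinels.

Kaplan–Meier estimation, k-sample log-rank and Cox proportional
hazards (Efron ties) are delegated to `lifelines`; the median is the
smallest time with survival ≤ 0.5 (infinity when never reached).
Matching-variant strata are 0, 1–2, 3–6, >6 with inclusive upper
bounds (6 belongs to "3–6", 7 to ">6"). Cox Wald p-values are primary;
Holm-adjusted values are reported alongside. Rank-deficient designs and
constant covariates are rejected before fitting. Group-location tests
choose Welch t versus Mann–Whitney by Shapiro–Wilk at α = 0.05 per
group.

## Shadow-feature importance

Boruta-style screening, implemented directly (no third-party Boruta
dependency): each iteration appends a row-permuted shadow copy of every
feature, fits a random forest, and credits a hit to every real feature
whose importance exceeds the best shadow importance. Final hit counts
are tested one-sided against Binomial(n_iter, ½) with Holm step-down in
both directions: significantly many hits → confirmed, significantly few
→ rejected, else tentative. This tests the final counts rather than
re-testing every round as the original algorithm does — a simplification
that keeps decisions deterministic for a fixed RNG and is validated by
planted-signal recovery and null-calibration tests. Constant features
are rejected outright; fewer than 20 iterations is an error.

## Discrimination (ROC)

AUC is the rank statistic U/(n₁n₂) with half credit for ties, which the
tests verify coincides with the Mann–Whitney U computed from the same
scores. Cross-validated discrimination fits a random forest (balanced
class weights) and pools out-of-fold probabilities. The default scheme
is stratified 5-fold, not leave-one-out: with heavily tied features —
here most patients have zero matching variants — leave-one-out scores
each tied sample by the event rate of the *other* tied samples, which
is anti-correlated with the sample's own label and drives a null AUC
far below 0.5. Stratified folds give all held-out samples of a fold the
same training statistics, removing the artifact. Leave-one-out remains
available (`scheme="leave-one-out"`) for comparability.

## Synthetic cohort

The generator encodes the study conditions as defaults; it is a model
of the *statistical structure* the analyses assume, not of sequencing
reads.

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 29 / 20 | cohort arms |
| tissue_positive_prob | 23/29 | P(case has ≥1 filter-passing tissue variant) |
| tissue_count_mean, dispersion | 8.4, 3.0 | truncated negative binomial on [1,23] |
| vaf law | Beta(1.2, 4.0) clipped to [0.028, 0.871] | tissue VAF |
| shed_prob_t12 / t34 | 0.10 / 0.556 | P(≥1 tissue variant detectable in plasma) |
| per_variant_detection_prob | 0.65 | thinning of tissue variants given shedding |
| m1_detection_boost | 1.4 | detection multiplier for M1 (metastatic burden) |
| plasma_private_mean | 2.0 | Poisson plasma-only variants per case |
| plasma_vaf_attenuation | 0.5 | E[plasma VAF] / tissue VAF |
| yield means | 87.59 / 2.01 ng/mL | arithmetic means of log-normal yields (σ=0.8) |
| peaks (control) | 170/350/520 bp, mass 0.60/0.25/0.15 | Gaussian nucleosomal peaks |
| peaks (case) | 160/345/515 bp | shifted down: shorter fragments in disease |
| survival | exponential PH, log-HR 0 / ln(803/469) / ln(803/315) / ln(803/44) | expected KM medians 803/469/315/44 d |
| censoring | Uniform(180, 2200) d | administrative censoring |
| marker link | Spearman(yield, CEA) = 0.6 via Gaussian copula | serum marker coupling |

Choices made where the study reports no value: the negative-binomial
dispersion (3.0) spreads counts over the reported 1–23 range;
per-variant detection 0.65 and private-variant mean 2.0 jointly place
the mean plasma count near 5.4 with matching mean near 3.5 among
detected patients; the Gaussian peak widths (22–60 bp) are typical of
electropherogram peaks; Spearman 0.6 is a "positive significant
correlation" of moderate strength; T-stage distribution puts 10/28 of
cases in T1–T2 and M stage is coupled to T (P(M1|T3–4) = 0.5,
P(M1|T1–2) = 0.25, marginal ≈ 0.41), reproducing the direction of the
higher detection rate in metastatic disease. Fragment curves are
rescaled so their integral equals the drawn yield exactly (mass
conservation by construction); multiplicative noise (σ = 0.02) is
applied before rescaling.

Every subject draws from an RNG stream keyed by (seed, subject index),
so output is byte-identical for a seed and independent of iteration
order. A fixture mode (`ensure_filter_edge_cases=True`) plants, for
each filter criterion, a variant failing only that criterion, including
a fixed key present in every tissue sample (ubiquity). A second
deterministic constructor (`make_concordance_fixture`) engineers exact
detection counts (23/29 tissue-positive, 21 plasma-positive, 11
shared-positive by default) to exercise the filter and concordance
stages with known denominators.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: sequencing and UMI-consensus error,
panel capture efficiency, real gene lengths and mutation hotspots,
clonal structure and subclonal VAF distributions, inter-marker
correlations beyond the single yield–CEA link, and any calibration of
absolute electropherogram shape. Tests against the simulator validate
the *pipeline's* algebra and the programmed statistical structure, not
biological effect sizes.

## Numerical and scale choices

Monte-Carlo batches in the test suite use 200 simulated cohorts for the
law-recovery checks (binomial positives, stage-wise shedding, yield
fold change ≈ 43.6 within 10 %, marker correlation ± 0.1) and 500 draws
per stratum for the survival-median ordering — sizes at which the
3-standard-error bands used are meaningfully narrow while the suite
stays fast. Exact tail sums use Python integers and `fractions`; yields
use plain float trapezoids with endpoint interpolation when the
analysis range cuts a grid interval. Ties in modal-size argmax resolve
to the smallest size. Degenerate inputs produce sentinels where the
result is a statistic (empty tumor fraction → NaN, unreached median →
inf, undefined fractions → None) and errors where the input violates a
contract (empty profiles, zero χ² margins, rank-deficient Cox designs).

## Known limitations

Cohort-dependent published quantities (per-sample variant-count means
as data, the concrete survival medians, Cox adjusted p-values, the
0.744 AUC, the instrument-specific fragment "sizes") are functions of
the unpublished patient-level data; the pipeline reproduces their
*computations* and the programmed directions, not their values. The
M0/M1 discrimination signal at n = 29 with two near-binary features is
intrinsically weak; cross-validated AUC around 0.45–0.55 is the honest
output under these conditions. The VCF dialect is flat INFO keys;
adapters for real VeP/SnpEff annotations must populate POP_AF, IMPACT,
CADD, SAF, SAR, VAF, GENE and CSQ_CLASS.
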