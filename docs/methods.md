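# Methods

This note documents the models behind `persistkit`, the parameters that
matter, the synthetic-data generators' assumptions, and the numerical and
design choices made where more than one reasonable option existed.

## Signature scoring

AUCell-style scoring ranks each observation's genes by decreasing expression
and integrates the gene-set recovery curve over the top `⌈top_fraction·G⌉`
ranks (default `top_fraction = 0.05`). The area is normalized by the maximal
achievable area `Σ min(i, |S|)`, so 1 means perfect early recovery and the
SMC gate at 0.05 is interpretable as "5% of the best possible early
enrichment". Only ranks matter: the score is invariant under any strictly
monotone transform of a cell's expression values. Ties in expression have no
defined rank order, so they are broken by a seeded random permutation within
each tie group; with continuous-valued input this never triggers, and with
heavily tied input the seed makes runs reproducible. Gene-set members absent
from the matrix are dropped with a logged warning; a set with no members
present, or a top window narrower than two ranks, is an error.

## Preranked enrichment

The enrichment statistic is the classical weighted running sum: walking down
the metric-sorted list, a gene-set hit adds `|r|^p` normalized over in-set
genes, a miss subtracts `1/(N−|S|)`; ES is the running-sum extremum by
absolute value. The weight exponent defaults to 1 (the common public-tool
convention); weight 0 gives the closed-form limits ES = ±1 for sets occupying
the top/bottom `|S|` ranks, which the exactness tests use. Hit and miss
contributions are accumulated in separate cumulative sums before
subtraction, which keeps those limits exact instead of accumulating per-step
rounding.

The null is gene-label permutation — with one pre/post pair per patient no
phenotype permutation exists. NES divides ES by the mean `|ES*|` of same-sign
permutations and the p value is `(1 + #{|ES*| ≥ |ES|, same sign}) /
(1 + #same-sign)`; Monte-Carlo calibration over random rankings puts the
realized rejection rate at α = 0.05 near 0.055. Per-patient enrichment ranks
genes by the difference of normalized expression (post − pre); the source
analyses do not state their paired metric, so this choice is logged
prominently as an assumption. When a patient has both on-treatment and
relapse samples, relapse is preferred (configurable). No FDR across gene-set
collections is computed — results are single-set, per patient.

## Cell-state gating and retention

Marker gating is an inclusive threshold on normalized expression
(CD36 ≥ 2.2 by default); gating is idempotent and monotone in the threshold.
Concordance between two gatings reports the 2×2 confusion counts, Jaccard on
positives, overall agreement and Cohen's κ (κ of two identical single-class
labelings is defined as 1).

"Retained expression" of a gene in the marker-positive population under
treatment is operationalized as the population × condition interaction in a
two-factor fixed-effects ANOVA on the log-normalized scale: retained means
the treatment-induced decrease among positives is smaller than among
negatives *and* the interaction p value clears the cutoff (0.05). With two
levels per factor the interaction has one degree of freedom and reduces to a
contrast of the four cell means against the pooled within-cell variance.
Strata with fewer than two observations are rejected rather than pooled —
variance is undefined below that. Per-group positive fractions carry exact
Clopper–Pearson 95% intervals.

## Risk score and survival

The risk model is rule-based. Five per-patient inputs — fold change of CD36
(RF1), baseline and fold change of AGPS (RF2a/b) and UGCG (RF3a/b) — are
z-normalized within each dataset (sample sd, n−1), which makes scores
comparable across cohorts profiled on different platforms and makes the rule
invariant to affine rescaling of any one dataset (but, deliberately, not to
non-affine monotone transforms; a test documents this). "High z" defaults to
z > 0, i.e. above the within-dataset mean — the only parameter-free reading —
and is configurable. RF2/RF3 fire when either sub-factor does; the score
RF1+RF2+RF3 splits patients at ≥ 2 (high) / ≤ 1 (low). Fold changes are
post − pre when the expression scale is declared log-normalized, else
log2(post/pre); the scale is an explicit argument, never guessed.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
(events precede censorings at tied times); their outputs are verified in the
test suite against closed forms and a brute-force risk-set enumeration
oracle. Mouse PFS derives from volume series by a configurable progression
rule, defaulting to the RECIST-like convention: event at the first
post-treatment day with volume ≥ 1.2 × max(nadir, baseline), censored at the
last measurement otherwise. The rule is a stand-in — published mouse PFS
endpoints rarely state their computational definition.

## Tumor response

Volumes use V = 3.1416/6 · L · W² with the literal constant (not π), and the
product is evaluated before the division so printed-precision examples
reproduce digit for digit (V(6, 3) = 28.2744 mm³). Width above length is
treated as a caliper-orientation swap and corrected with a logged note.
STR takes the measurement nearest 48 h after treatment start, matched with a
±12 h tolerance since measurement schedules use whole days; with no
measurement in the window the metric is a logged missing value, not an
error. BR windows of three consecutive measurements start strictly after
treatment start (the baseline is not part of the treatment course). Both
metrics are invariant to rescaling all volumes. Tumor initiation uses a
configurable palpable-volume threshold, 50 mm³ by default — an explicit
convention, since "palpable" is not quantified. Waterfall tables sort
animals by descending response within arm and attach a one-way ANOVA across
arms.

## Lipidomics

Abundances are normalized to DNA quantity (nmol lipid per mg DNA), log2
transformed, and zeros are imputed from a downshifted normal fitted per
replicate column over its nonzero log2 values: Normal(m − 1.8·s, (0.3·s)²),
the widely used defaults for left-censored proteomics/lipidomics imputation;
both knobs are exposed. A column with fewer than two nonzero values falls
back to global statistics with a warning; a table without zeros consumes no
randomness. Species imputed in at least half the replicates of both compared
groups are flagged `imputation_dominated`.

Differential testing is a one-way fixed-effects ANOVA across all groups per
species followed by a post hoc pairwise test against the reference group —
Tukey HSD by default, Fisher LSD as an alternative. Calls use inclusive
cutoffs: increased at fold change ≥ 1.5 and post hoc p ≤ 0.05, decreased
symmetrically at ≤ 1/1.5. No multiple-testing correction is applied by
default, mirroring the raw-p convention of the workflow this reproduces;
Benjamini–Hochberg is available as an option. Fully degenerate species
(every value identical) report p = 1 and "unchanged". Class composition
works on the original linear scale and its percentages sum to 100 per group
by construction. Chain-length profiles aggregate species by carbon count and
test each bin with the pooled residual variance of the carbon × group
cell-means model (the per-bin contrasts accompanying a two-way ANOVA); bins
whose group means agree to within 1e-10 relative report p = 1, which also
covers the zero-variance degenerate case.

## Synthetic data

All generators are pure functions of their spec (including its seed):
identical inputs give bit-identical outputs. Expression noise is Gaussian on
the log-normalized scale — every in-scope statistic operates on normalized
values, so raw counts are never simulated, and none of the generators try to
match real data's gene–gene covariance, library-size effects, or dropout
beyond the stated mechanisms. What passing tests show is therefore that the
*procedures* behave correctly under their stated assumptions, not that the
assumptions hold in any particular real dataset.

**Patient cohorts.** Each patient contributes a pre and a post (relapse)
sample; a latent fraction (default 0.5) is "true high risk" and receives an
elevated AGPS/UGCG baseline (+1.5 log2 by default) plus a post-treatment
induction of CD36/AGPS/UGCG (+1.5 log2). Both effects are modeled because
the high-risk phenotype is defined by *high or increased* expression; with
baseline signal absent, the baseline risk factors would be pure noise and,
under OR semantics with a z > 0 cutoff, would fire in half the low-risk
patients by chance. Baseline expression is N(5, 0.5) per gene on the
log-normalized scale — a spread typical of normalized cohort data. PFS is
exponential (median 180 days in the low-hazard arm, a realistic
progression-free interval under MAPK-inhibitor therapy) with the true-high
hazard scaled by the hazard ratio (default 3), censored administratively at
the horizon where the stated fraction (default 0.2) of the low-hazard arm
remains progression-free. Best overall response is drawn around −55%
(low risk) versus −10% (high risk), sd 20, clipped to [−100, 100].

**Single cells.** Cells draw a state from {SMC 0.2, pigmented 0.35,
NCSC 0.25, invasive 0.2}. CD36 and ten SMC-signature genes come from the
high component N(4.0, 0.5) in SMC cells and the low component N(0.5, 0.5)
elsewhere — separability matching a bimodal marker with a 2.2 cutoff between
the modes. A four-gene peroxisome/UGCG program (AGPS, SCP2, PEX1, UGCG) sits
at N(2.0, 0.5) everywhere untreated; under treatment it is decremented by
1.5 in non-SMC cells only, so the SMC state retains the program. Two hundred
background genes at N(2.0, 0.5) complete the matrix.

**Tumor courses.** Day 0 is treatment start at 200 mm³ (the usual enrollment
volume). Volume is piecewise exponential: growth at 0.15/day, net shrinkage
at 0.35/day on treatment (≈ −50% at 48 h), regrowth at the growth rate from
a per-animal relapse day N(21, 5). Measurement noise is multiplicative
lognormal with CV 0.1 and unit mean, so volumes stay positive and the
noise-free course is recovered exactly at CV 0. Caliper L and W are backed
out from the volume at aspect ratio 1.5 such that the volume formula
reproduces the simulated value exactly.

**Lipidomes.** Species abundances are lognormal around class means spanning
0.5–30 nmol/mg DNA (a realistic span across phospholipid, ether-lipid,
glycerolipid and sphingolipid families), with per-class log2 shifts planted
via the effect map. Dropouts emulate the detection limit: within each
replicate column the lowest `zero_rate` fraction of measurements reads out
as exactly zero. This left-censoring is the missingness mechanism
downshifted-normal imputation presumes; with dropouts placed uniformly at
random instead, a single imputed zero at n = 3 replicates inflates the
within-group variance past recoverability, and planted effects of realistic
size could not be detected — uniform dropout is therefore deliberately not
offered.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 200 cells × 50
genes for the scoring oracle, 200 replicates × 1000 permutations for null
calibration, 100 seeds × 100 patients for risk recovery, 50 seeds × 500
cells for gating concordance, 20 seeds for lipidomics recovery, and 10 000
draws for the imputation check — sizes at which the Monte-Carlo error of
each calibration claim is several times smaller than the asserted band.
Every stochastic component takes an explicit seed; the acceptance script
derives all of its randomness from a single `--seed` argument.

## Known limitations

- The paired ranking metric (post − pre) and the AUCell top fraction are
  assumptions where the source workflows leave the choice unstated; both are
  arguments, not constants.
- The mouse progression rule and the palpable-tumor threshold are explicit
  conventions, not published definitions.
- The risk model is rule-based by design; no proportional-hazards or other
  multivariate modeling is attempted.
- Generated data are structurally simple (independent genes, Gaussian noise);
  they validate procedure correctness and calibration, not robustness to
  real-data pathologies such as batch effects or correlated dropout.
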