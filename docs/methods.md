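# Methods

This note records the statistical models implemented in `copdwl`, the
assumptions behind the synthetic-data generator, and the numerical and
design choices made where the underlying procedures left room for
interpretation.

## Weight-loss phenotyping

### Visit-based classifier

For visit weights w₁…wₙ (time-ordered), a *loss event* occurs at the
consecutive pair (i, i+1) iff (wᵢ − wᵢ₊₁)/wᵢ ≥ 0.05. The event is
*regained* iff any later visit weight (ties included) returns to at least
wᵢ. A participant is a case iff some loss event is never regained, or the
final-visit BMI is below 20 kg/m². Interpretive choices: "5% between study
visits" is read as a consecutive-pair comparison (not any-visit-versus-
prior-maximum), and "fully regain" as any later visit ≥ the pre-loss
weight, with ties counting as regained. Both readings are the literal ones;
changing either would change labels near the boundary, so they are fixed
here and should not be silently altered.

### EHR sliding-window classifier

Records are first cleaned: weights below 20 kg and BMI below 10 kg/m² are
implausible and removed; then one pass removes weights beyond 3×IQR above
the 75th or below the 25th percentile, with quartiles computed per
participant over the post-implausible-removal weights (linear-interpolation
quartiles). Cleaning is a single pass, not iterated to a fixpoint —
iteration would silently change the quartiles being applied. The IQR pass
is intended for dense EHR histories; for sparse visit schedules it is
disabled (`apply_iqr=False`), because a genuine large loss at a final visit
is indistinguishable from an outlier against an almost-constant history.

Windows are measured in months before the last record, with one month =
30.4375 days throughout the codebase so that window arithmetic is
deterministic on integer-day timestamps. Start offsets run 60, 57, …, 12
(17 windows); each window ends max(start − 12, 6) months before the last
record, so the final two windows span 9 and 6 months. Intervals are open
at the far edge and closed at the near edge: a record m months before the
last record is in the window iff end ≤ m < start. Records older than 60
months are never used.

In each window with ≥ 3 records (and more than one distinct day), ordinary
least squares of weight (kg) on time (months) is fit. "The slope explains a
significant amount of variance" is implemented as the two-sided t-test of
the slope at p < 0.05 — identical to the one-predictor regression F-test,
which is the only standard reading. Perfectly collinear points leave zero
residual variance; the slope then explains all of it, and p is set to 0
(or to 1 when the slope is exactly zero). The annualized loss fraction is
(−slope × 12) / (mean in-window weight); the mean in-window weight is used
as the reference because it is robust and avoids extrapolating the fitted
line to the window edge. The ≥ 5% comparison carries a relative roundoff
guard of 10⁻⁹ so that a trajectory whose exact mathematical loss rate
equals the threshold is detected despite floating-point rounding; the
guard is six orders of magnitude below the 5.0%-versus-4.9% resolution the
classifier is required to have.

A participant is a case iff the maximum *observed* weight across all
records lying in any WL-flagged window exceeds the final weight, or the
final BMI (last recorded BMI, else derived from the last weight and
height) is below 20 kg/m². When several windows qualify, the maximum is
taken across all of them — the most inclusive reading. An empty
post-cleaning series yields an explicit *indeterminate* outcome, distinct
from control.

## Single-variant association

Each variant passing the strict MAC filter (MAC > threshold, applied per
analysis cohort) is tested by maximum-likelihood logistic regression of
case/control status on dosage plus age, sex and five ancestry PCs
(statsmodels Newton MLE). Wald tests are used throughout because odds
ratios with 95% CIs are the reported quantities; the CI multiplier is
fixed at 1.959964. Non-convergence and separation (detected via |β| > 30,
SE > 100, or failed Newton convergence) mark the result non-converged; such
results are counted but excluded from downstream outputs. A Firth-penalized
fit (Jeffreys-prior score correction) is available behind `firth=True` for
separated rare variants, off by default so that behaviour is explicit.

This is deliberately an *unrelated-sample* simplification: production WGS
pipelines use mixed models (GENESIS, SAIGE) with a sparse genetic
relationship matrix to absorb cryptic relatedness and case-control
imbalance. The synthetic cohorts here contain neither relatedness nor
extreme imbalance, so plain logistic regression is the correct model for
the data the package generates; results on real related samples would be
anti-conservative.

The genomic inflation factor is λ = median(χ²₁-quantiles of 1−p) / 0.4549364,
with λ ≈ 1 indicating a calibrated null.

## Fixed-effects meta-analysis

The effect-size (STDERR) scheme is used — sample-size-weighted z-scores
cannot produce pooled odds ratios with CIs. With wᵢ = 1/seᵢ²:
β̂ = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2), p from the two-sided normal test,
Q = Σwᵢ(βᵢ−β̂)² referred to χ²ₖ₋₁, and I² = max(0, (Q−(k−1))/Q)·100 with
I² = 0 when Q = 0.

Harmonization before pooling: variants are matched on chromosome and
position with an unordered allele pair; a study reporting swapped ref/alt
relative to the first contributing study has its β negated and AAF
complemented. Any position carrying more than one distinct allele pair in
any study (including records split from multi-allelic VCF rows, which keep
a shared-position flag) is removed entirely, and variants present in fewer
than two studies are dropped. No strand flipping or palindromic-SNP
handling is performed: all inputs are assumed to share one reference-genome
orientation, as is the case for jointly-called WGS data. No genomic-control
correction is applied before pooling. Direction strings always carry one
character per configured study, with '?' for a study that did not
contribute the variant.

## Gene-level burden tests

Mask member variants with in-sample minor-allele fraction strictly below
0.01 (computed per analysis cohort) are collapsed into a per-participant
count of minor alleles; dosages at variants whose alternate allele is the
major one are flipped before summing, because burden semantics count rare
alleles. Missing dosages contribute zero. The burden score enters the same
covariate-adjusted logistic regression as single variants. Genes with no
qualifying variants or a zero-variance burden are skipped with a recorded
reason.

This is a burden-only stand-in for kernel+burden omnibus tools
(SAIGE-GENE+ and relatives): it is well-powered when effects within a gene
share direction, and blind to genes where rare alleles push in both
directions. Burden p-values feed the cross-study combination; with ~10
carriers or fewer the Wald burden test becomes conservative, which is
visible in the null-calibration test (five-variant masks restore
calibration).

Fisher's method combines per-study gene p-values: X = −2Σln pᵢ ~ χ² with
2k df under the null; p = 0 is rejected as input (the log is undefined).
With k = 1 the combination is the identity, which the tests assert to
machine precision. The significance threshold applies a Bonferroni
correction for 20 000 independent gene tests at α = 0.05, i.e. 2.5×10⁻⁶.

## Synthetic-data generator

The generator's defaults describe the emulated study conditions: a target
case fraction of 0.45 (observed WL rates range from 31% to 54% across
contributing cohorts), weight-loss episodes of 5–15% of body weight per
year, a mixed common/rare allele-frequency spectrum (AAF 0.005–0.4),
measurement noise of 1 kg SD, 30% of control-side episodes fully regained,
and contamination of a few percent of EHR records.

Case/control labels are drawn from the same logistic model the association
stage fits — logit P(WL) = β₀ + Σβ_g·g + covariate terms — with β₀
calibrated by bisection so the realized case fraction hits its target.
Labels therefore have exactly the genetic architecture the association
stage assumes, which is what makes planted-effect recovery a meaningful
check.

Trajectories are piecewise-linear in time (baseline plateau → linear loss →
plateau or regain), deliberately within the model class of the slope-based
detector so its detection limits are interpretable. The loss rate is an
annualized fraction of the *pre-loss* weight. Height is constant per
participant and BMI = weight/height²; height dynamics are not modelled.
Specific constructions:

* EHR-style cohorts place records by a Poisson process (default 8/year over
  72 months); case episodes last 14–26 months and end 8–18 months before
  the last record, so they overlap several windows with enough points.
* Visit-based cohorts draw 2–8 visits at 6–84 month spacing. Case episodes
  are realized as a persistent step loss across one inter-visit gap of
  max(rate × gap, 8%) of body weight (capped at 35%): a between-visit drop
  must clear the 5% criterion by more than the measurement noise to be
  ascertainable at all, and an episode smaller than that would be invisible
  to any visit-based design.
* Regained episodes (controls) return to 3% above the pre-loss baseline by
  the last record. Real regain frequently overshoots; numerically the
  overshoot keeps the final weight above the noisy in-window maxima, so a
  truly regained episode is not misread as persistent loss.
* Drift controls move at −0.4% to +1.2% of baseline per year, within the
  < 2%/yr control envelope even across the longest visit gaps.
* Contamination (tagged low-weight, low-BMI, and > 3×IQR outlier records)
  is injected only into EHR-style cohorts; curated visit datasets do not
  exhibit data-entry artifacts, and the cleaning rules under test are
  EHR-specific.

Randomness is organized as one global seed expanded into per-(cohort,
stage) substreams (`default_rng([seed, cohort, stage])`), so a fixed seed
reproduces byte-identical output files and partial reruns are stable.

What the generator does *not* emulate: relatedness and family structure,
population stratification beyond supplied PC covariates, genotyping or
sequencing error, informative missingness of weights, height change, and
any realistic distribution of EHR measurement error (the Gaussian noise SD
is a free parameter, not an empirical claim). Passing benchmarks on this
data therefore demonstrates internal consistency of the pipeline — each
stage recovers what the generator planted — not field performance on real
EHR or study data.

## Problem sizes and verification

The test suite verifies, among others: exact closed-form OLS and
meta-analysis identities; equivalence of the EHR classifier with an
independent explicit-loop implementation on 1000 random series; agreement
of the logistic fits with a textbook Newton–Raphson implementation to six
significant digits; type-I error calibration at n = 2000 participants ×
2000 null variants against the binomial 99% interval; λ = 1.00 ± 0.02 on
10⁵ uniform p-values; 95%-CI coverage of a planted OR 1.5 in ≥ 90 of 100
replicates; and classifier sensitivity/specificity ≥ 0.95 against truth at
noise SD ≤ 0.5 kg. `scripts/acceptance.py` recomputes the headline
quantities at these sizes in well under a minute; the full suite runs in
about a minute.

## Known limitations

* No mixed-model relatedness correction (see above) and no saddlepoint or
  score-test option; Wald tests are anti-conservative for very rare
  variants with unbalanced phenotypes.
* Burden-only gene tests; no SKAT/ACAT components.
* The two WL definitions are benchmarked against a single ground-truth
  semantics (episode not fully regained, or final BMI < 20); where real
  designs disagree near boundaries, the generator does not model that
  disagreement.
* VCF support covers GT-based biallelic dosages with multi-allelic
  splitting; BCF, phasing, and dosage (DS) fields are out of scope.
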