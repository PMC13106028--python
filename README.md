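# copdwl

Weight loss (WL) is the cardinal feature of cachexia and a strong mortality
risk factor in chronic obstructive pulmonary disease (COPD). Finding genetic
risk variants for WL in COPD requires three ingredients that rarely live in
one codebase: longitudinal *phenotyping* that turns messy weight records into
a case/control label, *association* machinery for whole-genome variant and
gene-level testing, and *evidence combination* across heterogeneous cohorts.
`copdwl` implements that full chain as a tested Python library with a CLI,
together with a synthetic multi-cohort generator so every stage can be
exercised and benchmarked without access-controlled biobank data.

It is written for biostatisticians and genetic epidemiologists who want a
desk-scale, fully inspectable reimplementation of this analysis style.

## What it computes

**Phenotyping.** Two WL classifiers, matching the two kinds of longitudinal
weight data:

* *Visit-based*: a participant is a case iff some consecutive-visit loss
  reaches 5% of the earlier visit's weight and is never fully regained at a
  later visit, or the final-visit BMI is below 20 kg/m².
* *EHR sliding-window*: after cleaning (weight < 20 kg, BMI < 10 kg/m², and
  per-participant 3×IQR outliers removed), the last 60 months are scanned
  with a 12-month window stepping every 3 months (17 windows; the last two
  span 9 and 6 months). In each window with ≥ 3 points, OLS of weight on
  time is fit; the window flags WL when the slope is significantly negative
  (p < 0.05) and the annualized loss is ≥ 5% of the mean in-window weight.
  A participant is a case iff the maximum weight in any WL window exceeds
  the final weight, or the last BMI is below 20 kg/m².

COPD eligibility filters (spirometric FEV1/FVC < 0.7 with ≥ 10 pack-years,
or ICD-10 J41–J44 with smoking history at age 40–85) are included.

**Single-variant association.** For each variant with minor-allele count
strictly above a threshold (20 for visit-based, 40 for EHR cohorts by
convention), logistic regression of status on dosage adjusted for age, sex
and five ancestry PCs; Wald tests, odds ratios with 95% CIs, genomic
inflation factor λ = median(χ²)/0.4549, QQ/Manhattan plots, and the
5×10⁻⁸ genome-wide threshold.

**Meta-analysis.** METAL-style fixed-effects inverse-variance pooling
(weights 1/SE²) after allele harmonization, with multivalent positions
removed and variants required in ≥ 2 cohorts; Cochran's Q, I², heterogeneity
p, and per-study direction strings.

**Gene-level tests.** Burden collapsing of mask variants with in-sample
MAF < 0.01 into per-participant minor-allele counts, covariate-adjusted
logistic burden tests, Bonferroni threshold 0.05/20 000 = 2.5×10⁻⁶, and
cross-study combination by Fisher's method (−2Σln pᵢ ~ χ² with 2k df).

## Worked example

```python
>>> from copdwl import fisher_combine, cohort_accounting, gene_significance
>>> res = fisher_combine([(0.25, 1.0), (2.83e-7, 1.0)], gene="RNU6-565P")
>>> res.chi2, res.df, res.p_combined
(32.92822660084612, 4, 1.2355860160049341e-06)
```

Two study-level gene p-values (0.25 and 2.83×10⁻⁷) combine to p ≈ 1.24×10⁻⁶
on 4 degrees of freedom — far below the gene-level significance threshold:

```python
>>> gene_significance([], n_tests=20000, alpha=0.05)[0]
2.5e-06
>>> rep = cohort_accounting()
>>> rep["design_totals"]
{'COSMO': 16972, 'B/AA': 3335, 'NHW': 11223}
>>> rep["wl_percent"]["All of Us"]
48
```

The accounting report sums the bundled published per-study counts into the
three meta-analysis designs (all cohorts; the Black/African-American strata;
the non-Hispanic-white strata) and per-cohort WL percentages.

An end-to-end synthetic run:

```sh
copdwl run-all --seed 1 --out runs/demo
```

simulates two cohorts (one visit-based, one EHR-style), phenotypes them,
runs per-cohort association, meta-analyses the two result sets, performs
gene burden tests with Fisher combination, and writes a manifest with
per-stage row counts. Stage-level subcommands (`simulate`, `phenotype`,
`assoc`, `meta`, `gene`, `gene-combine`, `report`) operate on TSV/VCF files
for use with external data.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its limitations, numerical choices, and known simplifications (notably:
plain logistic regression in place of mixed models, and burden-only
gene tests).
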