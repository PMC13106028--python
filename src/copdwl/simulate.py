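"""Synthetic multi-cohort generator for weight-loss genetic analyses.

Generates, per cohort: biallelic genotype dosages with a configurable
allele-frequency spectrum and planted causal variants of known odds ratio;
covariates (age, sex, five ancestry PCs, pack-years, spirometry or ICD
codes); and longitudinal weight trajectories that realize the simulated
weight-loss labels — regular study-visit schedules or irregular EHR
timestamps — with optional contamination by implausible and outlying
records. A truth table records every label and episode parameter so the
downstream phenotyping, association and gene-test stages can be benchmarked
without any external data.

The generative model for case/control status is the same logistic model the
association stage fits: logit P(WL) = b0 + sum(beta_g * dosage) + covariate
terms, with the intercept calibrated by bisection to hit a target case
fraction. Weight-loss episodes are piecewise-linear in time: a baseline
plateau, a linear loss at an annualized rate expressed as a fraction of the
pre-loss weight, then a plateau (cases) or a linear regain (regained
controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genio import GenotypeBlock, Variant, compute_allele_stats, write_vcf
from .genio import GeneMask, write_group_file
from .phenotype import MONTH_DAYS, WeightRecord, WeightSeries
from .tables import write_covariates_tsv, write_weights_tsv

VISIT_BASED = "visit_based"
EHR_STYLE = "ehr_style"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults emulate the structure of the contributing studies: case
    fractions in the 31–54% range observed across cohorts (0.45), weight-loss
    episodes of 5–15% of body weight per year, a mixed common/rare allele
    spectrum, and a few percent of contaminated EHR records.
    """

    n_participants_per_cohort: int = 1000
    n_cohorts: int = 2
    visit_style: tuple[str, ...] = (VISIT_BASED, EHR_STYLE)  # cycled per cohort
    case_fraction_target: float = 0.45
    n_variants: int = 40
    aaf_spectrum: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1, 0.05, 0.02,
                                       0.008, 0.005)
    planted_effects: tuple[tuple[int, float], ...] = ()
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.02, "sex": 0.3, "pc": 0.1})   # log-odds per unit
    trajectory_noise_sd: float = 1.0           # kg
    wl_episode_rate_range: tuple[float, float] = (0.05, 0.15)  # fraction/yr
    regain_fraction: float = 0.3
    low_bmi_case_fraction: float = 0.10
    contamination_rates: dict = field(default_factory=lambda: {
        "low_weight": 0.02, "low_bmi": 0.01, "gross_outlier": 0.02})
    visit_spacing_months_range: tuple[float, float] = (6.0, 84.0)
    ehr_records_per_year: float = 8.0
    ehr_span_months: float = 72.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants_per_cohort <= 0 or self.n_cohorts <= 0:
            raise ValueError("participant and cohort counts must be positive")
        if not (0 < self.case_fraction_target < 1):
            raise ValueError("case_fraction_target must lie in (0, 1)")
        if not self.aaf_spectrum:
            raise ValueError("aaf_spectrum must be nonempty")
        if any(not (0 <= a <= 0.5) for a in self.aaf_spectrum):
            raise ValueError("aaf_spectrum values must lie in [0, 0.5]")
        for idx, _ in self.planted_effects:
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"planted effect references variant {idx} "
                                 f"outside 0..{self.n_variants - 1}")
        for k, v in self.contamination_rates.items():
            if not (0 <= v <= 1):
                raise ValueError(f"contamination rate {k} outside [0, 1]")
        lo, hi = self.wl_episode_rate_range
        if not (0 < lo <= hi):
            raise ValueError("wl_episode_rate_range must be increasing and positive")


@dataclass
class TruthTable:
    """Ground truth: per-participant labels/episodes, per-variant effects."""

    participants: pd.DataFrame   # participant_id, wl_label, episode_*, ...
    variants: pd.DataFrame       # variant_id, true_log_or

    def __post_init__(self):
        if self.participants["participant_id"].duplicated().any():
            raise ValueError("duplicate participant in truth table")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant in truth table")


@dataclass
class Cohort:
    name: str
    style: str
    genotypes: GenotypeBlock
    covariates: pd.DataFrame
    series: dict[str, WeightSeries]
    truth: TruthTable
    masks: list[GeneMask] = field(default_factory=list)


def _stage_rng(config: SimConfig, cohort_idx: int, stage: int) -> np.random.Generator:
    # documented substream rule: one generator per (seed, cohort, stage)
    return np.random.default_rng([config.seed, cohort_idx, stage])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig, cohort_idx: int = 0,
                       rng: Optional[np.random.Generator] = None) -> GenotypeBlock:
    """Draw dosages per variant as Binomial(2, AAF), iid per participant."""
    rng = rng or _stage_rng(config, cohort_idx, 0)
    n = config.n_participants_per_cohort
    aafs = np.array([config.aaf_spectrum[i % len(config.aaf_spectrum)]
                     for i in range(config.n_variants)])
    dosage = rng.binomial(2, aafs[:, None], size=(config.n_variants, n)).astype(float)
    participants = [f"C{cohort_idx}_P{i:05d}" for i in range(n)]
    variants = [Variant(chrom="1", pos=1000 * (i + 1), ref="A", alt="G")
                for i in range(config.n_variants)]
    block = GenotypeBlock(variants=variants, participants=participants,
                          dosage=dosage)
    return compute_allele_stats(block)


def default_gene_masks(block: GenotypeBlock, maf_max: float = 0.01,
                       gene_size: int = 5) -> list[GeneMask]:
    """Group the rare variants of a block into consecutive gene masks."""
    rare = [v.id for i, v in enumerate(block.variants)
            if min(block.aaf[i], 1 - block.aaf[i]) < maf_max]
    masks = []
    for g, start in enumerate(range(0, len(rare), gene_size)):
        members = rare[start:start + gene_size]
        if members:
            masks.append(GeneMask(gene=f"GENE{g + 1:03d}", members=members))
    return masks


# ---------------------------------------------------------------------------
# covariates and phenotype
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimConfig, cohort_idx: int = 0,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    rng = rng or _stage_rng(config, cohort_idx, 1)
    n = config.n_participants_per_cohort
    style = config.visit_style[cohort_idx % len(config.visit_style)]
    df = pd.DataFrame({
        "participant_id": [f"C{cohort_idx}_P{i:05d}" for i in range(n)],
        "age": np.clip(rng.normal(67, 9, n), 41, 85),
        "sex": rng.binomial(1, 0.55, n),
        **{f"pc{k}": rng.normal(0, 1, n) for k in range(1, 6)},
        "pack_years": 10 + rng.exponential(30, n),
        "fev1_fvc": rng.uniform(0.35, 0.69, n),
        "icd_codes": "J44.9",
        "smoker_flag": 1,
        "height_m": np.clip(rng.normal(1.70, 0.09, n), 1.45, 2.05),
        "cohort": f"cohort{cohort_idx}",
        "style": style,
    })
    return df


def _calibrate_intercept(eta: np.ndarray, target: float,
                         lo: float = -30.0, hi: float = 30.0,
                         tol: float = 1e-10) -> float:
    """Bisection on the intercept so mean(sigmoid(b0 + eta)) hits target."""
    def frac(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def simulate_phenotype(genotypes: GenotypeBlock, covariates: pd.DataFrame,
                       config: SimConfig, cohort_idx: int = 0,
                       rng: Optional[np.random.Generator] = None) -> TruthTable:
    """Draw true weight-loss labels from the logistic generative model."""
    rng = rng or _stage_rng(config, cohort_idx, 2)
    n = genotypes.n_participants
    eta = np.zeros(n)
    for idx, beta in config.planted_effects:
        eta += beta * np.nan_to_num(genotypes.dosage[idx], nan=0.0)
    eff = config.covariate_effects
    eta += eff.get("age", 0.0) * (covariates["age"].to_numpy() - 65.0)
    eta += eff.get("sex", 0.0) * covariates["sex"].to_numpy()
    for k in range(1, 6):
        eta += eff.get("pc", 0.0) * covariates[f"pc{k}"].to_numpy()
    b0 = _calibrate_intercept(eta, config.case_fraction_target)
    prob = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    labels = (rng.random(n) < prob).astype(int)

    # episode parameters are filled by simulate_trajectories
    participants = pd.DataFrame({
        "participant_id": genotypes.participants,
        "wl_label": labels,
        "episode_onset_months_before_end": np.nan,
        "episode_rate_per_year": np.nan,
        "episode_regained": False,
        "low_bmi_case": False,
    })
    truth_variants = pd.DataFrame({
        "variant_id": [v.id for v in genotypes.variants],
        "true_log_or": [dict(config.planted_effects).get(i, 0.0)
                        for i in range(genotypes.n_variants)],
    })
    return TruthTable(participants=participants, variants=truth_variants)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _piecewise_weight(t_days: np.ndarray, span_days: float, w0: float,
                      onset_mb: float, rate: float, duration_mo: float,
                      regained: bool) -> np.ndarray:
    """Piecewise-linear trajectory: plateau, loss, then plateau or regain.

    ``onset_mb`` is the loss onset in months before the last record; ``rate``
    is the annualized loss as a fraction of the pre-loss weight.
    """
    t_onset = span_days - onset_mb * MONTH_DAYS
    t_end_loss = t_onset + duration_mo * MONTH_DAYS
    loss_frac = rate * duration_mo / 12.0
    w = np.full_like(t_days, w0, dtype=float)
    in_loss = (t_days > t_onset) & (t_days <= t_end_loss)
    w[in_loss] = w0 * (1.0 - rate * (t_days[in_loss] - t_onset) / 365.25)
    after = t_days > t_end_loss
    if regained:
        # linear regain back above the pre-loss weight by the last record
        t_last = float(t_days.max())
        denom = max(t_last - t_end_loss, 1.0)
        frac_back = np.clip((t_days[after] - t_end_loss) / denom, 0, 1)
        w[after] = w0 * (1 - loss_frac) + frac_back * w0 * (loss_frac + 0.03)
    else:
        w[after] = w0 * (1.0 - loss_frac)
    return w


def simulate_trajectories(truth: TruthTable, covariates: pd.DataFrame,
                          config: SimConfig, cohort_idx: int = 0,
                          rng: Optional[np.random.Generator] = None
                          ) -> dict[str, WeightSeries]:
    """Realize weight series consistent with the true labels.

    True cases get a non-regained loss episode at a rate drawn from the
    configured range (or, for a configurable fraction, a decline ending at a
    final BMI below 20); true controls drift with |slope| well under 2%/yr or
    exhibit a fully regained episode. Gaussian measurement noise is added to
    every record and per-record BMI is derived from the participant's fixed
    height.
    """
    rng = rng or _stage_rng(config, cohort_idx, 3)
    style = config.visit_style[cohort_idx % len(config.visit_style)]
    cov = covariates.set_index("participant_id")
    out: dict[str, WeightSeries] = {}
    tp = truth.participants.set_index("participant_id")

    for pid in truth.participants["participant_id"]:
        height = float(cov.loc[pid, "height_m"])
        bmi0 = float(np.clip(rng.normal(27, 4), 20.5, 42))
        w0 = bmi0 * height ** 2
        label = int(tp.loc[pid, "wl_label"])

        # time grid
        if style == VISIT_BASED:
            n_visits = int(rng.integers(2, 9))
            spacing = rng.uniform(*config.visit_spacing_months_range)
            t_days = np.round(np.arange(n_visits) * spacing * MONTH_DAYS)
        else:
            span = config.ehr_span_months * MONTH_DAYS
            n_rec = max(4, rng.poisson(config.ehr_records_per_year
                                       * config.ehr_span_months / 12.0))
            t_days = np.sort(rng.uniform(0, span, n_rec))
            t_days = np.unique(np.round(np.append(t_days, span)))
        span_days = float(t_days.max()) if len(t_days) else 0.0

        low_bmi_case = False
        onset_mb = np.nan
        rate = np.nan
        regained = False

        if label == 1 and rng.random() < config.low_bmi_case_fraction:
            # slow decline ending below the low-BMI threshold
            low_bmi_case = True
            final_bmi = rng.uniform(17.0, 19.3)
            w_final = final_bmi * height ** 2
            w = w0 + (w_final - w0) * np.clip(t_days / max(span_days, 1.0), 0, 1)
        elif label == 1:
            rate = rng.uniform(*config.wl_episode_rate_range)
            if style == VISIT_BASED and len(t_days) >= 2:
                # persistent step loss across one inter-visit gap
                j = int(rng.integers(0, len(t_days) - 1))
                gap_years = (t_days[j + 1] - t_days[j]) / 365.25
                frac = float(np.clip(rate * gap_years, 0.08, 0.35))
                w = np.full_like(t_days, w0, dtype=float)
                w[j + 1:] = w0 * (1 - frac)
                onset_mb = (span_days - t_days[j]) / MONTH_DAYS
            else:
                duration = rng.uniform(14, 26)          # months
                end_before = rng.uniform(8, 18)         # months before last
                onset_mb = end_before + duration
                w = _piecewise_weight(t_days, span_days, w0, onset_mb, rate,
                                      duration, regained=False)
        else:
            if (rng.random() < config.regain_fraction
                    and len(t_days) >= (3 if style == VISIT_BASED else 6)):
                # fully regained episode: still a control
                regained = True
                rate = rng.uniform(*config.wl_episode_rate_range)
                if style == VISIT_BASED:
                    j = int(rng.integers(0, len(t_days) - 2))
                    gap_years = (t_days[j + 1] - t_days[j]) / 365.25
                    frac = float(np.clip(rate * gap_years, 0.08, 0.35))
                    w = np.full_like(t_days, w0, dtype=float)
                    w[j + 1] = w0 * (1 - frac)
                    w[j + 2:] = w0 * 1.03
                    onset_mb = (span_days - t_days[j]) / MONTH_DAYS
                else:
                    duration = rng.uniform(12, 20)
                    end_before = rng.uniform(24, 34)
                    onset_mb = end_before + duration
                    w = _piecewise_weight(t_days, span_days, w0, onset_mb,
                                          rate, duration, regained=True)
            else:
                drift = rng.uniform(-0.004, 0.012)      # fraction of w0 per yr
                w = w0 * (1.0 + drift * t_days / 365.25)

        w = w + rng.normal(0, config.trajectory_noise_sd, len(t_days))
        w = np.maximum(w, 25.0)   # clean weights stay plausible
        records = [WeightRecord(participant_id=pid, time_days=int(t),
                                weight_kg=float(wk),
                                bmi=float(wk / height ** 2))
                   for t, wk in zip(t_days, w)]
        if len(records) < 2:
            tp.loc[pid, "wl_label"] = -1   # flagged unusable
        out[pid] = WeightSeries(pid, records)

        tp.loc[pid, ["episode_onset_months_before_end", "episode_rate_per_year"]] = \
            [onset_mb, rate]
        tp.loc[pid, "episode_regained"] = regained
        tp.loc[pid, "low_bmi_case"] = low_bmi_case

    truth.participants = tp.reset_index()
    return out


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

def contaminate(series: dict[str, WeightSeries], config: SimConfig,
                covariates: Optional[pd.DataFrame] = None,
                cohort_idx: int = 0,
                rng: Optional[np.random.Generator] = None
                ) -> dict[str, WeightSeries]:
    """Inject tagged implausible and outlying records.

    With the configured per-participant probabilities, inserts a record with
    weight < 20 kg, a record implying BMI < 10 kg/m², and a gross outlier
    beyond 3×IQR of the participant's clean weights. Tags make cleaning
    recall measurable against truth.
    """
    rng = rng or _stage_rng(config, cohort_idx, 4)
    rates = config.contamination_rates
    heights = (covariates.set_index("participant_id")["height_m"]
               if covariates is not None else None)
    out: dict[str, WeightSeries] = {}
    for pid, s in series.items():
        records = list(s.records)
        t_lo, t_hi = s.times_days.min(), s.times_days.max()
        height = float(heights.loc[pid]) if heights is not None else 1.70

        def rand_t():
            return int(rng.uniform(t_lo, max(t_hi, t_lo + 1)))

        if rng.random() < rates.get("low_weight", 0):
            wkg = rng.uniform(5, 19)
            records.append(WeightRecord(pid, rand_t(), float(wkg),
                                        bmi=float(wkg / height ** 2),
                                        contaminant_tag="low_weight"))
        if rng.random() < rates.get("low_bmi", 0):
            bmi = rng.uniform(7.5, 9.5)
            records.append(WeightRecord(pid, rand_t(), float(bmi * height ** 2),
                                        bmi=float(bmi),
                                        contaminant_tag="low_bmi"))
        if rng.random() < rates.get("gross_outlier", 0):
            w = s.weights
            q1, q3 = np.percentile(w, [25, 75])
            iqr = q3 - q1
            excess = rng.uniform(3.5, 6.0)
            bump = excess * iqr if iqr > 0 else 0.6 * float(np.median(w))
            wkg = q3 + bump
            records.append(WeightRecord(pid, rand_t(), float(wkg),
                                        bmi=float(wkg / height ** 2),
                                        contaminant_tag="gross_outlier"))
        out[pid] = WeightSeries(pid, records)
    return out


# ---------------------------------------------------------------------------
# cohort assembly and files
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, cohort_idx: int = 0,
                    contaminated: bool = True) -> Cohort:
    """Run the full generative chain for one cohort."""
    style = config.visit_style[cohort_idx % len(config.visit_style)]
    genotypes = simulate_genotypes(config, cohort_idx)
    covariates = simulate_covariates(config, cohort_idx)
    truth = simulate_phenotype(genotypes, covariates, config, cohort_idx)
    series = simulate_trajectories(truth, covariates, config, cohort_idx)
    # contamination emulates EHR data entry; curated visit schedules stay clean
    if (contaminated and style == EHR_STYLE
            and any(v > 0 for v in config.contamination_rates.values())):
        series = contaminate(series, config, covariates, cohort_idx)
    masks = default_gene_masks(genotypes)
    return Cohort(name=f"cohort{cohort_idx}", style=style, genotypes=genotypes,
                  covariates=covariates, series=series, truth=truth,
                  masks=masks)


def simulate_study(config: SimConfig, contaminated: bool = True) -> list[Cohort]:
    return [simulate_cohort(config, i, contaminated)
            for i in range(config.n_cohorts)]


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write one cohort's weights/covariates/VCF/groups/truth files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": write_weights_tsv(cohort.series.values(),
                                     directory / "weights.tsv"),
        "covariates": write_covariates_tsv(cohort.covariates,
                                           directory / "covariates.tsv"),
        "vcf": write_vcf(cohort.genotypes, directory / "genotypes.vcf"),
        "groups": write_group_file(cohort.masks, directory / "groups.txt"),
    }
    cohort.truth.participants.to_csv(directory / "truth_participants.tsv",
                                     sep="\t", index=False)
    cohort.truth.variants.to_csv(directory / "truth_variants.tsv",
                                 sep="\t", index=False)
    paths["truth_participants"] = directory / "truth_participants.tsv"
    paths["truth_variants"] = directory / "truth_variants.tsv"
    return paths
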