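"""Synthetic cohort generator: determinism, calibration, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copdwl.phenotype import MONTH_DAYS
from copdwl.simulate import (SimConfig, contaminate, simulate_cohort,
                             simulate_covariates, simulate_genotypes,
                             simulate_phenotype, simulate_trajectories,
                             write_cohort, _piecewise_weight)
from copdwl.tables import read_weights_tsv


NO_CONTAM = {"low_weight": 0.0, "low_bmi": 0.0, "gross_outlier": 0.0}


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_participants_per_cohort=0)
    with pytest.raises(ValueError):
        SimConfig(case_fraction_target=1.0)
    with pytest.raises(ValueError):
        SimConfig(aaf_spectrum=())
    with pytest.raises(ValueError):
        SimConfig(aaf_spectrum=(0.7,))
    with pytest.raises(ValueError):
        SimConfig(n_variants=5, planted_effects=((7, 0.4),))
    with pytest.raises(ValueError):
        SimConfig(contamination_rates={"low_weight": 1.5})


def test_genotypes_aaf_zero_gives_all_reference():
    cfg = SimConfig(n_participants_per_cohort=50, n_variants=3,
                    aaf_spectrum=(0.0,), seed=1)
    b = simulate_genotypes(cfg)
    assert np.all(b.dosage == 0) and np.all(b.mac == 0)


def test_genotypes_realized_aaf_binomial_ci():
    cfg = SimConfig(n_participants_per_cohort=10_000, n_variants=1,
                    aaf_spectrum=(0.5,), seed=2)
    b = simulate_genotypes(cfg)
    assert 0.485 <= b.aaf[0] <= 0.515


def test_genotypes_deterministic():
    cfg = SimConfig(n_participants_per_cohort=200, n_variants=10, seed=3)
    b1, b2 = simulate_genotypes(cfg), simulate_genotypes(cfg)
    np.testing.assert_array_equal(b1.dosage, b2.dosage)


def test_rare_variant_present_when_requested():
    cfg = SimConfig(n_participants_per_cohort=2000, n_variants=8, seed=4)
    b = simulate_genotypes(cfg)
    assert np.any(b.aaf < 0.01)


def test_case_fraction_calibrated_without_effects():
    cfg = SimConfig(n_participants_per_cohort=5000, n_variants=4, seed=5,
                    case_fraction_target=0.5,
                    covariate_effects={"age": 0, "sex": 0, "pc": 0})
    g = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    truth = simulate_phenotype(g, cov, cfg)
    assert abs(truth.participants["wl_label"].mean() - 0.5) <= 0.02


def test_case_fraction_calibrated_with_covariate_effects():
    cfg = SimConfig(n_participants_per_cohort=5000, n_variants=4, seed=6,
                    case_fraction_target=0.45)
    g = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    truth = simulate_phenotype(g, cov, cfg)
    assert abs(truth.participants["wl_label"].mean() - 0.45) <= 0.02


def test_saturating_effect_makes_alt_homozygotes_cases():
    cfg = SimConfig(n_participants_per_cohort=3000, n_variants=2, seed=7,
                    aaf_spectrum=(0.3,), planted_effects=((0, 10.0),),
                    case_fraction_target=0.3,
                    covariate_effects={"age": 0, "sex": 0, "pc": 0})
    g = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    truth = simulate_phenotype(g, cov, cfg)
    hom = g.dosage[0] == 2
    assert truth.participants.loc[hom, "wl_label"].mean() > 0.99


def test_piecewise_trajectory_closed_form():
    # rate 0.10/yr over 24 months from 80 kg: final weight 80*(1-0.2) = 64
    t = np.array([0.0, 300, 600, 900, 1200, 1500, 1826])
    onset_mb = 1826.0 / MONTH_DAYS          # loss starts exactly at day 0
    w = _piecewise_weight(t, 1826.0, 80.0, onset_mb=onset_mb, rate=0.10,
                          duration_mo=24.0, regained=False)
    assert w[0] == pytest.approx(80.0)
    assert w[-1] == pytest.approx(64.0, abs=1e-9)
    # during the loss phase the decline is linear at 8 kg/yr
    in_loss = (t > 0) & (t <= 24 * MONTH_DAYS)
    slopes = np.diff(w[in_loss]) / np.diff(t[in_loss]) * 365.25
    assert np.allclose(slopes, -8.0)


def test_regained_trajectory_returns_above_baseline():
    t = np.linspace(0, 1826, 40)
    w = _piecewise_weight(t, 1826.0, 80.0, onset_mb=45.0, rate=0.12,
                          duration_mo=15.0, regained=True)
    assert w[-1] >= 80.0


def test_noiseless_controls_have_bounded_drift():
    cfg = SimConfig(n_participants_per_cohort=200, n_variants=4, seed=8,
                    trajectory_noise_sd=0.0, regain_fraction=0.0,
                    contamination_rates=NO_CONTAM)
    coh = simulate_cohort(cfg, 1)
    tp = coh.truth.participants.set_index("participant_id")
    for pid, s in coh.series.items():
        if tp.loc[pid, "wl_label"] != 0:
            continue
        w, t = s.weights, s.times_days
        years = (t[-1] - t[0]) / 365.25
        if years > 0:
            assert abs(w[-1] - w[0]) / w[0] / years < 0.02


def test_regain_fraction_one_every_episode_recovers():
    cfg = SimConfig(n_participants_per_cohort=150, n_variants=4, seed=9,
                    trajectory_noise_sd=0.0, regain_fraction=1.0,
                    contamination_rates=NO_CONTAM)
    for idx in (0, 1):
        coh = simulate_cohort(cfg, idx)
        tp = coh.truth.participants.set_index("participant_id")
        regained = tp[(tp["wl_label"] == 0) & tp["episode_regained"]]
        assert len(regained) > 0
        for pid in regained.index:
            s = coh.series[pid]
            onset_mb = tp.loc[pid, "episode_onset_months_before_end"]
            t_onset = s.times_days[-1] - onset_mb * MONTH_DAYS
            pre = s.weights[s.times_days <= t_onset]
            if len(pre):
                assert s.weights[-1] >= pre.max() - 1e-9


def test_cases_carry_episode_or_low_bmi():
    cfg = SimConfig(n_participants_per_cohort=300, n_variants=4, seed=10,
                    contamination_rates=NO_CONTAM)
    coh = simulate_cohort(cfg, 1)
    tp = coh.truth.participants
    cases = tp[tp["wl_label"] == 1]
    assert len(cases) > 50
    has_mechanism = (cases["low_bmi_case"]
                     | cases["episode_onset_months_before_end"].notna())
    assert has_mechanism.all()


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

def _clean_cohort(seed=11, n=300):
    cfg = SimConfig(n_participants_per_cohort=n, n_variants=4, seed=seed,
                    contamination_rates=NO_CONTAM)
    return cfg, simulate_cohort(cfg, 1, contaminated=False)


def test_contaminate_zero_rates_identity():
    cfg, coh = _clean_cohort()
    out = contaminate(coh.series, cfg, coh.covariates, 1)
    for pid in coh.series:
        assert [r.weight_kg for r in out[pid].records] == \
               [r.weight_kg for r in coh.series[pid].records]


def test_contaminate_rate_one_adds_low_weight_everywhere():
    cfg, coh = _clean_cohort()
    cfg2 = SimConfig(**{**cfg.__dict__,
                        "contamination_rates": {"low_weight": 1.0,
                                                "low_bmi": 0.0,
                                                "gross_outlier": 0.0}})
    out = contaminate(coh.series, cfg2, coh.covariates, 1)
    for pid, s in out.items():
        assert any(r.weight_kg < 20 and r.contaminant_tag == "low_weight"
                   for r in s.records)


def test_contaminant_count_within_binomial_interval():
    cfg, coh = _clean_cohort(seed=12, n=1000)
    rate = 0.05
    cfg2 = SimConfig(**{**cfg.__dict__,
                        "contamination_rates": {"low_weight": rate,
                                                "low_bmi": 0.0,
                                                "gross_outlier": 0.0}})
    out = contaminate(coh.series, cfg2, coh.covariates, 1)
    count = sum(any(r.contaminant_tag == "low_weight" for r in s.records)
                for s in out.values())
    lo = stats.binom.ppf(0.005, 1000, rate)
    hi = stats.binom.ppf(0.995, 1000, rate)
    assert lo <= count <= hi


def test_contaminants_are_tagged_and_measurable():
    cfg = SimConfig(n_participants_per_cohort=100, n_variants=4, seed=13,
                    contamination_rates={"low_weight": 0.5, "low_bmi": 0.5,
                                         "gross_outlier": 0.5})
    coh = simulate_cohort(cfg, 1)
    tags = {r.contaminant_tag for s in coh.series.values()
            for r in s.records if r.contaminant_tag}
    assert tags == {"low_weight", "low_bmi", "gross_outlier"}


# ---------------------------------------------------------------------------
# files
# ---------------------------------------------------------------------------

def test_write_cohort_round_trip_and_determinism(tmp_path):
    cfg = SimConfig(n_participants_per_cohort=60, n_variants=10, seed=14)
    coh = simulate_cohort(cfg, 1)
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    paths1 = write_cohort(coh, d1)
    paths2 = write_cohort(simulate_cohort(cfg, 1), d2)

    # fixed seed: byte-identical files
    for key in paths1:
        assert paths1[key].read_bytes() == paths2[key].read_bytes()

    # weights round-trip losslessly at TSV precision
    back = read_weights_tsv(paths1["weights"])
    assert set(back) == set(coh.series)
    for pid in coh.series:
        np.testing.assert_allclose(back[pid].weights, coh.series[pid].weights,
                                   rtol=1e-12)
        np.testing.assert_array_equal(back[pid].times_days,
                                      coh.series[pid].times_days)

    # VCF parses with htslib-based tooling and matches the block
    from copdwl.genio import read_vcf
    b2 = read_vcf(paths1["vcf"])
    assert [v.id for v in b2.variants] == \
           sorted((v.id for v in coh.genotypes.variants),
                  key=lambda s: (s.split(":")[0], int(s.split(":")[1])))

    # truth file row count equals participant count
    truth = pd.read_csv(paths1["truth_participants"], sep="\t")
    assert len(truth) == cfg.n_participants_per_cohort
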