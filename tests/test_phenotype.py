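"""Weight-loss classifiers, cleaning rules and eligibility filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_series
from oracles import brute_classify_ehr

from copdwl.phenotype import (MONTH_DAYS, EligibilityRecord, PhenoParams,
                              SlopeFit, Window, assess_eligibility,
                              classify_ehr, classify_visits, clean_series,
                              enumerate_windows, fit_window_slope)

PARAMS = PhenoParams()


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("age,ratio,py,expected", [
    (55, 0.69, 15, True),    # all thresholds satisfied
    (55, 0.70, 15, False),   # strict inequality on FEV1/FVC
    (55, 0.69, 9.9, False),  # insufficient pack-years
    (40, 0.69, 15, False),   # age must exceed 40
    (41, 0.69, 10, True),    # pack-years boundary is inclusive
])
def test_spirometric_eligibility(age, ratio, py, expected):
    rec = EligibilityRecord("p", age=age, fev1_fvc=ratio, pack_years=py)
    assert assess_eligibility(rec, PARAMS, "spirometric").eligible is expected


@pytest.mark.parametrize("age,codes,smoker,expected", [
    (60, ["J44.9"], True, True),
    (60, ["J40"], True, False),
    (86, ["J44.9"], True, False),
    (60, ["J43.1"], False, False),
])
def test_icd_eligibility(age, codes, smoker, expected):
    rec = EligibilityRecord("p", age=age, icd_codes=codes, smoker_flag=smoker)
    assert assess_eligibility(rec, PARAMS, "icd").eligible is expected


def test_missing_fields_are_indeterminate_not_excluded():
    rec = EligibilityRecord("p", age=55, fev1_fvc=0.6)
    out = assess_eligibility(rec, PARAMS, "spirometric")
    assert out.eligible is None and "pack_years" in out.reason
    out = assess_eligibility(EligibilityRecord("p", age=55), PARAMS, "spirometric")
    assert out.eligible is None


def test_smoker_flag_fallback_when_pack_years_unavailable():
    params = PhenoParams(allow_smoker_flag_fallback=True)
    rec = EligibilityRecord("p", age=55, fev1_fvc=0.6, smoker_flag=True)
    assert assess_eligibility(rec, params, "spirometric").eligible is True


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def test_low_weight_record_removed():
    s = make_series([0, 100, 200, 300], [80, 81, 19, 80])
    cleaned, rep = clean_series(s)
    assert rep.removed == {"low_weight": 1, "low_bmi": 0, "iqr_outlier": 0}
    assert list(cleaned.weights) == [80, 81, 80]


def test_iqr_outlier_with_degenerate_quartiles():
    # Q1 = Q3 = 80, IQR = 0, so 160 > 80 + 3*0 is an outlier
    s = make_series([0, 100, 200, 300, 400], [80, 80, 80, 80, 160])
    cleaned, rep = clean_series(s)
    assert rep.removed["iqr_outlier"] == 1
    assert 160 not in cleaned.weights


def test_clean_identity_and_accounting():
    s = make_series([0, 50, 100], [80, 82, 81])
    cleaned, rep = clean_series(s)
    assert list(cleaned.weights) == [80, 82, 81]
    assert rep.n_removed == 0 and rep.n_retained == 3
    assert rep.n_removed + rep.n_retained == rep.n_input


def test_low_bmi_record_removed_before_iqr():
    s = make_series([0, 100, 200], [80, 28, 80], bmis=[26.0, 9.0, 26.0])
    cleaned, rep = clean_series(s)
    assert rep.removed["low_bmi"] == 1
    assert len(cleaned) == 2


def test_all_records_removed_yields_empty_series():
    s = make_series([0, 100], [10, 15])
    cleaned, rep = clean_series(s)
    assert len(cleaned) == 0 and rep.removed["low_weight"] == 2


@settings(max_examples=200, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 3000),
                          st.floats(1, 300, allow_nan=False),
                          st.floats(3, 80, allow_nan=False)),
                min_size=1, max_size=30))
def test_cleaning_soundness(records):
    """No weight < 20 kg and no BMI < 10 survives cleaning."""
    s = make_series([r[0] for r in records], [r[1] for r in records],
                    bmis=[r[2] for r in records])
    cleaned, rep = clean_series(s)
    assert all(r.weight_kg >= 20 for r in cleaned.records)
    assert all(r.bmi is None or r.bmi >= 10 for r in cleaned.records)
    assert rep.n_removed + rep.n_retained == rep.n_input


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_window_enumeration_matches_published_schedule():
    s = make_series([0, 2000], [80, 80])
    windows = enumerate_windows(s)
    assert len(windows) == 17
    assert windows[0] == Window(60, 48)
    assert windows[-1] == Window(12, 6)
    spans = [w.span_months for w in windows]
    assert spans == [12] * 15 + [9, 6]
    # records older than 60 months before the last record join no window
    assert not any(w.contains(60.0) or w.contains(75.0) for w in windows)


def test_window_membership_half_open():
    w = Window(60, 48)
    assert w.contains(48.0) and w.contains(59.999)
    assert not w.contains(60.0) and not w.contains(47.999)


# ---------------------------------------------------------------------------
# window slope fits
# ---------------------------------------------------------------------------

def test_slope_fit_exact_on_collinear_points():
    # three collinear points inside the (60, 48] window, slope -1/3 kg/month
    anchor = 1796                       # ~59 months after the first record
    days = [0, 152, 335, anchor]
    slope_per_month = -1.0 / 3.0
    weights = [80 + slope_per_month * d / MONTH_DAYS for d in days[:3]]
    weights.append(70.0)
    s = make_series(days, weights)
    fit = fit_window_slope(s, Window(60, 48))
    assert isinstance(fit, SlopeFit)
    assert fit.n_points == 3
    assert fit.slope == pytest.approx(slope_per_month, rel=1e-9)
    assert fit.slope_p == 0.0           # collinear: all variance explained
    ref = np.mean(weights[:3])
    assert fit.ref_weight == pytest.approx(ref)
    assert fit.annualized_loss_fraction == pytest.approx(4.0 / ref, rel=1e-9)


def test_two_points_skipped():
    s = make_series([0, 100, 1796], [80, 78, 70])
    assert fit_window_slope(s, Window(60, 48)) == "skipped"


def test_constant_weights_zero_slope():
    s = make_series([0, 152, 335, 1796], [80, 80, 80, 70])
    fit = fit_window_slope(s, Window(60, 48))
    assert fit.slope == 0.0
    assert fit.annualized_loss_fraction == 0.0


def test_same_day_records_skipped():
    s = make_series([100, 100, 100, 1896], [80, 81, 79, 70])
    assert fit_window_slope(s, Window(60, 48)) == "skipped"


# ---------------------------------------------------------------------------
# EHR classifier
# ---------------------------------------------------------------------------

def _linear_series(baseline, annual_rate, n_months, tail_months, noise=0.0,
                   rng=None, height=1.7):
    """Monthly records: linear loss for n_months, then plateau to the end."""
    total = n_months + tail_months
    days = [round(m * MONTH_DAYS) for m in range(total + 1)]
    weights = []
    for m in range(total + 1):
        if m <= n_months:
            w = baseline * (1 - annual_rate * m / 12)
        else:
            w = baseline * (1 - annual_rate * n_months / 12)
        if rng is not None and noise > 0:
            w += rng.normal(0, noise)
        weights.append(w)
    bmis = [w / height ** 2 for w in weights]
    return make_series(days, weights, bmis=bmis)


def test_ehr_detects_sustained_loss():
    # 80 kg baseline, -10%/yr for 36 months, then 12-month plateau:
    # the loss overlaps several windows and the final weight sits well
    # below the in-window maxima
    s = _linear_series(80, 0.10, 36, 12)
    call = classify_ehr(s)
    assert call.status == "case" and call.basis == "slope_window"
    assert call.max_wl_window_weight > call.final_weight


def test_ehr_fully_regained_is_control():
    days = [round(m * MONTH_DAYS) for m in range(0, 61, 2)]
    weights = []
    for m in range(0, 61, 2):
        if m < 12:
            w = 80.0
        elif m < 24:
            w = 80 - (m - 12) * 0.8          # lose ~9.6 kg over a year
        elif m < 40:
            w = 70.4 + (m - 24) * 0.7        # regain past baseline
        else:
            w = 81.6
        weights.append(w)
    s = make_series(days, weights, bmis=[w / 1.72 ** 2 for w in weights])
    call = classify_ehr(s)
    assert call.status == "control"


def test_ehr_low_final_bmi_is_case_without_windows():
    days = [round(m * MONTH_DAYS) for m in range(0, 61, 3)]
    weights = [57.0] * len(days)             # flat trajectory
    bmis = [19.5] * len(days)
    call = classify_ehr(make_series(days, weights, bmis=bmis))
    assert call.status == "case" and call.basis == "low_bmi"


def test_ehr_empty_series_indeterminate():
    from copdwl.phenotype import WeightSeries
    call = classify_ehr(WeightSeries("p", []))
    assert call.status == "indeterminate"


def test_threshold_sharpness_five_percent_boundary():
    """A noiseless linear loss at exactly 5.0%/yr is detected; 4.9% is not."""
    def build(rate_frac):
        # symmetric 3-point design in the (60,48] window: mean weight is the
        # centre weight, so the annualized loss fraction equals rate_frac
        anchor = 1796
        centre_day = 335 // 2
        offs = 120
        days = [centre_day - offs, centre_day, centre_day + offs, anchor]
        w_mid = 80.0
        slope = -rate_frac * w_mid / 12          # kg per month
        weights = [w_mid + slope * (d - centre_day) / MONTH_DAYS
                   for d in days[:3]] + [70.0]
        return make_series(days, weights)

    assert classify_ehr(build(0.050)).status == "case"
    assert classify_ehr(build(0.049)).status == "control"


@settings(max_examples=60, deadline=None)
@given(st.integers(3, 25), st.floats(45, 120), st.floats(0.001, 0.03),
       st.integers(0, 10_000))
def test_monotone_increase_is_control(n, w0, step_frac, seed):
    """Strictly increasing weights with final BMI >= 20 are controls."""
    rng = np.random.default_rng(seed)
    days = np.sort(rng.choice(np.arange(0, 2200), size=n, replace=False))
    weights = w0 * (1 + step_frac) ** np.arange(n)
    height = np.sqrt(weights[-1] / 24.0)     # final BMI fixed at 24
    bmis = weights / height ** 2
    s = make_series(days, weights, bmis=bmis)
    assert classify_ehr(s).status == "control"
    if n >= 2:
        assert classify_visits(s).status == "control"


# ---------------------------------------------------------------------------
# visit-based classifier
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("weights,bmi,expected,basis", [
    ([80, 75, 76], 24.0, "case", "visit_loss"),   # 6.25% loss, not regained
    ([80, 75, 81], 24.0, "control", "none"),      # fully regained
    ([80, 78, 77], 21.0, "control", "none"),      # no pair reaches 5%
    ([80, 75, 80], 24.0, "control", "none"),      # tie counts as regained
    ([80, 79, 78], 19.0, "case", "low_bmi"),      # low final BMI only
])
def test_visit_classifier_rules(weights, bmi, expected, basis):
    bmis = [None] * (len(weights) - 1) + [bmi]
    s = make_series([0, 400, 800][:len(weights)], weights, bmis=bmis)
    call = classify_visits(s)
    assert call.status == expected and call.basis == basis


def test_visit_single_record_indeterminate():
    s = make_series([0], [80])
    assert classify_visits(s).status == "indeterminate"


def test_visit_regain_checks_all_later_visits():
    # loss at (0,1); regain only at the final visit
    s = make_series([0, 300, 600, 900], [80, 74, 75, 80],
                    bmis=[None, None, None, 25.0])
    assert classify_visits(s).status == "control"


# ---------------------------------------------------------------------------
# determinism and oracle equivalence
# ---------------------------------------------------------------------------

def test_classifier_deterministic():
    s = _linear_series(85, 0.08, 30, 14)
    c1, c2 = classify_ehr(s), classify_ehr(s)
    assert (c1.status, c1.basis, c1.final_weight) == \
           (c2.status, c2.basis, c2.final_weight)


def _random_series(rng):
    n = int(rng.integers(3, 50))
    days = np.sort(rng.choice(np.arange(0, 2300), size=n, replace=False))
    base = rng.uniform(50, 110)
    if rng.random() < 0.5:
        # inject a linear decline segment of random rate and extent
        rate = rng.uniform(0.0, 0.25)
        onset = rng.uniform(200, 1800)
        w = np.where(days < onset, base,
                     base * (1 - rate * (days - onset) / 365.25))
        w = np.maximum(w, 30.0)
    else:
        w = np.full(n, base)
    w = w + rng.normal(0, rng.uniform(0, 2.0), n)
    height = rng.uniform(1.5, 1.95)
    bmis = w / height ** 2
    return days, w, bmis


@pytest.mark.parametrize("n_series", [150])
def test_ehr_oracle_equivalence_random_series(n_series, rng):
    """classify_ehr matches the explicit-loop closed-form oracle."""
    for _ in range(n_series):
        days, w, bmis = _random_series(rng)
        s = make_series(days, w, bmis=bmis)
        call = classify_ehr(s)
        status, basis = brute_classify_ehr(days, w, bmis)
        assert (call.status, call.basis) == (status, basis)
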