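"""Weight-loss phenotyping for COPD cohorts.

Two classifiers are provided, matching the two kinds of longitudinal weight
data seen in practice:

* :func:`classify_visits` — discrete study visits: a participant is a weight-loss
  (WL) case if any consecutive-visit drop reaches 5% of the earlier visit's
  weight and is never fully regained at a later visit, or the final-visit BMI
  is below 20 kg/m².
* :func:`classify_ehr` — irregular EHR timestamps: the last 60 months of cleaned
  weights are scanned with a 12-month sliding window stepping every 3 months
  (the last two windows shrink to 9 and 6 months). A window flags WL when an
  ordinary least-squares line through ≥3 in-window weights has a significantly
  negative slope amounting to ≥5% of body weight per 12 months. A participant
  is a case if the maximum weight observed in any WL window exceeds the final
  weight, or the last BMI is below 20 kg/m².

Eligibility filters (spirometric FEV1/FVC < 0.7 with ≥10 pack-years, or
ICD-10 J41–J44 codes with smoking history at age 40–85) and EHR record
cleaning (implausible values, per-participant 3×IQR outliers) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

#: days per month used for all window arithmetic
MONTH_DAYS = 30.4375

#: relative guard so a trajectory whose exact annualized loss fraction equals
#: the threshold is still detected despite float roundoff
_THRESHOLD_GUARD = 1e-9


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightRecord:
    participant_id: str
    time_days: int
    weight_kg: float
    bmi: Optional[float] = None
    contaminant_tag: Optional[str] = None

    def __post_init__(self):
        if not np.isfinite(self.time_days):
            raise ValueError("time_days must be finite")
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")


@dataclass
class WeightSeries:
    """Ordered longitudinal weight/BMI records for one participant."""

    participant_id: str
    records: list[WeightRecord] = field(default_factory=list)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: r.time_days)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight_kg for r in self.records], dtype=float)

    @property
    def times_days(self) -> np.ndarray:
        return np.array([r.time_days for r in self.records], dtype=float)

    @property
    def last(self) -> WeightRecord:
        return self.records[-1]


@dataclass
class CleaningReport:
    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=lambda: {
        "low_weight": 0, "low_bmi": 0, "iqr_outlier": 0})
    reasons: list[tuple[WeightRecord, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


@dataclass(frozen=True)
class Window:
    """A sliding window measured in months before the last record.

    The interval is open at ``start_before`` and closed at ``end_before``:
    a record ``m`` months before the last record falls in the window iff
    ``end_before <= m < start_before``.
    """

    start_before: int
    end_before: int

    @property
    def span_months(self) -> int:
        return self.start_before - self.end_before

    def contains(self, months_before: float) -> bool:
        return self.end_before <= months_before < self.start_before


@dataclass
class SlopeFit:
    window: Window
    n_points: int
    slope: float            # kg per month
    intercept: float        # kg
    slope_p: float
    ref_weight: float       # mean in-window weight, kg
    annualized_loss_fraction: float


@dataclass
class PhenotypeCall:
    participant_id: str
    status: str                       # case | control | indeterminate
    basis: str                        # slope_window | visit_loss | low_bmi | none
    final_weight: Optional[float] = None
    final_bmi: Optional[float] = None
    wl_window: Optional[Window] = None
    max_wl_window_weight: Optional[float] = None

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class EligibilityRecord:
    participant_id: str
    age: float
    fev1_fvc: Optional[float] = None
    pack_years: Optional[float] = None
    icd_codes: Optional[Sequence[str]] = None
    smoker_flag: Optional[bool] = None

    def __post_init__(self):
        if self.fev1_fvc is not None and not (0 < self.fev1_fvc < 1.5):
            raise ValueError("fev1_fvc outside (0, 1.5)")


@dataclass
class PhenoParams:
    """Thresholds of the weight-loss phenotype and its eligibility filters."""

    wl_fraction_threshold: float = 0.05       # 5% body weight per 12 months
    low_bmi_threshold: float = 20.0           # kg/m²
    slope_p_threshold: float = 0.05
    min_window_points: int = 3
    lookback_months: int = 60
    window_span_months: int = 12
    window_step_months: int = 3
    min_end_before_months: int = 6
    # cleaning
    min_plausible_weight: float = 20.0        # kg
    min_plausible_bmi: float = 10.0           # kg/m²
    iqr_multiplier: float = 3.0
    # eligibility
    min_age_spirometric: float = 40.0
    icd_age_range: tuple[float, float] = (40.0, 85.0)
    min_pack_years: float = 10.0
    fev1_fvc_threshold: float = 0.7
    icd_prefixes: tuple[str, ...] = ("J41", "J42", "J43", "J44")
    allow_smoker_flag_fallback: bool = False  # JHS-style: any smoking history


@dataclass
class EligibilityResult:
    eligible: Optional[bool]   # None means indeterminate (missing field)
    reason: str


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def assess_eligibility(record: EligibilityRecord, params: PhenoParams,
                       mode: str = "spirometric") -> EligibilityResult:
    """Decide COPD eligibility for one participant.

    ``spirometric`` mode requires age above the minimum, FEV1/FVC strictly
    below 0.7 and at least 10 pack-years (or, when pack-years are unavailable
    and the fallback switch is on, any smoking history). ``icd`` mode requires
    age 40–85, an ICD-10 code with a J41–J44 prefix and smoking history.
    Missing required fields yield an explicit indeterminate outcome.
    """
    if mode == "spirometric":
        if record.fev1_fvc is None:
            return EligibilityResult(None, "missing fev1_fvc")
        if record.age <= params.min_age_spirometric:
            return EligibilityResult(False, "age at or below minimum")
        if record.fev1_fvc >= params.fev1_fvc_threshold:
            return EligibilityResult(False, "fev1_fvc not below threshold")
        if record.pack_years is None:
            if params.allow_smoker_flag_fallback:
                if record.smoker_flag is None:
                    return EligibilityResult(None, "missing smoking history")
                if record.smoker_flag:
                    return EligibilityResult(True, "eligible (smoker-flag fallback)")
                return EligibilityResult(False, "never smoker")
            return EligibilityResult(None, "missing pack_years")
        if record.pack_years < params.min_pack_years:
            return EligibilityResult(False, "insufficient pack-years")
        return EligibilityResult(True, "eligible (spirometric)")

    if mode == "icd":
        lo, hi = params.icd_age_range
        if not (lo <= record.age <= hi):
            return EligibilityResult(False, "age outside range")
        if record.icd_codes is None:
            return EligibilityResult(None, "missing icd_codes")
        has_code = any(str(c).upper().startswith(params.icd_prefixes)
                       for c in record.icd_codes)
        if not has_code:
            return EligibilityResult(False, "no qualifying diagnosis code")
        if record.smoker_flag is None:
            return EligibilityResult(None, "missing smoking history")
        if not record.smoker_flag:
            return EligibilityResult(False, "never smoker")
        return EligibilityResult(True, "eligible (icd)")

    raise ValueError(f"unknown eligibility mode: {mode!r}")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_series(series: WeightSeries, params: PhenoParams | None = None,
                 apply_iqr: bool = True) -> tuple[WeightSeries, CleaningReport]:
    """Remove implausible and outlying weight records.

    Implausible records (weight < 20 kg, or BMI < 10 kg/m² when a BMI is
    recorded) are removed first; a single IQR pass then removes weights more
    than 3×IQR above the 75th or below the 25th percentile, with quartiles
    computed per participant over the post-implausible-removal weights.

    The IQR pass is designed for dense EHR records and can be disabled
    (``apply_iqr=False``) for sparse study-visit schedules, where a genuine
    large weight loss at the final visit would otherwise look like an
    outlier against an almost-constant history.
    """
    params = params or PhenoParams()
    if len(series) == 0:
        raise ValueError("cannot clean an empty series")
    report = CleaningReport(n_input=len(series), n_retained=0)

    plausible: list[WeightRecord] = []
    for rec in series.records:
        if rec.weight_kg < params.min_plausible_weight:
            report.removed["low_weight"] += 1
            report.reasons.append((rec, "low_weight"))
        elif rec.bmi is not None and rec.bmi < params.min_plausible_bmi:
            report.removed["low_bmi"] += 1
            report.reasons.append((rec, "low_bmi"))
        else:
            plausible.append(rec)

    retained = plausible
    if plausible and apply_iqr:
        w = np.array([r.weight_kg for r in plausible])
        q1, q3 = np.percentile(w, [25, 75])
        iqr = q3 - q1
        lo = q1 - params.iqr_multiplier * iqr
        hi = q3 + params.iqr_multiplier * iqr
        retained = []
        for rec in plausible:
            if rec.weight_kg > hi or rec.weight_kg < lo:
                report.removed["iqr_outlier"] += 1
                report.reasons.append((rec, "iqr_outlier"))
            else:
                retained.append(rec)

    report.n_retained = len(retained)
    assert report.n_retained + report.n_removed == report.n_input
    return WeightSeries(series.participant_id, retained), report


# ---------------------------------------------------------------------------
# EHR sliding-window classifier
# ---------------------------------------------------------------------------

def enumerate_windows(series: WeightSeries,
                      params: PhenoParams | None = None) -> list[Window]:
    """Sliding windows anchored at the last record.

    Start offsets run 60, 57, …, 15, 12 months before the last record (17
    windows); each window ends 12 months after its start, but never closer
    than 6 months to the last record, so the final two windows span only 9
    and 6 months.
    """
    params = params or PhenoParams()
    windows = []
    start = params.lookback_months
    while start >= params.window_span_months:
        end = max(start - params.window_span_months, params.min_end_before_months)
        windows.append(Window(start_before=start, end_before=end))
        start -= params.window_step_months
    return windows


def fit_window_slope(series: WeightSeries, window: Window,
                     params: PhenoParams | None = None) -> SlopeFit | str:
    """OLS of weight on time (months) within one window.

    Returns the string ``"skipped"`` when fewer than three records fall in
    the window or all in-window records share one day. Perfectly collinear
    points leave no residual variance; the slope then trivially explains all
    of it and ``slope_p`` is set to 0.
    """
    params = params or PhenoParams()
    t_last = series.last.time_days
    months_before = (t_last - series.times_days) / MONTH_DAYS
    in_win = np.array([window.contains(m) for m in months_before])
    n = int(in_win.sum())
    if n < params.min_window_points:
        return "skipped"
    t = series.times_days[in_win] / MONTH_DAYS
    w = series.weights[in_win]
    if np.ptp(t) == 0:
        return "skipped"

    res = stats.linregress(t, w)
    slope, intercept = res.slope, res.intercept
    fitted = intercept + slope * t
    sse = float(np.sum((w - fitted) ** 2))
    ssy = float(np.sum((w - w.mean()) ** 2))
    if sse <= 1e-12 * max(ssy, 1.0):
        # zero residual variance: degenerate t-test
        p = 0.0 if slope != 0 else 1.0
    else:
        p = float(res.pvalue)
    ref = float(w.mean())
    return SlopeFit(window=window, n_points=n, slope=float(slope),
                    intercept=float(intercept), slope_p=p, ref_weight=ref,
                    annualized_loss_fraction=(-slope * 12.0) / ref)


def _final_bmi(series: WeightSeries, height_m: Optional[float]) -> Optional[float]:
    # last recorded BMI; if none exists, derive from last weight and height
    for rec in reversed(series.records):
        if rec.bmi is not None:
            return rec.bmi
    if height_m:
        return series.last.weight_kg / height_m ** 2
    return None


def classify_ehr(series: WeightSeries, params: PhenoParams | None = None,
                 height_m: Optional[float] = None) -> PhenotypeCall:
    """EHR sliding-window weight-loss call for one cleaned series.

    A window is a WL window iff its slope fit exists, the slope is negative
    and significant (p < 0.05), and the annualized loss is at least 5% of the
    mean in-window weight. The participant is a case iff the maximum weight
    observed in any WL window exceeds the last recorded weight, or the final
    BMI is below 20 kg/m².
    """
    params = params or PhenoParams()
    if len(series) == 0:
        return PhenotypeCall(series.participant_id, "indeterminate", "none")

    final_weight = series.last.weight_kg
    final_bmi = _final_bmi(series, height_m)

    wl_windows: list[SlopeFit] = []
    for window in enumerate_windows(series, params):
        fit = fit_window_slope(series, window, params)
        if fit == "skipped":
            continue
        assert isinstance(fit, SlopeFit)
        if (fit.slope < 0 and fit.slope_p < params.slope_p_threshold
                and fit.annualized_loss_fraction
                >= params.wl_fraction_threshold * (1 - _THRESHOLD_GUARD)):
            wl_windows.append(fit)

    max_wl_weight = None
    wl_by_slope = False
    best_window = None
    if wl_windows:
        t_last = series.last.time_days
        months_before = (t_last - series.times_days) / MONTH_DAYS
        in_any = np.zeros(len(series), dtype=bool)
        for fit in wl_windows:
            in_any |= np.array([fit.window.contains(m) for m in months_before])
        max_wl_weight = float(series.weights[in_any].max())
        wl_by_slope = max_wl_weight > final_weight
        best_window = wl_windows[0].window

    wl_by_bmi = final_bmi is not None and final_bmi < params.low_bmi_threshold

    if wl_by_slope:
        basis = "slope_window"
    elif wl_by_bmi:
        basis = "low_bmi"
    else:
        basis = "none"
    status = "case" if (wl_by_slope or wl_by_bmi) else "control"
    return PhenotypeCall(series.participant_id, status, basis,
                         final_weight=final_weight, final_bmi=final_bmi,
                         wl_window=best_window if wl_by_slope else None,
                         max_wl_window_weight=max_wl_weight)


# ---------------------------------------------------------------------------
# visit-based classifier
# ---------------------------------------------------------------------------

def classify_visits(series: WeightSeries, params: PhenoParams | None = None,
                    height_m: Optional[float] = None) -> PhenotypeCall:
    """Visit-based weight-loss call.

    A loss event occurs between consecutive visits i, i+1 when the drop
    reaches 5% of visit i's weight; the event is regained iff any subsequent
    visit weight (ties included) returns to at least visit i's weight. A
    participant is a case iff some loss event is never regained, or the
    final-visit BMI is below 20 kg/m².
    """
    params = params or PhenoParams()
    if len(series) < 2:
        return PhenotypeCall(series.participant_id, "indeterminate", "none",
                             final_weight=series.last.weight_kg if len(series) else None)

    w = series.weights
    final_weight = float(w[-1])
    final_bmi = _final_bmi(series, height_m)

    non_regained = False
    for i in range(len(w) - 1):
        if (w[i] - w[i + 1]) / w[i] >= params.wl_fraction_threshold:
            regained = bool(np.any(w[i + 1:] >= w[i]))
            if not regained:
                non_regained = True
                break

    wl_by_bmi = final_bmi is not None and final_bmi < params.low_bmi_threshold
    if non_regained:
        basis = "visit_loss"
    elif wl_by_bmi:
        basis = "low_bmi"
    else:
        basis = "none"
    status = "case" if (non_regained or wl_by_bmi) else "control"
    return PhenotypeCall(series.participant_id, status, basis,
                         final_weight=final_weight, final_bmi=final_bmi)
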