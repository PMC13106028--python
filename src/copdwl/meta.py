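"""Fixed-effects inverse-variance meta-analysis across cohorts.

METAL-style effect-size (STDERR) scheme: with per-study weights
``w_i = 1/se_i^2``, the pooled effect is ``sum(w_i b_i)/sum(w_i)`` with
standard error ``sum(w_i)^{-1/2}``. Heterogeneity is summarized by
Cochran's Q (chi-square with k-1 df) and ``I^2 = max(0, (Q-(k-1))/Q)·100``.
Direction strings carry one character per configured study: '+', '-' or '?'
when the study did not contribute the variant.

Harmonization before pooling: variants are matched on chrom:pos with an
unordered allele pair (a study reporting swapped ref/alt has its effect
negated and AAF complemented); any position observed with more than one
distinct allele pair in any study is removed entirely (multivalent), and
variants present in fewer than two studies are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z95
from .genio import Variant

META_COLUMNS = ["ID", "REF", "ALT", "TOTAL_N", "MIN_FREQ", "MAX_FREQ",
                "BETA", "SE", "OR", "L95", "U95", "P", "DIRECTION",
                "HET_Q", "HET_ISQ", "HET_DF", "HET_P"]


@dataclass
class MetaResult:
    variant: Variant
    k: int
    total_n: int
    direction: str
    beta_meta: float
    se_meta: float
    p: float
    q: float
    i2: float
    het_p: float
    min_aaf: float
    max_aaf: float

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_meta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta_meta - Z95 * self.se_meta)),
                float(np.exp(self.beta_meta + Z95 * self.se_meta)))


@dataclass
class HarmonizeReport:
    n_input_rows: int = 0
    n_multivalent_removed: int = 0
    n_single_study_dropped: int = 0
    n_variants_kept: int = 0
    flipped: list[str] = field(default_factory=list)


def harmonize(study_results: dict[str, pd.DataFrame],
              study_order: Sequence[str],
              min_studies: int = 2) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Align per-cohort association tables onto one variant orientation.

    ``study_results`` maps cohort label to a results table in the
    association-module TSV layout (CHR POS REF ALT N AAF BETA SE P ...).
    Returns a long DataFrame with one row per (variant, study) plus a report
    of multivalent and single-study removals.
    """
    for name in study_order:
        if name not in study_results:
            raise ValueError(f"study order names unknown cohort {name!r}")
    report = HarmonizeReport()

    frames = []
    for name in study_order:
        df = study_results[name].copy()
        df["STUDY"] = name
        dup = df.duplicated(subset=["CHR", "POS", "REF", "ALT"])
        if dup.any():
            vid = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate variant {vid['CHR']}:{vid['POS']}:{vid['REF']}:"
                f"{vid['ALT']} within study {name!r}")
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    report.n_input_rows = len(long)
    if long.empty:
        return long, report

    long["CHR"] = long["CHR"].astype(str)
    long["PAIR"] = [tuple(sorted((r, a)))
                    for r, a in zip(long["REF"], long["ALT"])]
    if "MULTI" in long.columns:
        multi_pos = set(map(tuple, long.loc[long["MULTI"].astype(bool),
                                            ["CHR", "POS"]].itertuples(index=False)))
    else:
        multi_pos = set()

    # multivalent: >1 distinct allele pair at a position, in any study
    npairs = long.groupby(["CHR", "POS"])["PAIR"].nunique()
    multi_pos |= set(npairs[npairs > 1].index)
    is_multi = [(c, p) in multi_pos
                for c, p in zip(long["CHR"], long["POS"])]
    report.n_multivalent_removed = int(np.sum(is_multi))
    long = long.loc[~np.array(is_multi, dtype=bool)].copy()
    if long.empty:
        return long.drop(columns=["PAIR"]), report

    # orient each variant to the first contributing study (in configured order)
    aligned_rows = []
    for (_, _), grp in long.groupby(["CHR", "POS"], sort=True):
        grp = grp.copy()
        grp["_order"] = [study_order.index(s) for s in grp["STUDY"]]
        grp = grp.sort_values("_order")
        ref, alt = grp.iloc[0]["REF"], grp.iloc[0]["ALT"]
        for _, row in grp.iterrows():
            row = row.copy()
            if (row["REF"], row["ALT"]) == (alt, ref):
                row["BETA"] = -row["BETA"]
                if "AAF" in row and pd.notna(row["AAF"]):
                    row["AAF"] = 1.0 - row["AAF"]
                row["REF"], row["ALT"] = ref, alt
                report.flipped.append(
                    f"{row['CHR']}:{row['POS']} in {row['STUDY']}")
            aligned_rows.append(row)
    aligned = pd.DataFrame(aligned_rows).drop(columns=["PAIR", "_order"],
                                              errors="ignore")

    counts = aligned.groupby(["CHR", "POS", "REF", "ALT"])["STUDY"].nunique()
    keep = counts[counts >= min_studies].index
    key = pd.MultiIndex.from_frame(aligned[["CHR", "POS", "REF", "ALT"]])
    dropped = ~key.isin(keep)
    report.n_single_study_dropped = int(
        aligned.loc[dropped].groupby(["CHR", "POS", "REF", "ALT"]).ngroups)
    aligned = aligned.loc[~dropped].reset_index(drop=True)
    report.n_variants_kept = int(
        aligned.groupby(["CHR", "POS", "REF", "ALT"]).ngroups)
    return aligned, report


def fixed_effects_meta(aligned: pd.DataFrame,
                       study_order: Sequence[str]) -> list[MetaResult]:
    """Inverse-variance pooling of a harmonized long table."""
    results: list[MetaResult] = []
    if aligned.empty:
        return results
    for (chrom, pos, ref, alt), grp in aligned.groupby(
            ["CHR", "POS", "REF", "ALT"], sort=True):
        beta = grp["BETA"].to_numpy(dtype=float)
        se = grp["SE"].to_numpy(dtype=float)
        if np.any(~np.isfinite(beta)) or np.any(se <= 0):
            raise ValueError(f"non-finite beta or non-positive se at "
                             f"{chrom}:{pos}")
        k = len(grp)
        w = 1.0 / se ** 2
        bm = float(np.sum(w * beta) / np.sum(w))
        sm = float(np.sum(w) ** -0.5)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(bm) / sm)))
        q = float(np.sum(w * (beta - bm) ** 2))
        het_df = k - 1
        het_p = float(stats.chi2.sf(q, het_df)) if het_df > 0 else 1.0
        i2 = 0.0 if q <= 0 else max(0.0, (q - het_df) / q) * 100.0

        by_study = dict(zip(grp["STUDY"], beta))
        direction = "".join(
            "?" if s not in by_study
            else ("+" if by_study[s] > 0 else "-" if by_study[s] < 0 else "+")
            for s in study_order)

        aaf = grp["AAF"].to_numpy(dtype=float) if "AAF" in grp else np.array([np.nan])
        results.append(MetaResult(
            variant=Variant(chrom=str(chrom), pos=int(pos), ref=str(ref),
                            alt=str(alt)),
            k=k, total_n=int(grp["N"].sum()) if "N" in grp else 0,
            direction=direction, beta_meta=bm, se_meta=sm, p=p, q=q, i2=i2,
            het_p=het_p, min_aaf=float(np.nanmin(aaf)),
            max_aaf=float(np.nanmax(aaf))))
    results.sort(key=lambda r: (r.variant.chrom, r.variant.pos, r.variant.alt))
    return results


class FixedEffectsMeta:
    """Meta-analysis model over per-cohort association tables.

    Parameters
    ----------
    study_results : dict mapping cohort label -> results DataFrame
    study_order : ordering used for direction strings and orientation
    min_studies : variants in fewer studies are dropped (default 2)
    """

    def __init__(self, study_results: dict[str, pd.DataFrame],
                 study_order: Optional[Sequence[str]] = None,
                 min_studies: int = 2):
        self.study_results = study_results
        self.study_order = list(study_order or study_results.keys())
        self.min_studies = min_studies

    def fit(self) -> "MetaAnalysisResults":
        aligned, report = harmonize(self.study_results, self.study_order,
                                    self.min_studies)
        results = fixed_effects_meta(aligned, self.study_order)
        for r in results:
            assert r.k >= min(self.min_studies, 2) or self.min_studies < 2
        return MetaAnalysisResults(results, self.study_order, report)


class MetaAnalysisResults:
    def __init__(self, results: list[MetaResult], study_order: Sequence[str],
                 harmonize_report: Optional[HarmonizeReport] = None):
        self.results = results
        self.study_order = list(study_order)
        self.harmonize_report = harmonize_report

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            lo, hi = r.ci95
            rows.append({"ID": r.variant.id, "REF": r.variant.ref,
                         "ALT": r.variant.alt, "TOTAL_N": r.total_n,
                         "MIN_FREQ": r.min_aaf, "MAX_FREQ": r.max_aaf,
                         "BETA": r.beta_meta, "SE": r.se_meta, "OR": r.or_,
                         "L95": lo, "U95": hi, "P": r.p,
                         "DIRECTION": r.direction, "HET_Q": r.q,
                         "HET_ISQ": r.i2, "HET_DF": r.k - 1, "HET_P": r.het_p})
        return pd.DataFrame(rows, columns=META_COLUMNS)

    def to_tsv(self, path: str | Path) -> Path:
        self.summary().to_csv(path, sep="\t", index=False)
        return Path(path)

    def significant_hits(self, alpha: float = 5e-8) -> pd.DataFrame:
        df = self.summary()
        return df[df["P"] < alpha].reset_index(drop=True)
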