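"""Plain-text table formats shared across the pipeline stages.

Weights are exchanged as long-format TSV (participant_id, time_days,
weight_kg, bmi); covariates as one row per participant (age, sex, pc1..pc5,
pack_years, fev1_fvc, icd_codes, cohort, height_m); phenotype calls as
(participant_id, status, basis, final_weight, final_bmi).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .phenotype import PhenotypeCall, WeightRecord, WeightSeries

WEIGHTS_COLUMNS = ["participant_id", "time_days", "weight_kg", "bmi"]


def write_weights_tsv(series: Iterable[WeightSeries], path: str | Path) -> Path:
    rows = []
    for s in series:
        for r in s.records:
            rows.append({"participant_id": s.participant_id,
                         "time_days": r.time_days, "weight_kg": r.weight_kg,
                         "bmi": r.bmi if r.bmi is not None else np.nan,
                         "contaminant_tag": r.contaminant_tag or ""})
    df = pd.DataFrame(rows, columns=WEIGHTS_COLUMNS + ["contaminant_tag"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_weights_tsv(path: str | Path) -> dict[str, WeightSeries]:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    out: dict[str, WeightSeries] = {}
    has_tag = "contaminant_tag" in df.columns
    for pid, grp in df.groupby("participant_id", sort=True):
        records = []
        for row in grp.itertuples(index=False):
            bmi = getattr(row, "bmi", np.nan)
            tag = getattr(row, "contaminant_tag", "") if has_tag else ""
            records.append(WeightRecord(
                participant_id=str(pid), time_days=int(row.time_days),
                weight_kg=float(row.weight_kg),
                bmi=None if pd.isna(bmi) else float(bmi),
                contaminant_tag=str(tag) if isinstance(tag, str) and tag else None))
        out[str(pid)] = WeightSeries(str(pid), records)
    return out


def write_covariates_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str})


def write_phenotype_tsv(calls: Iterable[PhenotypeCall], path: str | Path) -> Path:
    rows = [{"participant_id": c.participant_id, "status": c.status,
             "basis": c.basis, "final_weight": c.final_weight,
             "final_bmi": c.final_bmi} for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str})
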