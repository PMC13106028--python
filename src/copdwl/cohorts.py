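"""Published per-study cohort accounting for the weight-loss-in-COPD designs.

The contributing studies are seven TOPMed cohorts (FHS, MESA, CHS, JHS,
COPDGene, ECLIPSE, SPIROMICS) plus the All of Us Research Program. Three
meta-analysis designs are used downstream:

* ``COSMO`` — every participant, analysed together by cohort;
* ``B/AA`` — the Black/African-American-predominant strata: COPDGene B/AA,
  SPIROMICS B/AA, JHS and All of Us B/AA;
* ``NHW`` — the non-Hispanic-white-predominant strata: COPDGene NHW,
  SPIROMICS NHW, ECLIPSE, FHS and All of Us NHW.

:func:`cohort_accounting` reproduces the design totals and per-cohort
weight-loss percentages from any such table; the published characteristics
are bundled as :data:`PUBLISHED_COHORTS` so the arithmetic can be checked
against the printed study sizes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

#: published participant and weight-loss counts per study, with the race
#: strata needed by the meta-analysis designs
PUBLISHED_COHORTS = pd.DataFrame([
    # cohort,            participants, wl_count
    ("FHS",                546,  295),
    ("MESA",               452,  160),
    ("CHS",                795,  368),
    ("JHS",                104,   45),
    ("COPDGene",          3097, 1457),
    ("ECLIPSE",           1888,  590),
    ("SPIROMICS",         1234,  389),
    ("All of Us",         8856, 4287),
], columns=["cohort", "participants", "wl_count"])

#: race-stratum participant counts used by the B/AA and NHW designs
PUBLISHED_STRATA = pd.DataFrame([
    ("COPDGene NHW",      2311),
    ("COPDGene B/AA",      786),
    ("SPIROMICS NHW",      995),
    ("SPIROMICS B/AA",     167),
    ("ECLIPSE",           1888),
    ("FHS",                546),
    ("JHS",                104),
    ("All of Us NHW",     5483),
    ("All of Us B/AA",    2278),
], columns=["cohort", "participants"])

#: meta-analysis design groupings
DESIGNS: dict[str, tuple[str, ...]] = {
    "COSMO": tuple(PUBLISHED_COHORTS["cohort"]),
    "B/AA": ("COPDGene B/AA", "SPIROMICS B/AA", "JHS", "All of Us B/AA"),
    "NHW": ("COPDGene NHW", "SPIROMICS NHW", "ECLIPSE", "FHS", "All of Us NHW"),
}


def cohort_accounting(cohorts: pd.DataFrame | None = None,
                      strata: pd.DataFrame | None = None,
                      designs: Mapping[str, Sequence[str]] | None = None
                      ) -> dict:
    """Totals per meta-analysis design and WL percentages per cohort.

    ``cohorts`` must carry columns (cohort, participants[, wl_count]);
    ``strata`` supplies additional named participant groups referenced by
    the design definitions. With no arguments, the published study counts
    are used. Zero cohorts yield an empty report.
    """
    if cohorts is None:
        cohorts = PUBLISHED_COHORTS
    if strata is None and cohorts is PUBLISHED_COHORTS:
        strata = PUBLISHED_STRATA
    if designs is None:
        designs = DESIGNS if cohorts is PUBLISHED_COHORTS else {
            "ALL": tuple(cohorts["cohort"])}
    if cohorts.empty:
        return {"design_totals": {}, "wl_percent": {}}

    lookup = dict(zip(cohorts["cohort"], cohorts["participants"]))
    if strata is not None:
        lookup.update(dict(zip(strata["cohort"], strata["participants"])))

    totals = {}
    for design, members in designs.items():
        missing = [m for m in members if m not in lookup]
        if missing:
            raise KeyError(f"design {design!r} references unknown cohorts "
                           f"{missing}")
        totals[design] = int(sum(lookup[m] for m in members))

    wl_percent = {}
    if "wl_count" in cohorts.columns:
        for row in cohorts.itertuples(index=False):
            wl_percent[row.cohort] = round(100.0 * row.wl_count
                                           / row.participants)
    return {"design_totals": totals, "wl_percent": wl_percent}
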