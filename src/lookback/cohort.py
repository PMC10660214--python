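"""Cohort construction: prevalent pool and incident cases under look-back periods.

A *case* in a window is a patient with at least 1 inpatient disease claim or
at least 3 outpatient disease claims inside it. A look-back period (LP) of
length L before the index year reclassifies a case as prevalent if they have
*any* disease-coded claim (either type, any count) inside the LP window —
the case rule and the exclusion rule deliberately differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims import CodePredicate

logger = logging.getLogger(__name__)

DEFAULT_LP_YEARS = (0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0)


def _months(lp_years: float) -> int:
    months = round(lp_years * 12)
    if abs(months - lp_years * 12) > 1e-9 or months <= 0:
        raise ValueError(f"LP must be a positive whole number of months, got {lp_years}")
    return months


@dataclass(frozen=True)
class LPGrid:
    """Candidate look-back periods for one index year.

    LP windows are calendar-aligned: a k-year LP for index year Y runs from
    Jan 1 of (Y-k) up to (excluding) Jan 1 of Y; fractional-year LPs step
    back in whole 3-month calendar blocks.
    """

    index_year: int
    lp_years: tuple[float, ...] = field(default=DEFAULT_LP_YEARS)

    def __post_init__(self) -> None:
        if not self.lp_years:
            raise ValueError("empty LP grid")
        if list(self.lp_years) != sorted(set(self.lp_years)):
            raise ValueError("lp_years must be strictly increasing")
        for lp in self.lp_years:
            _months(lp)

    @property
    def reference_lp(self) -> float:
        return self.lp_years[-1]

    @property
    def index_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.index_year, 1, 1)

    @property
    def index_end(self) -> pd.Timestamp:
        return pd.Timestamp(self.index_year + 1, 1, 1)

    def lp_window(self, lp_years: float) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Half-open [start, end) window for one LP."""
        end = self.index_start
        start = end - pd.DateOffset(months=_months(lp_years))
        return start, end


def identify_disease_cases(
    claims: pd.DataFrame,
    predicate: CodePredicate,
    window: tuple[pd.Timestamp, pd.Timestamp],
) -> set[str]:
    """Patients meeting the case rule inside half-open [start, end).

    Case rule: >=1 inpatient disease claim OR >=3 outpatient disease claims.
    """
    start, end = window
    if start >= end:
        return set()
    dates = claims["service_date"]
    in_window = (dates >= start) & (dates < end)
    disease = predicate.mask(claims["diagnosis_codes"])
    sub = claims.loc[in_window & disease, ["patient_id", "claim_type"]]
    if sub.empty:
        return set()
    counts = (
        sub.groupby(["patient_id", "claim_type"]).size().unstack(fill_value=0)
    )
    inpt = counts.get("inpatient", pd.Series(0, index=counts.index))
    outpt = counts.get("outpatient", pd.Series(0, index=counts.index))
    qualifies = (inpt >= 1) | (outpt >= 3)
    return set(counts.index[qualifies])


def prevalent_pool(
    claims: pd.DataFrame, predicate: CodePredicate, index_year: int
) -> set[str]:
    """All patients meeting the case rule within the index calendar year."""
    start = pd.Timestamp(index_year, 1, 1)
    end = pd.Timestamp(index_year + 1, 1, 1)
    return identify_disease_cases(claims, predicate, (start, end))


def incident_cases(
    claims: pd.DataFrame,
    predicate: CodePredicate,
    index_year: int,
    lp_years: float,
    horizon_start: pd.Timestamp | None = None,
    pool: set[str] | None = None,
) -> set[str]:
    """Prevalent-pool patients with no disease-coded claim inside the LP.

    The exclusion rule is "any record": a single outpatient disease claim
    in the LP window (below the 3-visit case threshold) still excludes.
    ``lp_years = 0`` means an empty exclusion window: the incident set
    equals the prevalent pool.
    """
    if pool is None:
        pool = prevalent_pool(claims, predicate, index_year)
    if lp_years == 0:
        return set(pool)
    grid = LPGrid(index_year=index_year, lp_years=(lp_years,))
    start, end = grid.lp_window(lp_years)
    if horizon_start is not None and start < horizon_start:
        raise ValueError(
            f"LP of {lp_years} years starts {start.date()}, before the earliest "
            f"available date {horizon_start.date()}"
        )
    dates = claims["service_date"]
    disease = predicate.mask(claims["diagnosis_codes"])
    in_lp = (dates >= start) & (dates < end) & disease
    excluded = set(claims.loc[in_lp, "patient_id"])
    return pool - excluded


@dataclass(frozen=True)
class CohortResult:
    """Prevalent pool for the index year plus nested incident sets per LP."""

    index_year: int
    prevalent_ids: frozenset[str]
    incident_by_lp: dict[float, frozenset[str]]

    def __post_init__(self) -> None:
        prev: frozenset[str] | None = None
        for lp in sorted(self.incident_by_lp):
            s = self.incident_by_lp[lp]
            if not s <= self.prevalent_ids:
                raise ValueError(f"incident set for LP {lp} not inside prevalent pool")
            if prev is not None and not s <= prev:
                raise ValueError(f"incident sets not nested at LP {lp}")
            prev = s


def build_cohort(
    claims: pd.DataFrame,
    predicate: CodePredicate,
    grid: LPGrid,
    horizon_start: pd.Timestamp | None = None,
) -> CohortResult:
    """Prevalent pool + incident set for every LP in the grid."""
    pool = prevalent_pool(claims, predicate, grid.index_year)
    incident = {
        lp: frozenset(
            incident_cases(
                claims, predicate, grid.index_year, lp,
                horizon_start=horizon_start, pool=pool,
            )
        )
        for lp in grid.lp_years
    }
    return CohortResult(
        index_year=grid.index_year,
        prevalent_ids=frozenset(pool),
        incident_by_lp=incident,
    )


def stratify_by_age_sex(
    patient_ids: set[str],
    claims: pd.DataFrame,
    index_year: int,
    bin_width: int = 5,
    max_age: int = 100,
) -> pd.DataFrame:
    """Count a patient set by age bin x sex.

    Age is computed on Dec 31 of the index year from each patient's birth
    date (taken from their claims). Patients with no recorded birth date
    are tallied in an ``"unknown"`` bin with a warning; marginals always
    equal the set size.
    """
    ref_date = pd.Timestamp(index_year, 12, 31)
    per_patient = (
        claims[claims["patient_id"].isin(patient_ids)]
        .groupby("patient_id")[["birth_date", "sex"]]
        .first()
        .reindex(sorted(patient_ids))
    )
    age = (ref_date - per_patient["birth_date"]).dt.days // 365.25
    edges = list(range(0, max_age, bin_width))
    labels = [f"{lo}-{lo + bin_width - 1}" for lo in edges[:-1]] + [f"{edges[-1]}+"]

    def _bin(a: float) -> str:
        if np.isnan(a):
            return "unknown"
        idx = min(int(a) // bin_width, len(labels) - 1)
        return labels[idx]

    n_unknown = int(age.isna().sum())
    if n_unknown:
        logger.warning("%d patients without birth date tallied as 'unknown'", n_unknown)

    frame = pd.DataFrame(
        {"age_bin": age.map(_bin), "sex": per_patient["sex"].fillna("missing")}
    )
    table = (
        frame.groupby(["age_bin", "sex"]).size().unstack(fill_value=0)
    )
    order = [lab for lab in labels + ["unknown"] if lab in table.index]
    table = table.loc[order]
    assert int(table.to_numpy().sum()) == len(patient_ids)
    return table
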