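"""Consistency examination indexes (CEIs) between look-back periods.

Each candidate LP's incident classification of the prevalent pool is
compared, as a 2x2 agreement table, with the classification under the
reference (longest) LP. The CEIs are Cohen's kappa, the positive predictive
value (PPV) and the overestimation rate. Because longer LPs only remove
incident cases, the incident sets are nested and the table's ``c`` cell
(incident under reference only) is always 0; then PPV = n_ref / n_lp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .cohort import CohortResult, LPGrid


@dataclass(frozen=True)
class AgreementTable:
    """2x2 agreement of one LP's classification against the reference.

    a: incident under both; b: incident under LP only; c: incident under
    reference only; d: prevalent under both.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("agreement counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_agreement(
    lp_set: set[str], ref_set: set[str], pool: set[str]
) -> AgreementTable:
    if not lp_set <= pool or not ref_set <= pool:
        raise ValueError("incident sets must be subsets of the prevalent pool")
    a = len(lp_set & ref_set)
    b = len(lp_set - ref_set)
    c = len(ref_set - lp_set)
    return AgreementTable(a=a, b=b, c=c, d=len(pool) - a - b - c)


def kappa(table: AgreementTable) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e).

    Returns NaN when expected agreement is 1 (both classifications
    constant), where kappa is undefined.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def ppv(table: AgreementTable) -> float:
    """P(incident under reference | incident under LP) = a / (a + b)."""
    if table.a + table.b == 0:
        return math.nan
    return table.a / (table.a + table.b)


def overestimation(n_lp: int, n_ref: int) -> float:
    """Relative excess of LP-identified incident cases over the reference."""
    if n_ref == 0:
        return math.nan
    return (n_lp - n_ref) / n_ref


@dataclass(frozen=True)
class CEIThresholds:
    """Acceptability cut-offs for an LP's CEIs (all configurable)."""

    kappa_min: float = 0.9
    ppv_min: float = 0.90
    overestimation_max: float = 0.10


def cei_table(cohort: CohortResult, grid: LPGrid) -> pd.DataFrame:
    """One row per grid LP: n incident, PPV, kappa, overestimation.

    Values are exact (unrounded); kappa at the reference LP is reported
    NaN (not applicable) rather than 1.0. Use :func:`round_half_up` at
    reporting time.
    """
    missing = [lp for lp in grid.lp_years if lp not in cohort.incident_by_lp]
    if missing:
        raise ValueError(f"cohort lacks incident sets for LPs {missing}")
    ref_lp = grid.reference_lp
    ref_set = set(cohort.incident_by_lp[ref_lp])
    pool = set(cohort.prevalent_ids)
    rows = []
    for lp in grid.lp_years:
        lp_set = set(cohort.incident_by_lp[lp])
        table = build_agreement(lp_set, ref_set, pool)
        rows.append(
            {
                "lp_years": lp,
                "n_incident": len(lp_set),
                "ppv": ppv(table),
                "kappa": math.nan if lp == ref_lp else kappa(table),
                "overestimation": overestimation(len(lp_set), len(ref_set)),
            }
        )
    return pd.DataFrame(rows)


def meets_thresholds(row: pd.Series, thresholds: CEIThresholds) -> bool:
    """Does one CEI row pass all cut-offs?

    A NaN kappa (the reference LP, which agrees with itself perfectly)
    counts as passing the kappa cut-off.
    """
    kappa_ok = np.isnan(row["kappa"]) or row["kappa"] >= thresholds.kappa_min
    return bool(
        kappa_ok
        and row["ppv"] >= thresholds.ppv_min
        and row["overestimation"] <= thresholds.overestimation_max
    )


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (reporting convention for proportions)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
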