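"""Retrograde survival analysis for look-back-period convergence.

Time runs backwards from each prevalent patient's last index-year disease
record (date ``a``). "Surviving" to t days means having no prior disease
record within t days: a patient whose most recent disease record inside the
look-back window is at date ``b`` has an event at ``a - b`` days; a patient
with no record anywhere in the window is censored at ``a - c`` days, where
``c`` is the first day of the window. S(t) is the Kaplan-Meier
product-limit estimate of P(T > t); the optimal LP is where S(t) has
stabilized, judged two ways:

* the actuarial daily hazard ``h_t = d_t / n_t`` first drops to ~0
  (threshold 0.0005 by default), and
* the frequency-of-S(t) rule: the number of days spent at each rounded
  S value jumps (at least doubles) and peaks at the stable value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .claims import CodePredicate
from .cohort import LPGrid
from .concordance import CEIThresholds, meets_thresholds, round_half_up

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DEFAULT_HAZARD_THRESHOLD = 0.0005
DEFAULT_JUMP_FACTOR = 2.0
DEFAULT_S_PRECISION = 2


def build_observations(
    claims: pd.DataFrame,
    predicate: CodePredicate,
    index_year: int,
    lp_start: pd.Timestamp,
    pool: set[str] | None = None,
) -> pd.DataFrame:
    """One retrograde observation per prevalent patient.

    Columns: ``patient_id``, ``a`` (last disease record in the index
    year), ``b`` (most recent disease record in [lp_start, Jan 1 of the
    index year), or NaT), ``time`` (days, a-b if b exists else a-lp_start)
    and ``event`` (True iff b exists). Patients in ``pool`` without any
    index-year disease record are excluded with a warning (``a`` cannot
    be defined for them).
    """
    index_start = pd.Timestamp(index_year, 1, 1)
    index_end = pd.Timestamp(index_year + 1, 1, 1)
    if lp_start >= index_start:
        raise ValueError("lp_start must precede the index year")

    disease = claims.loc[predicate.mask(claims["diagnosis_codes"]),
                         ["patient_id", "service_date"]]
    if pool is not None:
        disease = disease[disease["patient_id"].isin(pool)]

    dates = disease["service_date"]
    in_index = disease[(dates >= index_start) & (dates < index_end)]
    a = in_index.groupby("patient_id")["service_date"].max()

    if pool is not None and len(a) < len(pool):
        logger.warning(
            "%d pooled patients have no index-year disease record; excluded",
            len(pool) - len(a),
        )

    in_lp = disease[(dates >= lp_start) & (dates < index_start)]
    b = in_lp.groupby("patient_id")["service_date"].max().reindex(a.index)

    event = b.notna()
    time = np.where(event, (a - b).dt.days, (a - lp_start).dt.days)
    obs = pd.DataFrame(
        {
            "patient_id": a.index,
            "a": a.to_numpy(),
            "b": b.to_numpy(),
            "time": time.astype(int),
            "event": event.to_numpy(),
        }
    ).reset_index(drop=True)
    assert (obs["time"] > 0).all()
    return obs


def km_curve(observations: pd.DataFrame) -> pd.DataFrame:
    """Daily product-limit survival table.

    Returns a frame indexed by day 0..max(time) with columns ``n_t``
    (at risk at the start of the day), ``d_t`` (events during the day)
    and ``S`` (Kaplan-Meier estimate of P(T > t), right-continuous).
    Censored observations leave the risk set at their censor day, after
    any events that day.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(observations["time"], observations["event"])
    max_day = int(observations["time"].max())
    days = np.arange(0, max_day + 1)

    et = kmf.event_table  # indexed by time: removed, observed, censored, at_risk
    d = pd.Series(0, index=days, dtype=int)
    d.loc[et.index.astype(int)] = et["observed"].to_numpy()

    removed = pd.Series(0, index=days, dtype=int)
    removed.loc[et.index.astype(int)] = et["removed"].to_numpy()
    n_total = len(observations)
    n_t = n_total - removed.cumsum().shift(1, fill_value=0)

    s = kmf.survival_function_at_times(days).to_numpy()
    curve = pd.DataFrame({"n_t": n_t.to_numpy(), "d_t": d.to_numpy(), "S": s},
                         index=pd.Index(days, name="day"))
    assert curve.loc[0, "S"] == 1.0
    assert int(curve["d_t"].sum()) == int(observations["event"].sum())
    return curve


def hazard_curve(curve: pd.DataFrame, window: int = 1) -> pd.DataFrame:
    """Actuarial daily hazard ``h_t = d / n_t``, optionally smoothed.

    With ``window`` w > 1, h_t = (sum of events over days [t, t+w)) / n_t,
    on a sliding window; the curve is truncated at the last day with a
    full window and a non-empty risk set.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    d = curve["d_t"].to_numpy(dtype=float)
    n = curve["n_t"].to_numpy(dtype=float)
    days = curve.index.to_numpy()
    if window > 1:
        # forward window: events over [t, t+w), risk set taken at t
        csum = np.concatenate(([0.0], np.cumsum(d)))
        d_win = csum[window:] - csum[:-window]
        days = days[: len(d_win)]
        n = n[: len(d_win)]
    else:
        d_win = d
    valid = n > 0
    h = np.full(len(d_win), np.nan)
    h[valid] = d_win[valid] / n[valid]
    out = pd.DataFrame({"h": h, "d_window": d_win, "n_t": n},
                       index=pd.Index(days, name="day"))
    out = out.loc[out["n_t"] > 0]
    # day 0 carries no events (all retrograde times are positive)
    return out.loc[out.index >= 1]


def first_hazard_below(
    hazard: pd.DataFrame,
    threshold: float = DEFAULT_HAZARD_THRESHOLD,
    min_day: int = 0,
) -> int | None:
    """First day >= min_day whose (defined) hazard is <= threshold.

    ``min_day`` guards against spuriously early crossings on small
    cohorts, where a single empty day puts the raw hazard at 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sub = hazard.loc[(hazard.index >= min_day) & hazard["h"].notna()]
    hits = sub.index[sub["h"] <= threshold]
    return int(hits[0]) if len(hits) else None


def s_frequency(curve: pd.DataFrame, precision: int = DEFAULT_S_PRECISION) -> pd.DataFrame:
    """Days spent at each rounded S value, over days 1..max.

    Each day contributes one count to the bin of its rounded S; the
    frequency total therefore equals the number of days.
    """
    days = curve.loc[curve.index >= 1]
    rounded = days["S"].map(lambda s: round_half_up(s, precision))
    freq = rounded.value_counts().sort_index(ascending=False)
    out = freq.rename_axis("s_value").rename("n_days").reset_index()
    assert int(out["n_days"].sum()) == len(days)
    return out


def stable_s_day(
    freq: pd.DataFrame,
    curve: pd.DataFrame,
    jump_factor: float = DEFAULT_JUMP_FACTOR,
    precision: int = DEFAULT_S_PRECISION,
) -> tuple[float, int] | None:
    """Locate the stable S value by the frequency-jump rule.

    Scanning rounded S values in decreasing order, the stable value is the
    first whose day-count is at least ``jump_factor`` times the count of
    the next-higher S value *and* is the maximum count overall — i.e. the
    value where the dwell time jumps and peaks. Returns ``(stable_S,
    first day at stable_S)`` or ``None`` (with a diagnostic log) if no
    value qualifies.
    """
    if len(freq) < 2:
        logger.info("fewer than 2 distinct rounded S values; no stable S")
        return None
    values = freq["s_value"].to_numpy()
    counts = freq["n_days"].to_numpy()
    peak = counts.max()
    for i in range(1, len(values)):
        if counts[i] >= jump_factor * counts[i - 1] and counts[i] >= peak:
            stable = float(values[i])
            rounded = curve.loc[curve.index >= 1, "S"].map(
                lambda s: round_half_up(s, precision)
            )
            day = int(rounded.index[rounded == stable][0])
            return stable, day
    logger.info(
        "no frequency jump >= %.3gx found (max count %d); S not judged stable",
        jump_factor, int(peak),
    )
    return None


@dataclass(frozen=True)
class OptimalLPResult:
    """Combined recommendation from the CEI and retrograde-survival rules."""

    t_f_hazard: int | None
    t_f_freq: int | None
    stable_s: float | None
    recommended_lp_years: float | None
    diagnostics: str = ""

    def __post_init__(self) -> None:
        if self.recommended_lp_years is not None:
            bounds = [t for t in (self.t_f_hazard, self.t_f_freq) if t is not None]
            if bounds and self.recommended_lp_years * DAYS_PER_YEAR < max(bounds):
                raise ValueError("recommended LP shorter than a convergence day")


def recommend_lp(
    cei_rows: pd.DataFrame,
    t_f_hazard: int | None,
    t_f_freq: int | None,
    grid: LPGrid,
    thresholds: CEIThresholds = CEIThresholds(),
    stable_s: float | None = None,
) -> OptimalLPResult:
    """Smallest grid LP meeting every CEI cut-off and covering both t_f.

    An LP of L years is taken to cover a convergence day t_f when
    L * 365.25 >= t_f. If no grid LP qualifies, the result carries a
    diagnostic message and no recommendation.
    """
    bounds = [t for t in (t_f_hazard, t_f_freq) if t is not None]
    chosen: float | None = None
    reasons = []
    for lp in grid.lp_years:
        row = cei_rows.loc[cei_rows["lp_years"] == lp]
        if row.empty:
            raise ValueError(f"no CEI row for LP {lp}")
        row = row.iloc[0]
        cei_ok = meets_thresholds(row, thresholds)
        cover_ok = all(lp * DAYS_PER_YEAR >= t for t in bounds)
        if cei_ok and cover_ok:
            chosen = lp
            break
        reasons.append(
            f"LP {lp}y: CEIs {'pass' if cei_ok else 'fail'}, "
            f"covers t_f: {'yes' if cover_ok else 'no'}"
        )
    diag = "" if chosen is not None else "; ".join(reasons) or "empty grid"
    return OptimalLPResult(
        t_f_hazard=t_f_hazard,
        t_f_freq=t_f_freq,
        stable_s=stable_s,
        recommended_lp_years=chosen,
        diagnostics=diag,
    )
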