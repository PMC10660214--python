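"""Synthetic claims generator with ground truth.

Emulates the structure the look-back analysis assumes: each diseased
patient has a latent onset date and, from onset onward, makes recurrent
disease-coded contacts as a renewal process (no disease claims before
onset — the identifying assumption of the look-back method). Most patients
are regular visitors with gamma-distributed inter-visit gaps; a minority
contact care irregularly with heavy-tailed (log-normal) gaps, which is the
mechanism that lengthens the required look-back period. Inpatient vs
outpatient mix, background (non-disease) claims and record-level missing
fields are layered on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims import CODE_SEP
from .cohort import CohortResult

DISEASE_CODES = ["E10.9", "E11.2", "E11.9", "E12.9", "E13.9", "E14.9"]
DISEASE_WEIGHTS = [0.05, 0.15, 0.60, 0.02, 0.03, 0.15]  # type-2 dominant
BACKGROUND_CODES = ["I10", "J06.9", "K29.7", "M54.5", "J18.9", "N39.0"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic claims stream.

    Defaults emulate the utilization magnitudes of a large urban claims
    database: regular patients average ~9 disease-coded outpatient visits
    per year (gamma gaps, mean 40 days, shape 2); ~10% of patients are
    irregular visitors with log-normal gaps (median ~200 days); ~4% of
    contacts are inpatient admissions.
    """

    n_patients: int = 2000
    horizon: tuple[str, str] = ("2016-01-01", "2020-12-31")
    #: probability a patient's onset predates the horizon (prevalent stratum);
    #: onsets uniform within each stratum (10 y pre-horizon / the horizon).
    prevalent_fraction: float = 0.5
    pre_horizon_years: float = 10.0
    gap_shape: float = 2.0
    gap_mean_days: float = 40.0
    irregular_fraction: float = 0.1
    irregular_median_days: float = 200.0
    irregular_sigma: float = 1.0
    inpatient_probability: float = 0.04
    #: non-disease claims per patient-year (Poisson)
    background_rate: float = 2.0
    missing_sex_probability: float = 0.00002
    missing_diagnosis_probability: float = 0.0489
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "prevalent_fraction", "irregular_fraction", "inpatient_probability",
            "missing_sex_probability", "missing_diagnosis_probability",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.gap_mean_days <= 0 or self.irregular_median_days <= 0:
            raise ValueError("gap distributions must be strictly positive")


def _fields(cfg: SimulationConfig):
    start = pd.Timestamp(cfg.horizon[0])
    end = pd.Timestamp(cfg.horizon[1])
    if (end - start).days < cfg.gap_mean_days:
        import warnings

        warnings.warn("horizon shorter than one mean inter-visit gap")
    return start, end


def simulate_claims(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a claims stream and its ground truth.

    Returns ``(claims, truth)``: claims in the standard schema (sorted by
    patient then date), truth with one row per patient (``patient_id``,
    ``onset_date``, ``irregular``, ``sex``, ``birth_date``). Deterministic
    under a fixed config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    start, end = _fields(cfg)
    horizon_days = (end - start).days

    n = cfg.n_patients
    ids = np.array([f"P{i:06d}" for i in range(n)])
    sex = rng.choice(["male", "female"], size=n)
    age_2020 = rng.uniform(20, 90, size=n)
    birth = pd.Timestamp(2020, 12, 31) - pd.to_timedelta(
        (age_2020 * 365.25).astype(int), unit="D"
    )

    prevalent = rng.random(n) < cfg.prevalent_fraction
    onset_offset = np.where(
        prevalent,
        -rng.uniform(0, cfg.pre_horizon_years * 365.25, size=n),
        rng.uniform(0, horizon_days + 1, size=n),
    ).astype(int)
    onset = start + pd.to_timedelta(onset_offset, unit="D")

    irregular = rng.random(n) < cfg.irregular_fraction
    scale = cfg.gap_mean_days / cfg.gap_shape
    mu = np.log(cfg.irregular_median_days)

    pid_col, date_col, type_col, code_col = [], [], [], []
    for i in range(n):
        span = (end - onset[i]).days
        if span < 0:
            continue
        # renewal process from onset; first contact at onset itself
        if irregular[i]:
            mean_gap = float(np.exp(mu + cfg.irregular_sigma**2 / 2))
        else:
            mean_gap = cfg.gap_mean_days
        est = max(8, int(span / mean_gap * 1.6) + 8)
        offsets = [0.0]
        total = 0.0
        while total <= span:
            gaps = (
                rng.lognormal(mu, cfg.irregular_sigma, size=est)
                if irregular[i]
                else rng.gamma(cfg.gap_shape, scale, size=est)
            )
            cum = total + np.cumsum(gaps)
            keep = cum <= span
            offsets.extend(cum[keep])
            total = cum[-1]
        days = np.unique(np.asarray(offsets).astype(int))
        visit_dates = onset[i] + pd.to_timedelta(days, unit="D")
        visible = visit_dates >= start
        visit_dates = visit_dates[visible]
        k = len(visit_dates)
        if k == 0:
            continue
        pid_col.append(np.repeat(ids[i], k))
        date_col.append(visit_dates)
        type_col.append(
            np.where(rng.random(k) < cfg.inpatient_probability, "inpatient", "outpatient")
        )
        code_col.append(rng.choice(DISEASE_CODES, size=k, p=DISEASE_WEIGHTS))

    # background, non-disease claims
    n_bg = rng.poisson(cfg.background_rate * horizon_days / 365.25, size=n)
    for i in range(n):
        if n_bg[i] == 0:
            continue
        bg_dates = start + pd.to_timedelta(
            rng.integers(0, horizon_days + 1, size=n_bg[i]), unit="D"
        )
        pid_col.append(np.repeat(ids[i], n_bg[i]))
        date_col.append(bg_dates)
        type_col.append(
            np.where(rng.random(n_bg[i]) < cfg.inpatient_probability,
                     "inpatient", "outpatient")
        )
        code_col.append(rng.choice(BACKGROUND_CODES, size=n_bg[i]))

    if pid_col:
        claims = pd.DataFrame(
            {
                "patient_id": np.concatenate(pid_col),
                "service_date": pd.DatetimeIndex(np.concatenate(date_col)),
                "claim_type": np.concatenate(type_col),
                "diagnosis_codes": np.concatenate(code_col),
            }
        )
    else:
        claims = pd.DataFrame(
            columns=["patient_id", "service_date", "claim_type", "diagnosis_codes"]
        )

    idx = pd.Index(ids)
    claims["sex"] = pd.Series(sex, index=idx).reindex(claims["patient_id"]).to_numpy()
    claims["birth_date"] = (
        pd.Series(birth, index=idx).reindex(claims["patient_id"]).to_numpy()
    )

    # record-level missingness, injected post hoc
    m = len(claims)
    if m:
        drop_sex = rng.random(m) < cfg.missing_sex_probability
        drop_dx = rng.random(m) < cfg.missing_diagnosis_probability
        claims.loc[drop_sex, "sex"] = np.nan
        claims.loc[drop_dx, "diagnosis_codes"] = ""

    claims = claims[
        ["patient_id", "sex", "birth_date", "claim_type", "service_date",
         "diagnosis_codes"]
    ].sort_values(["patient_id", "service_date"], kind="stable").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "onset_date": onset,
            "irregular": irregular,
            "sex": sex,
            "birth_date": birth,
        }
    )
    return claims, truth


def true_incident_ids(truth: pd.DataFrame, index_year: int) -> set[str]:
    """Patients whose latent onset falls inside the index year."""
    years = truth["onset_date"].dt.year
    return set(truth.loc[years == index_year, "patient_id"])


def evaluate_recovery(
    cohort: CohortResult, truth: pd.DataFrame, index_year: int
) -> pd.DataFrame:
    """Score each LP's incident set against the simulator's ground truth.

    Per LP: ``sensitivity`` and ``true_ppv`` of the identified incident
    set against patients whose onset truly falls in the index year (within
    the prevalent pool), and the overestimation of the true incident
    count. Raises if the cohort contains patients unknown to the truth.
    """
    universe = set(truth["patient_id"])
    if not set(cohort.prevalent_ids) <= universe:
        raise ValueError("cohort contains patients absent from ground truth")
    true_inc = true_incident_ids(truth, index_year) & set(cohort.prevalent_ids)
    rows = []
    for lp in sorted(cohort.incident_by_lp):
        ident = set(cohort.incident_by_lp[lp])
        tp = len(ident & true_inc)
        rows.append(
            {
                "lp_years": lp,
                "n_identified": len(ident),
                "n_true_incident": len(true_inc),
                "sensitivity": tp / len(true_inc) if true_inc else np.nan,
                "true_ppv": tp / len(ident) if ident else np.nan,
                "overestimation_vs_truth": (
                    (len(ident) - len(true_inc)) / len(true_inc)
                    if true_inc
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_gap_probe(
    n_patients: int,
    index_year: int,
    lp_years: float,
    seed: int = 0,
    gap_shape: float = 2.0,
    gap_mean_days: float = 40.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Claims fixture whose retrograde times are i.i.d. gamma gap draws.

    Every patient has a single inpatient disease record on Jan 1 of the
    index year (so the last index-year record is that day and the patient
    meets the case rule) and one outpatient disease record exactly one
    gap-draw earlier. Gaps longer than the look-back window leave no prior
    record (censored). Feeding this stream through the standard pipeline
    makes the retrograde Kaplan-Meier curve a direct estimate of the gap
    distribution's survival function — a probe isolating the estimator.

    Returns ``(claims, gaps)`` with the true gap draws in days.
    """
    rng = np.random.default_rng(seed)
    a = pd.Timestamp(index_year, 1, 1)
    lp_days = int(round(lp_years * 365.25))
    gaps = np.maximum(1, np.round(rng.gamma(gap_shape, gap_mean_days / gap_shape,
                                            size=n_patients))).astype(int)
    ids = np.array([f"G{i:06d}" for i in range(n_patients)])

    frames = [
        pd.DataFrame(
            {
                "patient_id": ids,
                "sex": "female",
                "birth_date": pd.Timestamp(1960, 1, 1),
                "claim_type": "inpatient",
                "service_date": a,
                "diagnosis_codes": "E11.9",
            }
        )
    ]
    observed = gaps <= lp_days
    frames.append(
        pd.DataFrame(
            {
                "patient_id": ids[observed],
                "sex": "female",
                "birth_date": pd.Timestamp(1960, 1, 1),
                "claim_type": "outpatient",
                "service_date": a - pd.to_timedelta(gaps[observed], unit="D"),
                "diagnosis_codes": "E11.9",
            }
        )
    )
    claims = pd.concat(frames, ignore_index=True)
    return claims, gaps
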