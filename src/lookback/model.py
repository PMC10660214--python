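"""Model/results objects orchestrating the look-back-period analysis.

:class:`LookbackModel` is built from a cleaned claims stream and a study
design (index year, LP grid, disease code predicate); ``fit()`` runs the
cohort construction, the consistency-examination indexes against the
reference LP, and the retrograde survival/hazard analysis, returning a
:class:`LookbackResults` with the estimates, the per-day curves, and the
combined LP recommendation.

Example
-------
>>> from lookback import LookbackModel, SimulationConfig, simulate_claims
>>> claims, truth = simulate_claims(SimulationConfig(n_patients=500, seed=7))
>>> res = LookbackModel(claims, index_year=2020).fit()
>>> res.recommended_lp_years  # doctest: +SKIP
2.0
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survival as rs
from .claims import DIABETES, CodePredicate, read_claims, ClaimsDialect, DEFAULT_DIALECT
from .cohort import CohortResult, LPGrid, build_cohort, DEFAULT_LP_YEARS
from .concordance import CEIThresholds, cei_table, round_half_up


class LookbackModel:
    """Optimal look-back-period selection on a longitudinal claims stream.

    Parameters
    ----------
    claims
        Cleaned claims in the standard schema (see :mod:`lookback.claims`).
    index_year
        Calendar year whose incident cases are being identified.
    lp_grid
        Candidate LPs; defaults to quarter-year steps over the first year
        then whole years up to 4 (the longest LP is the reference).
    code_predicate
        Disease definition; defaults to diabetes (ICD-10 E10-E14).
    thresholds
        CEI acceptability cut-offs for the recommender.
    horizon_start
        Earliest date available in the database; LPs reaching before it
        raise at fit time.
    """

    def __init__(
        self,
        claims: pd.DataFrame,
        index_year: int,
        lp_grid: LPGrid | None = None,
        code_predicate: CodePredicate = DIABETES,
        thresholds: CEIThresholds | None = None,
        horizon_start: pd.Timestamp | None = None,
    ):
        self.claims = claims
        self.index_year = index_year
        self.grid = lp_grid or LPGrid(index_year=index_year, lp_years=DEFAULT_LP_YEARS)
        if self.grid.index_year != index_year:
            raise ValueError("lp_grid.index_year disagrees with index_year")
        self.code_predicate = code_predicate
        self.thresholds = thresholds or CEIThresholds()
        self.horizon_start = horizon_start

    @classmethod
    def from_csv(
        cls,
        path,
        index_year: int,
        dialect: ClaimsDialect = DEFAULT_DIALECT,
        **kwargs,
    ) -> "LookbackModel":
        claims, rejects = read_claims(path, dialect)
        if len(rejects):
            import logging

            logging.getLogger(__name__).warning(
                "%d rows rejected while reading %s", len(rejects), path
            )
        return cls(claims, index_year=index_year, **kwargs)

    def fit(
        self,
        hazard_threshold: float = rs.DEFAULT_HAZARD_THRESHOLD,
        hazard_window: int = 1,
        min_day: int = 0,
        jump_factor: float = rs.DEFAULT_JUMP_FACTOR,
        s_precision: int = rs.DEFAULT_S_PRECISION,
    ) -> "LookbackResults":
        """Run the full analysis and return the results object."""
        cohort = build_cohort(
            self.claims, self.code_predicate, self.grid, self.horizon_start
        )
        cei = cei_table(cohort, self.grid)

        lp_start, _ = self.grid.lp_window(self.grid.reference_lp)
        observations = rs.build_observations(
            self.claims, self.code_predicate, self.index_year, lp_start,
            pool=set(cohort.prevalent_ids),
        )
        curve = rs.km_curve(observations)
        hazard = rs.hazard_curve(curve, window=hazard_window)
        t_f_hazard = rs.first_hazard_below(hazard, hazard_threshold, min_day)
        freq = rs.s_frequency(curve, s_precision)
        stable = rs.stable_s_day(freq, curve, jump_factor, s_precision)
        stable_s, t_f_freq = stable if stable is not None else (None, None)
        optimal = rs.recommend_lp(
            cei, t_f_hazard, t_f_freq, self.grid, self.thresholds, stable_s=stable_s
        )
        return LookbackResults(
            model=self,
            cohort=cohort,
            cei=cei,
            observations=observations,
            curve=curve,
            hazard=hazard,
            s_freq=freq,
            optimal=optimal,
            fit_params={
                "hazard_threshold": hazard_threshold,
                "hazard_window": hazard_window,
                "min_day": min_day,
                "jump_factor": jump_factor,
                "s_precision": s_precision,
            },
        )


@dataclass
class LookbackResults:
    """Fitted look-back analysis: cohort, CEIs, curves, recommendation."""

    model: LookbackModel
    cohort: CohortResult
    cei: pd.DataFrame
    observations: pd.DataFrame
    curve: pd.DataFrame
    hazard: pd.DataFrame
    s_freq: pd.DataFrame
    optimal: rs.OptimalLPResult
    fit_params: dict = field(default_factory=dict)

    @property
    def recommended_lp_years(self) -> float | None:
        return self.optimal.recommended_lp_years

    @property
    def n_prevalent(self) -> int:
        return len(self.cohort.prevalent_ids)

    def cei_rounded(self, ndigits: int = 3) -> pd.DataFrame:
        """CEI table with proportions rounded half-up for reporting."""
        out = self.cei.copy()
        for col in ("ppv", "kappa", "overestimation"):
            out[col] = out[col].map(lambda x: round_half_up(x, ndigits))
        return out

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels-style."""
        g = self.model.grid
        opt = self.optimal
        lines = [
            "Look-back period analysis",
            "=" * 64,
            f"Index year:            {g.index_year}",
            f"LP grid (years):       {', '.join(str(x) for x in g.lp_years)}"
            f"   (reference: {g.reference_lp})",
            f"Prevalent pool:        {self.n_prevalent}",
            f"Retrograde obs:        {len(self.observations)} "
            f"({int(self.observations['event'].sum())} events, "
            f"{int((~self.observations['event']).sum())} censored)",
            "",
            "Consistency examination indexes (vs reference LP)",
            "-" * 64,
        ]
        table = self.cei_rounded()
        lines.append(f"{'LP (y)':>7} {'incident':>9} {'PPV':>7} {'kappa':>7} {'overest':>8}")
        for _, r in table.iterrows():
            kap = "N/A" if np.isnan(r["kappa"]) else f"{r['kappa']:.3f}"
            lines.append(
                f"{r['lp_years']:>7} {int(r['n_incident']):>9} "
                f"{r['ppv']:>7.3f} {kap:>7} {r['overestimation']:>8.3f}"
            )
        lines += [
            "",
            "Retrograde survival",
            "-" * 64,
            f"Hazard threshold:      {self.fit_params.get('hazard_threshold')}",
            f"t_f (hazard rule):     {opt.t_f_hazard} days"
            if opt.t_f_hazard is not None else "t_f (hazard rule):     not reached",
            f"t_f (frequency rule):  {opt.t_f_freq} days (stable S = {opt.stable_s})"
            if opt.t_f_freq is not None else "t_f (frequency rule):  not found",
            "",
            f"Recommended LP:        "
            + (f"{opt.recommended_lp_years} years"
               if opt.recommended_lp_years is not None
               else f"none ({opt.diagnostics})"),
        ]
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_survival(self, ax=None):
        """Step plot of the retrograde S(t) (Kaplan-Meier estimate)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.curve.index, self.curve["S"], where="post")
        ax.set_xlabel("days before last index-year record")
        ax.set_ylabel("S(t) = P(no prior record within t days)")
        ax.set_ylim(0, 1.02)
        ax.set_title("Retrograde survival")
        return ax

    def plot_hazard(self, ax=None):
        """Daily actuarial hazard with the convergence threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.hazard.index, self.hazard["h"], lw=0.8)
        thr = self.fit_params.get("hazard_threshold", rs.DEFAULT_HAZARD_THRESHOLD)
        ax.axhline(thr, color="red", ls="--", label=f"threshold {thr}")
        if self.optimal.t_f_hazard is not None:
            ax.axvline(self.optimal.t_f_hazard, color="grey", ls=":",
                       label=f"t_f = {self.optimal.t_f_hazard} d")
        ax.set_xlabel("days before last index-year record")
        ax.set_ylabel("h(t)")
        ax.legend()
        ax.set_title("Retrograde actuarial hazard")
        return ax
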