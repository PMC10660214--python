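"""End-to-end pipeline: config, logging, publication-shaped outputs.

``run_pipeline`` executes clean -> code harmonization -> cohort -> CEIs ->
retrograde survival -> recommendation, writing CSV/JSON artifacts and a log
in which every excluded record is accounted for (input = output +
exclusions). All randomness (simulation only) flows from the single config
seed; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .claims import (
    DIABETES,
    CodePredicate,
    clean_claims,
    map_codes,
    read_claims,
    read_code_map,
    summarize_utilization,
    write_claims,
)
from .cohort import DEFAULT_LP_YEARS, LPGrid, stratify_by_age_sex
from .concordance import CEIThresholds
from .model import LookbackModel
from .simulate import SimulationConfig, simulate_claims

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    output_dir: str
    claims_path: str | None = None  # omit to simulate
    code_map_path: str | None = None
    index_year: int = 2020
    lp_years: tuple[float, ...] = DEFAULT_LP_YEARS
    code_prefixes: tuple[str, ...] = ("E10", "E11", "E12", "E13", "E14")
    kappa_min: float = 0.9
    ppv_min: float = 0.90
    overestimation_max: float = 0.10
    hazard_threshold: float = 0.0005
    hazard_window: int = 1
    min_day: int = 0
    jump_factor: float = 2.0
    seed: int = 0
    n_patients: int = 2000
    write_plots: bool = False
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("lp_years", "code_prefixes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, index=kwargs.pop("index", False), float_format="%.6g", **kwargs)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the whole analysis; returns a name -> path map of artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lookback")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}

    try:
        stage = "load"
        if config.claims_path:
            claims, rejects = read_claims(config.claims_path)
            logger.info("read %d claims, %d rejected rows", len(claims), len(rejects))
            if len(rejects):
                _write_csv(rejects, out / "rejects.csv")
                artifacts["rejects"] = out / "rejects.csv"
        else:
            sim_cfg = SimulationConfig(
                n_patients=config.n_patients, seed=config.seed, **config.simulation
            )
            claims, truth = simulate_claims(sim_cfg)
            truth.assign(
                onset_date=truth["onset_date"].dt.strftime("%Y-%m-%d"),
                birth_date=truth["birth_date"].dt.strftime("%Y-%m-%d"),
            ).to_csv(out / "truth.csv", index=False)
            artifacts["truth"] = out / "truth.csv"
            logger.info("simulated %d claims for %d patients",
                        len(claims), sim_cfg.n_patients)

        stage = "clean"
        n_in = len(claims)
        claims, report = clean_claims(claims)
        logger.info(
            "cleaning: %d in, %d removed (missing sex), %d removed "
            "(missing diagnosis), %d out",
            report.n_input, report.n_removed_missing_sex,
            report.n_removed_missing_diagnosis, report.n_output,
        )
        assert report.n_input == n_in

        stage = "map_codes"
        if config.code_map_path:
            code_map = read_code_map(config.code_map_path)
            claims, unmapped = map_codes(claims, code_map)
            logger.info("code harmonization: %d unmapped codes", len(unmapped))
        write_claims(claims, out / "claims_clean.csv")
        artifacts["claims_clean"] = out / "claims_clean.csv"

        stage = "fit"
        predicate = CodePredicate(config.code_prefixes)
        grid = LPGrid(index_year=config.index_year, lp_years=config.lp_years)
        thresholds = CEIThresholds(
            kappa_min=config.kappa_min,
            ppv_min=config.ppv_min,
            overestimation_max=config.overestimation_max,
        )
        model = LookbackModel(
            claims, index_year=config.index_year, lp_grid=grid,
            code_predicate=predicate, thresholds=thresholds,
        )
        results = model.fit(
            hazard_threshold=config.hazard_threshold,
            hazard_window=config.hazard_window,
            min_day=config.min_day,
            jump_factor=config.jump_factor,
        )

        stage = "report"
        years = sorted({d.year for d in claims["service_date"]})
        util = summarize_utilization(claims, years, set(results.cohort.prevalent_ids))
        _write_csv(util, out / "utilization.csv")
        artifacts["utilization"] = out / "utilization.csv"

        _write_csv(results.cei_rounded(), out / "cei.csv")
        artifacts["cei"] = out / "cei.csv"

        for lp, ids in sorted(results.cohort.incident_by_lp.items()):
            p = out / f"incident_lp_{lp}.csv"
            pd.DataFrame({"patient_id": sorted(ids)}).to_csv(p, index=False)
            artifacts[f"incident_lp_{lp}"] = p

        strat_lp = results.recommended_lp_years or model.grid.reference_lp
        strat = stratify_by_age_sex(
            set(results.cohort.incident_by_lp[strat_lp]), claims, config.index_year
        )
        strat.to_csv(out / "incident_by_age_sex.csv")
        artifacts["incident_by_age_sex"] = out / "incident_by_age_sex.csv"

        curve = results.curve.join(results.hazard["h"], how="left")
        _write_csv(curve, out / "survival_curve.csv", index=True)
        artifacts["survival_curve"] = out / "survival_curve.csv"
        _write_csv(results.s_freq, out / "s_frequency.csv")
        artifacts["s_frequency"] = out / "s_frequency.csv"

        opt = results.optimal
        (out / "optimal_lp.json").write_text(
            json.dumps(
                {
                    "t_f_hazard_days": opt.t_f_hazard,
                    "t_f_frequency_days": opt.t_f_freq,
                    "stable_s": opt.stable_s,
                    "recommended_lp_years": opt.recommended_lp_years,
                    "diagnostics": opt.diagnostics,
                },
                indent=2,
            )
            + "\n"
        )
        artifacts["optimal_lp"] = out / "optimal_lp.json"

        (out / "summary.txt").write_text(results.summary() + "\n")
        artifacts["summary"] = out / "summary.txt"

        if config.write_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for name, plot in (
                ("survival", results.plot_survival),
                ("hazard", results.plot_hazard),
            ):
                ax = plot()
                ax.figure.savefig(out / f"{name}.png", dpi=120)
                plt.close(ax.figure)
                artifacts[f"plot_{name}"] = out / f"{name}.png"

        logger.info("pipeline complete; recommended LP: %s years",
                    opt.recommended_lp_years)
        return artifacts
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
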