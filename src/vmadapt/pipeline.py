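"""End-to-end orchestration: cohort -> kinematics -> measures -> statistics.

Stages write plain tab-delimited intermediates so any stage can be
inspected or re-run from the previous stage's output, and a run manifest
records the configuration and master seed; reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import DEFAULT_RSCALE_ANOVA, DEFAULT_RSCALE_T
from .cohort import CohortConfig, default_cohort_config, simulate_cohort
from .kinematics import analyze_trial_log, read_trial_log
from .metrics import epoch_curves, screen_outliers, subject_summary
from .stats import GroupSummary, one_way_anova, tukey_posthoc, two_sample_t

__all__ = ["PipelineConfig", "PipelineResult", "run", "MEASURE_COLUMNS"]

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = {
    "target_error": "target_error_deg",
    "explicit": "explicit_deg",
    "implicit": "implicit_deg",
    "aftereffect": "aftereffect_deg",
    "rt": "rt_rotation_s",
}


@dataclass
class PipelineConfig:
    mode: str = "simulate"                      # simulate | ingest
    out_dir: str | Path | None = None
    input_dir: str | Path | None = None         # ingest mode: directory of trial logs
    experiment_id: str = "exp1"
    n_per_group: int = 10
    seed: int = 0
    render_trajectories: bool = True
    cohort: CohortConfig | None = None          # overrides the preset when given
    measures: tuple[str, ...] = ("target_error", "explicit", "implicit", "aftereffect")
    control_arm: str = "SHAM"
    t_method: str = "student"
    alpha: float = 0.05
    compute_bf: bool = True
    bf_rscale_t: float = DEFAULT_RSCALE_T
    bf_rscale_anova: float = DEFAULT_RSCALE_ANOVA

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and self.input_dir is None:
            raise ValueError("ingest mode requires input_dir")
        unknown = set(self.measures) - set(MEASURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}")


@dataclass
class PipelineResult:
    kinematics: pd.DataFrame
    summaries: pd.DataFrame          # all subjects, pre-screen
    outlier_report: object
    summaries_screened: pd.DataFrame
    anova_table: pd.DataFrame
    pairwise_table: pd.DataFrame
    epoch_table: pd.DataFrame
    manifest: dict


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def _acquire_logs(config: PipelineConfig) -> list[pd.DataFrame]:
    if config.mode == "simulate":
        _stage("simulate cohort")
        cohort = config.cohort or default_cohort_config(
            config.experiment_id,
            n_per_group=config.n_per_group,
            seed=config.seed,
            render_trajectories=config.render_trajectories,
        )
        out = None
        if config.out_dir is not None:
            out = Path(config.out_dir) / "logs"
        result = simulate_cohort(cohort, out_dir=out)
        return [log.trials for log in result.logs]
    _stage("ingest trial logs")
    paths = sorted(
        p for p in Path(config.input_dir).glob("*.tsv")
        if not p.name.endswith(".states.tsv") and p.name != "manifest.tsv"
    )
    if not paths:
        raise FileNotFoundError(f"no trial logs found in {config.input_dir}")
    return [read_trial_log(p) for p in paths]


def run(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and (optionally) write the report bundle."""
    logs = _acquire_logs(config)

    _stage("kinematics")
    kins = [analyze_trial_log(t) for t in logs]
    kinematics = pd.concat(kins, ignore_index=True)
    n_invalid = int((~kinematics["valid"]).sum())
    logger.info("kinematics: %d trials, %d flagged invalid", len(kinematics), n_invalid)

    _stage("subject summaries")
    summaries = pd.DataFrame([subject_summary(t, k) for t, k in zip(logs, kins)])
    epochs = pd.concat(
        [epoch_curves(t, k) for t, k in zip(logs, kins)], ignore_index=True
    )

    _stage("outlier screen")
    report = screen_outliers(summaries)
    screened = summaries[~summaries["subject"].isin(report.excluded_subjects)].reset_index(
        drop=True
    )
    logger.info("outlier screen: %d subjects excluded", len(report.excluded_subjects))

    _stage("group statistics")
    anova_rows, pair_rows = [], []
    arms = list(dict.fromkeys(screened["arm"]))
    for measure in config.measures:
        col = MEASURE_COLUMNS[measure]
        groups = [
            GroupSummary.from_values(
                screened.loc[screened["arm"] == arm, col].dropna(), label=arm
            )
            for arm in arms
        ]
        aov = one_way_anova(groups, compute_bf=config.compute_bf,
                            bf_rscale=config.bf_rscale_anova)
        anova_rows.append(
            {"measure": measure, "F": aov.F, "df_between": aov.df_between,
             "df_within": aov.df_within, "p": aov.p, "eta_p_sq": aov.eta_p_sq,
             "cohens_f": aov.cohens_f, "bf10": aov.bf10,
             "significant": aov.p < config.alpha}
        )
        by = {g.label: g for g in groups}
        for pair in tukey_posthoc(groups, aov.ms_within, aov.df_within):
            pair_rows.append(
                {"measure": measure, "test": "tukey",
                 "pair": f"{pair.label_a}-{pair.label_b}", "statistic": pair.q,
                 "p": pair.p, "cohens_d": pair.cohens_d, "hedges_g": pair.hedges_g}
            )
        if config.control_arm in by:
            for arm in arms:
                if arm == config.control_arm:
                    continue
                tt = two_sample_t(by[arm], by[config.control_arm], method=config.t_method)
                pair_rows.append(
                    {"measure": measure, "test": f"ttest_{config.t_method}",
                     "pair": f"{arm}-{config.control_arm}", "statistic": tt.t,
                     "p": tt.p, "cohens_d": tt.cohens_d, "hedges_g": tt.hedges_g}
                )
    anova_table = pd.DataFrame(anova_rows)
    pairwise_table = pd.DataFrame(pair_rows)

    manifest = {
        "vmadapt_version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "cohort"
        },
        "n_subjects": int(len(summaries)),
        "n_trials": int(len(kinematics)),
        "n_invalid_trials": n_invalid,
        "excluded_subjects": list(report.excluded_subjects),
    }

    if config.out_dir is not None:
        _stage("write report bundle")
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kinematics.to_csv(out / "kinematics.tsv", sep="\t", index=False)
        summaries.to_csv(out / "subject_summaries.tsv", sep="\t", index=False)
        epochs.to_csv(out / "epoch_curves.tsv", sep="\t", index=False)
        report.group_stats.to_csv(out / "outlier_groups.tsv", sep="\t", index=False)
        report.excluded.to_csv(out / "outlier_excluded.tsv", sep="\t", index=False)
        anova_table.to_csv(out / "stats_anova.tsv", sep="\t", index=False)
        pairwise_table.to_csv(out / "stats_pairwise.tsv", sep="\t", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(
        kinematics=kinematics,
        summaries=summaries,
        outlier_report=report,
        summaries_screened=screened,
        anova_table=anova_table,
        pairwise_table=pairwise_table,
        epoch_table=epochs,
        manifest=manifest,
    )
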