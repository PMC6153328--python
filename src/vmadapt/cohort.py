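"""Synthetic cohorts performing the rotation task.

Each simulated subject is a two-process learner: an explicit aiming
strategy updated from target error, plus an implicit state-space process
(retention ``A``, error sensitivity ``B``) driven by the discrepancy
between the aimed direction and the cursor.  Hand angle on a trial is the
sum of the (grid-snapped) aim, the implicit state, and motor noise.  The
generator writes trial logs in the same dialect the analysis pipeline
ingests, with the hidden learner states kept in a sidecar file so the
analysis path can be run blind to them.

The learner is synthetic scaffolding: it supplies the statistical
structure the analysis assumes (additive explicit + implicit components,
heavy-tailed between-subject variability), not a fitted model of any
particular dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .protocol import (
    AIM_SPACING_DEG,
    RING_RADIUS_CM,
    ExperimentDesign,
    build_schedule,
    default_design,
    number_to_hand_angle,
)

__all__ = [
    "LearnerParams",
    "ParamSpec",
    "CohortConfig",
    "SubjectTrialLog",
    "CohortResult",
    "CohortConfigError",
    "default_cohort_config",
    "sample_cohort_params",
    "simulate_subject",
    "render_trajectory",
    "samples_to_string",
    "string_to_samples",
    "simulate_cohort",
]

SAMPLE_DT_S = 0.01  # 100 Hz tablet sampling
_TRAJ_END_CM = 8.0  # rendered reaches overshoot the 7 cm ring


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class LearnerParams:
    """Per-subject learning and execution parameters.

    eta_explicit : strategy update gain on target error, in [0, 1]
    A_implicit   : implicit retention factor, in [0, 1]
    B_implicit   : implicit error sensitivity, in [0, 1]
    sigma_motor  : reach execution noise SD (deg)
    sigma_report : aim-report noise SD (aim-number units, before grid snap)
    explicit_cap_deg : maximum strategy magnitude (deg)
    rt_mean_s, rt_sd_s : reaction-time mean and trial-to-trial SD (s)
    mt_mean_s, mt_sd_s : movement-time mean and trial-to-trial SD (s)
    """

    eta_explicit: float
    A_implicit: float
    B_implicit: float
    sigma_motor: float
    sigma_report: float
    explicit_cap_deg: float = 60.0
    rt_mean_s: float = 1.3
    rt_sd_s: float = 0.25
    mt_mean_s: float = 0.30
    mt_sd_s: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.A_implicit <= 1.0):
            raise CohortConfigError(f"A_implicit must be in [0, 1], got {self.A_implicit}")
        if not (0.0 <= self.B_implicit <= 1.0):
            raise CohortConfigError(f"B_implicit must be in [0, 1], got {self.B_implicit}")
        if self.sigma_motor < 0:
            raise CohortConfigError("sigma_motor must be >= 0")


@dataclass(frozen=True)
class ParamSpec:
    """Normal distribution (clipped to bounds) for one LearnerParams field."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def draw(self, rng: np.random.Generator, scale: float = 1.0) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd * scale), self.lo, self.hi))


@dataclass
class CohortConfig:
    """Per-arm parameter distributions plus cohort-level settings.

    ``arms`` maps arm label -> field name -> ParamSpec.  With probability
    ``outlier_fraction`` a subject's eta_explicit and B_implicit are drawn
    from an inflated-variance component (SD scaled by ``outlier_scale``),
    emulating the few extreme performers seen per group in real cohorts.
    """

    arms: dict[str, dict[str, ParamSpec]]
    group_sizes: dict[str, int]
    experiment_id: str = "exp1"
    outlier_fraction: float = 0.1
    outlier_scale: float = 3.0
    seed: int = 0
    render_trajectories: bool = True
    curvature_noise_deg: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.outlier_fraction <= 0.5):
            raise CohortConfigError("outlier_fraction must be in [0, 0.5]")
        for arm, n in self.group_sizes.items():
            if n < 2:
                raise CohortConfigError(f"group {arm!r}: size must be >= 2, got {n}")
        for arm, specs in self.arms.items():
            for name, spec in specs.items():
                if spec.sd <= 0:
                    raise CohortConfigError(
                        f"arm {arm!r}, parameter {name!r}: SD must be positive"
                    )


@dataclass
class SubjectTrialLog:
    subject: str
    arm: str
    context: str
    trials: pd.DataFrame   # the analysis-facing trial log
    states: pd.DataFrame   # hidden learner states (sidecar; recovery tests only)
    params: LearnerParams


@dataclass
class CohortResult:
    logs: list[SubjectTrialLog]
    manifest: pd.DataFrame
    config: CohortConfig


# Base (SHAM-like) parameter distributions per experiment setup.  The
# horizontal/endpoint setup favors the explicit strategy (fast aim updates,
# low implicit sensitivity); online feedback on a vertical screen shifts
# the balance toward implicit adaptation and slows strategy discovery.
# Context and feedback enter only through these distributions, keeping the
# generator orthogonal to the analysis pipeline.
_BASE_ARMS: dict[str, dict[str, dict]] = {
    "exp1": dict(
        eta_explicit=dict(mean=0.15, sd=0.05, lo=0.0, hi=1.0),
        A_implicit=dict(mean=0.980, sd=0.008, lo=0.80, hi=0.999),
        B_implicit=dict(mean=0.010, sd=0.004, lo=0.0, hi=0.08),
        sigma_motor=dict(mean=3.5, sd=0.8, lo=0.5, hi=10.0),
        sigma_report=dict(mean=1.0, sd=0.3, lo=0.1, hi=4.0),
        explicit_cap_deg=dict(mean=60.0, sd=2.0, lo=45.0, hi=90.0),
        rt_mean_s=dict(mean=1.6, sd=0.35, lo=0.4, hi=3.0),
        rt_sd_s=dict(mean=0.25, sd=0.05, lo=0.02, hi=1.0),
        mt_mean_s=dict(mean=0.30, sd=0.03, lo=0.12, hi=0.39),
        mt_sd_s=dict(mean=0.04, sd=0.01, lo=0.005, hi=0.2),
    ),
    "exp2": dict(
        eta_explicit=dict(mean=0.05, sd=0.025, lo=0.0, hi=1.0),
        A_implicit=dict(mean=0.980, sd=0.008, lo=0.80, hi=0.999),
        B_implicit=dict(mean=0.022, sd=0.007, lo=0.0, hi=0.10),
        sigma_motor=dict(mean=4.0, sd=1.0, lo=0.5, hi=12.0),
        sigma_report=dict(mean=1.2, sd=0.4, lo=0.1, hi=4.0),
        explicit_cap_deg=dict(mean=60.0, sd=2.0, lo=45.0, hi=90.0),
        rt_mean_s=dict(mean=1.2, sd=0.35, lo=0.4, hi=3.0),
        rt_sd_s=dict(mean=0.25, sd=0.05, lo=0.02, hi=1.0),
        mt_mean_s=dict(mean=0.28, sd=0.03, lo=0.12, hi=0.39),
        mt_sd_s=dict(mean=0.04, sd=0.01, lo=0.005, hi=0.2),
    ),
}
_BASE_ARMS["exp3_horizontal"] = dict(_BASE_ARMS["exp1"])

# Arm-specific shifts applied on top of the base distributions: dlPFC
# stimulation nudges the strategy gain, cerebellar stimulation the implicit
# error sensitivity.
_ARM_SHIFTS: dict[str, dict[str, float]] = {
    "SHAM": {},
    "dlPFC": {"eta_explicit": 0.05},
    "CB": {"B_implicit": 0.006},
}


def default_cohort_config(
    experiment_id: str = "exp1",
    n_per_group: int = 10,
    arms: tuple[str, ...] = ("CB", "dlPFC", "SHAM"),
    seed: int = 0,
    outlier_fraction: float = 0.1,
    render_trajectories: bool = True,
) -> CohortConfig:
    """Cohort configuration emulating one of the three experiment setups."""
    if experiment_id not in _BASE_ARMS:
        raise CohortConfigError(f"unknown experiment_id {experiment_id!r}")
    base = _BASE_ARMS[experiment_id]
    arm_specs: dict[str, dict[str, ParamSpec]] = {}
    for arm in arms:
        shifts = _ARM_SHIFTS.get(arm, {})
        specs = {}
        for name, kw in base.items():
            kw = dict(kw)
            kw["mean"] = kw["mean"] + shifts.get(name, 0.0)
            specs[name] = ParamSpec(**kw)
        arm_specs[arm] = specs
    return CohortConfig(
        arms=arm_specs,
        group_sizes={arm: n_per_group for arm in arms},
        experiment_id=experiment_id,
        outlier_fraction=outlier_fraction,
        seed=seed,
        render_trajectories=render_trajectories,
    )


def sample_cohort_params(
    config: CohortConfig, rng: np.random.Generator
) -> list[tuple[str, LearnerParams, bool]]:
    """Draw one parameter set per subject.

    Returns (subject_id, params, from_outlier_component) triples, in a
    fixed arm-then-index order so the draw is reproducible under a fixed
    generator state.
    """
    out = []
    for arm in config.arms:
        specs = config.arms[arm]
        for i in range(config.group_sizes[arm]):
            is_outlier = bool(rng.random() < config.outlier_fraction)
            values = {}
            for name, spec in specs.items():
                scale = (
                    config.outlier_scale
                    if is_outlier and name in ("eta_explicit", "B_implicit")
                    else 1.0
                )
                values[name] = spec.draw(rng, scale=scale)
            out.append((f"{arm}{i + 1:02d}", LearnerParams(**values), is_outlier))
    return out


def _minjerk_fractions() -> tuple[float, float]:
    # movement-profile fractions at which radius crosses 1 and 7 of 8 cm
    s = lambda u: 10 * u**3 - 15 * u**4 + 6 * u**5
    t1 = brentq(lambda u: s(u) - 1.0 / _TRAJ_END_CM, 0.0, 1.0)
    t7 = brentq(lambda u: s(u) - RING_RADIUS_CM / _TRAJ_END_CM, 0.0, 1.0)
    return t1, t7


_TAU_1CM, _TAU_7CM = _minjerk_fractions()


def render_trajectory(
    hand_deg: float,
    rt: float,
    mt: float,
    rng: np.random.Generator | None = None,
    curvature_noise_deg: float = 0.0,
    dt: float = SAMPLE_DT_S,
) -> np.ndarray:
    """Render a 100 Hz reach trajectory at absolute direction ``hand_deg``.

    The radial profile is minimum-jerk from 0 to 8 cm, time-scaled so the
    1 cm radius is crossed at ``rt`` and the 7 cm radius at ``rt + mt``
    (exactly, up to sample discretization).  Curvature noise bends the path
    by a single smooth angular bump of random amplitude (SD
    ``curvature_noise_deg``, clipped to +-2.5 SD), so the 1-to-7 cm chord
    recovers ``hand_deg`` within that bound.

    Returns an (n, 3) array of (t, x, y) with t starting at 0 (target onset).
    """
    if mt <= 0:
        raise ValueError(f"movement time must be positive, got {mt}")
    if rt < 0:
        raise ValueError(f"reaction time must be nonnegative, got {rt}")
    T = mt / (_TAU_7CM - _TAU_1CM)
    t_move = max(0.0, rt - _TAU_1CM * T)  # movement onset
    t_end = t_move + T
    t = np.arange(0.0, t_end + dt / 2, dt)
    tau = np.clip((t - t_move) / T, 0.0, 1.0)
    r = _TRAJ_END_CM * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    if curvature_noise_deg > 0 and rng is not None:
        bend = float(
            np.clip(
                rng.normal(0.0, curvature_noise_deg),
                -2.5 * curvature_noise_deg,
                2.5 * curvature_noise_deg,
            )
        )
    else:
        bend = 0.0
    theta = np.deg2rad(hand_deg + bend * np.sin(np.pi * r / _TRAJ_END_CM))
    return np.column_stack([t, r * np.cos(theta), r * np.sin(theta)])


def samples_to_string(samples: np.ndarray) -> str:
    """Serialize (t, x, y) samples as ``t:x:y|t:x:y|...`` (s, cm, cm)."""
    return "|".join(f"{t:.3f}:{x:.5f}:{y:.5f}" for t, x, y in samples)


def string_to_samples(s: str) -> np.ndarray:
    rows = [triplet.split(":") for triplet in s.split("|")]
    return np.asarray(rows, dtype=float)


def simulate_subject(
    params: LearnerParams,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    subject: str = "S01",
    arm: str = "SHAM",
    context: str = "horizontal",
    render: bool = True,
    curvature_noise_deg: float = 0.2,
) -> SubjectTrialLog:
    """Simulate one subject over a trial schedule.

    Per trial: the aim is the capped explicit state snapped to the 5.625 deg
    number grid (with report noise on reporting trials); hand = aim +
    implicit + motor noise; cursor = hand + rotation.  When visual feedback
    is present the explicit state moves against target error
    (eta_explicit) on reporting trials, and the implicit state updates as
    ``A*implicit - B*(cursor - aim)``.  Without feedback the implicit state
    decays by A and the strategy is frozen.  The strategy is applied only
    while the aiming ring is on screen (reporting blocks); elsewhere the
    subject aims straight at the target.
    """
    n = len(schedule)
    target = schedule["target_deg"].to_numpy(float)
    rotation = schedule["rotation_deg"].to_numpy(float)
    feedback = schedule["feedback"].to_numpy()
    report_flag = schedule["report"].to_numpy(bool)

    x_e = 0.0  # explicit strategy state (deg, CCW positive)
    x_i = 0.0  # implicit adaptation state (deg)
    rec_report = np.full(n, np.nan)
    rec_aim = np.zeros(n)
    rec_hand = np.zeros(n)
    rec_xe = np.zeros(n)
    rec_xi = np.zeros(n)
    rec_rt = np.zeros(n)
    rec_mt = np.zeros(n)
    rec_samples = [""] * n

    for k in range(n):
        rec_xe[k] = x_e
        rec_xi[k] = x_i
        if report_flag[k]:
            strategy = float(np.clip(x_e, -params.explicit_cap_deg, params.explicit_cap_deg))
            num_f = -strategy / AIM_SPACING_DEG
            if params.sigma_report > 0:
                num_f += rng.normal(0.0, params.sigma_report)
            number = int(np.clip(np.rint(num_f), -31, 31))
            aim = float(number_to_hand_angle(number))
            rec_report[k] = number
        else:
            aim = 0.0
        noise = rng.normal(0.0, params.sigma_motor) if params.sigma_motor > 0 else 0.0
        hand = aim + x_i + noise
        cursor = hand + rotation[k]
        err = cursor  # common frame: target at 0
        if feedback[k] != "none":
            if report_flag[k]:
                x_e = x_e - params.eta_explicit * err
            x_i = params.A_implicit * x_i - params.B_implicit * (cursor - aim)
        else:
            x_i = params.A_implicit * x_i
        rec_aim[k] = aim
        rec_hand[k] = hand
        rec_rt[k] = max(0.15, rng.normal(params.rt_mean_s, params.rt_sd_s))
        rec_mt[k] = max(0.05, rng.normal(params.mt_mean_s, params.mt_sd_s))
        if render:
            traj = render_trajectory(
                target[k] + hand,
                rec_rt[k],
                rec_mt[k],
                rng,
                curvature_noise_deg=curvature_noise_deg,
            )
            rec_samples[k] = samples_to_string(traj)

    trials = schedule.copy()
    trials.insert(0, "subject", subject)
    trials.insert(1, "arm", arm)
    trials.insert(2, "context", context)
    trials["report_number"] = rec_report
    if render:
        trials["samples"] = rec_samples
        trials["hand_deg"] = np.nan  # analysis must derive kinematics from samples
        trials["rt_s"] = np.nan
        trials["mt_s"] = np.nan
    else:
        trials["samples"] = ""
        trials["hand_deg"] = rec_hand
        trials["rt_s"] = rec_rt
        trials["mt_s"] = rec_mt
    states = pd.DataFrame(
        {
            "subject": subject,
            "trial_global": schedule["trial_global"].to_numpy(),
            "explicit_state_deg": rec_xe,
            "implicit_state_deg": rec_xi,
            "aim_deg": rec_aim,
            "hand_deg_true": rec_hand,
        }
    )
    return SubjectTrialLog(
        subject=subject, arm=arm, context=context, trials=trials, states=states, params=params
    )


def simulate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Simulate a full cohort; optionally write trial logs and a manifest.

    One trial-log file per subject (plus a hidden-state sidecar) in the
    documented TSV dialect.  Each subject gets an independent child seed
    and an independent target-order schedule, both derived from the master
    seed, so repeated runs are byte-identical.
    """
    from .kinematics import write_trial_log  # deferred: kinematics owns the dialect

    master = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    drawn = sample_cohort_params(config, param_rng)

    logs: list[SubjectTrialLog] = []
    manifest_rows = []
    children = master.spawn(len(drawn) + 1)[1:]
    idx = 0
    for arm in config.arms:
        design = default_design(config.experiment_id, arm=arm)  # type: ignore[arg-type]
        for _ in range(config.group_sizes[arm]):
            subject, params, is_outlier = drawn[idx]
            child = children[idx]
            sched_seed = int(child.generate_state(1)[0] % (2**31))
            schedule = build_schedule(design, seed=sched_seed)
            rng = np.random.default_rng(child)
            log = simulate_subject(
                params,
                schedule,
                rng,
                subject=subject,
                arm=arm,
                context=design.context,
                render=config.render_trajectories,
                curvature_noise_deg=config.curvature_noise_deg,
            )
            logs.append(log)
            row = {
                "subject": subject,
                "arm": arm,
                "context": design.context,
                "experiment_id": config.experiment_id,
                "master_seed": config.seed,
                "schedule_seed": sched_seed,
                "outlier_component": is_outlier,
            }
            row.update({f"true_{k}": v for k, v in dataclasses.asdict(params).items()})
            manifest_rows.append(row)
            idx += 1
    manifest = pd.DataFrame(manifest_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for log in logs:
            write_trial_log(log.trials, out / f"{log.subject}.tsv")
            log.states.to_csv(out / f"{log.subject}.states.tsv", sep="\t", index=False)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return CohortResult(logs=logs, manifest=manifest, config=config)
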