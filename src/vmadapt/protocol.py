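"""Experiment design and trial scheduling for the center-out rotation task.

The task is a center-out reaching paradigm with 8 targets spaced 45 deg
around a 7 cm ring, a 63-number aiming ring at 5.625 deg spacing, and a
seven-block session (16/48/24/24/160/40/40 trials).  A -45 deg (clockwise)
cursor rotation is applied during the rotation block only.  Target order is
pseudorandomized so that every consecutive 8-trial epoch visits each of the
8 target locations exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AIM_SPACING_DEG",
    "N_AIM_NUMBERS",
    "RING_RADIUS_CM",
    "ROTATION_DEG",
    "TARGET_ANGLES_DEG",
    "BlockSpec",
    "ExperimentDesign",
    "ConfigurationError",
    "ScheduleError",
    "default_design",
    "build_schedule",
    "number_to_hand_angle",
    "write_schedule",
]

TARGET_ANGLES_DEG: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, -135.0, -90.0, -45.0)
RING_RADIUS_CM: float = 7.0
N_AIM_NUMBERS: int = 63
AIM_SPACING_DEG: float = 5.625
ROTATION_DEG: float = -45.0  # clockwise cursor rotation during the rotation block

Feedback = Literal["endpoint", "online", "none", "washout"]
Context = Literal["horizontal", "vertical"]
Arm = Literal["CB", "dlPFC", "SHAM"]

EXPERIMENT_IDS = ("exp1", "exp2", "exp3_horizontal")


class ConfigurationError(ValueError):
    """Invalid experiment configuration."""


class ScheduleError(ValueError):
    """Trial schedule cannot be built from the given design."""


@dataclass(frozen=True)
class BlockSpec:
    """One block of the session.

    ``rotation_deg`` follows the convention clockwise-negative, so the
    rotation block carries -45.  ``feedback`` is the cursor feedback mode
    in force during the block; ``report_required`` marks blocks in which
    the aiming ring is shown and a pre-movement aim number is reported.
    """

    name: str
    n_trials: int
    rotation_deg: float = 0.0
    feedback: Feedback = "endpoint"
    report_required: bool = False
    stim_on: bool = False

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_trials % 8 != 0:
            raise ConfigurationError(
                f"block {self.name!r}: n_trials must be a positive multiple of 8, "
                f"got {self.n_trials}"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    blocks: tuple[BlockSpec, ...]
    context: Context = "horizontal"
    arm: Arm = "SHAM"
    target_angles_deg: tuple[float, ...] = TARGET_ANGLES_DEG
    ring_radius_cm: float = RING_RADIUS_CM
    n_aim_numbers: int = N_AIM_NUMBERS
    aim_spacing_deg: float = AIM_SPACING_DEG

    def __post_init__(self) -> None:
        angles = [a % 360.0 for a in self.target_angles_deg]
        if len(set(angles)) != len(angles):
            raise ConfigurationError("target angles must be distinct modulo 360")

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def with_arm(self, arm: Arm) -> "ExperimentDesign":
        return replace(self, arm=arm)


# Session structure shared by all three experiment configurations.  Only the
# cursor feedback mode and screen context differ between experiments.
_BLOCK_TABLE = (
    # name, n_trials, rotated, report, stim
    ("familiarization", 16, False, False, False),
    ("baseline", 48, False, False, False),
    ("baseline_report", 24, False, True, False),
    ("baseline_stim", 24, False, True, True),
    ("rotation", 160, True, True, True),
    ("no_feedback", 40, False, False, False),
    ("washout", 40, False, False, False),
)

_EXPERIMENT_SETUPS: dict[str, tuple[Feedback, Context]] = {
    "exp1": ("endpoint", "horizontal"),
    "exp2": ("online", "vertical"),
    "exp3_horizontal": ("online", "horizontal"),
}


def default_design(experiment_id: str, arm: Arm = "SHAM") -> ExperimentDesign:
    """Return the seven-block design of one of the three experiment setups.

    ``exp1`` uses endpoint feedback on a horizontal screen, ``exp2`` online
    feedback on a vertical screen, and ``exp3_horizontal`` online feedback
    on a horizontal screen.  The -45 deg rotation is applied only in the
    rotation block; aim reporting in blocks 3-5; stimulation in blocks 4-5.
    """
    try:
        feedback, context = _EXPERIMENT_SETUPS[experiment_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown experiment_id {experiment_id!r}; expected one of {EXPERIMENT_IDS}"
        ) from None
    blocks = []
    for name, n, rotated, report, stim in _BLOCK_TABLE:
        if name == "no_feedback":
            fb: Feedback = "none"
        elif name == "washout":
            fb = "washout"
        else:
            fb = feedback
        blocks.append(
            BlockSpec(
                name=name,
                n_trials=n,
                rotation_deg=ROTATION_DEG if rotated else 0.0,
                feedback=fb,
                report_required=report,
                stim_on=stim,
            )
        )
    return ExperimentDesign(blocks=tuple(blocks), context=context, arm=arm)


def build_schedule(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Build a balanced pseudorandom trial schedule.

    Within every block, each consecutive 8-trial epoch contains each of the
    8 targets exactly once; epoch permutations are drawn independently.
    The schedule is a pure function of ``(design, seed)``.

    Returns a DataFrame with columns block, trial_in_block, trial_global,
    target_deg, rotation_deg, feedback, report, stim.
    """
    n_targets = len(design.target_angles_deg)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    g = 0
    for block in design.blocks:
        if block.n_trials % n_targets != 0:
            raise ScheduleError(
                f"block {block.name!r}: {block.n_trials} trials cannot be split "
                f"into epochs of {n_targets}"
            )
        for _ in range(block.n_trials // n_targets):
            for k in rng.permutation(n_targets):
                rows.append(
                    {
                        "block": block.name,
                        "trial_in_block": None,
                        "trial_global": g,
                        "target_deg": design.target_angles_deg[k],
                        "rotation_deg": block.rotation_deg,
                        "feedback": block.feedback,
                        "report": block.report_required,
                        "stim": block.stim_on,
                    }
                )
                g += 1
    sched = pd.DataFrame(rows)
    sched["trial_in_block"] = sched.groupby("block", sort=False).cumcount()
    return sched


def number_to_hand_angle(n: int | np.ndarray) -> float | np.ndarray:
    """Convert an aim-ring number to hand-space compensation in degrees.

    The ring numbers run -31..31 at 5.625 deg spacing.  The sign convention
    is fixed so that reporting -8 corresponds to +45 deg of counterclockwise
    compensation (the aim that lands the cursor on the target under the
    -45 deg clockwise rotation): ``angle = -n * 5.625``.
    """
    arr = np.asarray(n)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValueError("aim number must be an integer")
    if np.any(arr < -31) or np.any(arr > 31):
        raise ValueError(f"aim number out of range [-31, 31]: {n}")
    out = -arr * AIM_SPACING_DEG
    return float(out) if np.isscalar(n) else out


def write_schedule(schedule: pd.DataFrame, path) -> None:
    """Export a schedule as tab-delimited text, one row per trial."""
    schedule.to_csv(path, sep="\t", index=False)
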