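"""Per-subject learning measures and the +-3 SD outlier screen.

Measures follow the standard aiming-report decomposition: hand angles are
averaged over the rotation block after subtracting a baseline bias (mean
of the final 8 trials of the last baseline block); target error is the
normalized rotation-block hand angle minus 45 (full compensation of the
-45 deg cursor rotation gives 0, undershoot is negative); the explicit
component is the mean reported aim converted to degrees; the implicit
component is hand minus aim on the same trials, so explicit + implicit
equals the normalized hand angle exactly on the shared trial set; the
aftereffect is the first-8-trial mean of the no-feedback block minus the
baseline bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import number_to_hand_angle

__all__ = [
    "FULL_COMPENSATION_DEG",
    "OUTLIER_SD_MULTIPLE",
    "OUTLIER_MEASURES",
    "EpochSeries",
    "SubjectSummary",
    "OutlierReport",
    "PipelineError",
    "epochize",
    "baseline_bias",
    "rotation_summary",
    "aftereffect",
    "decompose",
    "subject_summary",
    "summarize_cohort",
    "epoch_curves",
    "screen_outliers",
]

logger = logging.getLogger(__name__)

FULL_COMPENSATION_DEG = 45.0
OUTLIER_SD_MULTIPLE = 3.0
# the three rotation-block measures screened for outliers
OUTLIER_MEASURES = ("target_error_deg", "explicit_deg", "implicit_deg")

EPOCH = 8


class PipelineError(RuntimeError):
    pass


@dataclass
class EpochSeries:
    block: str
    means: np.ndarray        # one mean per 8-trial epoch (NaN if all invalid)
    valid_counts: np.ndarray


@dataclass
class OutlierReport:
    group_stats: pd.DataFrame  # per (arm, measure): n, mean, sd, lo, hi
    excluded: pd.DataFrame     # subject, arm, measure, value
    excluded_subjects: tuple[str, ...]


def epochize(values, valid=None, block: str = "") -> EpochSeries:
    """Means over consecutive 8-trial epochs, omitting invalid trials.

    ``values`` must cover a whole number of epochs; invalid trials reduce
    the averaging count of their epoch (recorded), and an epoch with no
    valid trial is flagged missing (NaN).
    """
    v = np.asarray(values, float)
    if v.size % EPOCH != 0:
        raise ValueError(f"trial count {v.size} is not a multiple of {EPOCH}")
    ok = np.ones(v.size, bool) if valid is None else np.asarray(valid, bool)
    ok = ok & np.isfinite(v)
    v = v.reshape(-1, EPOCH)
    ok = ok.reshape(-1, EPOCH)
    counts = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.where(ok, v, 0.0).sum(axis=1) / counts, np.nan)
    return EpochSeries(block=block, means=means, valid_counts=counts)


def baseline_bias(block4_hand_angles, valid=None) -> float:
    """Mean hand angle over the final 8 valid trials of the last baseline block.

    With fewer than 8 valid trials the mean of whatever is available is
    used (degraded mode, logged).
    """
    v = np.asarray(block4_hand_angles, float)
    ok = np.ones(v.size, bool) if valid is None else np.asarray(valid, bool)
    ok = ok & np.isfinite(v)
    good = v[ok]
    if good.size == 0:
        raise PipelineError("no valid baseline trials to estimate hand bias")
    if good.size < EPOCH:
        logger.warning(
            "baseline bias from only %d valid trials (need %d)", good.size, EPOCH
        )
        return float(good.mean())
    return float(good[-EPOCH:].mean())


def _block(df: pd.DataFrame, name: str) -> pd.DataFrame:
    sub = df[df["block"] == name]
    if sub.empty:
        raise PipelineError(f"block {name!r} missing from trial data")
    return sub.sort_values("trial_global")


def rotation_summary(kin: pd.DataFrame, bias: float) -> tuple[float, float]:
    """(normalized rotation-block hand angle, target error) for one subject.

    ``kin`` is the per-trial kinematics table.  The rotation-block mean is
    over valid trials, minus the baseline bias; target error subtracts the
    full 45 deg compensation (0 = perfect, negative = clockwise undershoot).
    """
    rot = _block(kin, "rotation")
    vals = rot.loc[rot["valid"], "hand_angle_deg"].to_numpy(float)
    if vals.size == 0:
        raise PipelineError("no valid rotation-block trials")
    hand = float(vals.mean()) - bias
    return hand, hand - FULL_COMPENSATION_DEG


def aftereffect(kin: pd.DataFrame, bias: float) -> float:
    """First-8-trial mean of the no-feedback block, baseline-subtracted."""
    nf = _block(kin, "no_feedback")
    first = nf.head(EPOCH)
    vals = first.loc[first["valid"], "hand_angle_deg"].to_numpy(float)
    if vals.size == 0:
        raise PipelineError("no valid trials in the first no-feedback epoch")
    return float(vals.mean()) - bias


def decompose(
    hand_deg: np.ndarray, report_number: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split hand angles into explicit (reported aim) and implicit series.

    explicit_t = aim angle of the reported number; implicit_t = hand_t -
    explicit_t.  Entries with a missing report are NaN in both outputs
    (excluded from summary means, logged by the caller).
    """
    hand = np.asarray(hand_deg, float)
    rep = np.asarray(report_number, float)
    explicit = np.full(hand.shape, np.nan)
    has = np.isfinite(rep)
    explicit[has] = number_to_hand_angle(rep[has].astype(int))
    implicit = hand - explicit
    return explicit, implicit


def subject_summary(trials: pd.DataFrame, kin: pd.DataFrame) -> dict:
    """All per-subject scalars used by the group statistics.

    Explicit/implicit means use only rotation-block trials that have both
    valid kinematics and a recorded report, so the additivity identity
    explicit + implicit = normalized hand angle holds exactly on that set.
    """
    merged = trials.drop(
        columns=[c for c in ("hand_deg", "rt_s", "mt_s", "samples") if c in trials.columns]
    ).merge(
        kin[["trial_global", "hand_angle_deg", "rt_s", "mt_s", "valid"]],
        on="trial_global",
    )
    b4 = _block(merged, "baseline_stim")
    bias = baseline_bias(b4["hand_angle_deg"], b4["valid"])
    hand_mean, target_error = rotation_summary(merged, bias)
    after = aftereffect(merged, bias)

    rot = _block(merged, "rotation")
    usable = rot["valid"] & rot["report_number"].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info(
            "subject %s: %d rotation trials excluded from decomposition "
            "(invalid kinematics or missing report)",
            merged["subject"].iloc[0],
            n_dropped,
        )
    sel = rot[usable]
    hand_norm = sel["hand_angle_deg"].to_numpy(float) - bias
    explicit, implicit = decompose(hand_norm, sel["report_number"].to_numpy(float))
    out = {
        "subject": merged["subject"].iloc[0],
        "arm": merged["arm"].iloc[0],
        "context": merged["context"].iloc[0],
        "baseline_bias_deg": bias,
        "rotation_hand_angle_deg": hand_mean,
        "target_error_deg": target_error,
        "explicit_deg": float(np.nanmean(explicit)) if len(sel) else np.nan,
        "implicit_deg": float(np.nanmean(implicit)) if len(sel) else np.nan,
        "rotation_hand_angle_reported_deg": float(hand_norm.mean()) if len(sel) else np.nan,
        "aftereffect_deg": after,
        "n_decomposed_trials": int(len(sel)),
    }
    for block in merged["block"].unique():
        sub = merged[(merged["block"] == block) & merged["valid"]]
        out[f"rt_{block}_s"] = float(sub["rt_s"].mean()) if len(sub) else np.nan
        out[f"mt_{block}_s"] = float(sub["mt_s"].mean()) if len(sub) else np.nan
    return out


def summarize_cohort(logs, kins) -> pd.DataFrame:
    """Per-subject summary table for a list of (trials, kinematics) pairs."""
    return pd.DataFrame([subject_summary(t, k) for t, k in zip(logs, kins)])


def epoch_curves(trials: pd.DataFrame, kin: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch hand-angle curve for one subject (all blocks, in order)."""
    merged = trials.merge(
        kin[["trial_global", "hand_angle_deg", "valid"]], on="trial_global"
    ).sort_values("trial_global")
    rows = []
    for block in merged["block"].unique():
        sub = merged[merged["block"] == block]
        es = epochize(sub["hand_angle_deg"], sub["valid"], block=block)
        for i, (m, c) in enumerate(zip(es.means, es.valid_counts)):
            rows.append(
                {
                    "subject": merged["subject"].iloc[0],
                    "block": block,
                    "epoch": i,
                    "hand_angle_deg": m,
                    "n_valid": int(c),
                }
            )
    return pd.DataFrame(rows)


def screen_outliers(
    summaries: pd.DataFrame,
    measures: tuple[str, ...] = OUTLIER_MEASURES,
    sd_multiple: float = OUTLIER_SD_MULTIPLE,
) -> OutlierReport:
    """Single-pass per-group +-3 SD screen on the rotation-block measures.

    A subject is excluded iff at least one measure lies strictly outside
    its group's mean +- 3 SD (the bounds themselves are inclusive: values
    exactly at a bound are kept, and an all-identical group excludes
    nobody).  Groups smaller than 3 are skipped with a warning.
    """
    stats_rows = []
    excl_rows = []
    for arm, grp in summaries.groupby("arm"):
        if len(grp) < 3:
            logger.warning("group %s has %d subjects; outlier screen skipped", arm, len(grp))
            continue
        for measure in measures:
            vals = grp[measure].to_numpy(float)
            m, s = float(np.mean(vals)), float(np.std(vals, ddof=1))
            lo, hi = m - sd_multiple * s, m + sd_multiple * s
            stats_rows.append(
                {"arm": arm, "measure": measure, "n": len(grp), "mean": m, "sd": s,
                 "lo": lo, "hi": hi}
            )
            outside = (vals < lo) | (vals > hi)
            for subj, val in zip(grp.loc[outside, "subject"], vals[outside]):
                excl_rows.append({"subject": subj, "arm": arm, "measure": measure, "value": val})
    excluded = pd.DataFrame(excl_rows, columns=["subject", "arm", "measure", "value"])
    return OutlierReport(
        group_stats=pd.DataFrame(
            stats_rows, columns=["arm", "measure", "n", "mean", "sd", "lo", "hi"]
        ),
        excluded=excluded,
        excluded_subjects=tuple(dict.fromkeys(excluded["subject"])),
    )
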