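"""Reach-trajectory kinematics and trial-log I/O.

Hand angle is the direction of the chord between the points where the
trajectory first crosses radii 1 cm and 7 cm from the start, expressed in
a common frame with the target at 0 deg and counterclockwise positive.
Reaction time is target onset to the 1 cm crossing; movement time is the
1 cm to 7 cm traversal; movements longer than 400 ms are flagged too slow.
Radius crossings are linearly interpolated between the two samples
straddling each radius, and the first crossing is used if noise causes
re-entry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import string_to_samples

__all__ = [
    "TOO_SLOW_THRESHOLD_S",
    "REF_RADIUS_NEAR_CM",
    "REF_RADIUS_FAR_CM",
    "IncompleteTrialError",
    "TrialLogFormatError",
    "TrialLogDataError",
    "hand_angle",
    "rt_mt",
    "wrap_angle",
    "analyze_trial_log",
    "read_trial_log",
    "write_trial_log",
]

TOO_SLOW_THRESHOLD_S = 0.400
REF_RADIUS_NEAR_CM = 1.0
REF_RADIUS_FAR_CM = 7.0

REQUIRED_COLUMNS = (
    "subject",
    "arm",
    "context",
    "block",
    "trial_global",
    "target_deg",
    "rotation_deg",
    "feedback",
    "report",
    "report_number",
)


class IncompleteTrialError(ValueError):
    """Trajectory never crosses a required reference radius."""


class TrialLogFormatError(ValueError):
    """Trial-log file does not follow the documented dialect."""


class TrialLogDataError(ValueError):
    """Trial-log contents violate an invariant (e.g. non-monotone time)."""


def wrap_angle(a):
    """Wrap an angle in degrees to (-180, 180]."""
    w = -((-np.asarray(a, float) + 180.0) % 360.0 - 180.0)
    return float(w) if np.isscalar(a) or np.ndim(a) == 0 else w


def _first_crossing(t: np.ndarray, r: np.ndarray, xy: np.ndarray, radius: float):
    """Interpolated (time, point) of the first outward crossing of ``radius``."""
    above = r >= radius
    if not above.any():
        raise IncompleteTrialError(f"trajectory never reaches radius {radius} cm")
    i = int(np.argmax(above))
    if i == 0:
        raise IncompleteTrialError(
            f"trajectory starts beyond radius {radius} cm (no sample inside)"
        )
    f = (radius - r[i - 1]) / (r[i] - r[i - 1])
    return t[i - 1] + f * (t[i] - t[i - 1]), xy[i - 1] + f * (xy[i] - xy[i - 1])


def hand_angle(samples: np.ndarray, target_deg: float) -> float:
    """Hand angle (deg, CCW positive, target at 0) of one trajectory.

    ``samples`` is an (n, 3) array of (t, x, y) in s and cm relative to the
    start-circle center.
    """
    samples = np.asarray(samples, float)
    t, xy = samples[:, 0], samples[:, 1:3]
    r = np.hypot(xy[:, 0], xy[:, 1])
    _, p1 = _first_crossing(t, r, xy, REF_RADIUS_NEAR_CM)
    _, p7 = _first_crossing(t, r, xy, REF_RADIUS_FAR_CM)
    chord = p7 - p1
    ang = np.degrees(np.arctan2(chord[1], chord[0]))
    return wrap_angle(ang - target_deg)


def rt_mt(samples: np.ndarray, target_onset_t: float = 0.0) -> tuple[float, float, bool]:
    """Reaction time, movement time, and the too-slow flag for one trial."""
    samples = np.asarray(samples, float)
    t, xy = samples[:, 0], samples[:, 1:3]
    r = np.hypot(xy[:, 0], xy[:, 1])
    t1, _ = _first_crossing(t, r, xy, REF_RADIUS_NEAR_CM)
    t7, _ = _first_crossing(t, r, xy, REF_RADIUS_FAR_CM)
    rt = t1 - target_onset_t
    mt = t7 - t1
    return rt, mt, mt > TOO_SLOW_THRESHOLD_S


def analyze_trial_log(trials: pd.DataFrame, target_onset_t: float = 0.0) -> pd.DataFrame:
    """Per-trial kinematics table for one trial log.

    Trials with a trajectory get chord hand angle and interpolated RT/MT;
    trials carrying precomputed ``hand_deg``/``rt_s``/``mt_s`` (the
    no-trajectory dialect) are passed through.  Incomplete trials are
    flagged invalid, never silently dropped.

    Returns columns: subject, block, trial_global, hand_angle_deg, rt_s,
    mt_s, too_slow, valid.
    """
    out = []
    for row in trials.itertuples(index=False):
        samples_str = getattr(row, "samples", "") or ""
        rec = {
            "subject": row.subject,
            "block": row.block,
            "trial_global": row.trial_global,
            "hand_angle_deg": np.nan,
            "rt_s": np.nan,
            "mt_s": np.nan,
            "too_slow": False,
            "valid": False,
        }
        if isinstance(samples_str, str) and samples_str:
            try:
                samples = string_to_samples(samples_str)
                rec["hand_angle_deg"] = hand_angle(samples, row.target_deg)
                rt, mt, slow = rt_mt(samples, target_onset_t)
                rec.update(rt_s=rt, mt_s=mt, too_slow=slow, valid=True)
            except IncompleteTrialError:
                pass  # flagged invalid below
        elif pd.notna(getattr(row, "hand_deg", np.nan)):
            mt = float(getattr(row, "mt_s", np.nan))
            rec.update(
                hand_angle_deg=wrap_angle(row.hand_deg),
                rt_s=float(getattr(row, "rt_s", np.nan)),
                mt_s=mt,
                too_slow=bool(mt > TOO_SLOW_THRESHOLD_S) if np.isfinite(mt) else False,
                valid=True,
            )
        out.append(rec)
    return pd.DataFrame(out)


def write_trial_log(trials: pd.DataFrame, path) -> None:
    """Write a trial log as tab-delimited text (the documented dialect)."""
    trials.to_csv(path, sep="\t", index=False)


def read_trial_log(path, validate: bool = True) -> pd.DataFrame:
    """Read a trial log, checking the dialect and per-trial invariants.

    Raises TrialLogFormatError when required columns are missing and
    TrialLogDataError (naming the trial) when a trajectory's timestamps
    are not strictly increasing.
    """
    trials = pd.read_csv(path, sep="\t", keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialLogFormatError(f"{path}: missing required columns {missing}")
    if "samples" in trials.columns:
        trials["samples"] = trials["samples"].fillna("")
    else:
        trials["samples"] = ""
    if validate:
        for row in trials.itertuples():
            s = row.samples
            if isinstance(s, str) and s:
                try:
                    samples = string_to_samples(s)
                except ValueError as exc:
                    raise TrialLogFormatError(
                        f"{path}: malformed samples at line {row.Index + 2}"
                    ) from exc
                if np.any(np.diff(samples[:, 0]) <= 0):
                    raise TrialLogDataError(
                        f"{path}: non-monotone timestamps in trial "
                        f"{row.trial_global} (subject {row.subject})"
                    )
    return trials
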