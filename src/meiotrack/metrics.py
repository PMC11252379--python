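"""Per-track motion descriptors: instant speed, turning angle, outreach ratio.

Definitions
-----------
* instant speed: step length / step time, reported in nm/s;
* turning angle (TA): deflection angle (degrees, [0, 180]) between consecutive
  displacement vectors; 0° means straight-line motion, an excess above 90°
  means frequent backward steps (confined behavior);
* total displacement TD: sum of step lengths (µm);
* maximal distance MD: maximum distance between any two positions of the track;
* outreach ratio OR = (MD / TD) * sqrt(track duration in s), a speed-independent
  measure of how much space a trajectory explores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import TrackFormatError
from .trackio import Track, TrackSet

#: steps shorter than this (µm) are treated as zero-length for turning angles
ZERO_STEP_UM = 1e-9


def instant_speeds(track: Track) -> np.ndarray:
    """Per-step (time, speed) pairs; speed in nm/s, time = step end time.

    Returns an array of shape (n_steps, 2).
    """
    dts = track.dts
    if np.any(dts <= 0):
        raise TrackFormatError(f"track {track.track_id}: zero or negative dt")
    lengths = np.linalg.norm(track.steps, axis=1)  # µm
    speeds = lengths / dts * 1e3  # nm/s
    return np.c_[track.t[1:], speeds]


def turning_angles(track: Track) -> np.ndarray:
    """Deflection angles (degrees in [0, 180]) between consecutive steps.

    Steps shorter than ``ZERO_STEP_UM`` are skipped (the angle is undefined),
    so the result can be shorter than n_steps - 1.
    """
    if track.n_frames < 3:
        return np.empty(0)
    steps = track.steps
    lengths = np.linalg.norm(steps, axis=1)
    angles = []
    prev = None
    for i in range(len(steps)):
        if lengths[i] <= ZERO_STEP_UM:
            continue
        if prev is not None:
            cosang = np.dot(steps[prev], steps[i]) / (lengths[prev] * lengths[i])
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        prev = i
    return np.asarray(angles)


def total_displacement(track: Track) -> float:
    """TD: summed step lengths along the track (µm)."""
    return float(np.linalg.norm(track.steps, axis=1).sum())


def maximal_distance(track: Track) -> float:
    """MD: maximum distance between any two positions along the track (µm)."""
    return float(pdist(track.xyz).max())


def outreach_ratio(track: Track) -> float:
    """OR = (MD / TD) * sqrt(duration).  Fully stationary tracks return 0."""
    td = total_displacement(track)
    if td <= ZERO_STEP_UM:
        warnings.warn(f"track {track.track_id}: stationary track, OR defined as 0")
        return 0.0
    return maximal_distance(track) / td * np.sqrt(track.duration)


def summarize_track(track: Track) -> dict:
    """All MotionSummary fields for one track."""
    sp = instant_speeds(track)[:, 1]
    ta = turning_angles(track)
    td = total_displacement(track)
    return {
        "track_id": track.track_id,
        "anther_id": track.anther_id,
        "cell_id": track.cell_id,
        "compartment": track.compartment,
        "stage": track.stage,
        "n_steps": len(sp),
        # time-weighted mean speed = TD / duration (equals the plain mean of
        # instant speeds under uniform sampling)
        "avg_speed": td / track.duration * 1e3,
        "min_speed": float(sp.min()),
        "max_speed": float(sp.max()),
        "TD": td,
        "MD": maximal_distance(track),
        "outreach_ratio": outreach_ratio(track),
        "frac_ta_gt_90": float(np.mean(ta > 90.0)) if len(ta) else np.nan,
    }


def summarize_motion(ts: TrackSet) -> pd.DataFrame:
    """One MotionSummary row per track (tracks assumed filtered/drift-corrected)."""
    return pd.DataFrame([summarize_track(tr) for tr in ts])


def aggregate_motion(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-(stage, compartment) aggregates: mean ± sd and min–max of avg speed,
    OR and the TA > 90° fraction, plus the track count."""
    g = summary.groupby(["stage", "compartment"])
    out = g.agg(
        n_tracks=("track_id", "size"),
        avg_speed_mean=("avg_speed", "mean"),
        avg_speed_sd=("avg_speed", "std"),
        speed_min=("min_speed", "min"),
        speed_max=("max_speed", "max"),
        outreach_ratio_mean=("outreach_ratio", "mean"),
        outreach_ratio_sd=("outreach_ratio", "std"),
        frac_ta_gt_90=("frac_ta_gt_90", "mean"),
    )
    return out.reset_index()
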