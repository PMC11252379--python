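"""4D track containers, track-table IO, filtering and somatic-reference drift correction.

A :class:`Track` is one centromere's time-ordered 3D trajectory (µm, seconds)
together with its provenance (anther, cell, meiotic/somatic compartment, prophase
stage).  A :class:`TrackSet` groups all tracks of one acquisition, which share a
nominal frame interval and, optionally, the axis-aligned image bounds used for
boundary filtering.

The on-disk format is a plain CSV with columns
``track_id,anther_id,cell_id,compartment,stage,frame,time_s,x_um,y_um,z_um``
and an optional sidecar JSON (``<name>.meta.json``) carrying the acquisition
metadata (``frame_interval_s``, ``image_bounds_um``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DriftReferenceError,
    SchemaError,
    TrackFormatError,
)

logger = logging.getLogger(__name__)

COMPARTMENTS = ("meiotic", "somatic")
STAGES = (
    "leptotene",
    "zygotene",
    "pachytene",
    "diplotene",
    "zygotene_pachytene_like",
    "unknown",
)

#: canonical column order of the track table
TABLE_COLUMNS = (
    "track_id",
    "anther_id",
    "cell_id",
    "compartment",
    "stage",
    "frame",
    "time_s",
    "x_um",
    "y_um",
    "z_um",
)

#: logical field -> default physical column
DEFAULT_SCHEMA = {
    "track_id": "track_id",
    "anther_id": "anther_id",
    "cell_id": "cell_id",
    "compartment": "compartment",
    "stage": "stage",
    "frame": "frame",
    "time": "time_s",
    "x": "x_um",
    "y": "y_um",
    "z": "z_um",
}

_REQUIRED = ("track_id", "time", "x", "y", "z", "compartment", "cell_id", "anther_id")


@dataclass
class Track:
    """One centromere trajectory: strictly increasing times, positions in µm."""

    track_id: str
    t: np.ndarray
    xyz: np.ndarray
    anther_id: str = ""
    cell_id: str = ""
    compartment: str = "meiotic"
    stage: str = "unknown"
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise TrackFormatError(f"track {self.track_id}: xyz must be (n, 3)")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise TrackFormatError(f"track {self.track_id}: t/xyz length mismatch")
        if self.t.shape[0] < 2:
            raise TrackFormatError(
                f"track {self.track_id}: at least 2 frames required to define a step"
            )
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz)):
            raise TrackFormatError(f"track {self.track_id}: non-finite coordinates")
        if np.any(np.diff(self.t) <= 0):
            raise TrackFormatError(
                f"track {self.track_id}: times must be strictly increasing"
            )
        if self.compartment not in COMPARTMENTS:
            raise TrackFormatError(
                f"track {self.track_id}: unknown compartment {self.compartment!r}"
            )
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)
            if self.frames.shape[0] != self.t.shape[0]:
                raise TrackFormatError(f"track {self.track_id}: frames length mismatch")

    # -- derived quantities -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        """Track duration t_last - t_first in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def dts(self) -> np.ndarray:
        """Per-step time increments (s)."""
        return np.diff(self.t)

    @property
    def steps(self) -> np.ndarray:
        """Per-step displacement vectors (µm), shape (n-1, 3)."""
        return np.diff(self.xyz, axis=0)

    def with_frames(self, frame_interval: float, t0: float = 0.0) -> "Track":
        """Return a copy with integer frame indices inferred from times."""
        frames = np.rint((self.t - t0) / frame_interval).astype(int)
        return replace(self, frames=frames)


@dataclass
class TrackSet:
    """All tracks of one acquisition sharing a common time base."""

    tracks: list[Track] = field(default_factory=list)
    frame_interval: float = 1.0
    image_bounds: np.ndarray | None = None  # shape (2, 3): [[lo_xyz], [hi_xyz]]

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.image_bounds is not None:
            self.image_bounds = np.asarray(self.image_bounds, dtype=float)
            if self.image_bounds.shape != (2, 3):
                raise ConfigurationError("image_bounds must have shape (2, 3)")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def select(self, compartment: str | None = None, stage: str | None = None) -> "TrackSet":
        kept = [
            tr
            for tr in self.tracks
            if (compartment is None or tr.compartment == compartment)
            and (stage is None or tr.stage == stage)
        ]
        return TrackSet(kept, self.frame_interval, self.image_bounds)

    @property
    def somatic(self) -> list[Track]:
        return [tr for tr in self.tracks if tr.compartment == "somatic"]

    @property
    def meiotic(self) -> list[Track]:
        return [tr for tr in self.tracks if tr.compartment == "meiotic"]

    def ensure_frames(self) -> "TrackSet":
        """Infer integer frame indices from times where missing.

        All tracks are placed on one global grid anchored at the earliest
        timestamp of the acquisition, with spacing ``frame_interval``.
        """
        t0 = min(tr.t[0] for tr in self.tracks)
        new = [
            tr if tr.frames is not None else tr.with_frames(self.frame_interval, t0)
            for tr in self.tracks
        ]
        return TrackSet(new, self.frame_interval, self.image_bounds)

    def to_dataframe(self) -> pd.DataFrame:
        ts = self.ensure_frames()
        rows = []
        for tr in ts:
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": tr.track_id,
                        "anther_id": tr.anther_id,
                        "cell_id": tr.cell_id,
                        "compartment": tr.compartment,
                        "stage": tr.stage,
                        "frame": tr.frames,
                        "time_s": tr.t,
                        "x_um": tr.xyz[:, 0],
                        "y_um": tr.xyz[:, 1],
                        "z_um": tr.xyz[:, 2],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)[list(TABLE_COLUMNS)]


def _modal_step(times: np.ndarray) -> float:
    """Modal positive time step over an array of per-track time diffs."""
    diffs = times[times > 0]
    if diffs.size == 0:
        return 1.0
    # round to ns resolution so float noise does not fragment the mode
    rounded = np.round(diffs, 9)
    vals, counts = np.unique(rounded, return_counts=True)
    return float(vals[np.argmax(counts)])


def load_tracks(
    path: str | Path,
    schema: dict[str, str] | None = None,
) -> TrackSet:
    """Load a track table CSV into a :class:`TrackSet`.

    Parameters
    ----------
    path : CSV file with one row per (track, frame).
    schema : optional mapping from logical field names
        (``track_id, time, x, y, z, compartment, cell_id, anther_id`` and the
        optional ``frame, stage``) to the actual column names.

    Raises
    ------
    SchemaError : a required column is absent.
    TrackFormatError : duplicate timestamps within a track.
    """
    path = Path(path)
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    for logical in _REQUIRED:
        if cols[logical] not in df.columns:
            raise SchemaError(f"missing column: {logical}")

    meta = _read_sidecar(path)
    tracks: list[Track] = []
    n_dropped = 0
    for tid, sub in df.groupby(cols["track_id"], sort=False):
        sub = sub.sort_values(cols["time"])
        t = sub[cols["time"]].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrackFormatError(f"track {tid}: duplicate or non-increasing timestamps")
        if len(sub) < 2:
            n_dropped += 1
            continue
        xyz = sub[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
        frames = (
            sub[cols["frame"]].to_numpy(dtype=int) if cols["frame"] in sub.columns else None
        )
        stage = (
            str(sub[cols["stage"]].iloc[0]) if cols["stage"] in sub.columns else "unknown"
        )
        tracks.append(
            Track(
                track_id=str(tid),
                t=t,
                xyz=xyz,
                anther_id=str(sub[cols["anther_id"]].iloc[0]),
                cell_id=str(sub[cols["cell_id"]].iloc[0]),
                compartment=str(sub[cols["compartment"]].iloc[0]),
                stage=stage,
                frames=frames,
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} track(s) shorter than 2 frames")
    if not tracks:
        raise TrackFormatError(f"{path}: no usable tracks")

    if meta.get("frame_interval_s"):
        frame_interval = float(meta["frame_interval_s"])
    else:
        all_diffs = np.concatenate([tr.dts for tr in tracks])
        frame_interval = _modal_step(all_diffs)
    bounds = meta.get("image_bounds_um")
    bounds_arr = np.asarray(bounds, dtype=float) if bounds is not None else None
    return TrackSet(tracks, frame_interval=frame_interval, image_bounds=bounds_arr)


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write a :class:`TrackSet` as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    # %.17g keeps doubles bit-exact through the text round-trip
    ts.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "frame_interval_s": ts.frame_interval,
        "image_bounds_um": ts.image_bounds.tolist() if ts.image_bounds is not None else None,
    }
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def filter_tracks(
    ts: TrackSet,
    min_duration: float = 15.0,
    boundary_margin: float = 0.0,
) -> TrackSet:
    """Remove tracks that are too short or that touch the image boundary.

    Tracks with duration < ``min_duration`` seconds are excluded (default 15 s:
    shorter trajectories carry too few steps for meaningful statistics), as are
    tracks with any position closer than ``boundary_margin`` µm to a face of the
    acquisition's image bounds.
    """
    if min_duration < 0:
        raise ConfigurationError("min_duration must be >= 0")
    if boundary_margin > 0 and ts.image_bounds is None:
        raise ConfigurationError(
            "boundary_margin > 0 requires image_bounds on the TrackSet"
        )
    kept: list[Track] = []
    n_short = n_boundary = 0
    for tr in ts:
        if tr.duration < min_duration:
            n_short += 1
            continue
        if boundary_margin > 0:
            lo, hi = ts.image_bounds
            inside = np.all(tr.xyz >= lo + boundary_margin, axis=1) & np.all(
                tr.xyz <= hi - boundary_margin, axis=1
            )
            if not np.all(inside):
                n_boundary += 1
                continue
        kept.append(tr)
    logger.info(
        "filter_tracks: kept %d / %d (removed %d short, %d at boundary)",
        len(kept),
        len(ts),
        n_short,
        n_boundary,
    )
    return TrackSet(kept, ts.frame_interval, ts.image_bounds)


def drift_correct(ts: TrackSet) -> TrackSet:
    """Subtract the average somatic trajectory from every track of the acquisition.

    At each frame transition f-1 -> f, the mean displacement over the somatic
    tracks observed at both frames is taken as the drift increment at f; its
    cumulative sum is subtracted from every track.  Frames where no somatic
    track is observed contribute a zero increment (the drift estimate is
    carried over unchanged).  After correction the mean somatic per-frame
    displacement is the zero vector, which makes the operation idempotent.
    """
    ts = ts.ensure_frames()
    somatic = ts.somatic
    if not somatic:
        raise DriftReferenceError("no drift reference available")

    inc_sum: dict[int, np.ndarray] = {}
    inc_n: dict[int, int] = {}
    for tr in somatic:
        f = tr.frames
        d = tr.steps
        consecutive = np.diff(f) == 1
        for fi, di in zip(f[1:][consecutive], d[consecutive]):
            inc_sum[fi] = inc_sum.get(fi, np.zeros(3)) + di
            inc_n[fi] = inc_n.get(fi, 0) + 1

    fmin = min(int(tr.frames.min()) for tr in ts)
    fmax = max(int(tr.frames.max()) for tr in ts)
    drift = np.zeros((fmax - fmin + 1, 3))
    for f in range(fmin + 1, fmax + 1):
        step = inc_sum[f] / inc_n[f] if f in inc_n else np.zeros(3)
        drift[f - fmin] = drift[f - fmin - 1] + step

    corrected = [
        replace(tr, xyz=tr.xyz - drift[tr.frames - fmin]) for tr in ts
    ]
    return TrackSet(corrected, ts.frame_interval, ts.image_bounds)
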