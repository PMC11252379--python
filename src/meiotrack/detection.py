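"""Spot detection on 3D stacks and frame-to-frame linking into tracks.

Detection finds local maxima of the Gaussian-smoothed volume above an
intensity threshold (non-maximum suppression within a physical separation) and
refines each center to the intensity centroid of its 1 µm neighborhood.

Linking uses greedy mutual-nearest-neighbor assignment between consecutive
frames, gated by a maximum displacement, with the study's merge/split
conventions: when two centromeres meet and become indistinguishable a single
track continues (the other ends); when a signal splits, the original track
continues on the nearer spot and a new track starts at the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import ParameterError
from .simulate import ImageStack
from .trackio import Track, TrackSet


@dataclass
class SpotFrames:
    """Per-frame detections: (time, (n,3) xyz µm positions, intensities)."""

    frames: list[tuple[float, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f, (t, pts, inten) in enumerate(self.frames):
            for (x, y, z), i in zip(pts, inten):
                rows.append(
                    {"frame": f, "time_s": t, "x_um": x, "y_um": y, "z_um": z, "intensity": i}
                )
        return pd.DataFrame(rows, columns=["frame", "time_s", "x_um", "y_um", "z_um", "intensity"])


def spot_frames_from_dataframe(df: pd.DataFrame) -> SpotFrames:
    frames = []
    for f, sub in df.groupby("frame", sort=True):
        frames.append(
            (
                float(sub["time_s"].iloc[0]),
                sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                sub["intensity"].to_numpy(dtype=float)
                if "intensity" in sub.columns
                else np.ones(len(sub)),
            )
        )
    return SpotFrames(frames)


def detect_spots(
    stack: ImageStack,
    smoothing_sigma: float = 0.2,
    min_intensity: float | None = None,
    min_separation: float = 1.0,
    refine_radius: float = 0.5,
) -> SpotFrames:
    """Detect spots in every frame of a stack.

    All physical parameters are µm; the estimated spot diameter (~1 µm)
    motivates the default separation and the centroid-refinement neighborhood.
    ``min_intensity`` defaults to median + 8 robust sd (MAD-based) of each
    smoothed frame, which sits well above smoothed background noise.
    """
    if stack.voxel_size is None:
        raise ParameterError("voxel size missing from stack metadata")
    vz, vy, vx = stack.voxel_size
    sig_vox = (smoothing_sigma / vz, smoothing_sigma / vy, smoothing_sigma / vx)
    min_dist_vox = max(1, int(round(min_separation / min(stack.voxel_size))))
    rad_vox = (
        max(1, int(round(refine_radius / vz))),
        max(1, int(round(refine_radius / vy))),
        max(1, int(round(refine_radius / vx))),
    )

    frames = []
    for ti, vol in enumerate(stack.data):
        sm = ndimage.gaussian_filter(vol.astype(float), sigma=sig_vox)
        if min_intensity is not None:
            thr = min_intensity
        else:
            med = float(np.median(sm))
            mad_sd = float(np.median(np.abs(sm - med))) * 1.4826
            thr = med + 8.0 * max(mad_sd, 1e-6)
        coords = peak_local_max(
            sm, min_distance=min_dist_vox, threshold_abs=thr, exclude_border=False
        )
        pts, inten = [], []
        for zc, yc, xc in coords:
            sl = tuple(
                slice(max(c - r, 0), min(c + r + 1, s))
                for c, r, s in zip((zc, yc, xc), rad_vox, vol.shape)
            )
            patch = sm[sl]
            w = patch - patch.min()
            if w.sum() <= 0:
                zf, yf, xf = float(zc), float(yc), float(xc)
            else:
                idx = np.indices(patch.shape)
                zf = float((idx[0] * w).sum() / w.sum()) + sl[0].start
                yf = float((idx[1] * w).sum() / w.sum()) + sl[1].start
                xf = float((idx[2] * w).sum() / w.sum()) + sl[2].start
            pts.append([xf * vx, yf * vy, zf * vz])
            inten.append(float(sm[zc, yc, xc]))
        pts_arr = np.asarray(pts).reshape(-1, 3)
        frames.append((float(stack.times[ti]), pts_arr, np.asarray(inten)))
    return SpotFrames(frames)


def link_spots(sf: SpotFrames, max_displacement: float = 0.5) -> TrackSet:
    """Link detections across frames into tracks.

    Greedy mutual-nearest-neighbor matching between the active track heads and
    the next frame's spots, gated at ``max_displacement`` µm.  Unmatched spots
    start new tracks (this covers the split convention: the continuing track
    takes the nearer spot, the other spot seeds a new track); tracks losing
    the competition for a shared spot simply end (merge convention).  Ties on
    equal distance resolve to the lower existing track id.
    """
    if max_displacement <= 0:
        raise ParameterError("max_displacement must be > 0")
    if len(sf) == 0:
        raise ParameterError("empty frame sequence")

    tracks: list[dict] = []

    def new_track(t: float, f: int, p: np.ndarray) -> None:
        tracks.append({"t": [t], "f": [f], "xyz": [p.copy()], "active": True})

    t0, pts0, _ = sf.frames[0]
    for p in pts0:
        new_track(t0, 0, p)

    for f in range(1, len(sf)):
        t, pts, _ = sf.frames[f]
        active = [i for i, tr in enumerate(tracks) if tr["active"]]
        n_a, n_s = len(active), len(pts)
        matched_track = {}
        if n_a and n_s:
            heads = np.asarray([tracks[i]["xyz"][-1] for i in active])
            dm = np.linalg.norm(heads[:, None, :] - pts[None, :, :], axis=2)
            unmatched_a = set(range(n_a))
            unmatched_s = set(range(n_s))
            changed = True
            while changed:
                changed = False
                for ai in sorted(unmatched_a):  # ascending order = lower id wins ties
                    cand = [sj for sj in unmatched_s if dm[ai, sj] <= max_displacement]
                    if not cand:
                        continue
                    sj = min(cand, key=lambda s: (dm[ai, s], s))
                    back = [aj for aj in unmatched_a if dm[aj, sj] <= max_displacement]
                    best_back = min(back, key=lambda a_: (dm[a_, sj], a_))
                    if best_back == ai:
                        matched_track[active[ai]] = sj
                        unmatched_a.discard(ai)
                        unmatched_s.discard(sj)
                        changed = True
            for idx, sj in matched_track.items():
                tracks[idx]["t"].append(t)
                tracks[idx]["f"].append(f)
                tracks[idx]["xyz"].append(pts[sj].copy())
            for i in active:
                if i not in matched_track:
                    tracks[i]["active"] = False  # merge: the losing track ends
            for sj in sorted(unmatched_s):
                new_track(t, f, pts[sj])  # new appearance or split product
        else:
            for i in active:
                tracks[i]["active"] = False
            for p in pts:
                new_track(t, f, p)

    out = []
    counter = 0
    for tr in tracks:
        if len(tr["t"]) < 2:
            continue  # single-point tracks carry no step
        out.append(
            Track(
                track_id=f"link_{counter:04d}",
                t=np.asarray(tr["t"]),
                xyz=np.asarray(tr["xyz"]),
                frames=np.asarray(tr["f"]),
                compartment="meiotic",
            )
        )
        counter += 1
    times = [t for t, _, _ in sf.frames]
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    return TrackSet(out, frame_interval=dt)
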