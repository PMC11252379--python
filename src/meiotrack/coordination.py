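"""Between-track coordination within a cell.

Two complementary views of coordinated motion:

* pairwise speed cross-correlation at lag 0, measured with Kendall's tau on
  the temporally aligned instant-speed sequences of two tracks — a rank
  statistic, invariant under monotone rescaling of either sequence;
* the centroid size, the root-mean-squared distance of the co-observed
  centromeres from their mean position at each time step.  Being invariant
  under rigid motion, its temporal variation separates genuine relative
  movement from a shared global motion such as nuclear rotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .metrics import instant_speeds
from .trackio import Track, TrackSet

MIN_COMMON_STEPS = 5


def _aligned_speeds(a: Track, b: Track, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Instant speeds of two tracks at shared step times (|Δt| ≤ tol)."""
    sa, sb = instant_speeds(a), instant_speeds(b)
    ia = 0
    ib = 0
    va, vb = [], []
    while ia < len(sa) and ib < len(sb):
        dt = sa[ia, 0] - sb[ib, 0]
        if abs(dt) <= tol:
            va.append(sa[ia, 1])
            vb.append(sb[ib, 1])
            ia += 1
            ib += 1
        elif dt < 0:
            ia += 1
        else:
            ib += 1
    return np.asarray(va), np.asarray(vb)


def speed_crosscorrelation(
    a: Track, b: Track, tol: float | None = None, frame_interval: float | None = None
) -> tuple[float, int]:
    """Kendall tau of the aligned instant-speed sequences of two tracks.

    Alignment matches step times within ``tol`` (default: frame interval / 10;
    no interpolation).  Raises when fewer than 5 common steps exist.
    """
    if tol is None:
        dt = frame_interval if frame_interval is not None else float(np.median(a.dts))
        tol = dt / 10.0
    va, vb = _aligned_speeds(a, b, tol)
    if len(va) < MIN_COMMON_STEPS:
        raise ParameterError(
            f"only {len(va)} common steps between {a.track_id} and {b.track_id}"
        )
    tau = stats.kendalltau(va, vb).statistic
    return float(tau), int(len(va))


def pairwise_speed_correlations(ts: TrackSet) -> pd.DataFrame:
    """Kendall tau for every within-cell pair of meiotic tracks.

    Pairs with fewer than 5 temporally aligned steps are skipped; the returned
    table records one row per retained pair (cell_id, the two track ids, tau,
    n_common_steps).
    """
    rows = []
    by_cell: dict[str, list[Track]] = {}
    for tr in ts.meiotic:
        by_cell.setdefault(tr.cell_id, []).append(tr)
    for cell_id, tracks in by_cell.items():
        for i in range(len(tracks)):
            for j in range(i + 1, len(tracks)):
                try:
                    tau, n = speed_crosscorrelation(
                        tracks[i], tracks[j], frame_interval=ts.frame_interval
                    )
                except ParameterError:
                    continue
                rows.append(
                    {
                        "cell_id": cell_id,
                        "track_i": tracks[i].track_id,
                        "track_j": tracks[j].track_id,
                        "tau": tau,
                        "n_common_steps": n,
                    }
                )
    return pd.DataFrame(rows, columns=["cell_id", "track_i", "track_j", "tau", "n_common_steps"])


def centroid_size_series(
    tracks: list[Track], frame_interval: float | None = None
) -> pd.DataFrame:
    """Centroid size over time for the centromeres of one cell.

    At each time step with at least two co-observed centromeres, the centroid
    size is the RMS distance of the present positions to their mean; the delta
    series subtracts the value at the first retained step.  Steps with fewer
    than two centromeres are absent from the series.
    """
    if not tracks:
        raise ParameterError("no tracks")
    if frame_interval is None:
        frame_interval = float(np.median(np.concatenate([tr.dts for tr in tracks])))
    tol = frame_interval / 10.0

    all_times = np.concatenate([tr.t for tr in tracks])
    grid = [float(all_times.min())]
    for t in np.sort(all_times):
        if t - grid[-1] > tol:
            grid.append(float(t))

    rows = []
    for t0 in grid:
        present = []
        for tr in tracks:
            idx = np.argmin(np.abs(tr.t - t0))
            if abs(tr.t[idx] - t0) <= tol:
                present.append(tr.xyz[idx])
        if len(present) < 2:
            continue
        pts = np.asarray(present)
        centroid = pts.mean(axis=0)
        size = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
        rows.append({"time_s": t0, "centroid_size": size, "n_present": len(present)})
    if not rows:
        raise ParameterError("no time step with at least 2 co-observed centromeres")
    df = pd.DataFrame(rows)
    df["delta_from_t0"] = df["centroid_size"] - df["centroid_size"].iloc[0]
    return df
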