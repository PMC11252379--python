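"""Mean-squared displacement curves and diffusion-model fits.

The MSD is computed per track as the time average over all overlapping
position pairs at each lag, then optionally averaged across tracks at common
lags (ensemble scope, with the s.e.m. across tracks).  Three motion models are
fitted:

* power law            MSD(τ) = c · τ^α        (α = 1 for pure diffusion)
* Brownian (3D)        MSD(τ) = 6 D τ + offset (the offset absorbs
                       localization noise; D = slope / 6)
* confined diffusion   MSD(t) = R² {1 − a · exp(−b D t / R²)}, whose plateau
                       R² reflects the radius R of the confining domain

The factor 6 is the 3D convention; pass ``dimensionality=2`` to the Brownian
fit for 2D data (slope = 4 D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .errors import ParameterError
from .trackio import Track, TrackSet


@dataclass
class MSDCurve:
    lags: np.ndarray  # s, positive increasing
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # pairs (per_track) or contributing tracks (ensemble)
    sem: np.ndarray | None
    scope: str  # {"per_track", "ensemble"}

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.lags) <= 0) or np.any(self.lags <= 0):
            raise ParameterError("lags must be positive and increasing")


@dataclass
class DiffusionFit:
    model: str  # {"powerlaw", "brownian", "confined"}
    alpha: float | None = None
    D: float | None = None
    R: float | None = None
    a: float | None = None
    b: float | None = None
    rss: float = np.nan
    converged: bool = True


def _track_msd(track: Track, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    xyz = track.xyz
    n = xyz.shape[0]
    msd = np.empty(kmax)
    npairs = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        d = xyz[k:] - xyz[:-k]
        msd[k - 1] = np.mean(np.sum(d * d, axis=1))
        npairs[k - 1] = n - k
    return msd, npairs


def compute_msd(
    tracks: TrackSet | list[Track],
    max_lag: float | None = None,
    scope: str = "ensemble",
    max_lag_fraction: float = 0.25,
) -> MSDCurve:
    """Time-averaged MSD with overlapping window pairs.

    When ``max_lag`` is None it defaults to ``max_lag_fraction`` of the longest
    track duration (long lags are estimated from few pairs and are noisy).
    An explicit ``max_lag`` is honored as given.  Ensemble scope averages the
    per-track curves at common lags and reports the s.e.m. across tracks.
    """
    if isinstance(tracks, TrackSet):
        dt = tracks.frame_interval
        track_list = list(tracks)
    else:
        track_list = list(tracks)
        if not track_list:
            raise ParameterError("no tracks")
        dt = float(np.median(np.concatenate([tr.dts for tr in track_list])))
    if not track_list:
        raise ParameterError("no tracks")
    if max_lag is None:
        max_lag = max_lag_fraction * max(tr.duration for tr in track_list)
    kmax_global = int(np.floor(max_lag / dt + 1e-9))
    if kmax_global < 1:
        raise ParameterError("max_lag shorter than one frame interval")

    per_track = []
    for tr in track_list:
        kmax = min(kmax_global, tr.n_frames - 1)
        if kmax < 1:
            continue
        per_track.append(_track_msd(tr, kmax))
    if not per_track:
        raise ParameterError("no track long enough for the requested lags")

    if scope == "per_track":
        if len(per_track) != 1:
            raise ParameterError("per_track scope expects exactly one track")
        msd, npairs = per_track[0]
        lags = np.arange(1, len(msd) + 1) * dt
        return MSDCurve(lags, msd, npairs, None, "per_track")
    if scope != "ensemble":
        raise ParameterError(f"unknown scope {scope!r}")

    kmax = max(len(m) for m, _ in per_track)
    stack = np.full((len(per_track), kmax), np.nan)
    for i, (m, _) in enumerate(per_track):
        stack[i, : len(m)] = m
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        ntr = np.sum(~np.isnan(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(ntr > 1, sd / np.sqrt(ntr), np.nan)
    lags = np.arange(1, kmax + 1) * dt
    return MSDCurve(lags, mean, ntr, sem, "ensemble")


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

def _fit_range(c: MSDCurve, fit_max_lag: float | None) -> np.ndarray:
    mask = np.ones(len(c.lags), dtype=bool)
    if fit_max_lag is not None:
        mask &= c.lags <= fit_max_lag + 1e-12
    return mask


def fit_powerlaw(c: MSDCurve, fit_max_lag: float | None = None) -> DiffusionFit:
    """Least squares of log(MSD) on log(lag); alpha = 1 signals diffusion."""
    mask = _fit_range(c, fit_max_lag) & (c.msd > 0)
    if mask.sum() < 3:
        raise ParameterError("need at least 3 positive MSD values in the fit range")
    res = stats.linregress(np.log(c.lags[mask]), np.log(c.msd[mask]))
    pred = np.exp(res.intercept) * c.lags[mask] ** res.slope
    rss = float(np.sum((c.msd[mask] - pred) ** 2))
    return DiffusionFit(
        model="powerlaw", alpha=float(res.slope), a=float(np.exp(res.intercept)), rss=rss
    )


def fit_brownian(
    c: MSDCurve, fit_max_lag: float | None = None, dimensionality: int = 3
) -> DiffusionFit:
    """Weighted linear fit MSD = 2 d D τ + offset; D = slope / (2 d), floored at 0."""
    mask = _fit_range(c, fit_max_lag)
    if mask.sum() < 2:
        raise ParameterError("need at least 2 lags in the fit range")
    x, y = c.lags[mask], c.msd[mask]
    if c.sem is not None:
        s = c.sem[mask]
        w = np.where(np.isfinite(s) & (s > 0), 1.0 / s**2, 0.0)
        if not np.any(w > 0):
            w = np.ones_like(x)
    else:
        w = np.ones_like(x)
    sw = np.sqrt(w)
    A = np.c_[x * sw, sw]
    coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    slope, offset = float(coef[0]), float(coef[1])
    rss = float(np.sum(w * (y - slope * x - offset) ** 2))
    factor = 2.0 * dimensionality
    if slope < 0:
        return DiffusionFit(model="brownian", D=0.0, a=offset, rss=rss, converged=False)
    return DiffusionFit(model="brownian", D=slope / factor, a=offset, rss=rss)


def confined_msd(t: np.ndarray, R: float, D: float, a: float, b: float) -> np.ndarray:
    """Closed form of the confined-diffusion model MSD(t) = R²{1 − a e^(−bDt/R²)}."""
    return R**2 * (1.0 - a * np.exp(-b * D * np.asarray(t, dtype=float) / R**2))


def fit_confined(
    c: MSDCurve,
    init: tuple[float, float, float, float] | None = None,
    bounds: tuple | None = None,
    fit_max_lag: float | None = None,
) -> DiffusionFit:
    """Nonlinear least squares of the confined-diffusion model over (R, D, a, b).

    Default initialization: R₀ = sqrt(tail mean), D₀ = early slope / 6, a₀ = 1,
    b₀ = 6.  Bounds keep a in (0, 1.2] so R² keeps its plateau interpretation.
    A fit that pushes R against its upper bound (an essentially unconfined
    curve) is flagged ``converged=False``.
    """
    mask = _fit_range(c, fit_max_lag)
    lags, msd = c.lags[mask], c.msd[mask]
    if len(lags) < 10:
        warnings.warn("fewer than 10 lags for the confined fit; result may be unstable")
    n_tail = max(len(msd) // 4, 1)
    R0 = float(np.sqrt(max(np.mean(msd[-n_tail:]), 1e-9)))
    n_head = min(3, len(msd))
    slope0 = float(np.polyfit(lags[:n_head], msd[:n_head], 1)[0]) if n_head >= 2 else 0.0
    D0 = max(slope0 / 6.0, 1e-6)
    p0 = init if init is not None else (R0, D0, 1.0, 6.0)
    R_hi = 10.0 * float(np.sqrt(max(msd.max(), 1e-9)))
    lo = (1e-3, 1e-9, 1e-3, 1e-3)
    hi = (R_hi, 10.0, 1.2, 1e3)
    if bounds is not None:
        lo, hi = bounds
    p0 = tuple(np.clip(p0, lo, hi))
    try:
        popt, _ = optimize.curve_fit(
            confined_msd, lags, msd, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        ok = True
    except RuntimeError:
        popt, ok = np.asarray(p0), False
    R, D, a, b = (float(v) for v in popt)
    rss = float(np.sum((msd - confined_msd(lags, R, D, a, b)) ** 2))
    if R >= 0.99 * hi[0]:
        ok = False  # effectively unconfined
    return DiffusionFit(model="confined", D=D, R=R, a=a, b=b, rss=rss, converged=ok)


def estimate_plateau_period(
    c: MSDCurve, plateau_start: float, band_sigma: float = 2.0
) -> float | None:
    """Dominant oscillation period of the MSD plateau, or None.

    The plateau segment (lags ≥ ``plateau_start``) is detrended with a cubic
    polynomial (the slow approach to the plateau is smooth, the oscillation is
    not) and its autocorrelation computed; the first local maximum above the
    white-noise band ``band_sigma / sqrt(n)`` gives the period.  Returns None
    when no peak clears the band or the segment is shorter than two putative
    periods.
    """
    mask = c.lags >= plateau_start
    lags, y = c.lags[mask], c.msd[mask]
    n = len(y)
    if n < 8:
        warnings.warn("plateau segment too short for period estimation")
        return None
    dlag = float(np.median(np.diff(lags)))
    y = y - np.polyval(np.polyfit(lags, y, min(3, n - 2)), lags)
    sd = y.std()
    if sd < 1e-15:
        return None
    y = y / sd
    acf = np.correlate(y, y, mode="full")[n - 1 :] / n
    peaks, _ = signal.find_peaks(acf[1:])
    band = band_sigma / np.sqrt(n)
    for p in peaks:
        k = p + 1
        if acf[k] > band:
            period = k * dlag
            if 2 * period > (lags[-1] - lags[0]) + dlag:
                warnings.warn("plateau shorter than two putative periods")
                return None
            return float(period)
    return None
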