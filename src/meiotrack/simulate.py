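"""Synthetic data generators emulating the statistical structure of the study data.

Three generators are provided:

* :func:`simulate_tracks` — single-cell trajectories under five motion models
  (free Brownian, confined Brownian with reflection at a sphere, fixed-speed
  random walk, stationary jitter, directed motion);
* :func:`simulate_anther` — a nested anther > cell > track hierarchy with
  log-normal multiplicative speed factors at each level, low-mobility somatic
  reference tracks and a rigid sample drift shared within each anther;
* :func:`simulate_nucleus_configuration` — wild-type and *sun1 sun2*-like
  3D telomere / nucleolus arrangements on an idealized nuclear envelope;
* :func:`render_spot_stack` — 3D image stacks with Gaussian spots over Poisson
  background, for exercising the detection/linking stage.

The module also collects the study's measured constants (per-stage speeds and
apparent diffusion coefficients, the confinement radius, nuclear geometry),
which serve as generator defaults so simulations reproduce the reported
motion regimes.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .nucleus import NucleusGeometry, Sphere, TelomereSet
from .trackio import Track, TrackSet

# ---------------------------------------------------------------------------
# study constants (units in names)
# ---------------------------------------------------------------------------

#: average centromere speed by stage, nm/s
STAGE_SPEED_NM_S = {
    "leptotene": 55.0,
    "zygotene": 106.0,
    "pachytene": 100.0,
    "diplotene": 62.0,
    "somatic": 40.0,
    "sun1sun2": 54.0,
}

#: apparent diffusion coefficient by stage, µm²/s
STAGE_D_UM2_S = {
    "leptotene": 0.002,
    "zygotene": 0.045,
    "pachytene": 0.016,
    "diplotene": 0.002,
    "sun1sun2": 0.002,
}

#: somatic baseline, inside the measured 3.0e-4 – 6.2e-4 µm²/s range
SOMATIC_D_UM2_S = 5.0e-4

#: confinement-domain radius from the confined-diffusion fit, µm
CONFINEMENT_RADIUS_UM = 4.01

#: period of the MSD plateau oscillation, s
MSD_OSCILLATION_PERIOD_S = 150.0

#: nuclear geometry: zygotene/pachytene nucleus diameter 8.8 µm
NUCLEUS_RADIUS_UM = 4.4
NUCLEOLUS_RADIUS_UM = 2.25

#: default frame interval, s
DEFAULT_DT_S = 2.4

#: average bouquet size by stage (non-NOR ends in the cluster)
BOUQUET_SIZE_PER_STAGE = {"wt_zygotene": 10, "wt_pachytene": 9, "wt_diplotene": 8}

#: periphery-attachment fraction of detected ends (wild type Z+P vs sun1 sun2)
WT_PERIPHERY_FRACTION = 0.93
SUN1SUN2_PERIPHERY_FRACTION = 0.40
SUN1SUN2_INTERNAL_NUCLEOLUS_P = 0.5


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

MOTION_MODELS = ("brownian", "confined", "fixed_speed", "stationary_jitter", "directed")


@dataclass
class MotionModelConfig:
    """Parameters of one single-compartment motion model.

    Units: D in µm²/s, R_confine in µm, speed in nm/s, jitter_sd in µm, dt in s.
    """

    model: str = "brownian"
    D: float = STAGE_D_UM2_S["zygotene"]
    R_confine: float = CONFINEMENT_RADIUS_UM
    speed: float = STAGE_SPEED_NM_S["zygotene"]
    jitter_sd: float = 0.05
    velocity: tuple[float, float, float] = (0.1, 0.0, 0.0)
    n_tracks: int = 10
    n_steps: int = 50
    dt: float = DEFAULT_DT_S
    seed: int = 0
    stage: str = "unknown"
    compartment: str = "meiotic"
    oscillation_amplitude: float = 0.0  # µm, optional radial modulation (confined)
    oscillation_period: float = MSD_OSCILLATION_PERIOD_S

    def validate(self) -> None:
        if self.model not in MOTION_MODELS:
            raise ParameterError(f"unknown motion model {self.model!r}")
        if self.dt <= 0 or self.n_steps < 1 or self.n_tracks < 1:
            raise ParameterError("dt, n_steps and n_tracks must be positive")
        if self.model in ("brownian", "confined") and self.D <= 0:
            raise ParameterError("D must be > 0")
        if self.model == "confined" and self.R_confine <= 0:
            raise ParameterError("R_confine must be > 0")
        if self.model in ("fixed_speed", "directed") and self.speed <= 0:
            raise ParameterError("speed must be > 0")
        if self.model == "stationary_jitter" and self.jitter_sd <= 0:
            raise ParameterError("jitter_sd must be > 0")


@dataclass
class HierarchyConfig:
    """Nested anther > cell > track design with multiplicative speed factors."""

    n_anthers: int = 5
    cells_per_anther: int = 3
    tracks_per_cell: int = 3
    anther_speed_sd: float = 0.2  # log-scale sd of the anther factor
    cell_speed_sd: float = 0.1  # log-scale sd of the cell factor
    base: MotionModelConfig = field(default_factory=MotionModelConfig)
    drift_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)  # µm/s
    n_somatic_per_anther: int = 3
    somatic_D: float = SOMATIC_D_UM2_S
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_anthers, self.cells_per_anther, self.tracks_per_cell) < 1:
            raise ParameterError("counts must be >= 1")
        if self.anther_speed_sd < 0 or self.cell_speed_sd < 0:
            raise ParameterError("speed sds must be >= 0")
        self.base.validate()


NUCLEUS_KINDS = ("wt_zygotene", "wt_pachytene", "wt_diplotene", "sun1sun2_like")


@dataclass
class NucleusConfig:
    """Configuration of one simulated nucleus (telomeres + geometry)."""

    kind: str = "wt_zygotene"
    nucleus_radius: float = NUCLEUS_RADIUS_UM
    nucleolus_radius: float = NUCLEOLUS_RADIUS_UM
    n_telomeres: int = 20
    n_nor_ends: int = 4
    n_in_cluster: int | None = None  # default: stage average
    cluster_cap_geodesic_radius: float = 1.0  # µm
    periphery_fraction_target: float | None = None
    nucleolus_internal_probability: float | None = None
    surface_jitter_sd: float = 0.1  # µm, radial placement noise at the envelope
    min_separation: float = 5.0  # µm, between non-clustered peripheral ends
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in NUCLEUS_KINDS:
            raise ParameterError(f"unknown nucleus kind {self.kind!r}")
        if self.n_nor_ends > self.n_telomeres:
            raise ParameterError("n_nor_ends cannot exceed n_telomeres")
        if self.nucleolus_radius >= self.nucleus_radius:
            raise ParameterError("nucleolus must fit inside the nucleus")
        n_non_nor = self.n_telomeres - self.n_nor_ends
        if self.n_in_cluster is not None and self.n_in_cluster > n_non_nor:
            raise ParameterError("cluster size exceeds available non-NOR ends")
        for frac in (self.periphery_fraction_target, self.nucleolus_internal_probability):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ParameterError("fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# trajectory generators
# ---------------------------------------------------------------------------

def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    d = _uniform_directions(rng, n)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return d * r[:, None]


def _reflect_into_sphere(p: np.ndarray, radius: float) -> np.ndarray:
    """Radial mirror reflection of an out-of-bounds excess back into the sphere."""
    r = np.linalg.norm(p)
    while r > radius:
        p = p * (2.0 * radius - r) / r
        r = abs(2.0 * radius - r)
    return p


def _one_track(cfg: MotionModelConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_steps
    if cfg.model == "brownian":
        sigma = np.sqrt(2.0 * cfg.D * cfg.dt)
        steps = rng.normal(scale=sigma, size=(n, 3))
        return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    if cfg.model == "confined":
        sigma = np.sqrt(2.0 * cfg.D * cfg.dt)
        pos = np.empty((n + 1, 3))
        pos[0] = _uniform_in_ball(rng, 1, cfg.R_confine)[0]
        for i in range(n):
            prop = pos[i] + rng.normal(scale=sigma, size=3)
            if cfg.oscillation_amplitude > 0:
                # optional slow radial breathing of the confining domain
                phase = 2 * np.pi * (i + 1) * cfg.dt / cfg.oscillation_period
                prop = prop * (1 + cfg.oscillation_amplitude / cfg.R_confine * np.sin(phase))
            pos[i + 1] = _reflect_into_sphere(prop, cfg.R_confine)
        return pos
    if cfg.model == "fixed_speed":
        mag = cfg.speed * 1e-3 * cfg.dt  # nm/s -> µm per step
        steps = _uniform_directions(rng, n) * mag
        return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    if cfg.model == "stationary_jitter":
        return rng.normal(scale=cfg.jitter_sd, size=(n + 1, 3))
    if cfg.model == "directed":
        v = np.asarray(cfg.velocity, dtype=float)
        t = np.arange(n + 1)[:, None] * cfg.dt
        jitter = (
            rng.normal(scale=cfg.jitter_sd, size=(n + 1, 3)) if cfg.jitter_sd > 0 else 0.0
        )
        return t * v + jitter
    raise ParameterError(f"unknown motion model {cfg.model!r}")


def simulate_tracks(cfg: MotionModelConfig) -> TrackSet:
    """Generate ``cfg.n_tracks`` independent trajectories under one motion model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tracks = []
    t = np.arange(cfg.n_steps + 1) * cfg.dt
    frames = np.arange(cfg.n_steps + 1)
    for i in range(cfg.n_tracks):
        xyz = _one_track(cfg, rng)
        tracks.append(
            Track(
                track_id=f"sim_{i:04d}",
                t=t.copy(),
                xyz=xyz,
                anther_id="sim",
                cell_id="sim",
                compartment=cfg.compartment,
                stage=cfg.stage,
                frames=frames.copy(),
            )
        )
    return TrackSet(tracks, frame_interval=cfg.dt)


def _scaled(cfg: MotionModelConfig, factor: float) -> MotionModelConfig:
    """Scale a motion model's characteristic speed by a multiplicative factor.

    Speed-like parameters scale linearly; diffusion coefficients scale as the
    square (step length ~ sqrt(D)).
    """
    return replace(
        cfg,
        D=cfg.D * factor**2,
        speed=cfg.speed * factor,
        jitter_sd=cfg.jitter_sd * factor,
        velocity=tuple(v * factor for v in cfg.velocity),
    )


def simulate_anther(cfg: HierarchyConfig) -> TrackSet:
    """Generate a nested anther > cell > track hierarchy.

    Each anther draws a log-normal multiplicative speed factor (log-scale sd
    ``anther_speed_sd``), each cell a nested factor likewise; meiotic tracks
    come from the scaled base model.  ``n_somatic_per_anther`` low-mobility
    Brownian somatic tracks are added per anther, and the rigid
    ``drift_velocity`` is applied to every track of the anther.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.base.dt
    n_steps = cfg.base.n_steps
    t = np.arange(n_steps + 1) * dt
    frames = np.arange(n_steps + 1)
    drift = np.asarray(cfg.drift_velocity, dtype=float) * t[:, None]

    tracks: list[Track] = []
    for a in range(cfg.n_anthers):
        aid = f"anther_{a}"
        fa = float(np.exp(rng.normal(0.0, cfg.anther_speed_sd))) if cfg.anther_speed_sd else 1.0
        for c in range(cfg.cells_per_anther):
            cid = f"{aid}_cell_{c}"
            fc = float(np.exp(rng.normal(0.0, cfg.cell_speed_sd))) if cfg.cell_speed_sd else 1.0
            model = _scaled(cfg.base, fa * fc)
            for k in range(cfg.tracks_per_cell):
                xyz = _one_track(model, rng) + drift
                tracks.append(
                    Track(
                        track_id=f"{cid}_trk_{k}",
                        t=t.copy(),
                        xyz=xyz,
                        anther_id=aid,
                        cell_id=cid,
                        compartment="meiotic",
                        stage=cfg.base.stage,
                        frames=frames.copy(),
                    )
                )
        somatic_model = replace(
            cfg.base, model="brownian", D=cfg.somatic_D, compartment="somatic"
        )
        for k in range(cfg.n_somatic_per_anther):
            xyz = _one_track(somatic_model, rng) + drift
            tracks.append(
                Track(
                    track_id=f"{aid}_soma_trk_{k}",
                    t=t.copy(),
                    xyz=xyz,
                    anther_id=aid,
                    cell_id=f"{aid}_soma",
                    compartment="somatic",
                    stage="unknown",
                    frames=frames.copy(),
                )
            )
    return TrackSet(tracks, frame_interval=dt)


# ---------------------------------------------------------------------------
# nucleus configurations
# ---------------------------------------------------------------------------

def _cap_points(
    rng: np.random.Generator, n: int, center_dir: np.ndarray, radius: float, cap_geodesic: float
) -> np.ndarray:
    """Uniform points within a spherical cap of geodesic radius around a direction."""
    theta_max = cap_geodesic / radius
    # uniform over the cap: cos(theta) uniform on [cos(theta_max), 1]
    cost = 1.0 - rng.random(n) * (1.0 - np.cos(theta_max))
    sint = np.sqrt(1.0 - cost**2)
    phi = rng.random(n) * 2 * np.pi
    local = np.c_[sint * np.cos(phi), sint * np.sin(phi), cost]
    # rotate +z onto center_dir
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, center_dir)
    s = np.linalg.norm(v)
    if s < 1e-12:
        R = np.eye(3) if center_dir[2] > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        c = float(np.dot(z, center_dir))
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return (local @ R.T) * radius


def _spread_on_sphere(
    rng: np.random.Generator,
    n: int,
    radius: float,
    min_sep: float,
    avoid: np.ndarray | None = None,
    avoid_sep: float | None = None,
    n_candidates: int = 400,
) -> np.ndarray:
    """Well-separated random points on a sphere by best-candidate sampling.

    Each point is chosen among ``n_candidates`` uniform proposals as the one
    farthest from everything already placed (and from the ``avoid`` set,
    down-weighted by ``avoid_sep / min_sep``), which approaches the optimal
    packing; ``min_sep`` is therefore met whenever it is geometrically
    feasible.
    """
    if n == 0:
        return np.empty((0, 3))
    a_w = (avoid_sep / min_sep) if (avoid_sep and min_sep) else 1.0
    pts: list[np.ndarray] = []
    for _ in range(n):
        cands = _uniform_directions(rng, n_candidates) * radius
        score = np.full(n_candidates, np.inf)
        if pts:
            d = np.linalg.norm(cands[:, None, :] - np.asarray(pts)[None, :, :], axis=2)
            score = np.minimum(score, d.min(axis=1))
        if avoid is not None and len(avoid):
            d = np.linalg.norm(cands[:, None, :] - avoid[None, :, :], axis=2)
            score = np.minimum(score, d.min(axis=1) / a_w)
        if not pts and (avoid is None or not len(avoid)):
            pts.append(cands[0])
        else:
            pts.append(cands[int(np.argmax(score))])
    return np.array(pts)


def simulate_nucleus_configuration(cfg: NucleusConfig) -> tuple[NucleusGeometry, TelomereSet]:
    """Generate one nucleus: envelope/nucleolus spheres plus labeled telomeres.

    Wild-type kinds place the non-NOR ends at the envelope with a cluster of
    ``n_in_cluster`` ends inside a spherical cap (the bouquet) and a
    peripherally tangent nucleolus; ``sun1sun2_like`` draws peripheral
    attachment per end to hit ``periphery_fraction_target`` in expectation,
    parks detached ends near the nucleolus, and makes the nucleolus internal
    with probability ``nucleolus_internal_probability``.  NOR ends sit at the
    nucleolus/envelope interface (wild type) or at the nucleolus (mutant).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.nucleus_radius
    rn = cfg.nucleolus_radius
    n_non_nor = cfg.n_telomeres - cfg.n_nor_ends
    jitter = cfg.surface_jitter_sd

    def at_radius(dirs: np.ndarray, radius: float) -> np.ndarray:
        radial = radius + rng.normal(0.0, jitter, size=dirs.shape[0])
        radial = np.clip(radial, 0.0, R)
        units = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        return units * radial[:, None]

    if cfg.kind.startswith("wt"):
        genotype, stage = "wt", cfg.kind.split("_", 1)[1]
        k = cfg.n_in_cluster
        if k is None:
            k = BOUQUET_SIZE_PER_STAGE[cfg.kind]
        if k > n_non_nor:
            raise ParameterError("cluster size exceeds available non-NOR ends")
        nucleolus_dir = _uniform_directions(rng, 1)[0]
        nucleolus_center = nucleolus_dir * (R - rn)  # tangent to the envelope
        cap_dir = -nucleolus_dir  # bouquet opposite the nucleolus
        cap = _cap_points(rng, k, cap_dir, R, cfg.cluster_cap_geodesic_radius)
        cap = at_radius(cap, R)
        spread = _spread_on_sphere(
            rng, n_non_nor - k, R, cfg.min_separation, avoid=cap, avoid_sep=cfg.min_separation
        )
        spread = at_radius(spread, R)
        target = (
            cfg.periphery_fraction_target
            if cfg.periphery_fraction_target is not None
            else WT_PERIPHERY_FRACTION
        )
        if len(spread):
            # cluster ends are always peripheral; detach the remainder so the
            # overall expectation hits the target
            p_keep = np.clip((target * n_non_nor - k) / len(spread), 0.0, 1.0)
            detach = rng.random(len(spread)) >= p_keep
            for i in np.flatnonzero(detach):
                u = spread[i] / np.linalg.norm(spread[i])
                spread[i] = u * rng.uniform(0.3 * R, 0.7 * R)
        nor = at_radius(
            _cap_points(rng, cfg.n_nor_ends, nucleolus_dir, R, 1.5) if cfg.n_nor_ends else
            np.empty((0, 3)),
            R,
        ) if cfg.n_nor_ends else np.empty((0, 3))
        points = np.vstack([cap, spread, nor])
    else:
        genotype, stage = "sun1sun2", "zygotene_pachytene_like"
        p_per = (
            cfg.periphery_fraction_target
            if cfg.periphery_fraction_target is not None
            else SUN1SUN2_PERIPHERY_FRACTION
        )
        p_int = (
            cfg.nucleolus_internal_probability
            if cfg.nucleolus_internal_probability is not None
            else SUN1SUN2_INTERNAL_NUCLEOLUS_P
        )
        internal = rng.random() < p_int
        if internal:
            nucleolus_center = np.zeros(3)
        else:
            nucleolus_center = _uniform_directions(rng, 1)[0] * (R - rn)
        attached = rng.random(n_non_nor) < p_per
        n_att = int(attached.sum())
        pts = np.empty((n_non_nor, 3))
        if n_att:
            pts[attached] = at_radius(
                _spread_on_sphere(rng, n_att, R, min_sep=1.0), R
            )
        def clamp_interior(p: np.ndarray, margin: float = 1.0) -> np.ndarray:
            # keep detached ends clearly in the nucleoplasm, away from the envelope
            norms = np.linalg.norm(p, axis=1)
            deep = norms > R - margin
            p[deep] = p[deep] / norms[deep, None] * (R - margin)
            return p

        n_det = n_non_nor - n_att
        if n_det:
            # detached ends cluster near the nucleolus surface
            dirs = _uniform_directions(rng, n_det)
            det = nucleolus_center + dirs * (rn + np.abs(rng.normal(0, 0.3, n_det)))[:, None]
            pts[~attached] = clamp_interior(det)
        nor_dirs = _uniform_directions(rng, cfg.n_nor_ends)
        nor = (
            clamp_interior(nucleolus_center + nor_dirs * rn)
            if cfg.n_nor_ends
            else np.empty((0, 3))
        )
        points = np.vstack([pts, nor])

    nor_flag = np.zeros(cfg.n_telomeres, dtype=bool)
    nor_flag[n_non_nor:] = True
    geometry = NucleusGeometry(
        periphery=Sphere(np.zeros(3), R),
        nucleolus=Sphere(nucleolus_center, rn),
        stage=stage,
        genotype=genotype,
    )
    return geometry, TelomereSet(points=points, nor_flag=nor_flag)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A time series of 3D volumes with physical voxel size (µm, z/y/x order)."""

    data: np.ndarray  # (T, Z, Y, X)
    voxel_size: tuple[float, float, float]  # µm per voxel, (z, y, x)
    times: np.ndarray  # (T,) seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ParameterError("ImageStack data must be (T, Z, Y, X)")
        self.times = np.asarray(self.times, dtype=float)


def render_spot_stack(
    positions: Sequence[np.ndarray],
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.25),
    shape: tuple[int, int, int] = (32, 48, 48),
    psf_sigma: float = 0.3,
    snr: float = 10.0,
    background: float = 20.0,
    dt: float = DEFAULT_DT_S,
    seed: int = 0,
) -> ImageStack:
    """Render per-frame 3D point sets as Gaussian spots over Poisson background.

    ``positions`` is one (n, 3) array of (x, y, z) µm coordinates per frame.
    Spot amplitude is ``snr * sqrt(background)`` so the peak rises ``snr``
    background noise standard deviations above the baseline.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    vz, vy, vx = voxel_size
    nz, ny, nx = shape
    amp = snr * np.sqrt(background)
    frames = []
    for pts in positions:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        vol = np.zeros(shape, dtype=float)
        zz, yy, xx = np.meshgrid(
            np.arange(nz) * vz, np.arange(ny) * vy, np.arange(nx) * vx, indexing="ij"
        )
        for x, y, z in pts:
            if not (0 <= x <= (nx - 1) * vx and 0 <= y <= (ny - 1) * vy and 0 <= z <= (nz - 1) * vz):
                raise ParameterError(f"spot ({x}, {y}, {z}) outside the rendered volume")
            d2 = (xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2
            vol += amp * np.exp(-d2 / (2.0 * psf_sigma**2))
        noisy = rng.poisson(vol + background).astype(np.float32)
        frames.append(noisy)
    data = np.stack(frames)
    times = np.arange(data.shape[0]) * dt
    return ImageStack(data=data, voxel_size=voxel_size, times=times)
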