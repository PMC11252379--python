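"""3D telomere / nuclear-envelope / nucleolus quantification.

The nuclear periphery and the nucleolus are modeled as spheres, matching how
they are delimited on immunostained meiocytes.  Telomere positions (chromosome
axis extremities used as a proxy for telomeres) are 3D points, each carrying a
flag marking the ends of the NOR-bearing short arms of chromosomes 2 and 4;
those ends associate with the nucleolus rather than the envelope and are
excluded from bouquet quantification.

The bouquet call follows the published rule: telomeres whose average distance
to their 9 nearest neighbors falls below 4 µm (the median of that statistic)
are considered clustered, and a bouquet requires at least 6 of the 16 non-NOR
ends in a single cluster (37%).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

from .errors import GeometryError, ParameterError

# Wild-type baseline constants used in report generation: A. thaliana has 20
# telomeres, 4 of which belong to the NOR-bearing short arms (16 non-NOR ends).
N_TELOMERES_TOTAL = 20
N_NOR_ENDS = 4
N_NON_NOR_ENDS = N_TELOMERES_TOTAL - N_NOR_ENDS
MIN_BOUQUET_SIZE = 6
KNN_NEIGHBORS = 9
KNN_THRESHOLD_UM = 4.0
#: average number of detected telomeres per stage (zygotene, pachytene, diplotene)
DETECTED_PER_STAGE = {"zygotene": 19, "pachytene": 20, "diplotene": 16}


@dataclass
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise GeometryError("sphere radius must be > 0")


@dataclass
class NucleusGeometry:
    """Idealized nucleus: periphery sphere and nucleolus sphere."""

    periphery: Sphere
    nucleolus: Sphere
    cell_id: str = ""
    stage: str = "unknown"
    genotype: str = "wt"

    def __post_init__(self) -> None:
        if self.nucleolus.radius >= self.periphery.radius:
            raise GeometryError("nucleolus radius must be smaller than periphery radius")


@dataclass
class TelomereSet:
    """Labeled telomere point cloud with NOR flags."""

    points: np.ndarray
    nor_flag: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.shape[0] < 1:
            raise GeometryError("TelomereSet needs at least one point")
        self.nor_flag = np.asarray(self.nor_flag, dtype=bool).reshape(-1)
        if self.nor_flag.shape[0] != self.points.shape[0]:
            raise GeometryError("nor_flag length mismatch")
        if not self.labels:
            self.labels = [f"telo_{i}" for i in range(self.points.shape[0])]

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass
class BouquetResult:
    clustered_mask: np.ndarray
    bouquet: bool
    n_in_bouquet: int
    area_fraction: float | None
    periphery_fraction: float
    nucleolus_position: str

    def to_dict(self) -> dict:
        return {
            "bouquet": bool(self.bouquet),
            "n_in_bouquet": int(self.n_in_bouquet),
            "area_fraction": None if self.area_fraction is None else float(self.area_fraction),
            "periphery_fraction": float(self.periphery_fraction),
            "nucleolus_position": self.nucleolus_position,
            "clustered_mask": self.clustered_mask.astype(bool).tolist(),
        }


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def distance_to_periphery(ts: TelomereSet, g: NucleusGeometry) -> np.ndarray:
    """Signed distance of each telomere to the periphery sphere surface.

    Positive inside the nucleus, zero on the surface, negative outside.
    """
    r = np.linalg.norm(ts.points - g.periphery.center, axis=1)
    return g.periphery.radius - r


def classify_periphery(
    ts: TelomereSet, g: NucleusGeometry, eps: float = 0.5
) -> tuple[np.ndarray, float]:
    """Mark telomeres within ``eps`` µm of the envelope; return mask and fraction.

    The fraction is computed over all detected ends (NOR ends included in the
    denominator; pass a subset TelomereSet to change that convention).
    """
    if eps < 0:
        raise ParameterError("eps must be >= 0")
    mask = np.abs(distance_to_periphery(ts, g)) <= eps
    return mask, float(mask.mean())


def knn_average_distance(ts: TelomereSet, k: int = KNN_NEIGHBORS) -> np.ndarray:
    """Per-point mean Euclidean distance to the k nearest other points."""
    n = len(ts)
    if n < 2:
        raise ParameterError("knn_average_distance needs at least 2 points")
    if k > n - 1:
        warnings.warn(f"k={k} reduced to n-1={n - 1}")
        k = n - 1
    dm = squareform(pdist(ts.points))
    # exclude self-distance (the zero diagonal) by sorting and skipping col 0
    srt = np.sort(dm, axis=1)
    return srt[:, 1 : k + 1].mean(axis=1)


def _single_linkage_components(points: np.ndarray, radius: float) -> np.ndarray:
    """Connected components of the graph linking points closer than ``radius``."""
    n = points.shape[0]
    comp = np.arange(n)

    def find(i: int) -> int:
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    if n > 1:
        dm = squareform(pdist(points))
        for i in range(n):
            for j in range(i + 1, n):
                if dm[i, j] <= radius:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        comp[ri] = rj
    return np.array([find(i) for i in range(n)])


def detect_bouquet(
    ts: TelomereSet,
    g: NucleusGeometry,
    knn_threshold: float = KNN_THRESHOLD_UM,
    min_cluster: int = MIN_BOUQUET_SIZE,
    linkage_radius: float | None = None,
    k: int = KNN_NEIGHBORS,
    periphery_eps: float = 0.5,
    nucleolus_eps: float = 0.5,
    cluster_metric: str = "knn",
) -> BouquetResult:
    """Call a telomere bouquet on one nucleus.

    NOR-flagged ends are excluded before any counting.  With the default
    ``cluster_metric="knn"``, ends whose average distance to their ``k``
    nearest neighbors is below ``knn_threshold`` are marked as clustered; the
    marked ends are then grouped by single linkage at ``linkage_radius``
    (default: same as ``knn_threshold``), and the largest group is the
    candidate bouquet.  ``cluster_metric="pairwise"`` skips the kNN marking and
    single-links all ends directly at ``knn_threshold`` (the alternative
    reading of the clustering rule).  A bouquet is called when the candidate
    group has at least ``min_cluster`` ends; otherwise ``n_in_bouquet`` is
    reported as 0.
    """
    keep = ~ts.nor_flag
    if not np.any(keep):
        raise GeometryError("all ends are NOR-flagged; nothing to quantify")
    pts = ts.points[keep]
    sub = TelomereSet(pts, np.zeros(len(pts), dtype=bool))
    if linkage_radius is None:
        linkage_radius = knn_threshold

    if cluster_metric == "knn":
        marked = knn_average_distance(sub, k=k) < knn_threshold
    elif cluster_metric == "pairwise":
        marked = np.ones(len(pts), dtype=bool)
    else:
        raise ParameterError(f"unknown cluster_metric {cluster_metric!r}")

    best_members = np.zeros(len(pts), dtype=bool)
    if np.any(marked):
        comp = _single_linkage_components(pts[marked], linkage_radius)
        labels, counts = np.unique(comp, return_counts=True)
        biggest = labels[np.argmax(counts)]
        members = np.zeros(len(pts), dtype=bool)
        members[np.flatnonzero(marked)[comp == biggest]] = True
        best_members = members

    size = int(best_members.sum())
    bouquet = size >= min_cluster

    full_mask = np.zeros(len(ts), dtype=bool)
    if bouquet:
        full_mask[np.flatnonzero(keep)[best_members]] = True
    n_in_bouquet = size if bouquet else 0

    _, periphery_fraction = classify_periphery(sub, g, eps=periphery_eps)
    area = None
    if bouquet:
        area = bouquet_area_fraction(pts[best_members], g)
    nucleolus_position = classify_nucleolus(g, eps=nucleolus_eps)
    return BouquetResult(
        clustered_mask=full_mask,
        bouquet=bouquet,
        n_in_bouquet=n_in_bouquet,
        area_fraction=area,
        periphery_fraction=periphery_fraction,
        nucleolus_position=nucleolus_position,
    )


def _spherical_polygon_area(vertices_unit: np.ndarray) -> float:
    """Area of a convex spherical polygon on the unit sphere (angle-sum formula)."""
    n = vertices_unit.shape[0]
    total = 0.0
    for i in range(n):
        v = vertices_unit[i]
        prev = vertices_unit[(i - 1) % n]
        nxt = vertices_unit[(i + 1) % n]
        t1 = prev - np.dot(prev, v) * v
        t2 = nxt - np.dot(nxt, v) * v
        n1, n2 = np.linalg.norm(t1), np.linalg.norm(t2)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        cosang = np.clip(np.dot(t1 / n1, t2 / n2), -1.0, 1.0)
        total += np.arccos(cosang)
    return max(total - (n - 2) * np.pi, 0.0)


def bouquet_area_fraction(points: np.ndarray, g: NucleusGeometry) -> float:
    """Fraction of the envelope area covered by the spherical convex hull
    of the cluster points radially projected onto the periphery sphere."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    rel = points - g.periphery.center
    norms = np.linalg.norm(rel, axis=1)
    if np.any(norms < 1e-12):
        raise GeometryError("cluster point coincides with the periphery center")
    units = rel / norms[:, None]

    if points.shape[0] < 3:
        warnings.warn("fewer than 3 cluster points; using minimal-cap fallback")
        if points.shape[0] == 1:
            return 0.0
        cosang = np.clip(np.dot(units[0], units[1]), -1.0, 1.0)
        half = np.arccos(cosang) / 2.0
        return float((1.0 - np.cos(half)) / 2.0)  # cap area / 4 pi

    center = units.mean(axis=0)
    nc = np.linalg.norm(center)
    if nc < 1e-9:
        # degenerate spread (e.g. points on a great circle); hull ~ hemisphere
        return 0.5
    center /= nc
    # gnomonic projection onto the tangent plane at the spread center
    dots = units @ center
    if np.any(dots <= 1e-9):
        # spans a hemisphere or more; report the hemisphere bound
        return 0.5
    proj = units / dots[:, None] - center
    e1 = np.cross(center, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(center, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(center, e1)
    plane = np.c_[proj @ e1, proj @ e2]
    try:
        hull = ConvexHull(plane)
    except Exception:
        return 0.0  # collinear projections: zero area
    boundary = units[hull.vertices]
    area = _spherical_polygon_area(boundary)
    return float(area / (4.0 * np.pi))


def classify_nucleolus(g: NucleusGeometry, eps: float = 0.5) -> str:
    """Classify the nucleolus as ``"peripheral"`` or ``"internal"``.

    Peripheral means its surface comes within ``eps`` µm of the envelope.
    """
    offset = float(np.linalg.norm(g.nucleolus.center - g.periphery.center))
    gap = g.periphery.radius - offset - g.nucleolus.radius
    if gap < -1e-6:
        raise GeometryError("nucleolus extends outside the periphery sphere")
    return "peripheral" if gap <= eps else "internal"


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_geometry(g: NucleusGeometry, path: str | Path) -> None:
    data = {
        "periphery": {"center": g.periphery.center.tolist(), "radius": g.periphery.radius},
        "nucleolus": {"center": g.nucleolus.center.tolist(), "radius": g.nucleolus.radius},
        "cell_id": g.cell_id,
        "stage": g.stage,
        "genotype": g.genotype,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_geometry(path: str | Path) -> NucleusGeometry:
    with open(path) as fh:
        d = json.load(fh)
    return NucleusGeometry(
        periphery=Sphere(d["periphery"]["center"], d["periphery"]["radius"]),
        nucleolus=Sphere(d["nucleolus"]["center"], d["nucleolus"]["radius"]),
        cell_id=d.get("cell_id", ""),
        stage=d.get("stage", "unknown"),
        genotype=d.get("genotype", "wt"),
    )


def save_telomeres(ts: TelomereSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": ts.labels,
            "x_um": ts.points[:, 0],
            "y_um": ts.points[:, 1],
            "z_um": ts.points[:, 2],
            "nor_flag": ts.nor_flag.astype(int),
        }
    ).to_csv(path, index=False)


def load_telomeres(path: str | Path) -> TelomereSet:
    df = pd.read_csv(path)
    return TelomereSet(
        points=df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        nor_flag=df["nor_flag"].to_numpy(dtype=bool),
        labels=[str(x) for x in df["label"]],
    )
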