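"""Synthetic en-face OCTA scenes of a superficial capillary plexus.

The generator builds a planar capillary mesh (blue-noise points joined by
Delaunay edges) around a protected ring bounding a central foveal
avascular zone, then rasterizes the surviving edges as bright strokes on
a dark background.  Pathology is emulated by two mechanisms observed on
OCTA in diabetic retinas:

* permanent capillary dropout (``dropout_rate``) — edges removed for all
  frames, merging neighbouring intercapillary spaces into nonperfusion
  areas;
* transient flow-signal loss (``transient_rate``) — per-frame blanking of
  surviving capillaries, recovered by frame averaging.

Ground truth is exact: the faces of the planar line arrangement, as
shapely polygons with analytic areas and perimeters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Delaunay
from shapely.geometry import LineString, MultiLineString, Point, Polygon
from shapely.ops import polygonize, unary_union
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .preprocess import CircularROI

__all__ = [
    "SceneConfig",
    "CapillaryGraph",
    "GroundTruth",
    "FrameStack",
    "generate_graph",
    "apply_dropout",
    "render_frames",
    "render_mask",
    "compute_ground_truth",
    "true_face_metrics",
    "stroke_halfwidth_mm",
    "expected_space_pieces",
    "debris_floor_px",
    "euler_face_count",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic eye.

    Defaults emulate a healthy superficial plexus in a 3 x 3 mm field
    digitized to 1024 x 1024 px (pitch ~2.9 um): capillary mesh spacing
    around 0.09 mm so that roughly 500 intercapillary spaces fall inside
    the central 2 mm circle, a 0.30 mm FAZ, 12 um capillary strokes, mild
    additive noise, and three repeat frames.
    """

    fov_mm: float = 3.0
    grid_px: int = 1024
    faz_radius_mm: float = 0.30
    seed_point_density: float = 80.0  # mesh nodes per mm^2
    vessel_width_um: float = 12.0
    dropout_rate: float = 0.0
    transient_rate: float = 0.05
    noise_sd: float = 0.05
    n_frames: int = 3
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("dropout_rate", "transient_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if self.grid_px < 64:
            raise ValueError("grid_px must be >= 64")
        if not 0.0 <= self.faz_radius_mm < self.fov_mm / 2:
            raise ValueError("faz_radius_mm must satisfy 0 <= r < fov/2")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.seed_point_density < 0:
            raise ValueError("seed_point_density must be >= 0")
        if self.vessel_width_um <= 0:
            raise ValueError("vessel_width_um must be positive")

    @property
    def pitch_mm(self) -> float:
        return self.fov_mm / self.grid_px


@dataclass(frozen=True)
class CapillaryGraph:
    """Planar capillary network: nodes in mm, edges with state flags."""

    nodes: np.ndarray  # (N, 2) xy in mm
    edges: np.ndarray  # (E, 2) node indices
    width_mm: np.ndarray  # (E,) stroke width per edge
    alive: np.ndarray  # (E,) bool, False = permanent dropout
    protected: np.ndarray  # (E,) bool: FAZ ring and trunk vessels
    fov_mm: float
    faz_radius_mm: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def alive_segments(self, subset: Optional[np.ndarray] = None) -> np.ndarray:
        """(k, 2, 2) xy endpoints of alive edges (optionally a boolean subset)."""
        keep = self.alive if subset is None else (self.alive & subset)
        return self.nodes[self.edges[keep]]


@dataclass(frozen=True)
class GroundTruth:
    """Exact faces of the alive planar network.

    ``faces`` are shapely polygons (vertex loops in mm) bounded by alive
    edges; they tile the field minus the vessel strokes.  ``center_face``
    is the index of the face containing the image center (the true FAZ)
    or None if the center lies on an edge.
    """

    faces: List[Polygon]
    center_face: Optional[int]
    fov_mm: float

    @property
    def areas_mm2(self) -> np.ndarray:
        return np.array([f.area for f in self.faces])

    @property
    def perimeters_mm(self) -> np.ndarray:
        return np.array([f.length for f in self.faces])

    def adjacency(self, tol: float = 1e-9) -> set:
        """Pairs (i, j) of faces sharing a boundary edge of positive length."""
        from shapely.strtree import STRtree

        tree = STRtree(self.faces)
        pairs = set()
        for i, f in enumerate(self.faces):
            for j in tree.query(f):
                j = int(j)
                if j <= i:
                    continue
                inter = f.boundary.intersection(self.faces[j].boundary)
                if inter.length > tol:
                    pairs.add((i, j))
        return pairs


@dataclass(frozen=True)
class FrameStack:
    """Repeat frames of one synthetic eye plus the per-frame blanking record."""

    frames: np.ndarray  # (n_frames, H, W) float in [0, 1]
    pitch_mm: float
    blanked_edges: List[np.ndarray]  # edge indices blanked per frame

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# mesh construction


def _poisson_disc(
    rng: np.random.Generator,
    width: float,
    r: float,
    exclusion: Optional[tuple] = None,
    k: int = 30,
) -> np.ndarray:
    """Bridson blue-noise sample of the square [0, width]^2 with spacing >= r.

    ``exclusion = (cx, cy, radius)`` keeps a disk free of samples (the FAZ
    plus clearance for its bounding ring).
    """
    cell = r / math.sqrt(2.0)
    n = int(math.ceil(width / cell))
    grid = -np.ones((n, n), dtype=np.int64)
    pts: List[np.ndarray] = []

    def excluded(p) -> bool:
        if exclusion is None:
            return False
        cx, cy, rad = exclusion
        return (p[0] - cx) ** 2 + (p[1] - cy) ** 2 < rad * rad

    def fits(p) -> bool:
        gx = int(p[0] / cell)
        gy = int(p[1] / cell)
        for i in range(max(gx - 2, 0), min(gx + 3, n)):
            for j in range(max(gy - 2, 0), min(gy + 3, n)):
                q = grid[i, j]
                if q >= 0:
                    d = pts[q] - p
                    if d[0] * d[0] + d[1] * d[1] < r * r:
                        return False
        return True

    def insert(p) -> None:
        grid[int(p[0] / cell), int(p[1] / cell)] = len(pts)
        pts.append(p)
        active.append(p)

    active: List[np.ndarray] = []
    for _ in range(1000):
        p0 = rng.uniform(0.0, width, size=2)
        if not excluded(p0):
            insert(p0)
            break
    if not pts:
        return np.empty((0, 2))

    while active:
        idx = rng.integers(len(active))
        base = active[idx]
        placed = False
        for _ in range(k):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = rng.uniform(r, 2.0 * r)
            p = base + rad * np.array([math.cos(ang), math.sin(ang)])
            if (
                0.0 <= p[0] < width
                and 0.0 <= p[1] < width
                and not excluded(p)
                and fits(p)
            ):
                insert(p)
                placed = True
        if not placed:
            active.pop(idx)
    return np.array(pts)


def generate_graph(config: SceneConfig) -> tuple:
    """Build the planar capillary graph and its exact ground truth.

    Blue-noise points (spacing set by ``seed_point_density``) are
    Delaunay-triangulated; edges crossing the FAZ disk interior are
    removed and a protected vessel ring is laid on the FAZ circle.
    Convex-hull boundary edges act as protected trunk vessels with
    triple stroke width.  Deterministic given ``rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    if config.seed_point_density <= 0:
        raise ValueError("no interior faces: seed_point_density too low")
    # Bridson sampling at spacing r fills ~0.68/r^2 points per unit area.
    r_pd = math.sqrt(0.68 / config.seed_point_density)
    c = config.fov_mm / 2.0
    faz_r = config.faz_radius_mm

    exclusion = (c, c, faz_r + 0.5 * r_pd) if faz_r > 0 else None
    samples = _poisson_disc(rng, config.fov_mm, r_pd, exclusion=exclusion)

    n_ring = 0
    if faz_r > 0:
        n_ring = max(12, int(round(2.0 * math.pi * faz_r / (0.8 * r_pd))))
        ang = 2.0 * math.pi * np.arange(n_ring) / n_ring
        ring = np.column_stack([c + faz_r * np.cos(ang), c + faz_r * np.sin(ang)])
        nodes = np.vstack([ring, samples]) if len(samples) else ring
    else:
        nodes = samples

    if len(nodes) < 4:
        raise ValueError("no interior faces: seed_point_density too low")

    tri = Delaunay(nodes)
    edge_set = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = int(simplex[a]), int(simplex[b])
            edge_set.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edge_set), dtype=np.int64)

    # Drop edges crossing the FAZ interior: any edge whose midpoint falls
    # strictly inside the circle inscribed by adjacent ring chords.
    if faz_r > 0:
        mid = nodes[edges].mean(axis=1)
        d2 = (mid[:, 0] - c) ** 2 + (mid[:, 1] - c) ** 2
        inner = faz_r * math.cos(math.pi / n_ring) - 1e-12
        edges = edges[d2 >= inner * inner]

        ring_pairs = {
            (min(i, (i + 1) % n_ring), max(i, (i + 1) % n_ring))
            for i in range(n_ring)
        }
        existing = {tuple(e) for e in edges}
        missing = sorted(ring_pairs - existing)
        if missing:
            edges = np.vstack([edges, np.array(missing, dtype=np.int64)])
        is_ring = np.array([tuple(e) in ring_pairs for e in edges])
    else:
        is_ring = np.zeros(len(edges), dtype=bool)

    hull_pairs = {
        (min(int(a), int(b)), max(int(a), int(b))) for a, b in tri.convex_hull
    }
    is_trunk = np.array([tuple(e) in hull_pairs for e in edges])

    width = np.full(len(edges), config.vessel_width_um / 1000.0)
    width[is_trunk] *= 3.0  # arteriole/venule trunks
    protected = is_ring | is_trunk
    alive = np.ones(len(edges), dtype=bool)

    graph = CapillaryGraph(
        nodes=nodes,
        edges=edges,
        width_mm=width,
        alive=alive,
        protected=protected,
        fov_mm=config.fov_mm,
        faz_radius_mm=faz_r,
    )
    gt = compute_ground_truth(graph)
    if not gt.faces:
        raise ValueError("no interior faces: seed_point_density too low")
    return graph, gt


def compute_ground_truth(graph: CapillaryGraph) -> GroundTruth:
    """Faces of the alive planar network as exact polygons."""
    segs = graph.alive_segments()
    lines = MultiLineString([seg.tolist() for seg in segs])
    merged = unary_union(lines)
    faces = [p for p in polygonize(merged) if p.area > 0]
    center = Point(graph.fov_mm / 2.0, graph.fov_mm / 2.0)
    center_face = None
    for i, f in enumerate(faces):
        if f.contains(center):
            center_face = i
            break
    return GroundTruth(faces=faces, center_face=center_face, fov_mm=graph.fov_mm)


def euler_face_count(graph: CapillaryGraph) -> int:
    """Bounded-face count of the alive graph via Euler's formula.

    For a planar graph with V vertices, E edges and C connected
    components, the number of bounded faces is ``E - V + C``.  Serves as
    an oracle independent of the polygon route.
    """
    edges = graph.edges[graph.alive]
    if len(edges) == 0:
        return 0
    verts = np.unique(edges)
    index = {v: i for i, v in enumerate(verts)}
    parent = list(range(len(verts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(index[a]), find(index[b])
        if ra != rb:
            parent[ra] = rb
    comps = len({find(i) for i in range(len(verts))})
    return len(edges) - len(verts) + comps


def apply_dropout(
    graph: CapillaryGraph, rate: float, rng_seed: int
) -> CapillaryGraph:
    """Permanently remove each non-protected alive edge with probability rate.

    Models capillary obstruction: dropout merges adjacent intercapillary
    spaces into larger nonperfusion areas.  Protected trunk and FAZ-ring
    edges are never removed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"dropout rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(rng_seed)
    u = rng.random(graph.n_edges)
    dead = (u < rate) & graph.alive & ~graph.protected
    return replace(graph, alive=graph.alive & ~dead)


# ---------------------------------------------------------------------------
# rasterization


def _stroke_radius_px(width_mm: float, pitch_mm: float) -> int:
    return int(round(width_mm / (2.0 * pitch_mm)))


def stroke_halfwidth_mm(
    config: SceneConfig,
    width_mm: Optional[float] = None,
    angle_rad: Optional[float] = None,
) -> float:
    """Effective half-width of a rasterized stroke, in mm.

    A Bresenham line dilated with a discrete disk of radius ``rad`` covers
    ``(2*rad + 1) * max(|cos t|, |sin t|)`` px^2 per pixel of length at
    orientation ``t`` (one (2*rad+1)-pixel column per major-axis step), so
    the effective half-width is orientation dependent: ``(rad + 0.5) *
    pitch`` for axis-aligned strokes down to that over sqrt(2) for
    diagonals.  Without ``angle_rad`` the axis-aligned upper bound is
    returned.
    """
    if width_mm is None:
        width_mm = config.vessel_width_um / 1000.0
    rad = _stroke_radius_px(width_mm, config.pitch_mm)
    base = (rad + 0.5) * config.pitch_mm
    if angle_rad is None:
        return base
    return base * max(abs(math.cos(angle_rad)), abs(math.sin(angle_rad)))


def debris_floor_px(config: SceneConfig, width_mm: Optional[float] = None) -> int:
    """Pixel area of one capillary stroke-width square.

    Pockets smaller than this arise from stroke overlap at acute junctions
    during rasterization; they are below the capillary scale and carry no
    polygonal counterpart, so validation comparisons apply this floor on
    both the detected and the predicted side.
    """
    if width_mm is None:
        width_mm = config.vessel_width_um / 1000.0
    rad = _stroke_radius_px(width_mm, config.pitch_mm)
    return (2 * rad + 1) ** 2


def expected_space_pieces(
    graph: CapillaryGraph,
    config: SceneConfig,
    gt: Optional[GroundTruth] = None,
) -> List[tuple]:
    """Open pockets the raster leaves between strokes, predicted geometrically.

    Each ground-truth face minus its nearby alive strokes, every stroke
    buffered at its orientation-dependent effective half-width (see
    :func:`stroke_halfwidth_mm`).  Returns ``(face_id, polygon)`` pairs,
    one per connected pocket; a face pinched by stroke overlap at acute
    junctions contributes several pockets, exactly as the pixel pipeline
    sees it.
    """
    from shapely.strtree import STRtree

    if gt is None:
        gt = compute_ground_truth(graph)
    segs = graph.nodes[graph.edges[graph.alive]]
    widths = graph.width_mm[graph.alive]
    strokes = []
    for (p0, p1), w in zip(segs, widths):
        ang = math.atan2(p1[1] - p0[1], p1[0] - p0[0])
        hw = stroke_halfwidth_mm(config, width_mm=w, angle_rad=ang)
        strokes.append(LineString([p0, p1]).buffer(hw))
    tree = STRtree(strokes)
    pieces = []
    for i, face in enumerate(gt.faces):
        idx = tree.query(face)
        local = unary_union([strokes[j] for j in idx]) if len(idx) else None
        open_part = face.difference(local) if local is not None else face
        if open_part.is_empty:
            continue
        geoms = (
            open_part.geoms
            if open_part.geom_type == "MultiPolygon"
            else [open_part]
        )
        for gpoly in geoms:
            if gpoly.area > 0:
                pieces.append((i, gpoly))
    return pieces


def _rasterize_edges(
    graph: CapillaryGraph, keep: np.ndarray, config: SceneConfig
) -> np.ndarray:
    """Boolean stroke mask of the selected edges (hard strokes, no AA)."""
    n = config.grid_px
    pitch = config.pitch_mm
    mask = np.zeros((n, n), dtype=bool)
    radii = np.array(
        [_stroke_radius_px(w, pitch) for w in graph.width_mm], dtype=int
    )
    for rad in np.unique(radii[keep]):
        canvas = np.zeros((n, n), dtype=bool)
        sel = keep & (radii == rad)
        for a, b in graph.edges[sel]:
            x0, y0 = graph.nodes[a]
            x1, y1 = graph.nodes[b]
            r0 = int(round(y0 / pitch - 0.5))
            c0 = int(round(x0 / pitch - 0.5))
            r1 = int(round(y1 / pitch - 0.5))
            c1 = int(round(x1 / pitch - 0.5))
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            canvas[rr[ok], cc[ok]] = True
        if rad > 0:
            canvas = ndi.binary_dilation(canvas, structure=disk_footprint(rad))
        mask |= canvas
    return mask


def render_mask(graph: CapillaryGraph, config: SceneConfig) -> np.ndarray:
    """Noise-free boolean stroke mask of all alive edges."""
    if not graph.alive.any():
        raise ValueError("graph has no alive edges")
    return _rasterize_edges(graph, graph.alive.copy(), config)


def render_frames(graph: CapillaryGraph, config: SceneConfig) -> FrameStack:
    """Render repeat frames with per-frame transient blanking and noise.

    Each frame independently blanks every alive non-protected edge with
    probability ``transient_rate`` (temporary capillary plugging), draws
    surviving edges as intensity-1 strokes on an intensity-0 background,
    and adds Gaussian noise of sd ``noise_sd`` clipped to [0, 1].
    """
    config.validate()
    if not graph.alive.any():
        raise ValueError("graph has no alive edges")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 104729]))
    frames = np.empty((config.n_frames, config.grid_px, config.grid_px))
    blanked: List[np.ndarray] = []
    for f in range(config.n_frames):
        u = rng.random(graph.n_edges)
        blank = (u < config.transient_rate) & graph.alive & ~graph.protected
        keep = graph.alive & ~blank
        img = _rasterize_edges(graph, keep, config).astype(float)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[f] = np.clip(img, 0.0, 1.0)
        blanked.append(np.flatnonzero(blank))
    return FrameStack(frames=frames, pitch_mm=config.pitch_mm, blanked_edges=blanked)


# ---------------------------------------------------------------------------
# ground-truth metrics


def true_face_metrics(gt: GroundTruth, roi: Optional[CircularROI] = None) -> pd.DataFrame:
    """Exact per-face morphometry: area, perimeter, area/perimeter ratio.

    Shoelace area and polygon perimeter per face; ``intersects_roi`` flags
    faces overlapping the circular analysis region (requires a ROI whose
    pixel pitch is recoverable, i.e. built by ``make_circular_roi``).
    Zero-area degenerate polygons are excluded with a warning.
    """
    if not gt.faces:
        raise ValueError("ground truth contains no faces")
    disk = None
    if roi is not None:
        pitch = roi.pitch_mm
        cy, cx = roi.center
        center_mm = ((cx + 0.5) * pitch, (cy + 0.5) * pitch)
        disk = Point(center_mm).buffer(roi.diameter_mm / 2.0, quad_segs=256)
    rows = []
    for i, f in enumerate(gt.faces):
        if f.area <= 0:
            warnings.warn(f"face {i} has zero area; excluded")
            continue
        rows.append(
            {
                "face_id": i,
                "area_mm2": f.area,
                "perimeter_mm": f.length,
                "ap_ratio_mm": f.area / f.length,
                "intersects_roi": bool(f.intersects(disk)) if disk is not None else True,
                "is_center_face": i == gt.center_face,
            }
        )
    return pd.DataFrame(rows)
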