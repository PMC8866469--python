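"""Detection and morphometry of intercapillary spaces.

Spaces are the connected dark (non-vessel) regions inside the circular
analysis region.  For each region the module measures pixel area,
boundary perimeter, minimum and maximum Feret diameters and the
area/perimeter ratio, and identifies the foveal avascular zone as the
region containing the image center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .preprocess import BinaryVesselMap, CircularROI

__all__ = [
    "SpaceTable",
    "label_spaces",
    "measure_spaces",
    "feret_diameters",
    "identify_faz",
    "chain_code_perimeter_px",
]

SQRT2 = math.sqrt(2.0)

# Moore neighbourhood in clockwise order starting west; parallel step costs.
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
)
_STEP_LEN = np.array([1, SQRT2, 1, SQRT2, 1, SQRT2, 1, SQRT2])


@dataclass
class SpaceTable:
    """All detected spaces of one eye.

    ``regions`` holds one row per space: id, px_count, area_mm2,
    perimeter_mm, min_diam_mm, max_diam_mm, ap_ratio, centroid, boundary
    flag and is_faz.  At most one row has ``is_faz`` True; downstream
    spectrum summaries exclude it.
    """

    regions: pd.DataFrame
    pitch_mm: float
    eye_id: str = ""
    roi: Optional[CircularROI] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.regions):
            if self.regions["id"].duplicated().any():
                raise ValueError("region ids must be unique")
            if int(self.regions["is_faz"].sum()) > 1:
                raise ValueError("at most one region may be the FAZ")

    def __len__(self) -> int:
        return len(self.regions)

    def non_faz(self) -> pd.DataFrame:
        return self.regions[~self.regions["is_faz"]]

    def faz_row(self) -> Optional[pd.Series]:
        faz = self.regions[self.regions["is_faz"]]
        return faz.iloc[0] if len(faz) else None

    def to_csv(self, path) -> None:
        self.regions.to_csv(path, index=False)


def label_spaces(
    binary: BinaryVesselMap, roi: CircularROI, connectivity: int = 4
) -> np.ndarray:
    """Label connected non-vessel components inside the ROI.

    Spaces default to 4-connectivity (vessels implicitly 8-connected), so
    a one-pixel diagonal vessel line still separates two spaces.  Pixels
    outside the ROI are 0.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = roi.mask(binary.shape)
    if not mask.any():
        raise ValueError("empty ROI")
    space = ~binary.vessel & mask
    structure = ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labeled, _ = ndi.label(space, structure=structure)
    return labeled


_OFFSET_TO_DIR = {tuple(off): d for d, off in enumerate(_MOORE.tolist())}


def chain_code_perimeter_px(mask: np.ndarray) -> float:
    """Perimeter of a single connected region, in pixel units.

    The outer boundary of pixel centers is traced with Moore-neighbour
    following and summed with the classic 8-directional chain-code
    weights (1 for axial steps, sqrt(2) for diagonal steps).  Four pixel
    units are added to close the half-pixel outline the center chain
    cannot see, so an s x s pixel square measures exactly 4 s and a
    single pixel measures 4.

    The tracer is a deterministic map on (pixel, backtrack-direction)
    states; its periodic cycle is the closed boundary walk, so the
    perimeter is the step-length sum over one period.
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty region")
    if n_px == 1:
        return 4.0
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    i0 = np.lexsort((cols, rows))[0]
    start = (int(rows[i0]), int(cols[i0]))  # topmost-leftmost: west is outside

    state = (start, 0)  # backtrack direction 0 = west
    seen = {}
    lengths = []
    while state not in seen:
        seen[state] = len(lengths)
        cur, b_dir = state
        found = None
        for k in range(1, 9):
            d = (b_dir + k) % 8
            nb = (cur[0] + int(_MOORE[d][0]), cur[1] + int(_MOORE[d][1]))
            if padded[nb]:
                found = (d, k, nb)
                break
        if found is None:  # isolated pixel: cannot happen for n_px > 1
            return 4.0
        d, k, nxt = found
        prev_bg_dir = (b_dir + k - 1) % 8  # background checked just before
        prev_bg = (
            cur[0] + int(_MOORE[prev_bg_dir][0]),
            cur[1] + int(_MOORE[prev_bg_dir][1]),
        )
        lengths.append(float(_STEP_LEN[d]))
        new_b = _OFFSET_TO_DIR[(prev_bg[0] - nxt[0], prev_bg[1] - nxt[1])]
        state = (nxt, new_b)
    i = seen[state]
    return float(sum(lengths[i:]) + 4.0)


def feret_diameters(points: np.ndarray) -> tuple:
    """Minimum and maximum Feret diameters of a planar point set.

    Maximum = convex-hull diameter (largest pairwise distance); minimum =
    rotating-calipers width (smallest extent over all directions).
    Collinear sets return (0, L).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 2:
        raise ValueError("feret diameters need >= 2 distinct points")
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:
        # degenerate (collinear) set
        d = pts - pts[0]
        max_d = 0.0
        for i in range(len(pts)):
            dd = np.hypot(pts[:, 0] - pts[i, 0], pts[:, 1] - pts[i, 1]).max()
            max_d = max(max_d, float(dd))
        return 0.0, max_d

    diff = hp[:, None, :] - hp[None, :, :]
    max_f = float(np.sqrt((diff**2).sum(-1)).max())

    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    ok = lengths > 0
    normals = np.column_stack([-edges[ok, 1], edges[ok, 0]]) / lengths[ok, None]
    proj = hp @ normals.T  # (h, e)
    widths = proj.max(axis=0) - proj.min(axis=0)
    min_f = float(widths.min())
    return min_f, max_f


def _region_corner_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-corner points of the region's boundary pixels (x, y) order."""
    boundary = mask & ~ndi.binary_erosion(mask)
    rr, cc = np.nonzero(boundary)
    corners = np.concatenate(
        [
            np.column_stack([cc, rr]),
            np.column_stack([cc + 1, rr]),
            np.column_stack([cc, rr + 1]),
            np.column_stack([cc + 1, rr + 1]),
        ]
    )
    return np.unique(corners, axis=0)


def measure_spaces(
    labeled: np.ndarray,
    pitch_mm: float,
    roi: Optional[CircularROI] = None,
    eye_id: str = "",
    provenance: Optional[dict] = None,
) -> SpaceTable:
    """Morphometry of every labeled space.

    Per region: area = pixel count * pitch^2; perimeter = chain-code
    boundary length * pitch; min/max diameters = Feret diameters of the
    pixel-corner convex hull * pitch; ap_ratio = area / perimeter.
    ``touches_boundary`` marks regions 8-adjacent to non-ROI pixels.
    """
    labeled = np.asarray(labeled)
    n = int(labeled.max())
    slices = ndi.find_objects(labeled)
    if any(s is None for s in slices):
        raise ValueError("labels must be contiguous 1..N")

    out_dilated = None
    if roi is not None:
        outside = ~roi.mask(labeled.shape)
        out_dilated = ndi.binary_dilation(
            outside, structure=ndi.generate_binary_structure(2, 2)
        )

    rows = []
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        mask = labeled[sl] == lab
        px = int(mask.sum())
        area = px * pitch_mm**2
        perim = chain_code_perimeter_px(mask) * pitch_mm
        corners = _region_corner_points(mask)
        if len(corners) >= 2:
            min_f, max_f = feret_diameters(corners)
        else:  # single pixel
            min_f, max_f = 1.0, 1.0
        rr, cc = np.nonzero(mask)
        cy = rr.mean() + sl[0].start
        cx = cc.mean() + sl[1].start
        touches = (
            bool((out_dilated[sl] & mask).any()) if out_dilated is not None else False
        )
        rows.append(
            {
                "id": lab,
                "px_count": px,
                "area_mm2": area,
                "perimeter_mm": perim,
                "min_diam_mm": min_f * pitch_mm,
                "max_diam_mm": max_f * pitch_mm,
                "ap_ratio": area / perim,
                "centroid_y": cy,
                "centroid_x": cx,
                "touches_boundary": touches,
                "is_faz": False,
            }
        )
    columns = [
        "id",
        "px_count",
        "area_mm2",
        "perimeter_mm",
        "min_diam_mm",
        "max_diam_mm",
        "ap_ratio",
        "centroid_y",
        "centroid_x",
        "touches_boundary",
        "is_faz",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return SpaceTable(
        regions=df,
        pitch_mm=pitch_mm,
        eye_id=eye_id,
        roi=roi,
        provenance=provenance or {},
    )


def identify_faz(labeled: np.ndarray, roi: CircularROI) -> int:
    """Label of the region containing the image center (the FAZ).

    If the center pixel happens to be a vessel pixel, the nearest labeled
    pixel by Euclidean distance decides (documented fallback).
    """
    if labeled.max() < 1:
        raise ValueError("no intercapillary spaces in ROI")
    cy = int(round(roi.center[0]))
    cx = int(round(roi.center[1]))
    lab = int(labeled[cy, cx])
    if lab > 0:
        return lab
    _, (ind_y, ind_x) = ndi.distance_transform_edt(
        labeled == 0, return_indices=True
    )
    return int(labeled[ind_y[cy, cx], ind_x[cy, cx]])


def mark_faz(table: SpaceTable, faz_id: int) -> SpaceTable:
    """Return the table with ``is_faz`` set on the given region id."""
    df = table.regions.copy()
    if faz_id not in set(df["id"]):
        raise ValueError(f"region id {faz_id} not present")
    df["is_faz"] = df["id"] == faz_id
    return SpaceTable(
        regions=df,
        pitch_mm=table.pitch_mm,
        eye_id=table.eye_id,
        roi=table.roi,
        provenance=table.provenance,
    )
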