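"""Reading and writing the pipeline's file formats.

Grayscale TIFF/PNG in; CSV (tables), JSON (configs, nested reports) and
TIFF (frames, labeled regions) out.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import tifffile

from .synthetic import FrameStack, GroundTruth

__all__ = [
    "read_image",
    "write_frames_tiff",
    "write_labeled_tiff",
    "ground_truth_to_json",
    "write_json",
]


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF or a PNG.

    Returns a 2D array for single images or ``(n, H, W)`` for multi-page
    TIFF stacks.  Color input raises: the pipeline consumes grayscale
    en-face slabs.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path.name}: color images are not supported")
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path.name}: expected a 2D image or a page stack")
    return arr


def write_frames_tiff(stack: FrameStack, path: Union[str, Path]) -> None:
    """Write repeat frames as an 8-bit multi-page grayscale TIFF."""
    data = np.clip(stack.frames * 255.0, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_labeled_tiff(labeled: np.ndarray, path: Union[str, Path]) -> None:
    """Write a labeled-region grid as 16- or 32-bit TIFF for audit."""
    labeled = np.asarray(labeled)
    dtype = np.uint16 if labeled.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labeled.astype(dtype), photometric="minisblack")


def ground_truth_to_json(gt: GroundTruth, path: Union[str, Path]) -> None:
    """Serialize ground-truth face polygons (vertex loops in mm) as JSON."""
    payload = {
        "fov_mm": gt.fov_mm,
        "center_face": gt.center_face,
        "faces": [
            {
                "id": i,
                "area_mm2": f.area,
                "perimeter_mm": f.length,
                "exterior_mm": [list(xy) for xy in f.exterior.coords],
            }
            for i, f in enumerate(gt.faces)
        ],
    }
    write_json(payload, path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
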