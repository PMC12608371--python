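"""Image/mask domain types, standard-format I/O, and the mask-multiply step.

Conventions used throughout the package:

* A *gray image* is a 2-D ``float`` array with intensities in [0, 1],
  row-major with the origin at the top-left (row = y, column = x).
* A *pixel mask* is a 2-D ``uint8`` array over {0, 1} with the same shape
  as its paired image.
* Polygon annotations follow the LabelMe dialect: a JSON document with a
  ``shapes`` list of ``{"label", "points"}`` entries, where each point is
  an ``[x, y]`` pair in pixel coordinates (x = column).

The canonical frame size is 256 x 256 pixels; smaller frames are allowed
for synthetic fixtures.  Embryo extraction multiplies the image with its
predicted binary mask so that background pixels become exactly zero and
only the embryo region keeps its intensities — this is what lets the
downstream stage classifier concentrate on the embryo.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

FRAME_SIZE = 256

__all__ = [
    "FRAME_SIZE",
    "PolygonAnnotation",
    "EmbryoFrame",
    "validate_image",
    "validate_mask",
    "load_gray_image",
    "save_gray_image",
    "save_mask_png",
    "load_mask_png",
    "rasterize_annotation",
    "apply_mask",
    "read_labelme_json",
    "write_labelme_json",
]


@dataclass
class PolygonAnnotation:
    """A labelled polygon outline, e.g. a manually traced eggshell contour.

    ``vertices`` is an ordered list of ``(x, y)`` pixel coordinates; at
    least three vertices are required.
    """

    label: str
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError(
                f"polygon {self.label!r} needs >=3 vertices, got {len(self.vertices)}"
            )
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]

    def shoelace_area(self) -> float:
        """Signed-area magnitude of the polygon (shoelace formula)."""
        v = np.asarray(self.vertices, dtype=float)
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class EmbryoFrame:
    """One time point of a time-lapse recording.

    Frame times follow the acquisition grid: recording starts at
    ``time_origin`` minutes after the first cleavage and advances by
    ``interval`` minutes per frame (defaults 150 and 5).
    """

    index: int
    image: np.ndarray
    mask: np.ndarray | None = None
    time_origin: float = 150.0
    interval: float = 5.0
    time_min: float = field(init=False)

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        validate_image(self.image)
        if self.mask is not None:
            validate_mask(self.mask, like=self.image)
        self.time_min = self.time_origin + self.interval * self.index


def validate_image(img: np.ndarray, expect_size: int | None = None) -> np.ndarray:
    """Check gray-image invariants; returns the array unchanged."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {img.shape}")
    if img.shape[0] <= 0 or img.shape[1] <= 0:
        raise ValueError("image dimensions must be positive")
    if expect_size is not None and img.shape != (expect_size, expect_size):
        raise ValueError(
            f"expected a {expect_size}x{expect_size} frame, got {img.shape}"
        )
    lo, hi = float(img.min()), float(img.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"intensities must lie in [0,1], got range [{lo}, {hi}]")
    return img


def validate_mask(mask: np.ndarray, like: np.ndarray | None = None) -> np.ndarray:
    """Check pixel-mask invariants (binary, shape-matched); returns the array."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask values must be strictly binary {0,1}")
    if like is not None and mask.shape != np.asarray(like).shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {np.asarray(like).shape}"
        )
    return mask


def load_gray_image(
    path: str | Path,
    expect_size: int | None = FRAME_SIZE,
    allow_resize: bool = False,
) -> np.ndarray:
    """Load a JPEG/PNG frame as a [0,1] grayscale array.

    Colour inputs are converted by luminance.  Frames whose size differs
    from ``expect_size`` are rejected unless ``allow_resize`` opts into a
    bilinear resize; pass ``expect_size=None`` to accept any size.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("L")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"could not decode image file {path}: {exc}") from exc
    if expect_size is not None and arr.shape != (expect_size, expect_size):
        if not allow_resize:
            raise ValueError(
                f"{path}: frame is {arr.shape}, expected "
                f"{expect_size}x{expect_size} (pass allow_resize=True to resize)"
            )
        with Image.open(path) as im:
            im = im.convert("L").resize((expect_size, expect_size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float64) / 255.0
    return validate_image(arr)


def save_gray_image(img: np.ndarray, path: str | Path) -> Path:
    """Write a [0,1] gray image as 8-bit JPEG or PNG (by extension)."""
    validate_image(img)
    path = Path(path)
    arr8 = np.clip(np.rint(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr8, mode="L").save(path)
    return path


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    validate_mask(mask)
    path = Path(path)
    Image.fromarray((np.asarray(mask) * 255).astype(np.uint8), mode="L").save(path)
    return path


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a {0,255} PNG mask back to a {0,1} uint8 array."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return validate_mask((arr >= 128).astype(np.uint8))


def rasterize_annotation(
    ann: PolygonAnnotation, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a polygon outline to a binary mask.

    A pixel belongs to the mask when its centre — at ``(col + 0.5,
    row + 0.5)`` in LabelMe's (x, y) frame — lies inside the polygon under
    the even-odd fill rule.  Degenerate (zero-area) polygons yield an
    empty mask with a warning.
    """
    h, w = shape
    verts = np.asarray(ann.vertices, dtype=np.float64)
    if ann.shoelace_area() == 0.0:
        warnings.warn(
            f"polygon {ann.label!r} has zero area; returning empty mask",
            stacklevel=2,
        )
        return np.zeros((h, w), dtype=np.uint8)

    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    inside = _even_odd_inside(cols.ravel(), rows.ravel(), verts)
    return inside.reshape(h, w).astype(np.uint8)


def _even_odd_inside(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Vectorised even-odd (ray-casting) point-in-polygon test."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never cross a horizontal ray's y-level
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
    return inside


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract the embryo region: pixel-wise product of image and mask.

    Background pixels become exactly 0; embryo pixels are unchanged.
    Idempotent under repeated application with the same mask.
    """
    validate_image(img)
    validate_mask(mask, like=img)
    return np.asarray(img) * np.asarray(mask)


def read_labelme_json(path: str | Path) -> tuple[list[PolygonAnnotation], tuple[int, int]]:
    """Read LabelMe-dialect JSON; returns (annotations, (height, width))."""
    with open(Path(path)) as fh:
        doc = json.load(fh)
    anns = [
        PolygonAnnotation(label=s["label"], vertices=[tuple(p) for p in s["points"]])
        for s in doc.get("shapes", [])
    ]
    return anns, (int(doc["imageHeight"]), int(doc["imageWidth"]))


def write_labelme_json(
    path: str | Path,
    annotations: list[PolygonAnnotation],
    shape: tuple[int, int],
    image_path: str = "",
) -> Path:
    """Write annotations as LabelMe-dialect JSON (vertex-exact round trip)."""
    doc = {
        "version": "5.1.1",
        "shapes": [
            {
                "label": a.label,
                "points": [[x, y] for x, y in a.vertices],
                "shape_type": "polygon",
            }
            for a in annotations
        ],
        "imagePath": image_path,
        "imageHeight": int(shape[0]),
        "imageWidth": int(shape[1]),
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path
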