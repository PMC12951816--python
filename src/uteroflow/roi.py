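"""ROI cropping schemes for annotated cine frames.

Each case carries one hand-drawn rectangle around the uterus.  Four image
types are derived from it:

* ``O`` — the original full frame, no crop;
* ``R`` — the rectangle itself;
* ``C`` — the circle circumscribing the rectangle (side = rectangle
  diagonal, pixels outside the circle filled);
* ``P`` — a fixed-diameter circle centered on the rectangle, identical
  field of view for every case.

The fixed P diameter defaults to 644 px defined at a 1024-px display
width; for stacks stored at other widths it is scaled proportionally
(a 256-px matrix gets 644 * 256 / 1024 = 161 px), since a literal 644-px
circle cannot fit the acquisition matrix.  After cropping, frames are
resized to the network input size with bilinear interpolation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .encoding import FrameSequence

IMAGE_TYPES = ("O", "R", "C", "P")
REFERENCE_DISPLAY_WIDTH = 1024


@dataclass
class AnnotationRect:
    """Uterus bounding box in pixel coordinates, 0-based, half-open."""

    case_id: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate rectangle for {self.case_id!r}: "
                f"({self.x0},{self.y0})-({self.x1},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) of the rectangle in pixel coordinates."""
        return (self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))


@dataclass
class RoiSpec:
    image_type: str = "P"
    p_diameter_px: float = 644.0
    fill_value: float = 0.0
    output_size: tuple[int, int] = (224, 224)

    def __post_init__(self) -> None:
        if self.image_type not in IMAGE_TYPES:
            raise ValueError(
                f"unknown image type {self.image_type!r}; expected one of {IMAGE_TYPES}"
            )
        if self.p_diameter_px <= 0:
            raise ValueError("p_diameter_px must be positive")

    def effective_p_diameter(self, stored_width: int) -> float:
        """Diameter at the stored resolution (644 is display-relative)."""
        if stored_width >= REFERENCE_DISPLAY_WIDTH:
            return self.p_diameter_px
        return self.p_diameter_px * stored_width / REFERENCE_DISPLAY_WIDTH


# ---------------------------------------------------------------------------
# Crops
# ---------------------------------------------------------------------------

def crop_rect(image: np.ndarray, rect: AnnotationRect) -> np.ndarray:
    """R-type crop: the annotated sub-image, shape (height, width)."""
    h, w = image.shape[:2]
    if rect.x0 < 0 or rect.y0 < 0 or rect.x1 > w or rect.y1 > h:
        raise ValueError(
            f"rectangle ({rect.x0},{rect.y0})-({rect.x1},{rect.y1}) "
            f"outside a {w}x{h} image"
        )
    return image[rect.y0 : rect.y1, rect.x0 : rect.x1].copy()


def _extract_square(
    image: np.ndarray, cx: float, cy: float, side: int, fill: float
) -> np.ndarray:
    """Square window of the given side centered on (cx, cy); out-of-bounds
    source pixels take the fill value."""
    out = np.full((side, side), fill, dtype=np.float64)
    x_start = int(round(cx - side / 2.0))
    y_start = int(round(cy - side / 2.0))
    h, w = image.shape[:2]
    src_x0, src_x1 = max(0, x_start), min(w, x_start + side)
    src_y0, src_y1 = max(0, y_start), min(h, y_start + side)
    if src_x0 < src_x1 and src_y0 < src_y1:
        out[
            src_y0 - y_start : src_y1 - y_start,
            src_x0 - x_start : src_x1 - x_start,
        ] = image[src_y0:src_y1, src_x0:src_x1]
    return out


def _disk_mask(side: int, radius: float) -> np.ndarray:
    """Boolean in-circle mask for a side x side square centered at its middle."""
    yy, xx = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def crop_circumscribed_circle(
    image: np.ndarray, rect: AnnotationRect, fill: float = 0.0
) -> np.ndarray:
    """C-type crop: circle of radius diagonal/2 circumscribing the rectangle.

    Output is a square of side ceil(diagonal); pixels outside the circle
    (and out-of-bounds source pixels) are set to ``fill``.
    """
    side = int(np.ceil(rect.diagonal))
    cx, cy = rect.center
    out = _extract_square(image, cx, cy, side, fill)
    out[~_disk_mask(side, rect.diagonal / 2.0)] = fill
    return out


def crop_fixed_circle(
    image: np.ndarray, rect: AnnotationRect, spec: RoiSpec
) -> np.ndarray:
    """P-type crop: fixed-diameter circle centered on the rectangle.

    The output side equals the effective diameter for the stored width, so
    every case shares one field of view regardless of rectangle size.
    """
    diameter = spec.effective_p_diameter(image.shape[1])
    side = int(round(diameter))
    cx, cy = rect.center
    out = _extract_square(image, cx, cy, side, spec.fill_value)
    out[~_disk_mask(side, diameter / 2.0)] = spec.fill_value
    return out


def prepare_type(
    seq: FrameSequence, rect: AnnotationRect, spec: RoiSpec
) -> FrameSequence:
    """Apply the selected crop to every frame, then resize to the input size.

    The single per-case rectangle is applied to all frames; the resize uses
    bilinear interpolation with anti-aliasing on downscale.
    """
    if spec.image_type == "O":
        cropped = [frame for frame in seq.frames]
    elif spec.image_type == "R":
        cropped = [crop_rect(frame, rect) for frame in seq.frames]
    elif spec.image_type == "C":
        cropped = [
            crop_circumscribed_circle(frame, rect, spec.fill_value)
            for frame in seq.frames
        ]
    elif spec.image_type == "P":
        cropped = [crop_fixed_circle(frame, rect, spec) for frame in seq.frames]
    else:  # pragma: no cover - guarded by RoiSpec
        raise ValueError(f"unknown image type {spec.image_type!r}")
    resized = np.stack(
        [
            resize(
                frame,
                spec.output_size,
                order=1,
                mode="edge",
                anti_aliasing=frame.shape[0] > spec.output_size[0],
                preserve_range=True,
            )
            for frame in cropped
        ]
    )
    return FrameSequence(
        case_id=seq.case_id,
        frames=np.clip(resized, 0.0, 255.0),
        frame_interval_s=seq.frame_interval_s,
    )


# ---------------------------------------------------------------------------
# Annotation I/O  (CSV schema: case_id,x0,y0,x1,y1 — 0-based, half-open)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, AnnotationRect]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    out: dict[str, AnnotationRect] = {}
    for row in rows:
        rect = AnnotationRect(
            case_id=str(row["case_id"]),
            x0=int(row["x0"]),
            y0=int(row["y0"]),
            x1=int(row["x1"]),
            y1=int(row["y1"]),
        )
        out[rect.case_id] = rect
    return out


def write_annotations(rects: dict[str, AnnotationRect], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "x0", "y0", "x1", "y1"])
        for cid in sorted(rects):
            r = rects[cid]
            writer.writerow([cid, r.x0, r.y0, r.x1, r.y1])
    return path
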