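"""Training-target encoding: annotated image -> stride-4 head targets.

A positive image contributes a Gaussian heatmap splat (the keypoint
target), a sub-pixel center offset, the semi-axes and the rotation angle;
a negative image contributes an all-zero heatmap and no regression
targets.  The heatmap Gaussian is anisotropic with a box-size-adaptive
standard deviation: sigma_x = w/(6s), sigma_y = h/(6s) in grid units,
where (w, h) is the ellipse's smallest axis-aligned enclosing box and
s the output stride, so the +-3 sigma extent of the splat matches the
box.  Axes targets are regressed in input-image pixels (not stride
units), which keeps the head-circumference formula free of stride
bookkeeping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AABox, Ellipse, Gaussian2D, ellipse_to_gaussian, enclosing_box

__all__ = [
    "Annotation",
    "TargetSet",
    "splat_gaussian",
    "encode_offset",
    "encode_targets",
    "read_annotations",
    "write_annotations",
    "ANNOTATION_COLUMNS",
]

#: CSV dialect for annotations: one row per image, UTF-8, '.' decimal.
#: ``a`` and ``b`` are SEMI-axes in pixels; ``theta_deg`` is the angle
#: between the short axis and the vertical, in [0, 180).
ANNOTATION_COLUMNS = ["image_id", "cx", "cy", "a", "b", "theta_deg", "pixel_size_mm", "is_negative"]


@dataclass(frozen=True)
class Annotation:
    """Per-image ground truth: ellipse (absent for negatives) + pixel size."""

    image_id: str
    ellipse: Ellipse | None
    pixel_size_mm: float
    is_negative: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.is_negative and self.ellipse is not None:
            raise ValueError("negative images carry no ellipse")
        if not self.is_negative and self.ellipse is None:
            raise ValueError("positive images require an ellipse")


@dataclass
class TargetSet:
    """Stride-s training targets for one image.

    ``heatmap`` is (Hg, Wg) in [0, 1]; ``center_index`` is the integer
    grid cell (ix, iy) = (floor(cx/s), floor(cy/s)); ``offset`` the
    sub-pixel remainder in [0, 1)^2; ``axes`` the semi-axes in input
    pixels; ``angle`` in degrees.  All regression fields are None for a
    negative image.
    """

    heatmap: np.ndarray
    offset: tuple[float, float] | None
    axes: tuple[float, float] | None
    angle: float | None
    center_index: tuple[int, int] | None
    gt_gaussian: Gaussian2D | None
    stride: int
    is_negative: bool

    @property
    def n_objects(self) -> int:
        return 0 if self.is_negative else 1


def splat_gaussian(box: AABox, stride: int, grid_shape: tuple[int, int]) -> np.ndarray:
    """Render an anisotropic Gaussian bump for one object on the heatmap grid.

    ``grid_shape`` is (Hg, Wg) rows x cols.  The kernel is
    ``exp(-((px - bx/s)^2 / (2 sigma_x^2) + (py - by/s)^2 / (2 sigma_y^2)))``
    with sigma_x = w/(6s), sigma_y = h/(6s); the integer center cell is
    clamped to exactly 1 so the focal loss's P=1 branch has support.
    Multiple objects combine by elementwise max in the caller.
    """
    hg, wg = grid_shape
    gx, gy = box.bx / stride, box.by / stride
    ix, iy = int(math.floor(gx)), int(math.floor(gy))
    if not (0 <= ix < wg and 0 <= iy < hg):
        warnings.warn("box center falls outside the heatmap grid; empty heatmap")
        return np.zeros(grid_shape, dtype=np.float64)
    sig_x = max(box.w / (6.0 * stride), 1e-3)
    sig_y = max(box.h / (6.0 * stride), 1e-3)
    px = np.arange(wg, dtype=np.float64)[None, :]
    py = np.arange(hg, dtype=np.float64)[:, None]
    heat = np.exp(-((px - gx) ** 2 / (2 * sig_x**2) + (py - gy) ** 2 / (2 * sig_y**2)))
    heat[iy, ix] = 1.0
    return heat


def encode_offset(cx: float, cy: float, stride: int) -> tuple[float, float]:
    """Sub-pixel center offset (cx/s - floor(cx/s), cy/s - floor(cy/s))."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return (cx / stride - math.floor(cx / stride), cy / stride - math.floor(cy / stride))


def encode_targets(ann: Annotation, stride: int, image_shape: tuple[int, int]) -> TargetSet:
    """Assemble the full TargetSet for one annotated image.

    ``image_shape`` is (H, W) in input pixels; the grid is (H/s, W/s).
    """
    h, w = image_shape
    grid_shape = (h // stride, w // stride)
    if ann.is_negative:
        return TargetSet(
            heatmap=np.zeros(grid_shape),
            offset=None,
            axes=None,
            angle=None,
            center_index=None,
            gt_gaussian=None,
            stride=stride,
            is_negative=True,
        )
    e = ann.ellipse
    if not (0 <= e.cx < w and 0 <= e.cy < h):
        raise ValueError(f"ellipse center ({e.cx}, {e.cy}) outside image {image_shape}")
    box = enclosing_box(e)
    heat = splat_gaussian(box, stride, grid_shape)
    return TargetSet(
        heatmap=heat,
        offset=encode_offset(e.cx, e.cy, stride),
        axes=(e.a, e.b),
        angle=e.theta,
        center_index=(int(math.floor(e.cx / stride)), int(math.floor(e.cy / stride))),
        gt_gaussian=ellipse_to_gaussian(e),
        stride=stride,
        is_negative=False,
    )


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    """Write the annotation CSV dialect (see ANNOTATION_COLUMNS)."""
    rows = []
    for ann in annotations:
        e = ann.ellipse
        rows.append(
            {
                "image_id": ann.image_id,
                "cx": e.cx if e else "",
                "cy": e.cy if e else "",
                "a": e.a if e else "",
                "b": e.b if e else "",
                "theta_deg": e.theta if e else "",
                "pixel_size_mm": ann.pixel_size_mm,
                "is_negative": int(ann.is_negative),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read the annotation CSV dialect back into Annotation objects."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        neg = bool(int(row.is_negative))
        ellipse = None
        if not neg:
            ellipse = Ellipse(
                cx=float(row.cx),
                cy=float(row.cy),
                a=float(row.a),
                b=float(row.b),
                theta=float(row.theta_deg),
            )
        out.append(
            Annotation(
                image_id=str(row.image_id),
                ellipse=ellipse,
                pixel_size_mm=float(row.pixel_size_mm),
                is_negative=neg,
            )
        )
    return out
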