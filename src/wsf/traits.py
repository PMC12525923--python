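"""Mask-to-trait morphometry: stomatal length, width, area and count.

A 3-class mask (background / stoma / pore) is binarized — by default the
stoma region is the union of classes {1, 2}, since the pore sits inside
the guard-cell complex and excluding it would bias area low — then split
into 8-connected components. Each component's outer boundary is traced
(on a binary image this coincides with a Canny edge up to one pixel) and
the minimum-area enclosing rotated rectangle of the boundary is fitted;
its long side is the stomatal length, its short side the width. Area is
the component pixel count times the physical area of one pixel
(default 1, so areas are in px^2). Stomatal number is the component
count. Components touching the frame border are measured but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint

__all__ = ["StomaObject", "RotatedRect", "StomaRecord", "ImageTraits",
           "extract_stoma_objects", "min_area_rect", "measure_traits",
           "binary_boundary"]

_EIGHT = np.ones((3, 3), dtype=int)

CLASS_POLICIES = {
    "stoma_union_pore": (1, 2),
    "stoma_only": (1,),
    "pore_only": (2,),
}


@dataclass
class StomaObject:
    """One detected connected component."""

    pixels: np.ndarray          # (n, 2) array of (row, col)
    contour: np.ndarray         # (m, 2) boundary pixel coordinates (row, col)
    border_flag: bool

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class RotatedRect:
    center: tuple[float, float]   # (x, y)
    side_a: float                 # longer side, px
    side_b: float                 # shorter side, px
    angle_deg: float              # orientation of the long side

    def __post_init__(self):
        if self.side_b <= 0 or self.side_a < self.side_b:
            raise ValueError("rectangle sides must satisfy side_a >= side_b > 0")


@dataclass(frozen=True)
class StomaRecord:
    length: float      # px (long rectangle side)
    width: float       # px (short side)
    area: float        # px^2 x pixel_area
    border_flag: bool

    def __post_init__(self):
        if self.length < self.width:
            raise ValueError("length must be >= width")


@dataclass
class ImageTraits:
    sample_id: str
    surface: str
    records: list[StomaRecord] = field(default_factory=list)

    @property
    def stoma_count(self) -> int:
        return len(self.records)

    def summary(self) -> dict[str, float]:
        out = {"stoma_count": float(self.stoma_count)}
        for name in ("length", "width", "area"):
            vals = [getattr(r, name) for r in self.records]
            out[f"mean_{name}"] = float(np.mean(vals)) if vals else float("nan")
        return out


def binary_boundary(binary: np.ndarray) -> np.ndarray:
    """Outer boundary pixels of a binary blob (blob minus its erosion)."""
    er = ndimage.binary_erosion(binary, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    return binary & ~er


def extract_stoma_objects(mask: np.ndarray, min_size: int = 50,
                          class_policy: str = "stoma_union_pore") -> list[StomaObject]:
    """Connected components of the chosen foreground classes.

    8-connectivity; components smaller than ``min_size`` pixels are
    dropped as noise specks; components touching the image border get
    ``border_flag``.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("mask labels outside {0, 1, 2}")
    classes = CLASS_POLICIES[class_policy]
    fg = np.isin(mask, classes)
    labels, n = ndimage.label(fg, structure=_EIGHT)
    h, w = mask.shape
    objects: list[StomaObject] = []
    for k in range(1, n + 1):
        comp = labels == k
        count = int(comp.sum())
        if count < min_size:
            continue
        rows, cols = np.nonzero(comp)
        border = bool(rows.min() == 0 or cols.min() == 0 or
                      rows.max() == h - 1 or cols.max() == w - 1)
        bre, bce = np.nonzero(binary_boundary(comp))
        objects.append(StomaObject(
            pixels=np.column_stack([rows, cols]),
            contour=np.column_stack([bre, bce]),
            border_flag=border))
    return objects


def _pixel_corners(points_rc: np.ndarray) -> np.ndarray:
    """Expand pixel centers (row, col) to the 4 corners of each unit pixel,
    returned as (x, y) coordinates, so rectangle sides measure the true
    rasterized extent rather than the center-to-center span."""
    rc = np.asarray(points_rc, dtype=float)
    xy = rc[:, ::-1]
    offs = np.array([[-0.5, -0.5], [0.5, -0.5], [-0.5, 0.5], [0.5, 0.5]])
    return (xy[:, None, :] + offs[None]).reshape(-1, 2)


def min_area_rect(contour_rc: np.ndarray) -> RotatedRect:
    """Minimum-area enclosing rotated rectangle of a pixel contour.

    Computed by rotating calipers over the convex hull of the contour
    pixels' corner points. Degenerate point sets clamp to 1 px sides.
    """
    pts = np.asarray(contour_rc)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("contour must be a non-empty (n, 2) array")
    corners = _pixel_corners(pts)
    rect = MultiPoint(corners).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":          # single point / collinear
        xs, ys = corners[:, 0], corners[:, 1]
        return RotatedRect(center=(float(xs.mean()), float(ys.mean())),
                           side_a=max(float(np.ptp(xs)), float(np.ptp(ys)), 1.0),
                           side_b=1.0, angle_deg=0.0)
    xy = np.asarray(rect.exterior.coords)[:4]
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    l1, l2 = float(np.hypot(*e1)), float(np.hypot(*e2))
    if l1 >= l2:
        side_a, side_b = l1, l2
        angle = float(np.degrees(np.arctan2(e1[1], e1[0])))
    else:
        side_a, side_b = l2, l1
        angle = float(np.degrees(np.arctan2(e2[1], e2[0])))
    angle = (angle + 180.0) % 180.0
    cx, cy = xy[:4].mean(axis=0)
    return RotatedRect(center=(float(cx), float(cy)),
                       side_a=max(side_a, 1.0), side_b=max(side_b, 1.0),
                       angle_deg=angle)


def measure_traits(objects: list[StomaObject], pixel_area: float = 1.0,
                   sample_id: str = "", surface: str = "") -> ImageTraits:
    """Per-object length/width from the minimum enclosing rectangle and
    area from pixel counts; count = number of objects."""
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    traits = ImageTraits(sample_id=sample_id, surface=surface)
    for obj in objects:
        rect = min_area_rect(obj.contour)
        traits.records.append(StomaRecord(
            length=rect.side_a, width=rect.side_b,
            area=obj.pixel_count * pixel_area,
            border_flag=obj.border_flag))
    return traits


def traits_from_mask(mask: np.ndarray, pixel_area: float = 1.0,
                     min_size: int = 50, class_policy: str = "stoma_union_pore",
                     sample_id: str = "", surface: str = "") -> ImageTraits:
    """Convenience: mask -> ImageTraits in one call."""
    objs = extract_stoma_objects(mask, min_size=min_size, class_policy=class_policy)
    return measure_traits(objs, pixel_area=pixel_area,
                          sample_id=sample_id, surface=surface)
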