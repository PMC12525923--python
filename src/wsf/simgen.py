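"""Synthetic stomatal micrographs with exact ground truth.

Real acquisitions are 1600 x 1200 px leaf-surface micrographs with roughly
19-23 stomata per field, each an elongated guard-cell complex (long axis
on the order of 120 px, short axis about 67 px) containing an interior
pore. The generator emulates those fields: non-overlapping rotated
ellipses over a textured, unevenly illuminated background. Each stoma is
rendered as two tangent guard-cell lobes flanking the pore; the label
mask marks the full guard-cell-complex ellipse as class 1 (wheat_stoma)
and the interior pore ellipse as class 2 (pore), with background 0, so
every pore pixel lies strictly inside its stoma ellipse.

All geometry is in pixel units, matching how the traits are reported.
Randomness flows exclusively from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["StomaFieldSpec", "SyntheticSample", "AugmentationSpec",
           "generate_sample", "augment_sample"]

BACKGROUND, STOMA, PORE = 0, 1, 2


@dataclass(frozen=True)
class StomaFieldSpec:
    """Parameters of one synthetic field.

    ``n_stomata`` may be a fixed count or an inclusive ``(lo, hi)`` range.
    Axis ranges are full axis lengths in pixels. ``pore_fraction`` scales
    the pore ellipse axes relative to the stoma axes. Intensity levels are
    8-bit gray values; ``background_texture = (amplitude, scale)`` is
    smoothed Gaussian noise, ``illumination_gradient`` the amplitude of a
    linear shading ramp across the frame.
    """

    image_height: int = 1200
    image_width: int = 1600
    n_stomata: int | tuple[int, int] = (19, 23)
    long_axis_range: tuple[float, float] = (100.0, 140.0)
    short_axis_range: tuple[float, float] = (55.0, 80.0)
    pore_fraction: float = 0.4
    orientation_deg: float = 0.0
    orientation_jitter_deg: float = 12.0
    background_texture: tuple[float, float] = (10.0, 6.0)
    illumination_gradient: float = 18.0
    background_level: float = 95.0
    stoma_level: float = 185.0
    pore_level: float = 240.0
    noise_sigma: float = 4.0
    min_gap: float = 6.0
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.long_axis_range, self.short_axis_range):
            if lo <= 0 or hi < lo:
                raise ValueError("axis ranges must be positive and ordered")
        if not (0.0 < self.pore_fraction < 1.0):
            raise ValueError("pore_fraction must lie in (0, 1)")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")

    @classmethod
    def desk(cls, seed: int = 0, n_stomata: int | tuple[int, int] = (2, 3)) -> "StomaFieldSpec":
        """Desk-scale 128 x 128 high-contrast field for CPU training runs."""
        return cls(image_height=128, image_width=128, n_stomata=n_stomata,
                   long_axis_range=(36.0, 48.0), short_axis_range=(20.0, 28.0),
                   pore_fraction=0.5, background_texture=(6.0, 4.0),
                   illumination_gradient=10.0, noise_sigma=3.0, seed=seed)


@dataclass
class SyntheticSample:
    """Paired micrograph, 3-class mask and the generating object list.

    ``objects`` rows are (center_x, center_y, long_axis, short_axis,
    angle_deg), the exact parameters used to rasterize each stoma.
    """

    image: np.ndarray   # (H, W, 3) uint8
    mask: np.ndarray    # (H, W) uint8 in {0, 1, 2}
    objects: list[tuple[float, float, float, float, float]] = field(default_factory=list)

    def validate(self) -> "SyntheticSample":
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        if not np.isin(self.mask, (0, 1, 2)).all():
            raise ValueError("mask labels outside {0, 1, 2}")
        return self


def _ellipse_interior(h, w, cx, cy, ax, ay, angle_deg, shrink=1.0):
    """Boolean (H, W) of pixels whose centers fall inside the ellipse."""
    pad = int(np.ceil(max(ax, ay) / 2)) + 2
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    t = np.deg2rad(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    inside = (u / (shrink * ax / 2)) ** 2 + (v / (shrink * ay / 2)) ** 2 <= 1.0
    out = np.zeros((h, w), dtype=bool)
    out[y0:y1, x0:x1] = inside
    return out


def generate_sample(spec: StomaFieldSpec, seed: int | None = None,
                    max_attempts_per_object: int = 400) -> SyntheticSample:
    """Draw one field. Identical (spec, seed) gives bit-identical output.

    Objects are placed by rejection sampling against a conservative
    circular-footprint overlap test; an over-dense spec that cannot be
    placed raises ``RuntimeError``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.image_height, spec.image_width
    if isinstance(spec.n_stomata, tuple):
        n = int(rng.integers(spec.n_stomata[0], spec.n_stomata[1] + 1))
    else:
        n = int(spec.n_stomata)

    objects: list[tuple[float, float, float, float, float]] = []
    occupied = np.zeros((h, w), dtype=bool)   # gap-dilated footprints
    for _ in range(n):
        placed = False
        for _attempt in range(max_attempts_per_object):
            long_ax = rng.uniform(*spec.long_axis_range)
            short_ax = min(rng.uniform(*spec.short_axis_range), long_ax)
            angle = spec.orientation_deg + rng.uniform(
                -spec.orientation_jitter_deg, spec.orientation_jitter_deg)
            r = long_ax / 2
            if 2 * r + 2 >= min(h, w):
                continue
            cx = rng.uniform(r + 1, w - r - 1)
            cy = rng.uniform(r + 1, h - r - 1)
            footprint = _ellipse_interior(h, w, cx, cy,
                                          long_ax + 2 * spec.min_gap,
                                          short_ax + 2 * spec.min_gap, angle)
            if not (footprint & occupied).any():
                occupied |= footprint
                objects.append((cx, cy, long_ax, short_ax, angle))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place stoma {len(objects) + 1}/{n}: spec too dense "
                f"for a {w}x{h} frame")

    # background: base level + smoothed texture + illumination ramp
    amp, scale = spec.background_texture
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), scale)
    if texture.std() > 0:
        texture = texture / texture.std() * amp
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (xx * np.cos(theta) + yy * np.sin(theta))
    ramp = (ramp - ramp.mean()) / max(np.abs(ramp).max(), 1.0) * spec.illumination_gradient
    img = spec.background_level + texture + ramp

    mask = np.zeros((h, w), dtype=np.uint8)
    for cx, cy, long_ax, short_ax, angle in objects:
        stoma = _ellipse_interior(h, w, cx, cy, long_ax, short_ax, angle)
        pore = _ellipse_interior(h, w, cx, cy, spec.pore_fraction * long_ax,
                                 spec.pore_fraction * short_ax, angle)
        mask[stoma] = STOMA
        mask[pore & stoma] = PORE
        # image: two tangent guard-cell lobes flanking the pore
        t = np.deg2rad(angle)
        off = short_ax / 4
        level = spec.stoma_level + rng.uniform(-8, 8)
        img[stoma] = level - 6.0
        for sgn in (-1.0, 1.0):
            lobe = _ellipse_interior(h, w, cx - sgn * off * np.sin(t),
                                     cy + sgn * off * np.cos(t),
                                     long_ax, short_ax / 2, angle)
            img[lobe & stoma] = level + sgn * 3.0
        img[pore & stoma] = spec.pore_level

    img = ndimage.gaussian_filter(img, 0.7)
    img = img + rng.standard_normal((h, w)) * spec.noise_sigma
    img = np.clip(img, 0, 255)
    rgb = np.stack([img * 0.96, img, img * 0.92], axis=-1)
    return SyntheticSample(image=np.clip(rgb, 0, 255).astype(np.uint8),
                           mask=mask, objects=objects).validate()


@dataclass(frozen=True)
class AugmentationSpec:
    """Stochastic augmentation: rotation, scaling, flips, elastic
    deformation and noise injection, applied with identical geometric
    parameters to image and mask (nearest-neighbour for labels)."""

    rotation_range_deg: float = 30.0
    scale_range: tuple[float, float] = (0.85, 1.15)
    elastic_spacing: float = 64.0
    elastic_sigma: float = 2.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    noise_sigma: float = 4.0
    expansion_factor: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale_range must be positive and ordered")


def _warp(sample: SyntheticSample, angle: float, scl: float,
          hflip: bool, vflip: bool, disp: tuple[np.ndarray, np.ndarray] | None,
          noise: np.ndarray | None) -> SyntheticSample:
    img = sample.image.astype(np.float64)
    mask = sample.mask
    h, w = mask.shape

    if hflip:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if vflip:
        img, mask = img[::-1], mask[::-1]

    exact90 = (angle % 90 == 0) and scl == 1.0 and disp is None
    if exact90:
        k = int(angle // 90) % 4
        if k and h == w:
            img, mask = np.rot90(img, k), np.rot90(mask, k)
            angle_left = 0.0
        elif k:
            angle_left = angle
            exact90 = False
        else:
            angle_left = 0.0
    if not exact90:
        t = np.deg2rad(angle)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        dx, dy = xx - cx, yy - cy
        # inverse map: output -> input (rotate by -angle, scale by 1/s)
        sx = (dx * np.cos(t) + dy * np.sin(t)) / scl + cx
        sy = (-dx * np.sin(t) + dy * np.cos(t)) / scl + cy
        if disp is not None:
            sx = sx + disp[0]
            sy = sy + disp[1]
        fill = float(np.median(img))
        img = np.stack([
            ndimage.map_coordinates(img[..., c], [sy, sx], order=1,
                                    mode="constant", cval=fill)
            for c in range(3)], axis=-1)
        mask = ndimage.map_coordinates(mask, [sy, sx], order=0,
                                       mode="constant", cval=BACKGROUND)

    mask = np.ascontiguousarray(mask)
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("mask resampling produced labels outside {0, 1, 2}")
    img = np.ascontiguousarray(img)
    if noise is not None:
        img = img + noise
    img = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSample(image=img, mask=mask.astype(np.uint8),
                           objects=list(sample.objects))


def augment_sample(sample: SyntheticSample, aug: AugmentationSpec,
                   seed: int | None = None) -> SyntheticSample:
    """One random augmentation draw; geometry is shared by image and mask.

    Exposed regions after rotation/scaling are filled with background
    (class 0) in the mask and the median image intensity. Note the object
    list is carried over untransformed and refers to the source geometry.
    """
    rng = np.random.default_rng(aug.seed if seed is None else seed)
    angle = rng.uniform(-aug.rotation_range_deg, aug.rotation_range_deg)
    scl = rng.uniform(*aug.scale_range)
    hflip = rng.random() < aug.hflip_prob
    vflip = rng.random() < aug.vflip_prob
    disp = None
    if aug.elastic_sigma > 0:
        h, w = sample.mask.shape
        gh = max(int(h / aug.elastic_spacing), 2) + 1
        gw = max(int(w / aug.elastic_spacing), 2) + 1
        coarse = rng.standard_normal((2, gh, gw)) * aug.elastic_sigma
        zoom = (h / gh, w / gw)
        dxf = ndimage.zoom(coarse[0], zoom, order=1)[:h, :w]
        dyf = ndimage.zoom(coarse[1], zoom, order=1)[:h, :w]
        dxf = np.pad(dxf, ((0, h - dxf.shape[0]), (0, w - dxf.shape[1])), mode="edge")
        dyf = np.pad(dyf, ((0, h - dyf.shape[0]), (0, w - dyf.shape[1])), mode="edge")
        disp = (dxf, dyf)
    noise = None
    if aug.noise_sigma > 0:
        noise = rng.standard_normal(sample.image.shape) * aug.noise_sigma
    return _warp(sample, angle, scl, hflip, vflip, disp, noise)


def expand_dataset(samples: list[SyntheticSample], aug: AugmentationSpec,
                   seed: int = 0) -> list[tuple[int, SyntheticSample]]:
    """Expansion by ``aug.expansion_factor``: each source yields itself
    plus (factor - 1) augmented variants. Returns (source_index, sample)
    pairs so callers can keep augmented siblings in one split partition."""
    out: list[tuple[int, SyntheticSample]] = []
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(samples))
    for i, s in enumerate(samples):
        out.append((i, s))
        for k in range(aug.expansion_factor - 1):
            out.append((i, augment_sample(s, aug, seed=int(base[i]) + k)))
    return out
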