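"""Microscopy preprocessing and rigid MSI-to-microscopy registration.

Images live on physical grids: pixel (row, col) has its center at
``((col + 0.5) * pixel_size, (row + 0.5) * pixel_size)`` um, origin at the
top-left corner, y increasing downward.  A :class:`TransformSpec` maps
source-frame physical coordinates into target-frame physical coordinates by
rotating about the source image center (counter-clockwise in display sense),
scaling, and translating:

    p_tgt = scale * R(theta) @ (p_src - c_src) + c_src + (dx, dy)

Resampling is bilinear (the "linear interpolation" integration step);
samples falling outside the source image are 0 and excluded via a validity
mask so downstream statistics can ignore them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage
from skimage.restoration import ellipsoid_kernel, rolling_ball


@dataclass(frozen=True)
class TransformSpec:
    """Rigid 2D alignment between two physical frames.

    dx, dy : um translation applied after rotation.
    theta : degrees, counter-clockwise about the source image center.
    scale : physical magnification between frames (um-per-um; pixel sizes
        already carry grid resolution, so this is normally 1).
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not (-180.0 < self.theta <= 180.0):
            raise ValueError(f"theta must lie in (-180, 180], got {self.theta}")

    def inverse(self, source_shape: tuple[int, int], source_pixel_size: float) -> "TransformSpec":
        """Inverse transform, valid for the given source geometry.

        The rotation pivot is the source image center, so the inverse
        depends on the source extent: it undoes translation, scale, and
        rotation about that same physical point.
        """
        h, w = source_shape
        c = np.array([w * source_pixel_size / 2.0, h * source_pixel_size / 2.0])
        r_inv = _rotation_matrix(-self.theta)
        # forward: p' = s R (p - c) + c + t  =>  p = R^-1 (p' - c - t)/s + c
        # rewrite as p = s' R' (p' - c) + c + t' with s' = 1/s, R' = R^-1:
        t_prime = (r_inv @ (-np.array([self.dx, self.dy])) / self.scale)
        theta_inv = -self.theta if self.theta != 180.0 else 180.0
        return TransformSpec(
            dx=float(t_prime[0]), dy=float(t_prime[1]), theta=theta_inv, scale=1.0 / self.scale
        )


@dataclass
class GrayImage:
    """Single-channel image with physical pixel size.

    ``bit_depth`` is 8, 16, or the string ``"float"``; values must sit in
    the declared range.
    """

    grid: np.ndarray
    bit_depth: int | str = "float"
    pixel_size: float = 1.0
    valid: np.ndarray | None = None  # False where resampling left the source

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("GrayImage grid must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bit_depth == 8 and self.grid.size and (self.grid.min() < 0 or self.grid.max() > 255):
            raise ValueError("8-bit image values must lie in [0, 255]")
        if self.bit_depth == 16 and self.grid.size and (self.grid.min() < 0 or self.grid.max() > 65535):
            raise ValueError("16-bit image values must lie in [0, 65535]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    """Display-sense CCW rotation in (x, y-down) coordinates."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s], [-s, c]])


# ---------------------------------------------------------------------------
# Preprocessing


def to_8bit_autocontrast(
    image: GrayImage, p_low: float = 0.35, p_high: float = 99.65
) -> GrayImage:
    """Auto brightness/contrast to 8 bits.

    The [p_low, p_high] percentile window is stretched linearly onto
    [0, 255] with clipping, emulating the usual interactive "auto" contrast.
    A constant image has no contrast to stretch and maps to all zeros.
    """
    grid = np.asarray(image.grid, dtype=float)
    if grid.size == 0:
        raise ValueError("cannot autocontrast an empty image")
    lo, hi = np.percentile(grid, [p_low, p_high])
    if hi <= lo:
        out = np.zeros_like(grid, dtype=np.uint8)
    else:
        out = np.clip((grid - lo) / (hi - lo) * 255.0, 0, 255)
        out = np.rint(out).astype(np.uint8)
    return GrayImage(grid=out, bit_depth=8, pixel_size=image.pixel_size)


def subtract_background(
    image: GrayImage, radius: int = 25, paraboloid: bool = True
) -> GrayImage:
    """Rolling-ball / sliding-paraboloid background subtraction.

    The background is a grayscale opening with a ball (or paraboloid-like
    ellipsoid) structuring element of the given radius; subtracting it
    flattens slowly varying illumination while features smaller than the
    element survive.  The result is clamped at zero.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    grid = np.asarray(image.grid, dtype=float)
    if radius >= max(grid.shape):
        raise ValueError(
            f"radius {radius} exceeds image extent {grid.shape}"
        )
    if paraboloid:
        kernel = ellipsoid_kernel((2 * radius + 1, 2 * radius + 1), radius)
        background = rolling_ball(grid, kernel=kernel)
    else:
        background = rolling_ball(grid, radius=radius)
    out = np.clip(grid - background, 0, None)
    return GrayImage(grid=out, bit_depth="float", pixel_size=image.pixel_size)


# ---------------------------------------------------------------------------
# Rigid transform and resampling


def apply_rigid_transform(
    image: GrayImage,
    transform: TransformSpec,
    output_shape: tuple[int, int],
    output_pixel_size: float,
) -> GrayImage:
    """Resample a source image onto a target grid through a rigid transform.

    Each output pixel center is mapped through the inverse transform into
    the source physical frame and sampled bilinearly; samples outside the
    source are 0 and marked invalid in the result's ``valid`` mask.
    """
    src = np.asarray(image.grid, dtype=float)
    h_src, w_src = src.shape
    ps_src = image.pixel_size
    c_src = np.array([w_src * ps_src / 2.0, h_src * ps_src / 2.0])
    t = np.array([transform.dx, transform.dy])

    rows, cols = np.mgrid[0 : output_shape[0], 0 : output_shape[1]]
    x_tgt = (cols + 0.5) * output_pixel_size
    y_tgt = (rows + 0.5) * output_pixel_size

    r_inv = _rotation_matrix(-transform.theta)
    dxy = np.stack([x_tgt - c_src[0] - t[0], y_tgt - c_src[1] - t[1]])
    x_src = (r_inv[0, 0] * dxy[0] + r_inv[0, 1] * dxy[1]) / transform.scale + c_src[0]
    y_src = (r_inv[1, 0] * dxy[0] + r_inv[1, 1] * dxy[1]) / transform.scale + c_src[1]

    col_src = x_src / ps_src - 0.5
    row_src = y_src / ps_src - 0.5
    out = ndimage.map_coordinates(src, [row_src, col_src], order=1, mode="constant", cval=0.0)
    valid = (
        (row_src >= 0) & (row_src <= h_src - 1) & (col_src >= 0) & (col_src <= w_src - 1)
    )
    return GrayImage(grid=out, bit_depth="float", pixel_size=output_pixel_size, valid=valid)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalized cross-correlation over a boolean mask."""
    if mask.sum() < 2:
        return -np.inf
    av = a[mask].astype(float)
    bv = b[mask].astype(float)
    av -= av.mean()
    bv -= bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return -np.inf
    return float((av * bv).sum() / denom)


def estimate_transform(
    moving: GrayImage,
    fixed: GrayImage,
    dx_range: tuple[float, float, float],
    dy_range: tuple[float, float, float],
    theta_range: tuple[float, float, float],
    refine_levels: int = 2,
) -> tuple[TransformSpec, float]:
    """Recover a rigid transform by grid search maximizing NCC.

    Each range is (min, max, step) in um for dx/dy and degrees for theta.
    The full grid is searched, then ``refine_levels`` rounds of halved-step
    local search around the best candidate; ``refine_levels=0`` is an exact
    exhaustive enumeration of the stated grid.  Returns the best transform
    and its correlation score.  The score is invariant to affine intensity
    rescaling of either image.
    """

    def axis(rng: tuple[float, float, float]) -> np.ndarray:
        lo, hi, step = rng
        if step <= 0 or hi < lo:
            raise ValueError(f"invalid search range {rng}")
        return np.arange(lo, hi + step / 2, step)

    def score(dx: float, dy: float, theta: float) -> float:
        spec = TransformSpec(dx=dx, dy=dy, theta=theta)
        warped = apply_rigid_transform(moving, spec, fixed.shape, fixed.pixel_size)
        return _ncc(warped.grid, np.asarray(fixed.grid, float), warped.valid)

    dxs, dys, thetas = axis(dx_range), axis(dy_range), axis(theta_range)
    if dxs.size == 0 or dys.size == 0 or thetas.size == 0:
        raise ValueError("empty search range")

    best = (-np.inf, 0.0, 0.0, 0.0)
    for theta in thetas:
        for dy in dys:
            for dx in dxs:
                s = score(dx, dy, theta)
                if s > best[0]:
                    best = (s, dx, dy, theta)

    steps = np.array([dx_range[2], dy_range[2], theta_range[2]], dtype=float)
    for _ in range(refine_levels):
        steps = steps / 2.0
        center = np.array([best[1], best[2], best[3]])
        for dth in (-steps[2], 0, steps[2]):
            for ddy in (-steps[1], 0, steps[1]):
                for ddx in (-steps[0], 0, steps[0]):
                    cand = center + np.array([ddx, ddy, dth])
                    s = score(*cand)
                    if s > best[0]:
                        best = (s, *cand)

    return TransformSpec(dx=best[1], dy=best[2], theta=best[3]), best[0]


# ---------------------------------------------------------------------------
# Alignment-file I/O (per-section transforms)


def write_alignment(transforms: dict[str, TransformSpec], path: str | Path) -> Path:
    """Store per-section transforms as YAML (or JSON by extension)."""
    path = Path(path)
    payload = {
        section: {"dx": t.dx, "dy": t.dy, "theta": t.theta, "scale": t.scale}
        for section, t in transforms.items()
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_alignment(path: str | Path) -> dict[str, TransformSpec]:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return {
        str(section): TransformSpec(
            dx=float(v["dx"]), dy=float(v["dy"]), theta=float(v["theta"]),
            scale=float(v.get("scale", 1.0)),
        )
        for section, v in payload.items()
    }
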