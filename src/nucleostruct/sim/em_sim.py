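"""Synthetic immunogold EM fields with ground-truth particle tables.

Gold particles are rendered as anti-aliased uniform dark disks (no PSF) on a
textured bright background; the two fixed size classes are 12 nm and 6 nm in
diameter. A minimum center-to-center separation is enforced across *all*
placed particles (a superset of the per-class requirement): a 6 nm particle
rendered on top of a 12 nm one would be unresolvable by construction and the
two-pass exclusion would discard it anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..immunogold import EmField, LARGE_NM, SMALL_NM

_MAX_ATTEMPTS = 20_000


class PlacementError(RuntimeError):
    """Requested particle density cannot be placed under min_separation."""


@dataclass(frozen=True)
class EllipseRoi:
    """Elliptical nucleolar outline: center (row, col) and semi-axes in px."""

    center_y: float
    center_x: float
    semi_y: float
    semi_x: float

    def mask(self, shape) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return ((yy - self.center_y) / self.semi_y) ** 2 + (
            (xx - self.center_x) / self.semi_x
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class EmSimParams:
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 2.0  # nm/px
    roi: EllipseRoi | None = None  # default: centered ellipse, 0.35 * shape semi-axes
    n_large: int = 30  # 12 nm particles inside the ROI
    n_small: int = 60  # 6 nm particles inside the ROI
    n_outside: int = 20  # total outside (ceil half large, floor half small)
    background_level: float = 200.0
    background_noise_sd: float = 8.0
    particle_contrast: float = 120.0  # particles darker than background
    min_separation: float = 30.0  # nm, center-to-center, all particles
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.n_large, self.n_small, self.n_outside) < 0:
            raise ValueError("particle counts must be non-negative")

    def resolved_roi(self) -> EllipseRoi:
        if self.roi is not None:
            return self.roi
        h, w = self.image_shape
        return EllipseRoi(h / 2.0, w / 2.0, 0.35 * h, 0.35 * w)


def _place(rng, region_mask, n, placed_px, min_sep_px, margin_px):
    """Rejection-sample n centers inside region_mask respecting separation."""
    h, w = region_mask.shape
    pts = []
    for _ in range(n):
        for attempt in range(_MAX_ATTEMPTS):
            y = rng.uniform(margin_px, h - 1 - margin_px)
            x = rng.uniform(margin_px, w - 1 - margin_px)
            if not region_mask[int(round(y)), int(round(x))]:
                continue
            if placed_px:
                arr = np.asarray(placed_px)
                if np.min(np.hypot(arr[:, 0] - y, arr[:, 1] - x)) < min_sep_px:
                    continue
            placed_px.append((y, x))
            pts.append((y, x))
            break
        else:
            raise PlacementError(
                f"could not place particle {len(pts) + 1}/{n} after {_MAX_ATTEMPTS} attempts; "
                "reduce counts or min_separation"
            )
    return pts


def _render_disk(img, y, x, radius_px, depth):
    """Subtract an anti-aliased uniform dark disk (linear edge ramp, ~1 px)."""
    r_out = int(np.ceil(radius_px + 1))
    y0, y1 = max(0, int(y) - r_out), min(img.shape[0], int(y) + r_out + 1)
    x0, x1 = max(0, int(x) - r_out), min(img.shape[1], int(x) + r_out + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - y, xx - x)
    cov = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    img[y0:y1, x0:x1] -= depth * cov


def simulate_em_image(params: EmSimParams) -> tuple[EmField, pd.DataFrame]:
    """Render one field and return (EmField, ground-truth particle table).

    The truth table has columns x_px, y_px, size_class ('12nm'/'6nm'), in_roi.
    Identical seeds reproduce placement bit-exactly; unplaceable densities
    raise PlacementError rather than silently truncating.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    roi = params.resolved_roi()
    roi_mask = roi.mask(params.image_shape)
    min_sep_px = params.min_separation / params.pixel_size
    margin = LARGE_NM / params.pixel_size  # keep whole disks inside the frame

    placed: list[tuple[float, float]] = []
    rows = []
    n_out_large = (params.n_outside + 1) // 2
    n_out_small = params.n_outside // 2
    outside = ~roi_mask
    for region, n, cls in (
        (roi_mask, params.n_large, "12nm"),
        (roi_mask, params.n_small, "6nm"),
        (outside, n_out_large, "12nm"),
        (outside, n_out_small, "6nm"),
    ):
        if n == 0:
            continue
        if not region.any():
            raise PlacementError("placement region is empty")
        for y, x in _place(rng, region, n, placed, min_sep_px, margin):
            rows.append({"x_px": x, "y_px": y, "size_class": cls,
                         "in_roi": bool(roi_mask[int(round(y)), int(round(x))])})

    img = np.full((h, w), params.background_level, dtype=float)
    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, size=(h, w))
    for r in rows:
        d_nm = LARGE_NM if r["size_class"] == "12nm" else SMALL_NM
        _render_disk(img, r["y_px"], r["x_px"], (d_nm / 2.0) / params.pixel_size,
                     params.particle_contrast)

    truth = pd.DataFrame(rows, columns=["x_px", "y_px", "size_class", "in_roi"])
    field = EmField(image=img, pixel_size=params.pixel_size, roi_mask=roi_mask,
                    image_id=f"sim{params.seed}")
    return field, truth
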