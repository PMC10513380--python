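"""Two-pass immunogold particle detection and density estimation.

Gold particles of two diameters (12 nm and 6 nm) are localized with a
Laplacian-of-Gaussian blob detector, sign-adjusted so dark blobs give positive
response, with sigma_px = (diameter_nm / pixel_size) / (2 * sqrt(2)) — the
standard LoG blob-radius relation r = sigma * sqrt(2). The larger class is
found first; exclusion zones around accepted 12 nm particles prevent them from
re-detecting as 6 nm hits in the second pass. Detections are labeled against
the nucleolar ROI mask and densities reported as particles per nm^2 of ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from ._stats import GroupComparison, two_sample_t

LARGE_NM = 12.0
SMALL_NM = 6.0
# Exclusion default: 1.5 x large-particle radius + small-particle radius.
DEFAULT_EXCLUSION_NM = 1.5 * (LARGE_NM / 2.0) + SMALL_NM / 2.0
_MAD_K = 5.0

PARTICLE_COLUMNS = ["x_px", "y_px", "size_class", "response", "in_roi"]


@dataclass(frozen=True)
class EmField:
    """One EM image with physical pixel size and a nucleolar ROI mask."""

    image: np.ndarray
    pixel_size: float  # nm/px
    roi_mask: np.ndarray
    image_id: str = "field0"

    def __post_init__(self):
        object.__setattr__(self, "image", np.asarray(self.image, dtype=float))
        object.__setattr__(self, "roi_mask", np.asarray(self.roi_mask, dtype=bool))
        if self.roi_mask.shape != self.image.shape:
            raise ValueError("roi_mask must match image shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class DensityResult:
    image_id: str
    count_12: int
    count_6: int
    roi_area_nm2: float
    density_12: float  # particles / nm^2
    density_6: float
    condition: str = ""


def log_sigma_px(diameter_nm: float, pixel_size: float) -> float:
    return (diameter_nm / pixel_size) / (2.0 * np.sqrt(2.0))


def log_response(image: np.ndarray, diameter_nm: float, pixel_size: float) -> np.ndarray:
    """Scale-normalized LoG response, positive on dark (gold) blobs."""
    sigma = log_sigma_px(diameter_nm, pixel_size)
    # gaussian_laplace is positive at intensity minima; sigma^2 normalizes scale
    return sigma**2 * ndi.gaussian_laplace(np.asarray(image, dtype=float), sigma)


def log_detect(
    image: np.ndarray,
    diameter_nm: float,
    pixel_size: float,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Local maxima of the LoG response above threshold, strongest first.

    threshold=None uses a robust background estimate, median + 5*MAD of the
    response. Coordinates are 0-based integer pixel centers; ordering is by
    descending response with (y, x) tie-break for determinism.
    """
    if diameter_nm < 2.0 * pixel_size:
        raise ValueError(
            f"diameter {diameter_nm} nm is below the resolvable limit "
            f"2 * pixel_size = {2 * pixel_size} nm"
        )
    resp = log_response(image, diameter_nm, pixel_size)
    return _peaks_from_response(resp, threshold)


def _robust_threshold(resp: np.ndarray) -> float:
    med = float(np.median(resp))
    mad = float(np.median(np.abs(resp - med)))
    if mad == 0.0:  # noise-free background: any strictly positive peak
        return med + 1e-9
    return med + _MAD_K * 1.4826 * mad


def _peaks_from_response(resp: np.ndarray, threshold: float | None) -> pd.DataFrame:
    if threshold is None:
        threshold = _robust_threshold(resp)
    peaks = peak_local_max(resp, min_distance=1, threshold_abs=threshold, exclude_border=False)
    if peaks.size == 0:
        return pd.DataFrame(columns=["x_px", "y_px", "response"]).astype(
            {"x_px": int, "y_px": int, "response": float}
        )
    responses = resp[peaks[:, 0], peaks[:, 1]]
    df = pd.DataFrame({"x_px": peaks[:, 1], "y_px": peaks[:, 0], "response": responses})
    return df.sort_values(
        ["response", "y_px", "x_px"], ascending=[False, True, True]
    ).reset_index(drop=True)


def exclude_around(
    candidates: pd.DataFrame, anchors: pd.DataFrame, radius_nm: float, pixel_size: float
) -> pd.DataFrame:
    """Drop candidates strictly closer than radius_nm to any anchor center.

    The boundary is open: a candidate at exactly radius_nm is retained.
    Candidate order is preserved; empty anchors is the identity.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive")
    if len(anchors) == 0 or len(candidates) == 0:
        return candidates.reset_index(drop=True)
    r_px = radius_nm / pixel_size
    cy = candidates["y_px"].to_numpy(float)[:, None]
    cx = candidates["x_px"].to_numpy(float)[:, None]
    ay = anchors["y_px"].to_numpy(float)[None, :]
    ax = anchors["x_px"].to_numpy(float)[None, :]
    dmin = np.hypot(cy - ay, cx - ax).min(axis=1)
    return candidates[dmin >= r_px].reset_index(drop=True)


def _suppress_same_class(cands: pd.DataFrame, diameter_nm: float, pixel_size: float) -> pd.DataFrame:
    """Greedy duplicate suppression: highest response wins within one diameter."""
    d_px = diameter_nm / pixel_size
    kept_y: list[float] = []
    kept_x: list[float] = []
    kept_idx = []
    for idx, row in cands.iterrows():
        if kept_y:
            d = np.hypot(np.asarray(kept_y) - row["y_px"], np.asarray(kept_x) - row["x_px"])
            if np.min(d) < d_px:  # open boundary: strictly-less removes
                continue
        kept_y.append(row["y_px"])
        kept_x.append(row["x_px"])
        kept_idx.append(idx)
    return cands.loc[kept_idx].reset_index(drop=True)


def detect_two_pass(
    field: EmField,
    thresholds: dict[str, float] | None = None,
    exclusion_radius_nm: float = DEFAULT_EXCLUSION_NM,
) -> pd.DataFrame:
    """Detect 12 nm then 6 nm particles with exclusion zones around the former.

    Returns a ParticleSet table (x_px, y_px, size_class, response, in_roi),
    deterministic for fixed input. Size classes are separated by scale
    selection: the first pass keeps only maxima whose scale-normalized
    response at the 12 nm scale exceeds the response at the 6 nm scale, the
    standard criterion for assigning a blob to its characteristic scale.
    ROI masking is applied after detection so outside-ROI hits remain
    inspectable; densities later use in_roi only.
    """
    thresholds = thresholds or {}
    resp_large = log_response(field.image, LARGE_NM, field.pixel_size)
    resp_small = log_response(field.image, SMALL_NM, field.pixel_size)
    large = _peaks_from_response(resp_large, thresholds.get("12nm"))
    if len(large):
        ys, xs = large["y_px"].to_numpy(int), large["x_px"].to_numpy(int)
        large = large[resp_large[ys, xs] > resp_small[ys, xs]].reset_index(drop=True)
    large = _suppress_same_class(large, LARGE_NM, field.pixel_size)
    small = _peaks_from_response(resp_small, thresholds.get("6nm"))
    small = exclude_around(small, large, exclusion_radius_nm, field.pixel_size)
    small = _suppress_same_class(small, SMALL_NM, field.pixel_size)
    large = large.assign(size_class="12nm")
    small = small.assign(size_class="6nm")
    out = pd.concat([large, small], ignore_index=True)
    if len(out) == 0:
        return pd.DataFrame(columns=PARTICLE_COLUMNS)
    ys = out["y_px"].to_numpy(int)
    xs = out["x_px"].to_numpy(int)
    out["in_roi"] = field.roi_mask[ys, xs]
    return out[PARTICLE_COLUMNS]


def density(field: EmField, particles: pd.DataFrame, condition: str = "") -> DensityResult:
    """Particles per nm^2 of ROI for each size class (in-ROI detections only)."""
    roi_px = int(field.roi_mask.sum())
    if roi_px == 0:
        raise ValueError("empty ROI: cannot compute density")
    area = roi_px * field.pixel_size**2
    inside = particles[particles["in_roi"]] if len(particles) else particles
    c12 = int((inside["size_class"] == "12nm").sum()) if len(inside) else 0
    c6 = int((inside["size_class"] == "6nm").sum()) if len(inside) else 0
    return DensityResult(
        image_id=field.image_id,
        count_12=c12,
        count_6=c6,
        roi_area_nm2=float(area),
        density_12=c12 / area,
        density_6=c6 / area,
        condition=condition,
    )


def compare_densities(
    group_a: list[DensityResult], group_b: list[DensityResult], *, welch: bool = False
) -> dict[str, GroupComparison]:
    """Per-class two-sample t test on densities across images (mean +/- SEM)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs n >= 2 images")
    out = {}
    for cls, attr in (("12nm", "density_12"), ("6nm", "density_6")):
        va = [getattr(d, attr) for d in group_a]
        vb = [getattr(d, attr) for d in group_b]
        out[cls] = two_sample_t(va, vb, welch=welch, label=f"density_{cls}")
    return out
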