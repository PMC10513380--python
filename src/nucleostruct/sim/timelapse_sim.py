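"""Synthetic 3-channel nucleolar time-lapse movies with per-cell ground truth.

Each cell occupies one tile of a mosaic field and carries three channels
(UBF: fibrillar-center puncta, FBL: dense-fibrillar-component puncta, NPM1:
granular component). Control cells hold their puncta counts and NPM1 shape
stationary up to noise. Pol-I-inhibited cells condense: UBF/FBL puncta merge
at condensation_rate per frame and the NPM1 component shrinks and rounds up
(area down, sphericity up, both monotone in expectation). A division event
dissolves all nucleolar components for one frame; afterwards the cell either
reassembles (1 component) or, with probability fragmentation_probability,
scatters into n_fragments small dispersed puncta — the fragmented phenotype.

Movies are rendered in 2-D+t; shapes are axis-aligned ellipses and disks so
that per-frame truth (component counts, NPM1 area and circularity) is exact
and analytic. Rendering applies a light Gaussian blur (anti-aliasing stand-in
for optics) and i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

CHANNELS = ("UBF", "FBL", "NPM1")

_BLUR_SIGMA = 0.7
_PUNCTUM_R = 2.0  # px
_FRAGMENT_R = 2.5  # px


def ellipse_circularity(aspect: float) -> float:
    """Circularity 4*pi*A/P^2 of an ellipse with given aspect ratio (>= 1).

    Perimeter via Ramanujan's approximation; depends on aspect only.
    """
    a, b = aspect, 1.0
    h = ((a - b) / (a + b)) ** 2
    p = np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))
    return float(4.0 * np.pi * (np.pi * a * b) / p**2)


@dataclass(frozen=True)
class TimelapseSimParams:
    """Study conditions: 10-minute frames for 5 hours (31 frames)."""

    n_cells: int = 12
    n_frames: int = 31
    frame_interval: float = 10.0  # minutes
    condition: str = "control"  # "control" | "inhibited"
    initial_ubf: int = 6
    initial_fbl: int = 5
    condensation_rate: float = 0.15  # per-frame merge probability (inhibited)
    division_frame: int | None = None  # common frame; None = random per dividing cell
    divide_fraction: float = 0.0  # fraction of cells that divide
    fragmentation_probability: float = 0.0
    n_fragments: int = 8
    noise_sd: float = 0.02
    pixel_size: float = 0.2  # um/px
    tile_px: int = 48
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fragmentation_probability <= 1.0):
            raise ValueError("fragmentation_probability must be in [0, 1]")
        if not (0.0 <= self.divide_fraction <= 1.0):
            raise ValueError("divide_fraction must be in [0, 1]")
        if self.condition not in ("control", "inhibited"):
            raise ValueError("condition must be 'control' or 'inhibited'")
        if self.n_cells < 0 or self.n_frames < 2:
            raise ValueError("need n_cells >= 0 and n_frames >= 2")


@dataclass(frozen=True)
class TimelapseMovie:
    """Rendered movie, TCYX layout, plus nucleus label masks per frame."""

    data: np.ndarray  # (T, C, Y, X) float32
    channels: tuple[str, ...]
    pixel_size: float  # um/px
    frame_interval: float  # minutes
    nucleus_masks: np.ndarray  # (T, Y, X) int32 labels; label i+1 = cell i


@dataclass(frozen=True)
class PhenotypeTruth:
    """Ground truth: final phenotype per cell and per-frame component truth."""

    phenotypes: pd.DataFrame  # cell_id, phenotype, divides, division_frame
    frames: pd.DataFrame  # cell_id, frame, n_ubf, n_fbl, n_npm1, npm1_area_um2, npm1_sphericity


# ---------------------------------------------------------------- cell model


def _place_puncta(rng, n, region_r, min_sep, existing=None):
    pts = [] if existing is None else list(existing)
    out = []
    for _ in range(n):
        for _attempt in range(5000):
            r = region_r * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            y, x = r * np.sin(th), r * np.cos(th)
            if pts and np.min(np.hypot(np.asarray([p[0] for p in pts]) - y,
                                       np.asarray([p[1] for p in pts]) - x)) < min_sep:
                continue
            pts.append((y, x))
            out.append((y, x))
            break
        else:
            raise RuntimeError("could not place puncta; lower counts or separation")
    return out


def _merge_nearest(puncta):
    """Merge the two nearest puncta; the product conserves area."""
    n = len(puncta)
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(puncta[i][0] - puncta[j][0], puncta[i][1] - puncta[j][1])
            if best is None or d < best[0]:
                best = (d, i, j)
    _, i, j = best
    yi, xi, ri = puncta[i]
    yj, xj, rj = puncta[j]
    merged = ((yi + yj) / 2, (xi + xj) / 2, float(np.hypot(ri, rj)))
    return [p for k, p in enumerate(puncta) if k not in (i, j)] + [merged]


class _CellTruth:
    """Frame-by-frame parametric state of one simulated cell."""

    def __init__(self, cell_id, params: TimelapseSimParams, rng, divides, division_frame,
                 fragmented):
        self.cell_id = cell_id
        self.divides = divides
        self.division_frame = division_frame
        self.fragmented = fragmented
        p = params
        F = p.n_frames
        inhibited = p.condition == "inhibited"
        nuc_r = 0.40 * p.tile_px

        # nucleus drift (random walk, small vs the tracking gate)
        steps = rng.normal(0, 0.4, size=(F, 2))
        self.centers = np.cumsum(steps, axis=0)

        # NPM1 base ellipse: aspect 2 control, condensing to a circle when inhibited
        a0 = 0.21 * p.tile_px  # semi-major, px
        base_area = np.pi * a0 * (a0 / 2.0)

        # separation is only enforced within a channel: UBF and FBL mark
        # different compartments and may overlap spatially
        ubf = [(y, x, _PUNCTUM_R) for (y, x) in _place_puncta(rng, p.initial_ubf, 0.6 * nuc_r, 6.0)]
        fbl = [(y, x, _PUNCTUM_R) for (y, x) in _place_puncta(rng, p.initial_fbl, 0.6 * nuc_r, 6.0)]

        self.nuc_r = nuc_r
        self.frames = []  # per frame: dict(ubf=[(y,x,r)], fbl=[...], npm1=[shape...])
        for f in range(F):
            if divides and f == division_frame:
                self.frames.append({"ubf": [], "fbl": [], "npm1": []})
                continue
            if divides and f > division_frame:
                if f == division_frame + 1:
                    if fragmented:
                        frag = _place_puncta(rng, p.n_fragments, 0.75 * nuc_r, 7.0)
                        self._post = {
                            "npm1": [("disk", y, x, _FRAGMENT_R) for (y, x) in frag],
                            "ubf": [(y, x, _PUNCTUM_R) for (y, x) in
                                    _place_puncta(rng, max(2, p.initial_ubf // 2),
                                                  0.75 * nuc_r, 6.0)],
                            "fbl": [(y, x, _PUNCTUM_R) for (y, x) in
                                    _place_puncta(rng, max(2, p.initial_fbl // 2),
                                                  0.75 * nuc_r, 6.0)],
                        }
                    else:
                        # reassembly into one component; inhibited cells condense
                        if inhibited:
                            a = 0.70 * a0
                            shape = ("ellipse", 0.0, 0.0, a, a)  # round
                        else:
                            area = 0.8 * base_area
                            q = 1.8
                            a = np.sqrt(area * q / np.pi)
                            shape = ("ellipse", 0.0, 0.0, a, a / q)
                        self._post = {
                            "npm1": [shape],
                            "ubf": [(y, x, _PUNCTUM_R) for (y, x) in
                                    _place_puncta(rng, min(3, p.initial_ubf), 0.5 * nuc_r, 6.0)],
                            "fbl": [(y, x, _PUNCTUM_R) for (y, x) in
                                    _place_puncta(rng, min(2, p.initial_fbl), 0.5 * nuc_r, 6.0)],
                        }
                self.frames.append(dict(self._post))
                continue
            # pre-division (or no division) trajectory
            prog = f / max(F - 1, 1)
            if inhibited:
                area = base_area * (1.0 - 0.45 * prog)
                q = 2.0 - 1.0 * prog  # aspect 2 -> 1: sphericity rises monotonically
                if len(ubf) > 1 and rng.uniform() < p.condensation_rate:
                    ubf = _merge_nearest(ubf)
                if len(fbl) > 1 and rng.uniform() < p.condensation_rate:
                    fbl = _merge_nearest(fbl)
            else:
                area, q = base_area, 2.0
            a = np.sqrt(area * q / np.pi)
            self.frames.append({
                "ubf": list(ubf),
                "fbl": list(fbl),
                "npm1": [("ellipse", 0.0, 0.0, a, a / q)],
            })

    def truth_rows(self, pixel_size):
        rows = []
        for f, comp in enumerate(self.frames):
            npm1 = comp["npm1"]
            areas, sph = [], []
            for s in npm1:
                if s[0] == "ellipse":
                    _, _, _, a, b = s
                    areas.append(np.pi * a * b)
                    sph.append(ellipse_circularity(max(a, b) / min(a, b)))
                else:
                    _, _, _, r = s
                    areas.append(np.pi * r * r)
                    sph.append(1.0)
            total = float(np.sum(areas)) if areas else 0.0
            if areas:
                w = np.asarray(areas) / total
                mean_sph = float(np.sum(w * np.asarray(sph)))
            else:
                mean_sph = np.nan
            rows.append({
                "cell_id": self.cell_id,
                "frame": f,
                "n_ubf": len(comp["ubf"]),
                "n_fbl": len(comp["fbl"]),
                "n_npm1": len(npm1),
                "npm1_area_um2": total * pixel_size**2,
                "npm1_sphericity": mean_sph,
            })
        return rows


# ------------------------------------------------------------------- drivers


def simulate_timelapse_truth(params: TimelapseSimParams):
    """Draw all cell fates and per-frame truth without rendering pixels."""
    rng = np.random.default_rng(params.seed)
    cells = []
    pheno_rows = []
    frame_rows = []
    for i in range(params.n_cells):
        divides = bool(rng.uniform() < params.divide_fraction)
        if divides:
            if params.division_frame is not None:
                dframe = int(params.division_frame)
            else:
                dframe = int(rng.integers(3, max(4, params.n_frames - 5)))
            fragmented = bool(rng.uniform() < params.fragmentation_probability)
        else:
            dframe, fragmented = None, False
        cell = _CellTruth(f"cell{i:04d}", params, rng, divides, dframe, fragmented)
        cells.append(cell)
        if fragmented:
            phenotype = "fragmented"
        elif params.condition == "inhibited":
            phenotype = "condensed"
        else:
            phenotype = "normal"
        pheno_rows.append({
            "cell_id": cell.cell_id,
            "phenotype": phenotype,
            "divides": divides,
            "division_frame": dframe if dframe is not None else np.nan,
        })
        frame_rows.extend(cell.truth_rows(params.pixel_size))
    truth = PhenotypeTruth(
        phenotypes=pd.DataFrame(
            pheno_rows, columns=["cell_id", "phenotype", "divides", "division_frame"]
        ),
        frames=pd.DataFrame(
            frame_rows,
            columns=["cell_id", "frame", "n_ubf", "n_fbl", "n_npm1",
                     "npm1_area_um2", "npm1_sphericity"],
        ),
    )
    return cells, truth


def _draw_disk(canvas, cy, cx, r):
    r_out = int(np.ceil(r + 1))
    y0, y1 = max(0, int(cy) - r_out), min(canvas.shape[0], int(cy) + r_out + 1)
    x0, x1 = max(0, int(cx) - r_out), min(canvas.shape[1], int(cx) + r_out + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] = np.maximum(
        canvas[y0:y1, x0:x1], (np.hypot(yy - cy, xx - cx) <= r).astype(np.float32)
    )


def _draw_ellipse(canvas, cy, cx, a, b):
    r_out = int(np.ceil(max(a, b) + 1))
    y0, y1 = max(0, int(cy) - r_out), min(canvas.shape[0], int(cy) + r_out + 1)
    x0, x1 = max(0, int(cx) - r_out), min(canvas.shape[1], int(cx) + r_out + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    canvas[y0:y1, x0:x1] = np.maximum(canvas[y0:y1, x0:x1], inside.astype(np.float32))


def simulate_timelapse(params: TimelapseSimParams) -> tuple[TimelapseMovie, PhenotypeTruth]:
    """Render the mosaic movie (TCYX) and return it with the ground truth.

    n_cells=0 yields an empty movie and empty truth tables, not an error.
    Identical seeds reproduce the movie bit-exactly.
    """
    cells, truth = simulate_timelapse_truth(params)
    n = params.n_cells
    ncols = int(np.ceil(np.sqrt(n))) if n else 0
    nrows = int(np.ceil(n / ncols)) if n else 0
    T, tile = params.n_frames, params.tile_px
    H, W = nrows * tile, ncols * tile
    data = np.zeros((T, len(CHANNELS), H, W), dtype=np.float32)
    masks = np.zeros((T, H, W), dtype=np.int32)
    rng = np.random.default_rng(params.seed + 777_001)

    for i, cell in enumerate(cells):
        oy, ox = (i // ncols) * tile + tile / 2, (i % ncols) * tile + tile / 2
        for f in range(T):
            cy, cx = oy + cell.centers[f, 0], ox + cell.centers[f, 1]
            # nucleus label mask
            r_out = int(np.ceil(cell.nuc_r + 1))
            y0, y1 = max(0, int(cy) - r_out), min(H, int(cy) + r_out + 1)
            x0, x1 = max(0, int(cx) - r_out), min(W, int(cx) + r_out + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            nuc = np.hypot(yy - cy, xx - cx) <= cell.nuc_r
            masks[f, y0:y1, x0:x1][nuc] = i + 1
            comp = cell.frames[f]
            for y, x, r in comp["ubf"]:
                _draw_disk(data[f, 0], cy + y, cx + x, r)
            for y, x, r in comp["fbl"]:
                _draw_disk(data[f, 1], cy + y, cx + x, r)
            for s in comp["npm1"]:
                if s[0] == "ellipse":
                    _, y, x, a, b = s
                    _draw_ellipse(data[f, 2], cy + y, cx + x, a, b)
                else:
                    _, y, x, r = s
                    _draw_disk(data[f, 2], cy + y, cx + x, r)

    if H and W:
        for f in range(T):
            for c in range(len(CHANNELS)):
                data[f, c] = ndi.gaussian_filter(data[f, c], _BLUR_SIGMA)
        if params.noise_sd > 0:
            data += rng.normal(0.0, params.noise_sd, size=data.shape).astype(np.float32)

    movie = TimelapseMovie(
        data=data,
        channels=CHANNELS,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        nucleus_masks=masks,
    )
    return movie, truth
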