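"""Time-lapse nucleolar morphometry: segmentation, shape, tracking, phenotypes.

Per channel and per nucleus, components ("surfaces") are segmented by Otsu
thresholding within the nucleus mask and filtered by a minimum size. In 2-D,
"sphericity" is reported as circularity 4*pi*A/P^2 (labeled as such in
outputs); in 3-D it is Psi = pi^(1/3) * (6V)^(2/3) / S. Nuclei are tracked by
nearest-centroid linking with a maximum-displacement gate, populations are
summarized as per-frame mean with a t-based 95% CI, and a rule-based
classifier calls condensed vs fragmented nucleolar phenotypes on the NPM1
channel. The fragmentation rule is an explicit, configurable stand-in for
manual scoring: fragmented when the NPM1 component count is at least
fragment_count_min and no single component holds half the total area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

from ._stats import one_way_anova, t_confidence_interval

DEFAULT_MIN_AREA_PX = 4
DEFAULT_GATE_UM = 10.0  # max displacement per frame
FRAGMENT_COUNT_MIN = 6
FRAGMENT_MAX_AREA_FRACTION = 0.5
CONDENSED_SPHERICITY_MIN = 0.9

COMPONENT_COLUMNS = [
    "frame", "cell_id", "channel", "component_id",
    "area_um2", "perimeter_um", "sphericity", "centroid_y", "centroid_x",
]


@dataclass(frozen=True)
class PhenotypeCall:
    cell_id: str
    phenotype: str  # normal | condensed | fragmented | unclassifiable
    n_components: int
    max_area_fraction: float
    sphericity: float


def segment_components(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    *,
    threshold: float | None = None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> np.ndarray:
    """Label connected foreground components of one channel within a nucleus.

    Otsu within the mask by default (fixed threshold overridable); components
    below min_area_px are removed. An all-background channel returns an empty
    labeling, not an error. Deterministic.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    vals = channel[cell_mask]
    if threshold is None:
        if np.ptp(vals) == 0:
            return np.zeros(channel.shape, dtype=np.int32)
        threshold = float(threshold_otsu(vals))
        # guard against Otsu splitting pure background noise: require the
        # foreground class to stand clear of the background spread
        fg = vals[vals > threshold]
        bg = vals[vals <= threshold]
        if fg.size == 0 or fg.mean() - bg.mean() < 4 * max(bg.std(), 1e-12):
            return np.zeros(channel.shape, dtype=np.int32)
    fg_mask = (channel > threshold) & cell_mask
    labels = measure.label(fg_mask, connectivity=1)
    if min_area_px > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts < min_area_px)[0]
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels = measure.label(labels > 0, connectivity=1)
    return labels.astype(np.int32)


def measure_shape(component_mask: np.ndarray, pixel_size: float):
    """(area_or_volume, perimeter_or_surface, sphericity) of one component.

    2-D input: area in um^2, Crofton perimeter in um, circularity 4*pi*A/P^2.
    3-D input: volume in um^3, marching-cubes surface in um^2, Psi.
    Sphericity is clipped at 1.05 to absorb discretization overshoot; a 1-px
    (or 1-voxel) component yields NaN sphericity (degenerate).
    """
    m = np.asarray(component_mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty component")
    if m.ndim == 2:
        area = n * pixel_size**2
        if n < 2:
            return area, np.nan, np.nan
        perim = float(measure.perimeter_crofton(m, directions=4)) * pixel_size
        if perim <= 0:
            return area, perim, np.nan
        sph = min(4.0 * np.pi * area / perim**2, 1.05)
        return area, perim, sph
    if m.ndim == 3:
        vol = n * pixel_size**3
        if n < 2:
            return vol, np.nan, np.nan
        padded = np.pad(m, 1).astype(float)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
        surf = float(measure.mesh_surface_area(verts, faces)) * pixel_size**2
        psi = min(np.pi ** (1 / 3) * (6.0 * vol) ** (2 / 3) / surf, 1.05)
        return vol, surf, psi
    raise ValueError("component must be 2-D or 3-D")


def measure_components(
    labels: np.ndarray, pixel_size: float, *, frame: int = 0, cell_id: str = "cell0",
    channel: str = "",
) -> pd.DataFrame:
    """ComponentTable rows for one labeled frame/channel."""
    rows = []
    for region in measure.regionprops(labels):
        area, perim, sph = measure_shape(labels == region.label, pixel_size)
        cy, cx = region.centroid
        rows.append({
            "frame": frame, "cell_id": cell_id, "channel": channel,
            "component_id": int(region.label), "area_um2": area,
            "perimeter_um": perim, "sphericity": sph,
            "centroid_y": cy, "centroid_x": cx,
        })
    return pd.DataFrame(rows, columns=COMPONENT_COLUMNS)


# -------------------------------------------------------------------- tracking


def track_cells(
    centroids_per_frame: list[pd.DataFrame],
    *,
    pixel_size: float = 1.0,
    gate_um: float = DEFAULT_GATE_UM,
) -> pd.DataFrame:
    """Nearest-centroid linking of cell ROIs across consecutive frames.

    Input: one DataFrame per frame with columns label, centroid_y, centroid_x.
    Links are greedy by ascending distance and rejected beyond the gate;
    unlinked detections start new tracks (fragments rather than swaps).
    Returns rows (frame, label, track_id).
    """
    if len(centroids_per_frame) < 2:
        raise ValueError("tracking needs at least 2 frames")
    gate_px = gate_um / pixel_size
    rows = []
    next_track = 0
    prev: dict[int, tuple[float, float]] = {}  # track_id -> centroid
    for f, det in enumerate(centroids_per_frame):
        det = det.reset_index(drop=True)
        assigned: dict[int, int] = {}
        if prev and len(det):
            pairs = []
            for tid, (py, px_) in prev.items():
                for i in range(len(det)):
                    d = np.hypot(det.loc[i, "centroid_y"] - py, det.loc[i, "centroid_x"] - px_)
                    if d <= gate_px:
                        pairs.append((d, tid, i))
            used_t, used_d = set(), set()
            for d, tid, i in sorted(pairs):
                if tid in used_t or i in used_d:
                    continue
                assigned[i] = tid
                used_t.add(tid)
                used_d.add(i)
        new_prev = {}
        for i in range(len(det)):
            tid = assigned.get(i)
            if tid is None:
                tid = next_track
                next_track += 1
            rows.append({"frame": f, "label": int(det.loc[i, "label"]), "track_id": tid})
            new_prev[tid] = (float(det.loc[i, "centroid_y"]), float(det.loc[i, "centroid_x"]))
        prev = new_prev
    return pd.DataFrame(rows, columns=["frame", "label", "track_id"])


# --------------------------------------------------------------- movie driver


def mask_centroids(label_mask: np.ndarray) -> pd.DataFrame:
    rows = []
    for region in measure.regionprops(label_mask):
        cy, cx = region.centroid
        rows.append({"label": int(region.label), "centroid_y": cy, "centroid_x": cx})
    return pd.DataFrame(rows, columns=["label", "centroid_y", "centroid_x"])


def measure_movie(movie, *, min_area_px: int = DEFAULT_MIN_AREA_PX,
                  gate_um: float = DEFAULT_GATE_UM):
    """Segment every channel of every tracked nucleus in a TimelapseMovie.

    Returns (component_table, series) where series has one row per
    (cell_id, frame) with n_ubf_puncta, n_fbl_puncta, npm1_n_components,
    npm1_total_area_um2, npm1_sphericity (area-weighted mean circularity)
    and npm1_max_area_fraction.
    """
    T = movie.data.shape[0]
    chan_idx = {c: i for i, c in enumerate(movie.channels)}
    cents = [mask_centroids(movie.nucleus_masks[f]) for f in range(T)]
    tracks = track_cells(cents, pixel_size=movie.pixel_size, gate_um=gate_um)
    comp_rows = []
    series_rows = []
    for f in range(T):
        frame_tracks = tracks[tracks["frame"] == f]
        slices = ndi.find_objects(movie.nucleus_masks[f])
        for _, tr in frame_tracks.iterrows():
            label = int(tr["label"])
            sl = slices[label - 1]
            cell_mask = movie.nucleus_masks[f][sl] == label
            cid = f"track{tr['track_id']:04d}"
            per_channel = {}
            for cname in ("UBF", "FBL", "NPM1"):
                labels = segment_components(
                    movie.data[f, chan_idx[cname]][sl], cell_mask, min_area_px=min_area_px
                )
                tab = measure_components(labels, movie.pixel_size, frame=f,
                                         cell_id=cid, channel=cname)
                if len(tab):
                    tab["centroid_y"] += sl[0].start
                    tab["centroid_x"] += sl[1].start
                    comp_rows.append(tab)
                per_channel[cname] = tab
            npm1 = per_channel["NPM1"]
            total = float(npm1["area_um2"].sum())
            if len(npm1) and total > 0:
                w = npm1["area_um2"] / total
                sph = float((w * npm1["sphericity"]).sum())
                maxfrac = float(npm1["area_um2"].max() / total)
            else:
                sph, maxfrac = np.nan, np.nan
            series_rows.append({
                "cell_id": cid, "frame": f,
                "n_ubf_puncta": int(len(per_channel["UBF"])),
                "n_fbl_puncta": int(len(per_channel["FBL"])),
                "npm1_n_components": int(len(npm1)),
                "npm1_total_area_um2": total,
                "npm1_sphericity": sph,
                "npm1_max_area_fraction": maxfrac,
            })
    components = (
        pd.concat(comp_rows, ignore_index=True) if comp_rows
        else pd.DataFrame(columns=COMPONENT_COLUMNS)
    )
    series = pd.DataFrame(series_rows)
    return components, series


SUMMARY_METRICS = (
    "n_ubf_puncta", "n_fbl_puncta", "npm1_total_area_um2", "npm1_sphericity",
)


def summarize_population(series: pd.DataFrame, metrics=SUMMARY_METRICS,
                         confidence: float = 0.95) -> pd.DataFrame:
    """Per-frame mean and t-based CI across cells for each metric.

    Single-cell frames yield a NaN CI and are flagged in the 'flagged' column.
    """
    rows = []
    for frame, grp in series.groupby("frame"):
        for metric in metrics:
            mean, half, n = t_confidence_interval(grp[metric], confidence)
            rows.append({
                "frame": int(frame), "metric": metric, "mean": mean,
                "ci_lo": mean - half, "ci_hi": mean + half, "n": n,
                "flagged": n < 2,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- phenotypes


def classify_phenotype(
    cell_id: str,
    npm1_components: pd.DataFrame,
    *,
    fragment_count_min: int = FRAGMENT_COUNT_MIN,
    fragment_max_area_fraction: float = FRAGMENT_MAX_AREA_FRACTION,
    condensed_sphericity_min: float = CONDENSED_SPHERICITY_MIN,
) -> PhenotypeCall:
    """Rule-based phenotype call from one cell's NPM1 components at one frame.

    fragmented: count >= fragment_count_min and the largest component holds
    less than fragment_max_area_fraction of the total area. condensed: exactly
    one component with sphericity >= condensed_sphericity_min. Otherwise
    normal; no NPM1 signal at all is unclassifiable (excluded downstream).
    """
    n = len(npm1_components)
    if n == 0:
        return PhenotypeCall(cell_id, "unclassifiable", 0, np.nan, np.nan)
    total = float(npm1_components["area_um2"].sum())
    maxfrac = float(npm1_components["area_um2"].max() / total)
    w = npm1_components["area_um2"] / total
    sph = float((w * npm1_components["sphericity"]).sum())
    if n >= fragment_count_min and maxfrac < fragment_max_area_fraction:
        phenotype = "fragmented"
    elif n == 1 and sph >= condensed_sphericity_min:
        phenotype = "condensed"
    else:
        phenotype = "normal"
    return PhenotypeCall(cell_id, phenotype, n, maxfrac, sph)


def classify_final_frames(components: pd.DataFrame, **rule_kwargs) -> list[PhenotypeCall]:
    """Classify each tracked cell at the final frame of its track (NPM1 only)."""
    npm1 = components[components["channel"] == "NPM1"]
    calls = []
    for cid, grp in components.groupby("cell_id"):
        last = int(grp["frame"].max())
        cell_npm1 = npm1[(npm1["cell_id"] == cid) & (npm1["frame"] == last)]
        calls.append(classify_phenotype(cid, cell_npm1, **rule_kwargs))
    return calls


def fraction_fragmented(
    calls_by_condition: dict[str, list[PhenotypeCall]],
    replicate_percentages: dict[str, list[float]] | None = None,
):
    """Percentage of classifiable cells called fragmented, per condition.

    With >= 2 conditions and per-replicate percentages supplied, a one-way
    ANOVA across conditions is run on those percentages.
    """
    out = {}
    for cond, calls in calls_by_condition.items():
        classifiable = [c for c in calls if c.phenotype != "unclassifiable"]
        if not classifiable:
            raise ValueError(f"no classifiable cells in condition {cond!r}")
        frag = sum(c.phenotype == "fragmented" for c in classifiable)
        out[cond] = 100.0 * frag / len(classifiable)
    anova = None
    if replicate_percentages is not None and len(replicate_percentages) >= 2:
        f, p = one_way_anova(replicate_percentages)
        anova = {"F": f, "p": p}
    return out, anova
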