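"""Readers and writers shared by the simulators and analysis stages.

CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header, empty
fields for missing values. Physical quantities carry units in column names.
Images and movies are written as multi-page TIFF (CYX / TCYX) with pixel size
and frame interval in the image-description JSON metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import FrapTrajectory
from .immunogold import DensityResult, EmField
from .sim.timelapse_sim import CHANNELS, TimelapseMovie

FRAP_COLUMNS = ["cell_id", "roi_id", "condition", "geometry", "frame", "time_s", "intensity"]


def write_frap_csv(trajs: list[FrapTrajectory], path) -> None:
    rows = []
    for k, t in enumerate(trajs):
        for i in range(t.times.size):
            rows.append({
                "cell_id": t.cell_id, "roi_id": f"roi{k}", "condition": t.condition,
                "geometry": t.geometry, "frame": i, "time_s": t.times[i],
                "intensity": t.intensities[i],
                "bleach_index": t.bleach_index if t.bleach_index is not None else "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frap_csv(path) -> list[FrapTrajectory]:
    df = pd.read_csv(path)
    trajs = []
    for (cell, roi), grp in df.groupby(["cell_id", "roi_id"], sort=False):
        grp = grp.sort_values("frame")
        bidx = grp["bleach_index"].iloc[0] if "bleach_index" in grp else np.nan
        trajs.append(FrapTrajectory(
            times=grp["time_s"].to_numpy(float),
            intensities=grp["intensity"].to_numpy(float),
            bleach_index=None if pd.isna(bidx) else int(bidx),
            geometry=str(grp["geometry"].iloc[0]),
            cell_id=str(cell),
            condition=str(grp["condition"].iloc[0]),
        ))
    return trajs


def read_two_column_csv(path, *, geometry="whole", cell_id="cell0",
                        condition="unknown") -> FrapTrajectory:
    """Per-curve plain (time_s, intensity) CSV with metadata supplied by flags."""
    df = pd.read_csv(path)
    return FrapTrajectory(
        times=df.iloc[:, 0].to_numpy(float), intensities=df.iloc[:, 1].to_numpy(float),
        geometry=geometry, cell_id=cell_id, condition=condition,
    )


def write_fits_csv(whole_fits, half_fits, path) -> None:
    rows = []
    for f in whole_fits:
        rows.append({
            "cell_id": f.cell_id, "condition": f.condition, "geometry": "whole",
            "tau_s": f.tau, "tau1_s": "", "tau2_fixed_s": "",
            "percent_recovery": f.percent_recovery, "rss": f.rss, "converged": f.converged,
        })
    for f in half_fits:
        rows.append({
            "cell_id": f.cell_id, "condition": f.condition, "geometry": "half",
            "tau_s": "", "tau1_s": f.tau1, "tau2_fixed_s": f.tau2_fixed,
            "percent_recovery": f.percent_recovery, "rss": f.rss, "converged": f.converged,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_particles_csv(particles: pd.DataFrame, path) -> None:
    particles.to_csv(path, index=False)


def read_particles_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_density_json(results: list[DensityResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([dataclasses.asdict(r) for r in results], fh, indent=2)


def read_density_json(path) -> list[DensityResult]:
    with open(path, encoding="utf-8") as fh:
        return [DensityResult(**d) for d in json.load(fh)]


def write_em_tiff(field: EmField, image_path, mask_path) -> None:
    meta = json.dumps({"pixel_size_nm": field.pixel_size, "image_id": field.image_id})
    tifffile.imwrite(image_path, field.image.astype(np.float32), description=meta,
                     photometric="minisblack")
    tifffile.imwrite(mask_path, field.roi_mask.astype(np.uint8) * 255,
                     photometric="minisblack")


def read_em_tiff(image_path, mask_path, pixel_size_nm: float | None = None,
                 image_id: str | None = None) -> EmField:
    with tifffile.TiffFile(image_path) as tf:
        image = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    mask = tifffile.imread(mask_path) > 0
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError("pixel size not in metadata; pass pixel_size_nm explicitly")
    return EmField(image=image, pixel_size=float(px), roi_mask=mask,
                   image_id=image_id or meta.get("image_id", Path(image_path).stem))


def write_movie_tiff(movie: TimelapseMovie, movie_path, mask_path) -> None:
    meta = json.dumps({
        "axes": "TCYX", "channels": list(movie.channels),
        "pixel_size_um": movie.pixel_size, "frame_interval_min": movie.frame_interval,
    })
    tifffile.imwrite(movie_path, movie.data, description=meta, photometric="minisblack")
    tifffile.imwrite(mask_path, movie.nucleus_masks, photometric="minisblack")


def read_movie_tiff(movie_path, mask_path, *, channels=None, pixel_size_um=None,
                    frame_interval_min=None) -> TimelapseMovie:
    with tifffile.TiffFile(movie_path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    masks = tifffile.imread(mask_path)
    return TimelapseMovie(
        data=data,
        channels=tuple(channels or meta.get("channels", CHANNELS)),
        pixel_size=float(pixel_size_um or meta.get("pixel_size_um", 1.0)),
        frame_interval=float(frame_interval_min or meta.get("frame_interval_min", 1.0)),
        nucleus_masks=masks,
    )


def write_truth_csv(truth, phenotype_path, frames_path) -> None:
    truth.phenotypes.to_csv(phenotype_path, index=False)
    truth.frames.to_csv(frames_path, index=False)
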