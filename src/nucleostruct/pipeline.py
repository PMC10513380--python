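"""End-to-end runs: simulate -> analyze -> summarize, with a run manifest.

Stages execute in dependency order; whole-FRAP fits always precede half-FRAP
fits so the per-condition mean whole-FRAP tau can be injected as the fixed
tau2. Every run writes the fully-resolved config and a manifest (version,
timestamp, config digest, input/output digests) beside its outputs;
re-running a deterministic config reproduces the output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from . import frap as frap_mod
from . import immunogold, io_utils, morphometry
from .config import KNOWN_STAGES, RunConfig, resolve_config, save_resolved_config
from .sim.em_sim import EmSimParams, simulate_em_image
from .sim.frap_sim import FrapSimParams, simulate_frap_ensemble
from .sim.timelapse_sim import TimelapseSimParams, simulate_timelapse

log = logging.getLogger("nucleostruct")


class DependencyError(RuntimeError):
    """An analysis stage is missing its upstream inputs."""


@dataclass
class RunManifest:
    version: str
    timestamp: str
    config_digest: str
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, out_dir) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = resolve_config(cfg)
    save_resolved_config(resolved, out / "resolved_config.yaml")
    manifest = RunManifest(
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config_digest=hashlib.sha256(
            json.dumps(resolved, sort_keys=True, default=str).encode()
        ).hexdigest(),
    )
    written: list[Path] = [out / "resolved_config.yaml"]

    # canonical dependency order regardless of the order stages were listed in
    ordered = [s for s in KNOWN_STAGES if s in cfg.stages]
    for stage in ordered:
        t0 = time.perf_counter()
        written += _STAGE_RUNNERS[stage](resolved, out, manifest)
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)

    for p in written:
        manifest.outputs[p.name] = _sha256(p)
    manifest.save(out / "manifest.json")
    return manifest


def _stage_simulate_frap(resolved, out, manifest):
    block = dict(resolved["frap_sim"])
    n = resolved["n_frap_curves"]
    half = FrapSimParams(**{**block, "geometry": "half"})
    whole = FrapSimParams.whole(
        tau=block["tau2"], plateau=min(block["plateau"], 1.0),
        **{k: block[k] for k in
           ("n_prebleach_frames", "frame_interval", "duration", "noise_sd")},
        seed=block["seed"] + 500_000,
    )
    half_trajs = [replace(t, condition="sim") for t in simulate_frap_ensemble(half, n)]
    whole_trajs = [replace(t, condition="sim") for t in simulate_frap_ensemble(whole, n)]
    io_utils.write_frap_csv(whole_trajs, out / "frap_whole.csv")
    io_utils.write_frap_csv(half_trajs, out / "frap_half.csv")
    log.info("simulated %d whole and %d half FRAP curves", n, n)
    return [out / "frap_whole.csv", out / "frap_half.csv"]


def _stage_frap_fit(resolved, out, manifest):
    whole_path, half_path = out / "frap_whole.csv", out / "frap_half.csv"
    explicit_tau2 = resolved["frap_fit"].get("explicit_tau2")
    if not half_path.exists() and not whole_path.exists():
        raise DependencyError("frap_fit requires stage simulate_frap (no FRAP CSVs found)")
    half = io_utils.read_frap_csv(half_path) if half_path.exists() else []
    if half and not whole_path.exists() and explicit_tau2 is None:
        raise DependencyError(
            "half-FRAP fitting requires whole-FRAP fits (stage simulate_frap / "
            "frap_whole.csv) or an explicit tau2 in the frap_fit block"
        )
    whole = io_utils.read_frap_csv(whole_path) if whole_path.exists() else []
    manifest.input_digests.update({p.name: _sha256(p) for p in (whole_path, half_path)
                                   if p.exists()})
    if explicit_tau2 is not None and not whole:
        whole_fits = []
        half_fits = [frap_mod.fit_half_frap(frap_mod._ensure_normalized(t), explicit_tau2)
                     for t in half]
        tau2_by_cond = {"explicit": explicit_tau2}
    else:
        whole_fits, half_fits, tau2_by_cond = frap_mod.fit_frap_dataset(
            whole, half, tau2_mode=resolved["frap_fit"]["tau2_mode"]
        )
    io_utils.write_fits_csv(whole_fits, half_fits, out / "frap_fits.csv")
    summary = {
        "tau2_by_condition_s": tau2_by_cond,
        "n_whole": len(whole_fits),
        "n_half": len(half_fits),
        "mean_tau_s": float(np.mean([f.tau for f in whole_fits if f.converged]))
        if whole_fits else None,
        "mean_tau1_s": float(np.mean([f.tau1 for f in half_fits if f.converged]))
        if half_fits else None,
        "mean_percent_recovery_whole": float(np.mean(
            [f.percent_recovery for f in whole_fits if f.converged])) if whole_fits else None,
    }
    with open(out / "frap_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return [out / "frap_fits.csv", out / "frap_summary.json"]


def _stage_simulate_em(resolved, out, manifest):
    params = EmSimParams(**resolved["em_sim"])
    field_, truth = simulate_em_image(params)
    io_utils.write_em_tiff(field_, out / "em_image.tif", out / "em_mask.tif")
    truth.to_csv(out / "em_truth.csv", index=False)
    return [out / "em_image.tif", out / "em_mask.tif", out / "em_truth.csv"]


def _stage_gold_detect(resolved, out, manifest):
    img, mask = out / "em_image.tif", out / "em_mask.tif"
    if not img.exists() or not mask.exists():
        raise DependencyError("gold_detect requires stage simulate_em (no EM TIFFs found)")
    manifest.input_digests.update({p.name: _sha256(p) for p in (img, mask)})
    field_ = io_utils.read_em_tiff(img, mask)
    block = resolved["gold_detect"]
    thresholds = {}
    if block["threshold_12nm"] is not None:
        thresholds["12nm"] = block["threshold_12nm"]
    if block["threshold_6nm"] is not None:
        thresholds["6nm"] = block["threshold_6nm"]
    particles = immunogold.detect_two_pass(
        field_, thresholds or None, exclusion_radius_nm=block["exclusion_radius_nm"]
    )
    dens = immunogold.density(field_, particles)
    io_utils.write_particles_csv(particles, out / "particles.csv")
    io_utils.write_density_json([dens], out / "density.json")
    log.info("detected %d particles (%d in ROI)", len(particles),
             int(particles["in_roi"].sum()) if len(particles) else 0)
    return [out / "particles.csv", out / "density.json"]


def _stage_simulate_timelapse(resolved, out, manifest):
    params = TimelapseSimParams(**resolved["timelapse_sim"])
    movie, truth = simulate_timelapse(params)
    io_utils.write_movie_tiff(movie, out / "movie.tif", out / "nucleus_masks.tif")
    io_utils.write_truth_csv(truth, out / "truth_phenotypes.csv", out / "truth_frames.csv")
    return [out / "movie.tif", out / "nucleus_masks.tif",
            out / "truth_phenotypes.csv", out / "truth_frames.csv"]


def _stage_morpho_measure(resolved, out, manifest):
    movie_p, mask_p = out / "movie.tif", out / "nucleus_masks.tif"
    if not movie_p.exists() or not mask_p.exists():
        raise DependencyError("morpho_measure requires stage simulate_timelapse (no movie found)")
    manifest.input_digests.update({p.name: _sha256(p) for p in (movie_p, mask_p)})
    movie = io_utils.read_movie_tiff(movie_p, mask_p)
    block = resolved["morpho"]
    components, series = morphometry.measure_movie(
        movie, min_area_px=block["min_area_px"], gate_um=block["gate_um"]
    )
    summary = morphometry.summarize_population(series)
    calls = morphometry.classify_final_frames(
        components,
        fragment_count_min=block["fragment_count_min"],
        fragment_max_area_fraction=block["fragment_max_area_fraction"],
        condensed_sphericity_min=block["condensed_sphericity_min"],
    )
    fractions, _ = morphometry.fraction_fragmented({"run": calls})
    components.to_csv(out / "components.csv", index=False)
    series.to_csv(out / "series.csv", index=False)
    summary.to_csv(out / "population_summary.csv", index=False)
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        out / "phenotypes.csv", index=False
    )
    with open(out / "fraction_fragmented.json", "w", encoding="utf-8") as fh:
        json.dump({"percent_fragmented": fractions["run"], "n_cells": len(calls)}, fh, indent=2)
    return [out / "components.csv", out / "series.csv", out / "population_summary.csv",
            out / "phenotypes.csv", out / "fraction_fragmented.json"]


_STAGE_RUNNERS = {
    "simulate_frap": _stage_simulate_frap,
    "simulate_em": _stage_simulate_em,
    "simulate_timelapse": _stage_simulate_timelapse,
    "frap_fit": _stage_frap_fit,
    "gold_detect": _stage_gold_detect,
    "morpho_measure": _stage_morpho_measure,
}
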