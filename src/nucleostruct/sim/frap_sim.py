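"""Generative twin of the FRAP recovery models.

Curves are produced already min-max normalized (pre-bleach ~ 1, bleach ~ 0)
because the analysis pipeline normalizes before fitting; the post-bleach
expectation is

    F(t) = plateau - amp1 * exp(-t / tau1) - amp2 * exp(-t / tau2)

with amp1 + amp2 = plateau so F(0) = 0. Whole-FRAP geometry sets amp1 = 0,
making tau2 the single exchange constant. Noise is i.i.d. Gaussian per frame
on the normalized scale (mean-ROI photon noise after averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..frap import FrapTrajectory

_AMP_TOL = 1e-9


class FrapParameterError(ValueError):
    pass


@dataclass(frozen=True)
class FrapSimParams:
    """Generating parameters for one simulated FRAP curve.

    Defaults follow the study conditions: 0.5 s frames, 2 min of recovery,
    a fast intranucleolar component tau1 and a slow exchange component tau2.
    """

    geometry: str = "half"  # "half" | "whole"
    tau1: float = 3.33  # s, fast internal-mixing component
    tau2: float = 25.0  # s, slow nucleoplasmic-exchange component
    amp1: float = 0.5
    amp2: float = 0.4
    plateau: float = 0.9
    n_prebleach_frames: int = 5
    frame_interval: float = 0.5  # s
    duration: float = 120.0  # s of recovery
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in ("half", "whole"):
            raise FrapParameterError(f"geometry must be 'half' or 'whole', got {self.geometry!r}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise FrapParameterError("tau1 and tau2 must be positive")
        if self.amp1 < 0 or self.amp2 < 0:
            raise FrapParameterError("amplitudes must be non-negative")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise FrapParameterError("frame_interval and duration must be positive")
        if self.n_prebleach_frames < 1:
            raise FrapParameterError("need at least one pre-bleach frame")
        if not (0 < self.plateau <= 1.0 + _AMP_TOL):
            raise FrapParameterError("plateau must lie in (0, 1]")
        if abs(self.amp1 + self.amp2 - self.plateau) > 1e-6:
            raise FrapParameterError(
                f"amp1 + amp2 = {self.amp1 + self.amp2} must equal plateau = {self.plateau} "
                "(the curve starts at 0 immediately post-bleach)"
            )
        if self.geometry == "whole" and self.amp1 != 0:
            raise FrapParameterError("whole-FRAP geometry requires amp1 = 0 (single component)")

    @classmethod
    def whole(cls, tau: float, plateau: float = 0.85, **kw) -> "FrapSimParams":
        """Whole-FRAP convenience constructor: single component with constant tau."""
        return cls(geometry="whole", tau1=1.0, tau2=tau, amp1=0.0, amp2=plateau,
                   plateau=plateau, **kw)


def recovery_expectation(params: FrapSimParams, t_post: np.ndarray) -> np.ndarray:
    """Noise-free post-bleach expectation, t measured from the bleach frame."""
    return (
        params.plateau
        - params.amp1 * np.exp(-t_post / params.tau1)
        - params.amp2 * np.exp(-t_post / params.tau2)
    )


def simulate_frap_curve(
    params: FrapSimParams, *, raw_range: tuple[float, float] | None = None
) -> FrapTrajectory:
    """Simulate one FRAP trajectory on the normalized scale.

    Length is n_prebleach_frames + duration/frame_interval + 1; the bleach
    frame (index n_prebleach_frames) has expectation 0. raw_range=(lo, hi)
    applies an affine map to emulate raw detector intensities.
    """
    n_post = int(round(params.duration / params.frame_interval))
    n_total = params.n_prebleach_frames + n_post + 1
    times = np.arange(n_total) * params.frame_interval
    bleach = params.n_prebleach_frames
    values = np.ones(n_total)
    t_post = times[bleach:] - times[bleach]
    values[bleach:] = recovery_expectation(params, t_post)
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=n_total)
    if raw_range is not None:
        lo, hi = raw_range
        if hi <= lo:
            raise FrapParameterError("raw_range must satisfy hi > lo")
        values = lo + values * (hi - lo)
    return FrapTrajectory(
        times=times,
        intensities=values,
        bleach_index=bleach,
        geometry=params.geometry,
        cell_id=f"sim{params.seed}",
        condition="sim",
    )


def simulate_frap_ensemble(
    params: FrapSimParams,
    n_curves: int,
    *,
    tau_cv: float = 0.0,
    prebleach_range: tuple[int, int] | None = None,
    seed: int | None = None,
) -> list[FrapTrajectory]:
    """Simulate an ensemble of curves with per-curve seeds.

    tau_cv adds lognormal cell-to-cell variability (coefficient of variation)
    to both time constants; prebleach_range randomizes the pre-bleach length
    to exercise bleach alignment. Curve i uses seed (seed or params.seed) + i.
    """
    base = params.seed if seed is None else seed
    rng = np.random.default_rng(base + 990_001)
    out = []
    for i in range(n_curves):
        p = replace(params, seed=base + i)
        if tau_cv > 0:
            sig = np.sqrt(np.log(1 + tau_cv**2))
            f1, f2 = np.exp(rng.normal(-sig**2 / 2, sig, size=2))
            p = replace(p, tau1=p.tau1 * f1, tau2=p.tau2 * f2)
        if prebleach_range is not None:
            lo, hi = prebleach_range
            p = replace(p, n_prebleach_frames=int(rng.integers(lo, hi + 1)))
        out.append(simulate_frap_curve(p))
    return out
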