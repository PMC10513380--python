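"""FRAP trajectory processing and constrained exponential recovery fitting.

Whole-FRAP curves (the entire punctum bleached) recover by exchange with the
nucleoplasm and are fit with a single exponential,

    F(t) = plateau * (1 - exp(-t / tau)),

while half-FRAP curves (part of the punctum bleached) recover through both
internal mixing (fast, tau1) and nucleoplasmic exchange (slow, tau2) and are
fit with a constrained double exponential,

    F(t) = plateau - amp1 * exp(-t / tau1) - amp2 * exp(-t / tau2),

with tau2 held fixed to the whole-FRAP value and amp1 + amp2 = plateau so that
F(0) = 0 on the min-max normalized scale. Percent recovery is 100 * plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from ._stats import GroupComparison, two_sample_t

__all__ = [
    "FrapTrajectory",
    "NormalizedTrajectory",
    "WholeFrapFit",
    "HalfFrapFit",
    "FrapFitError",
    "UnconvergedFitError",
    "detect_bleach_index",
    "normalize_trajectory",
    "denormalize_trajectory",
    "align_bleach",
    "fit_whole_frap",
    "fit_half_frap",
    "percent_recovery",
    "compare_groups",
    "fit_frap_dataset",
]

MIN_PREBLEACH = 3
MIN_POSTBLEACH = 10


class FrapFitError(ValueError):
    """Raised for invalid trajectories or fitting preconditions."""


class UnconvergedFitError(RuntimeError):
    """Raised when a result is requested from an unconverged fit."""


@dataclass(frozen=True)
class FrapTrajectory:
    """One bleached-ROI mean-intensity time series.

    times are seconds on a uniform grid; bleach_index is the first frame after
    the bleach event (intensity minimum on a clean curve).
    """

    times: np.ndarray
    intensities: np.ndarray
    bleach_index: int | None = None
    geometry: str = "whole"  # "half" | "whole"
    cell_id: str = "cell0"
    condition: str = "control"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if self.times.shape != self.intensities.shape:
            raise FrapFitError("times and intensities must have equal length")
        if self.geometry not in ("half", "whole"):
            raise FrapFitError(f"geometry must be 'half' or 'whole', got {self.geometry!r}")
        t = self.times[~np.isnan(self.times)]
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise FrapFitError("times must be strictly increasing")
            if not np.allclose(dt, np.median(dt), rtol=0.01):
                raise FrapFitError("times must lie on a uniform grid (1% tolerance)")
        if self.bleach_index is not None and not (0 <= self.bleach_index < self.times.size):
            raise FrapFitError("bleach_index out of range")

    @property
    def frame_interval(self) -> float:
        return float(np.nanmedian(np.diff(self.times)))


@dataclass(frozen=True)
class NormalizedTrajectory(FrapTrajectory):
    """Min-max normalized trajectory; raw min/max kept for invertibility."""

    raw_min: float = 0.0
    raw_max: float = 1.0


@dataclass(frozen=True)
class WholeFrapFit:
    tau: float
    plateau: float
    percent_recovery: float
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()
    cell_id: str = ""
    condition: str = ""


@dataclass(frozen=True)
class HalfFrapFit:
    tau1: float
    tau2_fixed: float
    amp1: float
    amp2: float
    plateau: float
    percent_recovery: float
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()
    cell_id: str = ""
    condition: str = ""


def detect_bleach_index(traj: FrapTrajectory) -> int:
    """Index of the largest single-frame intensity drop (earliest on ties)."""
    y = traj.intensities
    if y.size < 5:
        raise FrapFitError("need at least 5 frames to detect a bleach event")
    d = np.diff(y)
    if np.all(d >= 0):
        raise FrapFitError("no bleach event detected")
    # argmin returns the earliest minimum, which is the required tie-break
    return int(np.argmin(d)) + 1


def normalize_trajectory(traj: FrapTrajectory) -> NormalizedTrajectory:
    """Min-max normalize so the curve spans exactly [0, 1]."""
    y = traj.intensities
    lo, hi = float(np.nanmin(y)), float(np.nanmax(y))
    if hi <= lo:
        raise FrapFitError("constant trajectory has zero dynamic range")
    return NormalizedTrajectory(
        times=traj.times,
        intensities=(y - lo) / (hi - lo),
        bleach_index=traj.bleach_index,
        geometry=traj.geometry,
        cell_id=traj.cell_id,
        condition=traj.condition,
        raw_min=lo,
        raw_max=hi,
    )


def denormalize_trajectory(traj: NormalizedTrajectory) -> FrapTrajectory:
    y = traj.intensities * (traj.raw_max - traj.raw_min) + traj.raw_min
    return FrapTrajectory(
        times=traj.times,
        intensities=y,
        bleach_index=traj.bleach_index,
        geometry=traj.geometry,
        cell_id=traj.cell_id,
        condition=traj.condition,
    )


def align_bleach(trajs: list[NormalizedTrajectory]) -> list[NormalizedTrajectory]:
    """Shift curves so all bleach events fall on a common frame index.

    The common index is the maximum bleach_index in the set; shorter pre-bleach
    segments gain leading NaN frames (never fabricated data). Averaging across
    aligned curves should ignore NaNs.
    """
    if not trajs:
        raise FrapFitError("align_bleach needs at least one trajectory")
    for t in trajs:
        if t.bleach_index is None:
            raise FrapFitError("every trajectory must carry a bleach_index")
    common = max(t.bleach_index for t in trajs)
    out = []
    for t in trajs:
        pad = common - t.bleach_index
        if pad == 0:
            out.append(t)
            continue
        dt = t.frame_interval
        times = np.concatenate([t.times[0] - dt * np.arange(pad, 0, -1), t.times])
        vals = np.concatenate([np.full(pad, np.nan), t.intensities])
        out.append(replace(t, times=times, intensities=vals, bleach_index=common))
    return out


def _post_bleach(traj: FrapTrajectory):
    if traj.bleach_index is None:
        raise FrapFitError("trajectory has no bleach_index; run detect_bleach_index first")
    i = traj.bleach_index
    n_pre = int(np.sum(~np.isnan(traj.intensities[:i])))
    if n_pre < MIN_PREBLEACH:
        raise FrapFitError(f"need >= {MIN_PREBLEACH} pre-bleach frames, got {n_pre}")
    t = traj.times[i:] - traj.times[i]
    y = traj.intensities[i:]
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if t.size < MIN_POSTBLEACH:
        raise FrapFitError(f"need >= {MIN_POSTBLEACH} post-bleach frames, got {t.size}")
    return t, y


def _tau_bounds(t):
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return dt / 10.0, 10.0 * float(t[-1] - t[0] if t[-1] > t[0] else dt)


def _init_tau(t, y, plateau0):
    """Time to half recovery over ln 2; falls back to a quarter of the trace."""
    if plateau0 > 0:
        above = np.nonzero(y >= 0.5 * plateau0)[0]
        if above.size and t[above[0]] > 0:
            return float(t[above[0]]) / np.log(2.0)
    return float(t[-1]) / 4.0 if t[-1] > 0 else 1.0


_N_RESTARTS = 5


def fit_whole_frap(traj: FrapTrajectory) -> WholeFrapFit:
    """Single-exponential fit of the post-bleach recovery (whole-FRAP geometry)."""
    if traj.geometry != "whole":
        raise FrapFitError("fit_whole_frap requires geometry='whole'")
    t, y = _post_bleach(traj)
    lo, hi = _tau_bounds(t)
    plateau0 = float(np.mean(y[-5:]))
    flags: list[str] = []

    def resid(x):
        tau, plateau = x
        return plateau * (1.0 - np.exp(-t / tau)) - y

    x0 = np.array([np.clip(_init_tau(t, y, plateau0), lo, hi), np.clip(plateau0, 0.0, 1.05)])
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(_N_RESTARTS):
        start = x0 if attempt == 0 else np.clip(
            x0 * rng.uniform(0.3, 3.0, size=2), [lo, 0.0], [hi, 1.05]
        )
        res = least_squares(resid, start, bounds=([lo, 0.0], [hi, 1.05]))
        if best is None or res.cost < best.cost:
            best = res
        if best.success and attempt == 0:
            break
    tau, plateau = best.x
    converged = bool(best.success)
    if plateau < 0.01:
        flags.append("degenerate-plateau")
    if tau <= lo * (1 + 1e-6) or tau >= hi * (1 - 1e-6):
        flags.append("tau-at-bound")
        converged = False
    return WholeFrapFit(
        tau=float(tau),
        plateau=float(plateau),
        percent_recovery=100.0 * float(plateau),
        rss=float(2 * best.cost),
        converged=converged,
        flags=tuple(flags),
        cell_id=traj.cell_id,
        condition=traj.condition,
    )


def fit_half_frap(
    traj: FrapTrajectory, tau2: float, *, amp2_fixed: float | None = None
) -> HalfFrapFit:
    """Constrained double-exponential fit with the slow time constant held fixed.

    tau2 is the nucleoplasmic-exchange constant taken from whole-FRAP fits and
    is echoed bit-exactly into the result. amp1 + amp2 = plateau is enforced by
    parametrization (F(0) = 0 on the normalized scale). Forcing amp2_fixed=0
    reduces the model to the whole-FRAP single exponential.
    """
    if traj.geometry != "half" and amp2_fixed is None:
        raise FrapFitError("fit_half_frap requires geometry='half'")
    if tau2 <= 0:
        raise FrapFitError("tau2 must be positive")
    t, y = _post_bleach(traj)
    lo, hi = _tau_bounds(t)
    plateau0 = float(np.clip(np.mean(y[-5:]), 1e-3, 1.05))
    flags: list[str] = []

    fixed2 = amp2_fixed is not None

    def model(tau1, amp1, amp2):
        return (amp1 + amp2) - amp1 * np.exp(-t / tau1) - amp2 * np.exp(-t / tau2)

    if fixed2:
        def resid(x):
            return model(x[0], x[1], amp2_fixed) - y
        x0 = np.array([_init_tau(t, y, plateau0), plateau0 - amp2_fixed])
        lb, ub = [lo, 0.0], [hi, 1.1]
    else:
        def resid(x):
            return model(x[0], x[1], x[2]) - y
        x0 = np.array([min(_init_tau(t, y, plateau0), tau2 / 3.0), plateau0 / 2, plateau0 / 2])
        lb, ub = [lo, 0.0, 0.0], [hi, 1.1, 1.1]

    x0 = np.clip(x0, lb, ub)
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(_N_RESTARTS):
        start = x0 if attempt == 0 else np.clip(
            x0 * rng.uniform(0.3, 3.0, size=x0.size), lb, ub
        )
        res = least_squares(resid, start, bounds=(lb, ub))
        if best is None or res.cost < best.cost:
            best = res
        if best.success and attempt == 0:
            break
    tau1 = float(best.x[0])
    amp1 = float(best.x[1])
    amp2 = float(amp2_fixed) if fixed2 else float(best.x[2])
    converged = bool(best.success)
    # tie-break on the degenerate manifold: when the fitted fast component is
    # indistinguishable from the fixed slow one (tau1 ~ tau2 the amplitude
    # split is arbitrary), attribute everything to nucleoplasmic exchange
    if not fixed2 and abs(tau1 - tau2) < 0.01 * tau2:
        amp2 += amp1
        amp1 = 0.0
        flags.append("components-degenerate")
    if tau1 <= lo * (1 + 1e-6) or tau1 >= hi * (1 - 1e-6):
        flags.append("tau1-at-bound")
        converged = False
    plateau = amp1 + amp2
    return HalfFrapFit(
        tau1=tau1,
        tau2_fixed=tau2,
        amp1=amp1,
        amp2=amp2,
        plateau=plateau,
        percent_recovery=100.0 * plateau,
        rss=float(2 * best.cost),
        converged=converged,
        flags=tuple(flags),
        cell_id=traj.cell_id,
        condition=traj.condition,
    )


def percent_recovery(fit: WholeFrapFit | HalfFrapFit) -> float:
    """Plateau fluorescence as a percentage of normalized pre-bleach intensity."""
    if not fit.converged:
        raise UnconvergedFitError(
            f"fit did not converge (flags: {', '.join(fit.flags) or 'none'}); "
            "inspect flags/rss before extracting percent recovery"
        )
    return 100.0 * fit.plateau


_FIELD_OWNERS = {"tau": WholeFrapFit, "tau1": HalfFrapFit, "percent_recovery": (WholeFrapFit, HalfFrapFit)}


def compare_groups(a, b, field: str, *, welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t test on a fitted field across two groups of fits."""
    if field not in _FIELD_OWNERS:
        raise ValueError(f"field must be one of {sorted(_FIELD_OWNERS)}")
    owner = _FIELD_OWNERS[field]
    for grp, name in ((a, "a"), (b, "b")):
        types = {type(f) for f in grp}
        if len(types) > 1:
            raise FrapFitError(f"group {name} mixes fit types: {sorted(t.__name__ for t in types)}")
        for f in grp:
            if not isinstance(f, owner):
                raise FrapFitError(f"field {field!r} not defined on {type(f).__name__}")
    va = [getattr(f, field) for f in a]
    vb = [getattr(f, field) for f in b]
    return two_sample_t(va, vb, welch=welch, label=field)


def fit_frap_dataset(
    whole: list[FrapTrajectory], half: list[FrapTrajectory], *, tau2_mode: str = "condition_mean"
):
    """Whole fits first, then constrained half fits with the injected tau2.

    tau2_mode 'condition_mean' fixes each half fit's tau2 to the mean converged
    whole-FRAP tau of the matching condition; 'per_cell' pairs by cell_id;
    'global' uses the grand mean. Returns (whole_fits, half_fits, tau2_by_condition).
    """
    whole_fits = [fit_whole_frap(_ensure_normalized(t)) for t in whole]
    by_cond: dict[str, list[float]] = {}
    by_cell: dict[str, float] = {}
    for f in whole_fits:
        if f.converged:
            by_cond.setdefault(f.condition, []).append(f.tau)
            by_cell[f.cell_id] = f.tau
    tau2_by_cond = {c: float(np.mean(v)) for c, v in by_cond.items()}
    all_taus = [f.tau for f in whole_fits if f.converged]
    grand = float(np.mean(all_taus)) if all_taus else None

    half_fits = []
    for t in half:
        if tau2_mode == "per_cell":
            tau2 = by_cell.get(t.cell_id)
        elif tau2_mode == "global":
            tau2 = grand
        else:
            tau2 = tau2_by_cond.get(t.condition, grand)
        if tau2 is None:
            raise FrapFitError(
                f"no whole-FRAP tau available for half-FRAP curve {t.cell_id!r} "
                f"(condition {t.condition!r}); fit whole-FRAP first or pass tau2 explicitly"
            )
        half_fits.append(fit_half_frap(_ensure_normalized(t), tau2))
    return whole_fits, half_fits, tau2_by_cond


def _ensure_normalized(traj: FrapTrajectory) -> NormalizedTrajectory:
    if isinstance(traj, NormalizedTrajectory):
        return traj
    t = traj
    if t.bleach_index is None:
        t = replace(t, bleach_index=detect_bleach_index(t))
    return normalize_trajectory(t)
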