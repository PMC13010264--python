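"""Correlating nanomechanical evolution with material loss.

Builds per-nanodomain degradation trajectories (relative volume, E*_av,
relative activity), quantifies the coupling between degradation rate and
surface stiffness, and classifies the E*_av-vs-loss shape as

* *continuous* — modulus rises in parallel with degradation from the start
  (layer-by-layer surface ablation, the cellulase signature), or
* *biphasic* — a near-flat initial phase followed by a sharp rise
  (cavity/fragmentation degradation, the cellulosome signature),

by comparing a single line against a continuous two-segment piecewise
linear fit with a small-sample-corrected information criterion (AICc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .afm import scale_series
from .errors import DegenerateScaleError, InputError, InsufficientDataError

__all__ = [
    "DegradationTrajectory",
    "PatternResult",
    "CorrelationResult",
    "build_trajectory",
    "correlate_rate_stiffness",
    "classify_pattern",
    "plot_trajectory",
    "plot_rate_vs_stiffness",
]


@dataclass
class DegradationTrajectory:
    """Flag-filtered, normalized per-frame degradation record."""

    times: np.ndarray  # min
    rel_volume: np.ndarray  # V(t)/V(0)
    estar_av: np.ndarray  # MPa (raw)
    estar_scaled: np.ndarray  # 0-100 %, NaN if the series is constant
    activity: np.ndarray  # %/min, NaN for the first frame
    scale_defined: bool = True

    def __len__(self) -> int:
        return len(self.times)

    @property
    def loss_pct(self) -> np.ndarray:
        return 100.0 * (1.0 - self.rel_volume)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_min": self.times,
            "rel_volume": self.rel_volume,
            "estar_av": self.estar_av,
            "estar_av_scaled": self.estar_scaled,
            "activity_pct_per_min": self.activity,
        })


@dataclass
class PatternResult:
    label: str  # "continuous" | "biphasic" | "insufficient-data"
    breakpoint_loss_pct: float | None
    slope_first: float | None
    slope_second: float | None
    slope_single: float
    aicc_single: float
    aicc_two_segment: float

    @property
    def delta_aicc(self) -> float:
        """AICc(single) - AICc(two-segment); positive favours biphasic."""
        return self.aicc_single - self.aicc_two_segment


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float
    n: int
    defined: bool = True


def build_trajectory(records) -> DegradationTrajectory:
    """Assemble a trajectory from per-frame pipeline records.

    ``records`` is the list of dicts produced by
    :func:`cellodyn.afm.process_stack` (keys: time_min, volume_nm3,
    estar_av, activity_pct_per_min, excluded).  Excluded frames are
    dropped; the volume is normalized to the first retained frame and
    E*_av linearly scaled to 0-100%.
    """
    kept = [r for r in records if not r.get("excluded", False)]
    if not kept:
        raise InputError("all frames excluded; empty trajectory")
    times = np.array([r["time_min"] for r in kept], dtype=float)
    vol = np.array([r["volume_nm3"] for r in kept], dtype=float)
    estar = np.array([r["estar_av"] for r in kept], dtype=float)
    act = np.array([r.get("activity_pct_per_min", np.nan) for r in kept], dtype=float)
    if vol[0] <= 0:
        raise InputError("initial volume must be positive")
    try:
        scaled = scale_series(estar)
        defined = True
    except DegenerateScaleError:
        scaled = np.full_like(estar, np.nan)
        defined = False
    return DegradationTrajectory(times=times, rel_volume=vol / vol[0], estar_av=estar,
                                 estar_scaled=scaled, activity=act, scale_defined=defined)


def correlate_rate_stiffness(traj: DegradationTrajectory, lag: int = 0) -> CorrelationResult:
    """Couple degradation rate to surface stiffness.

    Least-squares slope of activity against scaled E*_av plus the Spearman
    rank correlation (invariant under any monotone rescaling of E*_av).
    ``lag`` pairs the activity at frame i with E*_av at frame i - lag.
    """
    if not traj.scale_defined:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, 0, defined=False)
    act = traj.activity
    est = traj.estar_scaled
    if lag > 0:
        act, est = act[lag:], est[:-lag]
    ok = np.isfinite(act) & np.isfinite(est)
    n = int(np.count_nonzero(ok))
    if n < 4:
        raise InsufficientDataError("need >= 4 paired (activity, E*_av) points")
    x, y = est[ok], act[ok]
    if np.ptp(x) < 1e-12:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, n, defined=False)
    slope, intercept = np.polyfit(x, y, 1)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(slope), float(intercept), float(rho), float(p), n)


# --------------------------------------------------------------------------
# continuous vs biphasic classification
# --------------------------------------------------------------------------

def _aicc(rss: float, n: int, k: int) -> float:
    """AICc for a Gaussian model with RSS; k counts mean-model params + sigma."""
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return np.inf
    return aic + 2 * k * (k + 1) / denom


def _two_segment_fit(x, y, bp):
    """Continuous piecewise-linear lstsq fit with a fixed breakpoint."""
    A = np.column_stack([np.ones_like(x), x, np.clip(x - bp, 0.0, None)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((A @ coef - y) ** 2))
    return coef, rss


def classify_pattern(traj_or_xy, flat_slope_frac: float = 0.2,
                     n_breakpoints: int = 50) -> PatternResult:
    """Label an E*_av-vs-loss trajectory as continuous or biphasic.

    A single straight line is compared by AICc against the best
    *lag-compatible* continuous two-segment piecewise-linear model (two
    extra parameters: second slope and breakpoint): among breakpoint
    candidates on a grid spanning the interior of the observed loss range,
    only fits whose first segment is nearly flat (|slope| below
    ``flat_slope_frac`` times the single-line slope magnitude) qualify —
    the biphasic pattern of interest is a lag phase followed by a rise,
    not an arbitrary slope change.  The pattern is biphasic iff such a fit
    exists and beats the single line on AICc.

    Accepts either a :class:`DegradationTrajectory` (x = volume loss %,
    y = scaled E*_av) or an ``(x, y)`` tuple.
    """
    if isinstance(traj_or_xy, DegradationTrajectory):
        x = traj_or_xy.loss_pct
        y = traj_or_xy.estar_scaled if traj_or_xy.scale_defined else traj_or_xy.estar_av
    else:
        x, y = traj_or_xy
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 6:
        return PatternResult("insufficient-data", None, None, None,
                             np.nan, np.nan, np.nan)
    order = np.argsort(x)
    x, y = x[order], y[order]

    slope1, intercept1 = np.polyfit(x, y, 1)
    rss1 = float(np.sum((slope1 * x + intercept1 - y) ** 2))
    aicc1 = _aicc(rss1, n, 3)  # intercept, slope, sigma

    # breakpoint grid: interior of the observed range, at least one point
    # on each side of every candidate
    lo, hi = x[1], x[-2]
    if hi <= lo:
        return PatternResult("continuous", None, None, None,
                             float(slope1), aicc1, np.inf)
    grid = np.linspace(lo, hi, n_breakpoints)
    flat_cut = flat_slope_frac * max(abs(slope1), 1e-12)
    best = None       # best two-segment fit overall (reported slopes)
    best_flat = None  # best fit with a lag-phase (flat) first segment
    for bp in grid:
        if np.count_nonzero(x < bp) < 2 or np.count_nonzero(x > bp) < 2:
            continue
        coef, rss = _two_segment_fit(x, y, bp)
        if best is None or rss < best[1]:
            best = (coef, rss, bp)
        if abs(coef[1]) < flat_cut and (best_flat is None or rss < best_flat[1]):
            best_flat = (coef, rss, bp)
    if best is None:
        return PatternResult("continuous", None, None, None,
                             float(slope1), aicc1, np.inf)

    if best_flat is not None:
        coef, rss2, bp = best_flat
        aicc2 = _aicc(rss2, n, 5)  # intercept, 2 slopes, breakpoint, sigma
        if aicc2 < aicc1:
            return PatternResult("biphasic", float(bp), float(coef[1]),
                                 float(coef[1] + coef[2]), float(slope1),
                                 aicc1, aicc2)
    coef, rss2, bp = best
    aicc2 = _aicc(rss2, n, 5)
    return PatternResult("continuous", None, float(coef[1]),
                         float(coef[1] + coef[2]), float(slope1), aicc1, aicc2)


# --------------------------------------------------------------------------
# plots
# --------------------------------------------------------------------------

def plot_trajectory(traj: DegradationTrajectory, path):
    """Relative volume and E*_av (0-100%) against time."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(traj.times, traj.rel_volume * 100.0, "o-", label="relative volume (%)")
    if traj.scale_defined:
        ax.plot(traj.times, traj.estar_scaled, "s-", label="E*_av (scaled, %)")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("% of range")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rate_vs_stiffness(traj: DegradationTrajectory, path):
    """Relative activity against scaled E*_av."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ok = np.isfinite(traj.activity)
    ax.plot(traj.estar_scaled[ok], traj.activity[ok], "o")
    ax.set_xlabel("E*_av (scaled, %)")
    ax.set_ylabel("relative activity (%/min)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
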