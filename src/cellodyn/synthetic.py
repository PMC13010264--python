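"""Synthetic ground-truth generators for every pipeline input.

The generators emulate the measurements the pipeline consumes, with full
knowledge of the truth so that every analysis stage can be verified without
experimental data:

* isotope-competition glucose-fraction series (via the kinetics model plus
  truncated-Gaussian fraction noise);
* a core-shell cellulose fibril phantom: a rounded ridge (half-elliptical
  cross-section) 10-30 nm wide and ~20 nm tall with a stiff crystalline
  core under a softer surface shell, and periodically spaced soft segments
  (twists/fiber ends) along its length;
* time-lapse degradation stacks in two modes:
  - *ablation* (cellulase-like): uniform layer-by-layer erosion that thins
    the ridge laterally while the exposed surface follows the core-shell
    depth profile, so the surface stiffens monotonically with volume loss;
  - *fragmentation* (cellulosome-like): full-depth cavities nucleate
    (preferentially at soft segments) and expand, cutting the fiber into
    fragments; the surface modulus stays at the shell value until fragments
    shorten below ~150 nm, then rises sharply (biphasic truth);
* imaging corruptions applied after degradation: sample tilt, frame-to-
  frame drift, additive height/modulus noise and per-frame multiplicative
  gain jitter (tip and laser drift surrogates);
* single synthetic force-distance curves from the same adhesive contact
  model the fitter assumes;
* lightweight (loss, E*_av, activity) trajectories for large Monte-Carlo
  classification studies.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .afm import ForceCurve, FrameStack, MapFrame, dmt_force
from .errors import InputError
from .kinetics import AdsorptionParams, CompetitionDesign, CompetitionSeries, simulate_competition

__all__ = [
    "FibrilPhantom",
    "DegradationScenario",
    "GroundTruth",
    "gen_competition_data",
    "gen_fibril_phantom",
    "gen_ablation_stack",
    "gen_fragmentation_stack",
    "gen_force_curve",
    "gen_trajectory",
]

#: fragment length below which near-complete degradation exposes the core
FRAGMENT_LENGTH_THRESHOLD_NM = 150.0

#: modulus of the flat HOPG support before gain jitter (MPa)
HOPG_TRUE_MODULUS = 1000.0


# --------------------------------------------------------------------------
# competition data
# --------------------------------------------------------------------------

def gen_competition_data(truth: AdsorptionParams, design: CompetitionDesign, seed: int = 0):
    """Noisy competition series plus the generating truth record.

    Noise is truncated-Gaussian on the 12C fraction (clipped to [0, 1]) and
    the pair renormalized to sum to one.
    """
    if design.noise_sd >= 0.5:
        raise InputError("noise_sd >= 0.5 makes fractions meaningless")
    series = simulate_competition(truth, design, seed=seed)
    record = {"k_off": truth.k_off, "E_i": truth.E_i, "k_on": truth.k_on,
              "kcat_app": truth.kcat_app, "seed": seed, "noise_sd": design.noise_sd}
    return series, record


# --------------------------------------------------------------------------
# fibril phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FibrilPhantom:
    """Core-shell cellulose fibril bundle with periodic soft segments.

    The cross-section is a half-ellipse (width x height), giving the
    closed-form volume ``pi/4 * length * width * height``.  The modulus
    seen at erosion depth ``d`` follows a logistic transition from the
    shell to the core value across the shell thickness; soft segments
    multiply the modulus by ``soft_factor``.
    """

    length_nm: float = 1000.0
    width_nm: float = 24.0
    height_nm: float = 20.0
    E_core: float = 40.0  # MPa
    E_shell: float = 15.0  # MPa
    shell_thickness_nm: float = 6.0
    soft_spacing_nm: float = 250.0
    soft_width_nm: float = 24.0
    soft_factor: float = 0.7

    def __post_init__(self) -> None:
        if self.length_nm < 250.0:
            raise InputError("phantom must span >= 250 nm of regular nanostructure")
        if not (0 < self.E_shell < self.E_core):
            raise InputError("need E_core > E_shell > 0")
        if self.shell_thickness_nm >= self.height_nm / 2:
            raise InputError("shell thicker than half the ridge height")
        if not 0 < self.soft_factor <= 1:
            raise InputError("soft_factor must be in (0, 1]")

    @property
    def volume_nm3(self) -> float:
        """Closed-form volume of the half-elliptical ridge."""
        return np.pi / 4.0 * self.length_nm * self.width_nm * self.height_nm

    def modulus_at_depth(self, depth_nm) -> np.ndarray:
        """Surface modulus after eroding ``depth_nm`` of material.

        Logistic shell->core transition pinned to the exact endpoint values:
        E(0) = E_shell and E(d >= shell thickness) = E_core.
        """
        d = np.clip(np.asarray(depth_nm, dtype=float), 0.0, self.shell_thickness_nm)
        ts = self.shell_thickness_nm
        raw = 1.0 / (1.0 + np.exp(-(d - ts / 2.0) / (ts / 8.0)))
        lo = 1.0 / (1.0 + np.exp(ts / 2.0 / (ts / 8.0)))
        hi = 1.0 / (1.0 + np.exp(-ts / 2.0 / (ts / 8.0)))
        u = (raw - lo) / (hi - lo)
        return self.E_shell + (self.E_core - self.E_shell) * u


def _soft_mask_1d(phantom: FibrilPhantom, x_nm: np.ndarray) -> np.ndarray:
    """Columns (along the fiber axis) belonging to periodic soft segments."""
    if phantom.soft_spacing_nm <= 0:
        return np.zeros_like(x_nm, dtype=bool)
    phase = np.mod(x_nm + phantom.soft_spacing_nm / 2.0, phantom.soft_spacing_nm)
    return np.abs(phase - phantom.soft_spacing_nm / 2.0) < phantom.soft_width_nm / 2.0


def gen_fibril_phantom(
    phantom: FibrilPhantom,
    pixel_size: float = 2.0,
    canvas_shape: tuple | None = None,
    *,
    supersample: int = 4,
):
    """Rasterize the phantom to (height map, surface modulus map, meta).

    The height is area-averaged over ``supersample**2`` sub-pixel samples so
    the rasterized volume tracks the analytic value closely even at the
    default 2 nm/px.  The returned modulus map is the zero-erosion surface:
    the shell value everywhere on the fiber (softened at the soft segments)
    and the HOPG value on the background.
    """
    if canvas_shape is None:
        nx = int(round((phantom.length_nm + 120.0) / pixel_size))
        ny = int(round((phantom.width_nm + 96.0) / pixel_size))
        canvas_shape = (ny, nx)
    ny, nx = canvas_shape
    y0 = ny * pixel_size / 2.0
    x0 = nx * pixel_size / 2.0

    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss
    height = np.zeros(canvas_shape)
    for oy in offs:
        for ox in offs:
            Y = (np.arange(ny)[:, None] + oy) * pixel_size - y0
            X = (np.arange(nx)[None, :] + ox) * pixel_size - x0
            u = 2.0 * Y / phantom.width_nm
            inside = (np.abs(u) < 1.0) & (np.abs(X) < phantom.length_nm / 2.0)
            h = np.where(inside, phantom.height_nm * np.sqrt(np.clip(1.0 - u ** 2, 0.0, 1.0)), 0.0)
            height += h
    height /= ss * ss

    x_centers = (np.arange(nx) + 0.5) * pixel_size - x0
    soft_cols = _soft_mask_1d(phantom, x_centers)
    fiber = height > 0
    surf = phantom.modulus_at_depth(0.0) * np.ones(canvas_shape)
    surf[:, soft_cols] *= phantom.soft_factor
    modulus = np.where(fiber, surf, HOPG_TRUE_MODULUS)
    meta = {"pixel_size": pixel_size, "soft_cols": soft_cols, "x_centers": x_centers,
            "fiber_mask": fiber, "x0": x0, "y0": y0}
    return height, modulus, meta


# --------------------------------------------------------------------------
# degradation scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationScenario:
    """Degradation program plus the imaging corruptions of one experiment.

    Defaults mimic the time-lapse measurement conditions: ~5 min frame
    interval over ~2 h, sub-nm height noise, ~5% modulus noise, per-frame
    gain jitter up to +/-20% and slow lateral drift of a few nm per frame.
    """

    mode: str = "ablation"
    ablation_rate_nm: float = 1.2  # initial height removed per frame
    ablation_slowdown: float = 1.0  # rate reduction at full surface stiffening
    cavity_intensity: float = 0.6  # expected nucleations per frame
    cavity_growth_nm: float = 24.0  # max cavity-edge advance per frame (cap)
    cavity_initial_nm: float = 10.0
    fragment_erode_nm: float = 2.0  # per-frame erosion of sub-threshold fragments
    loss_rate_frac: float = 0.022  # fragmentation: target volume loss per frame
    rate_jitter: float = 0.05  # relative sd of the per-frame loss target
    n_frames: int = 24
    frame_interval_min: float = 5.0
    drift_per_frame_nm: tuple = (1.2, -0.8)  # (row, col)
    tilt_gradient: tuple = (0.004, 0.006)  # nm per px (row, col)
    height_noise_nm: float = 0.3
    modulus_noise_frac: float = 0.05
    gain_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ablation", "fragmentation"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.n_frames < 2:
            raise InputError("need at least two frames")
        if self.ablation_rate_nm < 0 or self.cavity_growth_nm < 0 or self.cavity_intensity < 0:
            raise InputError("rates must be non-negative")
        duration = (self.n_frames - 1) * self.frame_interval_min
        if duration > 180.0:
            raise InputError("total duration exceeds the ~2 h imaging window")


@dataclass
class GroundTruth:
    """Pre-corruption truth for one synthetic degradation experiment."""

    mode: str
    times: np.ndarray
    true_volume: np.ndarray  # nm^3
    true_surface_modulus: np.ndarray  # mean E over fiber surface, MPa
    true_masks: list
    loss_pct: np.ndarray = field(default=None)
    breakpoint_loss_pct: float | None = None
    applied_drift: np.ndarray | None = None
    applied_gain: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.loss_pct is None:
            v0 = self.true_volume[0]
            self.loss_pct = 100.0 * (1.0 - self.true_volume / v0) if v0 > 0 else np.zeros_like(self.true_volume)


def _corrupt_frames(heights, moduli, scenario, pixel_size, times, rng):
    """Apply tilt, cumulative drift, gain jitter and noise; return MapFrames."""
    ny, nx = heights[0].shape
    Y, X = np.mgrid[0:ny, 0:nx]
    tilt = scenario.tilt_gradient[0] * Y + scenario.tilt_gradient[1] * X
    gains = 1.0 + rng.uniform(-scenario.gain_jitter, scenario.gain_jitter, size=len(heights))
    drifts = np.zeros((len(heights), 2))
    frames = []
    for k, (h, m) in enumerate(zip(heights, moduli)):
        drift_px = (k * np.asarray(scenario.drift_per_frame_nm)) / pixel_size
        drifts[k] = drift_px
        h_d = ndimage.shift(h, drift_px, order=1, mode="nearest") if k else h.copy()
        m_d = ndimage.shift(m, drift_px, order=1, mode="nearest") if k else m.copy()
        h_d = h_d + tilt + rng.normal(0.0, scenario.height_noise_nm, h.shape)
        m_d = gains[k] * m_d * (1.0 + rng.normal(0.0, scenario.modulus_noise_frac, m.shape))
        m_d = np.clip(m_d, 1e-3, None)
        frames.append(MapFrame(height=h_d, modulus=m_d, pixel_size=pixel_size, time=times[k]))
    return frames, drifts, gains


def _truth_breakpoint(loss_pct, modulus_series) -> float | None:
    """Knee of the noise-free truth curve (two-segment piecewise fit)."""
    from .degradation import classify_pattern

    ok = np.isfinite(modulus_series)
    if np.count_nonzero(ok) < 6:
        return None
    res = classify_pattern((loss_pct[ok], modulus_series[ok]))
    return res.breakpoint_loss_pct


def gen_ablation_stack(phantom: FibrilPhantom, scenario: DegradationScenario,
                       seed: int | None = None, pixel_size: float = 2.0):
    """Layer-by-layer (cellulase-like) degradation stack plus ground truth.

    Each frame removes a uniform layer from the remaining material; columns
    thinner than the cumulative erosion disappear, so the ridge thins
    laterally while the exposed surface follows the core-shell depth
    profile and the true surface-mean modulus rises monotonically with
    volume loss.  The per-frame erosion rate slows as the exposed surface
    stiffens (``rate = rate0 * (1 - slowdown * s)`` with s the 0-1 scaled
    depth modulus), reproducing the cellulase signature of activity
    dropping while E*_av rises.
    """
    if scenario.mode != "ablation":
        raise InputError("scenario.mode must be 'ablation'")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    h0, _m0, meta = gen_fibril_phantom(phantom, pixel_size)
    soft_cols = meta["soft_cols"]
    times = np.arange(scenario.n_frames) * scenario.frame_interval_min

    e_span = phantom.E_core - phantom.E_shell
    heights, moduli, masks, vols, mod_means = [], [], [], [], []
    depth = 0.0
    for k in range(scenario.n_frames):
        if k > 0:
            s = (phantom.modulus_at_depth(depth) - phantom.E_shell) / e_span
            depth += scenario.ablation_rate_nm * (1.0 - scenario.ablation_slowdown * float(s))
        h = np.clip(h0 - depth, 0.0, None)
        fiber = h > 1e-9
        surf = phantom.modulus_at_depth(depth) * np.ones_like(h)
        surf[:, soft_cols] *= phantom.soft_factor
        m = np.where(fiber, surf, HOPG_TRUE_MODULUS)
        heights.append(h)
        moduli.append(m)
        masks.append(fiber)
        vols.append(float(h.sum() * pixel_size ** 2))
        mod_means.append(float(surf[fiber].mean()) if fiber.any() else np.nan)

    frames, drifts, gains = _corrupt_frames(heights, moduli, scenario, pixel_size, times, rng)
    vols = np.array(vols)
    mod_means = np.array(mod_means)
    truth = GroundTruth(mode="ablation", times=times, true_volume=vols,
                        true_surface_modulus=mod_means, true_masks=masks,
                        applied_drift=drifts, applied_gain=gains)
    truth.breakpoint_loss_pct = None
    return FrameStack(frames), truth


def _nucleation_weights(phantom, x_centers, soft_cols, removed):
    """Per-column nucleation probabilities on the remaining material.

    3:1 bias toward the preferred soft-segment sites (75% of nucleations),
    uniform within each class.
    """
    fiber_cols = (np.abs(x_centers) < phantom.length_nm / 2.0) & ~removed
    soft = soft_cols & fiber_cols
    hard = fiber_cols & ~soft
    weights = np.zeros(len(x_centers))
    if soft.any() and hard.any():
        weights[soft] = 0.75 / soft.sum()
        weights[hard] = 0.25 / hard.sum()
    elif fiber_cols.any():
        weights[fiber_cols] = 1.0 / fiber_cols.sum()
    return weights


def gen_fragmentation_stack(phantom: FibrilPhantom, scenario: DegradationScenario,
                            seed: int | None = None, pixel_size: float = 2.0):
    """Cavity/fragmentation (cellulosome-like) degradation stack plus truth.

    Full-depth cavities nucleate as a Poisson process along the fiber,
    biased 3:1 toward the soft segments, and widen every frame.  Remaining
    fragments keep their shell-surface modulus until they shorten below
    ~150 nm; such short fragments then undergo near-complete degradation
    (progressive erosion) with their exposed surface ramping toward the
    core value — producing the biphasic (flat-then-rising) E*_av truth
    while volume is lost from the start.

    The total material loss per frame is rate-controlled at
    ``loss_rate_frac`` of the initial volume, partitioned between cavity
    expansion (dominant early) and short-fragment consumption (dominant
    late): the hallmark of the cellulosome is that its degradation rate is
    unaffected by the stiffening of the remaining substrate.
    """
    if scenario.mode != "fragmentation":
        raise InputError("scenario.mode must be 'fragmentation'")
    if scenario.cavity_intensity == 0 and scenario.cavity_growth_nm > 0:
        import warnings
        warnings.warn("cavity growth without nucleation is a no-op")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    h0, _m0, meta = gen_fibril_phantom(phantom, pixel_size)
    soft_cols = meta["soft_cols"]
    x_centers = meta["x_centers"]
    times = np.arange(scenario.n_frames) * scenario.frame_interval_min

    nx = len(x_centers)
    in_fiber = np.abs(x_centers) < phantom.length_nm / 2.0
    removed = np.zeros(nx, dtype=bool)
    depth_col = np.zeros(nx)  # cumulative erosion of short fragments
    px_area = pixel_size ** 2
    V0 = float(h0.sum() * px_area)
    cap_px = max(int(round(scenario.cavity_growth_nm / pixel_size)), 1)
    half_init = max(int(round(scenario.cavity_initial_nm / 2.0 / pixel_size)), 1)

    def col_mass(cols) -> float:
        h = np.clip(h0[:, cols] - depth_col[cols][None, :], 0.0, None)
        return float(h.sum() * px_area * (~removed[cols]).any())

    def remaining_height() -> np.ndarray:
        return np.clip(h0 - depth_col[None, :], 0.0, None) * (~removed)[None, :]

    def short_fragment_cols():
        keep = remaining_height().any(axis=0)
        out = np.zeros(nx, dtype=bool)
        lengths = {}
        if keep.any():
            lbl, nlab = ndimage.label(keep)
            for lab in range(1, nlab + 1):
                cols = lbl == lab
                frag_len = cols.sum() * pixel_size
                lengths[lab] = (cols, frag_len)
                if frag_len < FRAGMENT_LENGTH_THRESHOLD_NM:
                    out |= cols
        return out, lengths

    heights, moduli, masks, vols, mod_means = [], [], [], [], []
    carry = 0.0  # column-quantization remainder carried between frames
    for k in range(scenario.n_frames):
        if k > 0:
            target = scenario.loss_rate_frac * V0 * (
                1.0 + scenario.rate_jitter * rng.standard_normal())
            budget = max(target, 0.0) + carry

            # (a) cavity nucleation; the rate ramps up linearly in time
            # (fragmentation intensifies late, mean rate = cavity_intensity)
            # and the attack is underway at the first observed interval
            lam = scenario.cavity_intensity * 2.0 * k / max(scenario.n_frames - 1, 1)
            n_new = rng.poisson(lam)
            if k == 1:
                n_new = max(n_new, 1)
            for _ in range(n_new):
                w = _nucleation_weights(phantom, x_centers, soft_cols, removed)
                if w.sum() <= 0:
                    break
                c = int(rng.choice(nx, p=w))
                span = slice(max(c - half_init, 0), min(c + half_init + 1, nx))
                before = float(remaining_height()[:, span].sum() * px_area)
                if before > budget:
                    break  # defer: nucleation may not exceed the rate budget
                removed[span] = True
                budget -= before

            # (b) short fragments erode, capped at half the remaining rate
            # budget so cavity expansion and fragment consumption coexist
            short, _ = short_fragment_cols()
            if short.any() and budget > 0:
                erode_budget = 0.5 * budget
                area_per_nm = float((remaining_height()[:, short] > 0).sum() * px_area)
                if area_per_nm > 0:
                    d = min(scenario.fragment_erode_nm, erode_budget / area_per_nm)
                    before = float(remaining_height().sum() * px_area)
                    depth_col[short] += d
                    budget -= before - float(remaining_height().sum() * px_area)

            # (c) cavity edges (and the receding fiber ends) advance with
            # the leftover budget
            for _pass in range(cap_px):
                eroding = removed | ~in_fiber
                if budget <= 0 or not eroding.any():
                    break
                lbl, nlab = ndimage.label(eroding)
                for lab in range(1, nlab + 1):
                    run = np.nonzero(lbl == lab)[0]
                    for c in (run[0] - 1, run[-1] + 1):
                        if budget <= 0:
                            break
                        if 0 <= c < nx and in_fiber[c] and not removed[c]:
                            m = float(np.clip(h0[:, c] - depth_col[c], 0.0, None).sum() * px_area)
                            removed[c] = True
                            budget -= m
            carry = budget if np.isfinite(budget) else 0.0

        h = remaining_height()
        fiber = h > 1e-9

        # exposed-surface modulus: fragments below the length threshold
        # ramp toward the core (length rule or accumulated erosion,
        # whichever is deeper)
        surf_1d = phantom.modulus_at_depth(depth_col)
        _, lengths = short_fragment_cols()
        for cols, frag_len in lengths.values():
            if frag_len < FRAGMENT_LENGTH_THRESHOLD_NM:
                ramp = phantom.shell_thickness_nm * (1.0 - frag_len / FRAGMENT_LENGTH_THRESHOLD_NM)
                surf_1d[cols] = phantom.modulus_at_depth(np.maximum(depth_col[cols], ramp))
        surf = np.tile(surf_1d, (h.shape[0], 1))
        surf[:, soft_cols] *= phantom.soft_factor
        m = np.where(fiber, surf, HOPG_TRUE_MODULUS)
        heights.append(h)
        moduli.append(m)
        masks.append(fiber)
        vols.append(float(h.sum() * px_area))
        mod_means.append(float(surf[fiber].mean()) if fiber.any() else np.nan)

    frames, drifts, gains = _corrupt_frames(heights, moduli, scenario, pixel_size, times, rng)
    vols = np.array(vols)
    mod_means = np.array(mod_means)
    truth = GroundTruth(mode="fragmentation", times=times, true_volume=vols,
                        true_surface_modulus=mod_means, true_masks=masks,
                        applied_drift=drifts, applied_gain=gains)
    truth.breakpoint_loss_pct = _truth_breakpoint(truth.loss_pct, mod_means)
    return FrameStack(frames), truth


# --------------------------------------------------------------------------
# force curves and trajectories
# --------------------------------------------------------------------------

def gen_force_curve(modulus: float, tip_radius: float = 5.0, adhesion: float = 0.2,
                    noise_sd: float = 0.0, seed: int | None = None,
                    peak_force: float = 2.0, n_points: int = 256) -> ForceCurve:
    """Synthesize a force-distance curve from the adhesive contact model.

    The indentation range is chosen so the force reaches ``peak_force``
    (~2 nN by default, gentle enough not to damage cellulose).
    """
    if modulus <= 0:
        raise InputError("modulus must be positive")
    if tip_radius <= 0:
        raise InputError("tip radius must be positive")
    contact_point = 0.0
    delta_max = ((peak_force + adhesion) /
                 ((4.0 / 3.0) * modulus * 1e-3 * np.sqrt(tip_radius))) ** (2.0 / 3.0)
    # half the ramp samples the indentation regime, half the free air
    s = np.concatenate([
        np.linspace(contact_point - delta_max, contact_point, n_points // 2, endpoint=False),
        np.linspace(contact_point, contact_point + 3.0 * delta_max + 5.0, n_points - n_points // 2),
    ])
    f = dmt_force(s, modulus, contact_point, adhesion, tip_radius)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    retract = np.ones_like(s, dtype=bool)
    return ForceCurve(separation=s, force=f, retract=retract,
                      tip_radius=tip_radius, peak_force=peak_force)


def gen_trajectory(mode: str, n_points: int = 15, noise_sd: float = 5.0,
                   seed: int = 0, max_loss_pct: float = 85.0,
                   breakpoint_loss_pct: float = 40.0):
    """Lightweight (loss, scaled E*_av, activity) trajectory with known label.

    Used for large Monte-Carlo classification studies where rendering full
    image stacks would be wasteful.  Ablation: E*_av rises continuously
    with loss and activity declines with E*_av.  Fragmentation: E*_av is
    flat until the breakpoint, then rises; activity is loss-rate driven and
    unrelated to E*_av.  Noise is Gaussian on the 0-100 scaled modulus.
    """
    if mode not in ("ablation", "fragmentation"):
        raise InputError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    loss = np.linspace(0.0, max_loss_pct, n_points)
    if mode == "ablation":
        estar_true = 100.0 * (loss / max_loss_pct) ** 0.9
        activity = 1.0 + 0.02 * (100.0 - estar_true)
    else:
        bp = breakpoint_loss_pct
        estar_true = np.where(loss <= bp, 0.0, (loss - bp) / (max_loss_pct - bp) * 100.0)
        activity = np.full(n_points, 2.0)
    estar = estar_true + rng.normal(0.0, noise_sd, n_points)
    activity = activity * (1.0 + rng.normal(0.0, 0.05, n_points))
    return {"loss_pct": loss, "estar_scaled_true": estar_true, "estar_scaled": estar,
            "activity": activity, "label": "continuous" if mode == "ablation" else "biphasic",
            "breakpoint_loss_pct": None if mode == "ablation" else breakpoint_loss_pct}
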