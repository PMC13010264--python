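"""Time-lapse force-volume AFM nanomechanics.

Turns stacks of paired height (nm) / elastic-modulus (MPa) maps recorded on
cellulose fibrils deposited on HOPG into corrected, registered, segmented
frames and the quantities the degradation analysis consumes:

* ``E*`` — modulus normalized per frame to the HOPG background, which is
  assumed mechanically constant, so tip wear and laser drift cancel;
* ``E*_av`` — the arithmetic mean of E* over the fiber pixels of a
  nanodomain (minimum analysis area ~10,000 nm^2, 2500 points at the
  default 2 nm/px);
* fiber volume — height pixel sum times pixel area;
* relative activity — percent of the initial fiber material lost per
  minute, from the backward difference of the height pixel sum.

Single force-distance curves are reduced to modulus/adhesion/contact point
with a sphere-on-flat adhesive (DMT-form) contact model; a pure Hertz
variant (no adhesion) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize, signal, stats
from skimage import measure, morphology
from skimage.draw import polygon2mask
from skimage.registration import phase_cross_correlation

from .errors import (
    DegenerateScaleError,
    FitFailureError,
    InputError,
    InsufficientDataError,
    MaskError,
    NoContactError,
)

__all__ = [
    "ForceCurve",
    "ContactFit",
    "MapFrame",
    "FrameStack",
    "NanodomainROI",
    "EStarSummary",
    "fit_contact_model",
    "level_plane",
    "provisional_background",
    "register_drift",
    "segment_fiber",
    "normalize_modulus",
    "estar_distribution",
    "estar_av",
    "fiber_volume",
    "relative_activity",
    "scale_series",
    "process_stack",
]

# force prefactor: E [MPa] * nm^2 -> nN  (1 MPa = 1e-3 nN/nm^2)
_MPA_NM2_TO_NN = 1e-3

#: minimum nanodomain analysis area (nm^2) and point count
MIN_ROI_AREA_NM2 = 10_000.0
MIN_ROI_POINTS = 2500


# --------------------------------------------------------------------------
# force curves
# --------------------------------------------------------------------------

@dataclass
class ForceCurve:
    """A single force-distance curve (tip-sample separation vs force)."""

    separation: np.ndarray  # nm
    force: np.ndarray  # nN
    retract: np.ndarray  # boolean mask marking the retract segment
    tip_radius: float = 5.0  # nm
    peak_force: float = 2.0  # nN

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.retract = np.asarray(self.retract, dtype=bool)
        if not (len(self.separation) == len(self.force) == len(self.retract)):
            raise InputError("curve arrays must have equal length")
        if len(self.force) < 16:
            raise InputError("curve too short (< 16 samples)")
        if self.peak_force <= 0:
            raise InputError("peak force must be positive")


@dataclass
class ContactFit:
    modulus: float  # MPa
    adhesion: float  # nN
    contact_point: float  # nm
    residual: float  # RMS force residual, nN


def dmt_force(separation, modulus, contact_point, adhesion, tip_radius, *, hertz=False):
    """Sphere-on-flat contact force (nN) at the given separations (nm).

    DMT form: F = 4/3 * E * sqrt(R) * d^{3/2} - F_adh inside contact
    (indentation d = contact_point - separation > 0), zero outside.  With
    ``hertz=True`` the adhesive offset is dropped.
    """
    s = np.asarray(separation, dtype=float)
    delta = np.clip(contact_point - s, 0.0, None)
    f = (4.0 / 3.0) * modulus * _MPA_NM2_TO_NN * np.sqrt(tip_radius) * delta ** 1.5
    if not hertz:
        f = np.where(delta > 0, f - adhesion, 0.0)
    return f


def fit_contact_model(curve: ForceCurve, model: str = "dmt") -> ContactFit:
    """Extract local elastic modulus from the retract segment of a curve.

    A no-contact error is raised when the force never rises resolvably above
    the free-air baseline; a fit-failure error when the optimum is
    unphysical (non-positive modulus).
    """
    if model not in ("dmt", "hertz"):
        raise InputError(f"unknown contact model {model!r}")
    hertz = model == "hertz"
    s = curve.separation[curve.retract]
    f = curve.force[curve.retract]
    if len(s) < 16:
        raise InputError("retract segment too short")
    order = np.argsort(s)
    s, f = s[order], f[order]

    # free-air baseline from the far third of the curve
    far = s >= s[0] + 0.67 * (s[-1] - s[0])
    baseline = float(np.median(f[far]))
    noise = 1.4826 * float(np.median(np.abs(f[far] - baseline))) + 1e-12
    if np.max(f) - baseline < max(6.0 * noise, 0.02):
        raise NoContactError("no indentation regime above the adhesion baseline")

    # initial guesses: contact point from threshold crossing, adhesion from
    # the force minimum, modulus from the peak-force point
    above = np.nonzero(f > baseline + max(6.0 * noise, 0.02))[0]
    c0 = s[above[-1]] if len(above) else s[len(s) // 2]
    adh0 = max(baseline - float(np.min(f)), 0.0)
    delta_peak = max(c0 - s[0], 1e-3)
    e0 = max(
        (f[0] - baseline + adh0) / ((4.0 / 3.0) * _MPA_NM2_TO_NN * np.sqrt(curve.tip_radius) * delta_peak ** 1.5),
        1e-3,
    )

    def residuals(theta):
        log_e, c, adh = theta
        return dmt_force(s, np.exp(log_e), c, adh, curve.tip_radius, hertz=hertz) - (f - baseline)

    res = optimize.least_squares(
        residuals,
        x0=[np.log(e0), c0, adh0],
        bounds=([-10.0, s[0], 0.0], [20.0, s[-1], 10.0 * curve.peak_force]),
        method="trf",
    )
    modulus = float(np.exp(res.x[0]))
    if not res.success and res.status <= 0:
        raise FitFailureError(f"contact-model fit failed: {res.message}")
    if not np.isfinite(modulus) or modulus <= 0:
        raise FitFailureError("fitted modulus is non-positive")
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return ContactFit(modulus=modulus, adhesion=float(res.x[2]),
                      contact_point=float(res.x[1]), residual=rms)


# --------------------------------------------------------------------------
# map frames and stacks
# --------------------------------------------------------------------------

@dataclass
class MapFrame:
    """One co-registered height/modulus map pair."""

    height: np.ndarray  # nm
    modulus: np.ndarray  # MPa
    pixel_size: float  # nm
    time: float = 0.0  # min
    background_mask: np.ndarray | None = None
    fiber_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        self.modulus = np.asarray(self.modulus, dtype=float)
        if self.height.shape != self.modulus.shape:
            raise InputError("height and modulus must have the same shape")
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be positive")

    def copy(self) -> "MapFrame":
        return MapFrame(
            height=self.height.copy(),
            modulus=self.modulus.copy(),
            pixel_size=self.pixel_size,
            time=self.time,
            background_mask=None if self.background_mask is None else self.background_mask.copy(),
            fiber_mask=None if self.fiber_mask is None else self.fiber_mask.copy(),
        )


@dataclass
class FrameStack:
    """Ordered frames on a common grid."""

    frames: list
    offsets: np.ndarray | None = None  # (n, 2) applied (row, col) shifts
    registration_failed: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if len(times) >= 2 and np.any(np.diff(times) <= 0):
            raise InputError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)


@dataclass
class NanodomainROI:
    """Analysis region on the registered grid (rectangle or polygon).

    Rectangles are (row_start, row_stop, col_start, col_stop) half-open
    pixel slices; polygons are (row, col) vertex arrays.
    """

    kind: str = "rect"
    rect: tuple | None = None
    vertices: np.ndarray | None = None

    def to_mask(self, shape) -> np.ndarray:
        if self.kind == "rect":
            if self.rect is None:
                raise InputError("rect ROI needs a rect tuple")
            r0, r1, c0, c1 = self.rect
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            return m
        if self.kind == "polygon":
            if self.vertices is None:
                raise InputError("polygon ROI needs vertices")
            return polygon2mask(shape, np.asarray(self.vertices, dtype=float))
        raise InputError(f"unknown ROI kind {self.kind!r}")

    @classmethod
    def full_frame(cls, shape) -> "NanodomainROI":
        return cls(kind="rect", rect=(0, shape[0], 0, shape[1]))


@dataclass
class EStarSummary:
    mode: float
    mean: float
    skewness: float
    n: int
    unimodal: bool
    excluded: bool = False
    reason: str = ""


# --------------------------------------------------------------------------
# frame corrections
# --------------------------------------------------------------------------

def provisional_background(height: np.ndarray) -> np.ndarray:
    """Rough background mask for a raw frame (below-median plus noise band).

    Used to bootstrap plane leveling before any proper segmentation exists.
    """
    med = np.median(height)
    mad = 1.4826 * np.median(np.abs(height - med)) + 1e-12
    return height < med + 3.0 * mad


def level_plane(frame: MapFrame) -> MapFrame:
    """Subtract the least-squares background plane and zero the background.

    The plane is fitted on background pixels only, so tilt confined to the
    fiber does not perturb the correction; afterwards the background median
    height is zero.
    """
    if frame.background_mask is None:
        raise MaskError("level_plane requires a background mask")
    bg = frame.background_mask
    if np.count_nonzero(bg) < 0.10 * bg.size:
        raise MaskError("background mask covers less than 10% of the frame")
    rr, cc = np.nonzero(bg)
    A = np.column_stack([cc, rr, np.ones(len(rr))])
    coef, *_ = np.linalg.lstsq(A, frame.height[rr, cc], rcond=None)
    ny, nx = frame.height.shape
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
    plane = coef[0] * X + coef[1] * Y + coef[2]
    out = frame.copy()
    out.height = frame.height - plane
    out.height -= np.median(out.height[bg])
    return out


def auto_height_threshold(height: np.ndarray) -> float:
    """Background median plus five robust (MAD-based) standard deviations."""
    low = height[height <= np.percentile(height, 75)]
    med = np.median(low)
    sigma = 1.4826 * np.median(np.abs(low - med)) + 1e-12
    return float(med + 5.0 * sigma)


def material_mask(frame: MapFrame, height_threshold="auto", min_area_px: int = 25) -> np.ndarray:
    """All above-threshold substrate material, noise specks removed.

    Broader than the fiber class: includes attached fragments too small or
    too compact to pass the elongation filter.  Used for volumetrics and
    relative activity, where every bit of remaining material counts.
    """
    thr = auto_height_threshold(frame.height) if height_threshold == "auto" else float(height_threshold)
    above = frame.height > thr
    return morphology.remove_small_objects(above, max_size=min_area_px - 1)


def segment_fiber(
    frame: MapFrame,
    height_threshold="auto",
    *,
    min_area_px: int = 100,
    min_aspect: float = 3.0,
) -> MapFrame:
    """Classify pixels into fiber, background, and excluded residues.

    Fiber = connected components above the height threshold that are large
    (>= ``min_area_px``) and elongated (major/minor axis >= ``min_aspect``);
    small or compact residues (detached fragments, adsorbed enzymes) are
    excluded from both masks.  Background = below-threshold pixels.

    The automatic threshold is the background median plus five robust
    standard deviations (MAD-based).
    """
    h = frame.height
    thr = auto_height_threshold(h) if height_threshold == "auto" else float(height_threshold)

    above = h > thr
    out = frame.copy()
    out.background_mask = ~above
    fiber = np.zeros_like(above)
    if above.any():
        labels = measure.label(above, connectivity=2)
        for region in measure.regionprops(labels):
            if region.area < min_area_px:
                continue
            minor = region.axis_minor_length
            major = region.axis_major_length
            aspect = np.inf if minor < 1e-9 else major / minor
            if aspect < min_aspect:
                continue
            fiber[labels == region.label] = True
    out.fiber_mask = fiber
    if not fiber.any():
        warnings.warn("segment_fiber: empty fiber mask")
    return out


def register_drift(
    stack: FrameStack,
    reference_index: int = 0,
    *,
    upsample_factor: int = 10,
    crop: bool = True,
    sequential: bool = True,
) -> FrameStack:
    """Translate every frame onto the reference by cross-correlation.

    Offsets are refined to sub-pixel precision by Fourier upsampling of the
    correlation peak; height and modulus are shifted with bilinear
    interpolation, masks (if present) with nearest-neighbour.  Frames whose
    height map is essentially flat cannot be registered and are flagged.
    When ``crop`` is set, the common valid region is cropped identically
    across frames.

    With ``sequential`` (the default, appropriate for time-lapse data of a
    degrading sample) each frame is registered to its temporal neighbour
    and the pairwise shifts are accumulated relative to the reference:
    adjacent frames differ by a single step of degradation, whereas a late
    frame may share too little structure with the reference for a direct
    correlation to lock on.
    """
    if len(stack) < 2:
        raise InsufficientDataError("need at least two frames to register")
    heights = [f.height for f in stack.frames]
    n = len(stack)
    failed = np.zeros(n, dtype=bool)
    offsets = np.zeros((n, 2))
    if sequential:
        pair = np.zeros((n, 2))
        for i in range(1, n):
            if np.ptp(heights[i]) < 1e-9 or np.ptp(heights[i - 1]) < 1e-9:
                failed[i] = True
                continue
            shift, _err, _ = phase_cross_correlation(
                heights[i - 1], heights[i], upsample_factor=upsample_factor)
            pair[i] = shift
        cum = np.cumsum(pair, axis=0)
        offsets = cum - cum[reference_index]
    else:
        ref = heights[reference_index]
        for i in range(n):
            if i == reference_index:
                continue
            if np.ptp(heights[i]) < 1e-9 or np.ptp(ref) < 1e-9:
                failed[i] = True
                continue
            shift, _err, _ = phase_cross_correlation(ref, heights[i],
                                                     upsample_factor=upsample_factor)
            offsets[i] = shift

    out = apply_shifts(stack, offsets, crop=crop)
    out.registration_failed = failed
    return out


def apply_shifts(stack: FrameStack, offsets, crop: bool = True) -> FrameStack:
    """Translate frames by precomputed (row, col) offsets and crop the
    common valid region.  Height/modulus use bilinear interpolation, masks
    nearest-neighbour."""
    offsets = np.asarray(offsets, dtype=float)
    new_frames = []
    for fr, shift in zip(stack.frames, offsets):
        if abs(shift[0]) < 1e-12 and abs(shift[1]) < 1e-12:
            new_frames.append(fr.copy())
            continue
        g = fr.copy()
        g.height = ndimage.shift(fr.height, shift, order=1, mode="nearest")
        g.modulus = ndimage.shift(fr.modulus, shift, order=1, mode="nearest")
        if fr.fiber_mask is not None:
            g.fiber_mask = ndimage.shift(fr.fiber_mask.astype(float), shift, order=0, mode="constant") > 0.5
        if fr.background_mask is not None:
            g.background_mask = ndimage.shift(fr.background_mask.astype(float), shift, order=0,
                                              mode="constant", cval=1.0) > 0.5
        new_frames.append(g)

    if crop:
        pad_top = int(np.ceil(max(0.0, offsets[:, 0].max())))
        pad_bot = int(np.ceil(max(0.0, -offsets[:, 0].min())))
        pad_lef = int(np.ceil(max(0.0, offsets[:, 1].max())))
        pad_rig = int(np.ceil(max(0.0, -offsets[:, 1].min())))
        ny, nx = stack.frames[0].height.shape
        rs = slice(pad_top, ny - pad_bot if pad_bot else ny)
        cs = slice(pad_lef, nx - pad_rig if pad_rig else nx)
        for g in new_frames:
            g.height = g.height[rs, cs]
            g.modulus = g.modulus[rs, cs]
            if g.fiber_mask is not None:
                g.fiber_mask = g.fiber_mask[rs, cs]
            if g.background_mask is not None:
                g.background_mask = g.background_mask[rs, cs]
    return FrameStack(frames=new_frames, offsets=offsets)


def normalize_modulus(frame: MapFrame, E_hopg_nominal: float = 1000.0) -> MapFrame:
    """Reference the modulus map to the HOPG background (yielding E*).

    Each frame is rescaled so its background mean equals the nominal HOPG
    modulus; any uniform per-frame gain (tip wear, laser drift) therefore
    cancels, while MPa units are preserved.
    """
    if frame.background_mask is None or not frame.background_mask.any():
        raise MaskError("normalize_modulus requires a non-empty background mask")
    bg_mean = float(np.mean(frame.modulus[frame.background_mask]))
    if bg_mean <= 0:
        raise InputError("background modulus mean must be positive")
    out = frame.copy()
    out.modulus = frame.modulus * (E_hopg_nominal / bg_mean)
    return out


# --------------------------------------------------------------------------
# nanodomain statistics
# --------------------------------------------------------------------------

def _roi_values(frame: MapFrame, roi: NanodomainROI | None) -> np.ndarray:
    if frame.fiber_mask is None:
        raise MaskError("fiber mask required; run segment_fiber first")
    m = frame.fiber_mask
    if roi is not None:
        m = m & roi.to_mask(frame.height.shape)
    return frame.modulus[m]


def estar_av(frame: MapFrame, roi: NanodomainROI | None = None,
             min_points: int = MIN_ROI_POINTS) -> float:
    """Arithmetic mean of E* over the fiber pixels inside the ROI."""
    vals = _roi_values(frame, roi)
    if len(vals) < min_points:
        raise InsufficientDataError(
            f"{len(vals)} fiber pixels in ROI; minimum is {min_points}")
    return float(np.mean(vals))


def estar_distribution(frame: MapFrame, roi: NanodomainROI | None = None,
                       min_points: int = MIN_ROI_POINTS) -> EStarSummary:
    """Distribution summary of E* in a nanodomain.

    Mode from a Gaussian KDE (Silverman bandwidth); skewness as the
    adjusted Fisher-Pearson coefficient; unimodality by counting prominent
    peaks of the smoothed density.  ROIs with too few points or a
    multimodal distribution should be excluded from trend analysis.
    """
    vals = _roi_values(frame, roi)
    n = len(vals)
    if n < min_points:
        return EStarSummary(np.nan, np.nan, np.nan, n, False, excluded=True,
                            reason="insufficient points")
    if np.ptp(vals) < 1e-12:
        c = float(vals[0])
        return EStarSummary(c, c, 0.0, n, True)
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 512)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=0.05 * dens.max())
    if dens[0] > dens[1]:
        peaks = np.concatenate(([0], peaks))
    if dens[-1] > dens[-2]:
        peaks = np.concatenate((peaks, [len(grid) - 1]))
    unimodal = len(peaks) <= 1
    mode = float(grid[np.argmax(dens)])
    skew = float(stats.skew(vals, bias=False))
    return EStarSummary(mode=mode, mean=float(np.mean(vals)), skewness=skew,
                        n=n, unimodal=unimodal,
                        excluded=not unimodal,
                        reason="" if unimodal else "multimodal distribution")


def fiber_volume(frame: MapFrame, mask: np.ndarray | None = None) -> float:
    """Fiber volume in nm^3: height pixel sum times pixel area."""
    if mask is None:
        mask = frame.fiber_mask
    if mask is None:
        raise MaskError("fiber mask required")
    if not mask.any():
        return 0.0
    if frame.background_mask is not None and frame.background_mask.any():
        bg_med = np.median(frame.height[frame.background_mask])
        if abs(bg_med) > 0.05:
            warnings.warn(f"frame looks unleveled (background median {bg_med:.3g} nm)")
    return float(np.sum(frame.height[mask]) * frame.pixel_size ** 2)


def relative_activity(stack: FrameStack, masks=None) -> tuple:
    """Degradation rate as percent of initial material lost per minute.

    ``A(t_i) = 100 * (P(t_{i-1}) - P(t_i)) / (P(t_0) * (t_i - t_{i-1}))``
    with P the height pixel sum over the fiber mask.  Returns
    ``(times[1:], activity)``.
    """
    if len(stack) < 2:
        raise InsufficientDataError("need at least two frames")
    P = []
    for i, fr in enumerate(stack.frames):
        m = masks[i] if masks is not None else fr.fiber_mask
        if m is None:
            raise MaskError("fiber mask required for every frame")
        P.append(float(np.sum(fr.height[m])))
    P = np.array(P)
    if P[0] <= 0:
        raise InputError("initial pixel sum must be positive")
    t = stack.times
    act = 100.0 * (P[:-1] - P[1:]) / (P[0] * np.diff(t))
    return t[1:], act


def scale_series(values) -> np.ndarray:
    """Linearly rescale a series to 0-100% (affine-invariant)."""
    v = np.asarray(values, dtype=float)
    span = np.nanmax(v) - np.nanmin(v)
    if not np.isfinite(span) or span <= 0:
        raise DegenerateScaleError("constant series cannot be scaled to 0-100%")
    return (v - np.nanmin(v)) / span * 100.0


# --------------------------------------------------------------------------
# end-to-end convenience pipeline
# --------------------------------------------------------------------------

def process_stack(
    stack: FrameStack,
    *,
    E_hopg_nominal: float = 1000.0,
    roi: NanodomainROI | None = None,
    height_threshold="auto",
    min_area_px: int = 100,
    min_aspect: float = 2.0,
    min_points: int = MIN_ROI_POINTS,
    min_points_frame: int = 100,
    reference_index: int = 0,
    edge_erode_px: int = 2,
):
    """Run the full correction/measurement pipeline on a raw stack.

    Steps: provisional leveling -> drift registration -> segmentation ->
    plane re-leveling on the proper background -> HOPG normalization ->
    per-frame volume, E*_av and relative activity.

    The minimum-area rule (``min_points``, 2500 points ~ 10,000 nm^2 at
    2 nm/px) is an *admission* check on the nanodomain: it is applied to
    the first frame, and an undersized unit is excluded wholesale.  An
    admitted unit is then followed to near-complete degradation; later
    frames only require ``min_points_frame`` fiber pixels for a meaningful
    mean, since material loss is the very signal under study.

    The default elongation filter is relaxed to 2.0 here (vs 3.0 for
    single-frame segmentation): isolated crystalline cores remaining at
    late degradation stages are legitimate analysis targets even when
    shortened below 3x their width.

    For the modulus statistics the fiber mask is eroded by
    ``edge_erode_px`` pixels: fiber-boundary pixels mix the soft fiber
    with the stiff support (tip convolution, drift-correction
    interpolation) and would bias the arithmetic mean E*_av upward.
    Volume and activity use the full mask.

    Returns ``(records, qc)`` where ``records`` is a list of per-frame
    dicts (time_min, volume_nm3, estar_av, n_points, excluded, reason) and
    ``qc`` carries registration offsets/flags.  The scaled E*_av and
    activity columns are attached by :func:`cellodyn.degradation.build_trajectory`.
    """
    def _guarded_level(g: MapFrame) -> MapFrame:
        # a guard band around the material keeps sub-threshold fiber-edge
        # tails (tip convolution, interpolation) out of the plane fit,
        # whose intercept is otherwise biased by them
        mat = material_mask(g, height_threshold)
        bg = g.background_mask & ~ndimage.binary_dilation(mat, iterations=4)
        if np.count_nonzero(bg) >= 0.10 * bg.size:
            g = replace(g, background_mask=bg)
            g = level_plane(g)
        return g

    # two-pass leveling: provisional background -> plane -> segmentation ->
    # guarded plane on the proper background
    clean = []
    for fr in stack.frames:
        g = fr.copy()
        g.background_mask = provisional_background(g.height)
        g = level_plane(g)
        g = segment_fiber(g, height_threshold, min_area_px=min_area_px, min_aspect=min_aspect)
        g = _guarded_level(g)
        clean.append(g)

    # offsets estimated on the twice-leveled heights: leveling on the
    # proper background first is essential, since any static residual
    # (tilt/leveling imperfection) anchors the correlation at zero shift
    # and biases the drift estimate low
    est = register_drift(FrameStack(clean), reference_index=reference_index, crop=False)
    # integer-rounded application: a whole-pixel translation is exact
    # (no interpolation), so pixel sums carry no resampling noise; the
    # residual sub-pixel misalignment is harmless to region statistics
    reg = apply_shifts(FrameStack(clean), np.round(est.offsets), crop=True)

    frames = []
    for fr in reg.frames:
        seg = segment_fiber(fr, height_threshold, min_area_px=min_area_px, min_aspect=min_aspect)
        seg = _guarded_level(seg)
        norm = normalize_modulus(seg, E_hopg_nominal)
        frames.append(norm)
    proc = FrameStack(frames, offsets=reg.offsets, registration_failed=est.registration_failed)

    # volumetrics count all substrate material, not just the elongated
    # fiber class: attached fragments below the aspect filter still hold
    # genuine volume
    mat_masks = [material_mask(fr, height_threshold) for fr in proc.frames]
    records = []
    for idx, fr in enumerate(proc.frames):
        required = min_points if idx == 0 else min_points_frame
        rec = {"time_min": fr.time, "volume_nm3": fiber_volume(fr, mat_masks[idx]),
               "estar_av": np.nan, "n_points": 0, "excluded": False, "reason": ""}
        stat = fr
        if fr.fiber_mask is not None and fr.fiber_mask.any():
            m = fr.fiber_mask
            if edge_erode_px > 0:
                m = ndimage.binary_erosion(m, iterations=edge_erode_px)
            # pixels more than halfway to the support modulus are
            # fiber/support mixtures (tip convolution, interpolation)
            m = m & (fr.modulus < 0.5 * E_hopg_nominal)
            stat = replace(fr, fiber_mask=m)
        try:
            rec["estar_av"] = estar_av(stat, roi, min_points=required)
            m = stat.fiber_mask if roi is None else stat.fiber_mask & roi.to_mask(fr.height.shape)
            rec["n_points"] = int(np.count_nonzero(m))
        except (InsufficientDataError, MaskError) as exc:
            rec["excluded"] = True
            rec["reason"] = str(exc)
        records.append(rec)

    # activity from the pixel sum over one consistent region (the union of
    # material masks, dilated to catch sub-threshold interpolation tails at
    # the fiber edge): a fixed region makes the temporal difference immune
    # to frame-to-frame segmentation flicker
    region = ndimage.binary_dilation(np.logical_or.reduce(mat_masks), iterations=3)
    t_act, act = relative_activity(proc, masks=[region] * len(proc))
    for rec in records:
        rec["activity_pct_per_min"] = np.nan
    for ti, ai in zip(t_act, act):
        for rec in records:
            if abs(rec["time_min"] - ti) < 1e-9:
                rec["activity_pct_per_min"] = float(ai)
    qc = {
        "offsets": None if proc.offsets is None else proc.offsets.tolist(),
        "registration_failed": None if proc.registration_failed is None
        else proc.registration_failed.tolist(),
    }
    return records, qc
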