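"""Per-sub-ROI instantaneous motion between consecutive RF frames.

The ROI is tiled laterally into overlapping sub-ROI windows spanning its
full depth.  For each window and each consecutive frame pair the estimator
runs two stages:

1. ``match_window`` — integer-pixel block matching by normalized
   cross-correlation of the raw RF, exhaustively over a small search grid;
2. ``refine_affine`` — a Gauss–Newton least-squares fit of a local affine
   warp (2 translations + 4 displacement gradients) to the linearized
   brightness-constancy equation, about the integer shift.

Working on RF rather than the detected envelope preserves the carrier phase
and gives sub-pixel sensitivity; an envelope fallback is available for
robustness studies.  Outputs are expressed in physical units (mm for shifts,
percent for strains and shears) using the pixel pitches, with lateral =
perpendicular to the beam and axial = along it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter
from scipy.signal import fftconvolve, hilbert

from .geometry import AcquisitionGeometry
from .roi import ROIGeometry, ROITrack, assess_adequacy
from .simulate import RFCineloop


@dataclass(frozen=True)
class SubROIParams:
    """Sub-ROI tiling and estimator settings.

    Windows are 4 mm wide with 75% lateral overlap.  The width matters for
    strain: displacement-gradient leverage is lost within roughly one
    lateral PSF width of each window edge, so windows much narrower than
    ~10 speckle cells systematically attenuate strain estimates (about 8%
    at 2 mm for a 0.3 mm speckle size, under 1% at 4 mm).  The search grid
    allows ±1 mm lateral and ±0.5 mm axial motion per frame pair, generous
    at a 30 Hz frame rate.  Windows whose peak correlation falls below
    ``correlation_threshold`` are masked invalid and excluded from
    per-frame averages.
    """

    window_lateral_mm: float = 4.0
    overlap: float = 0.75
    search_lateral_mm: float = 1.0
    search_axial_mm: float = 0.5
    correlation_threshold: float = 0.7
    max_iterations: int = 20
    tolerance: float = 1e-4
    use_envelope: bool = False

    def window_width_px(self, geometry: AcquisitionGeometry) -> int:
        return max(2, int(round(self.window_lateral_mm / geometry.lateral_pitch_mm)))

    def search_radius_px(self, geometry: AcquisitionGeometry) -> tuple[int, int]:
        return (
            max(1, int(round(self.search_lateral_mm / geometry.lateral_pitch_mm))),
            max(1, int(round(self.search_axial_mm / geometry.axial_pitch_mm))),
        )


@dataclass(frozen=True)
class SubROIWindow:
    """One rectangular sub-ROI in integer pixel coordinates."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    @property
    def center(self) -> tuple[float, float]:
        """(axial, lateral) center in pixel coordinates."""
        return (self.row0 + (self.n_rows - 1) / 2.0,
                self.col0 + (self.n_cols - 1) / 2.0)

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.n_rows),
                slice(self.col0, self.col0 + self.n_cols))


@dataclass
class SubROIGrid:
    windows: list[SubROIWindow]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.windows)


def partition_subrois(
    roi: ROIGeometry,
    params: SubROIParams,
    geometry: AcquisitionGeometry,
    frame_shape: tuple[int, int] | None = None,
) -> SubROIGrid:
    """Tile the ROI laterally into overlapping full-depth windows.

    Window tops follow the (rounded) local upper boundary.  Windows that
    would be clipped by the frame edge are dropped and counted; an ROI
    narrower than one window is rejected.
    """
    if not 0 <= params.overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    w = params.window_width_px(geometry)
    h = int(round(roi.depth_px))
    n_cols_roi = len(roi.columns)
    if n_cols_roi < w:
        raise ValueError(
            f"ROI spans {n_cols_roi} columns, narrower than one {w}-column window"
        )
    step = max(1, int(round(w * (1.0 - params.overlap))))

    windows: list[SubROIWindow] = []
    dropped = 0
    for start in range(0, n_cols_roi - w + 1, step):
        cols = roi.columns[start:start + w]
        row0 = int(round(float(np.mean(roi.upper_px[start:start + w]))))
        win = SubROIWindow(row0=row0, col0=int(cols[0]), n_rows=h, n_cols=w)
        if frame_shape is not None:
            if (win.row0 < 0 or win.col0 < 0
                    or win.row0 + h > frame_shape[0] or win.col0 + w > frame_shape[1]):
                dropped += 1
                continue
        windows.append(win)
    if not windows:
        raise ValueError("no sub-ROI window fits inside the frame")
    return SubROIGrid(windows=windows, n_dropped=dropped)


def _ncc_map(region: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation of template at every valid offset."""
    h, w = template.shape
    n = h * w
    t = template - template.mean()
    t_norm = np.sqrt((t**2).sum())
    num = fftconvolve(region, t[::-1, ::-1], mode="valid")
    s1 = fftconvolve(region, np.ones((h, w)), mode="valid")
    s2 = fftconvolve(region**2, np.ones((h, w)), mode="valid")
    var = np.maximum(s2 - s1**2 / n, 0.0)
    denom = np.sqrt(var) * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = num / denom
    ncc[denom <= 1e-12 * max(t_norm, 1.0)] = 0.0
    return np.clip(ncc, -1.0, 1.0)


def match_window(
    frame_k: np.ndarray,
    frame_k1: np.ndarray,
    window: SubROIWindow,
    search_radius: tuple[int, int],
) -> tuple[tuple[int, int], float]:
    """Integer (lateral, axial) shift maximizing NCC, with its score.

    Ties (within 1e-12) are broken toward the smallest displacement
    magnitude, then the smaller lateral component.  A flat (zero-variance)
    template returns a NaN score so the caller can mask the window invalid.
    """
    rl, ra = int(search_radius[0]), int(search_radius[1])
    tpl = frame_k[window.slice()]
    if tpl.std() == 0:
        return (0, 0), float("nan")

    r0 = max(window.row0 - ra, 0)
    r1 = min(window.row0 + window.n_rows + ra, frame_k1.shape[0])
    c0 = max(window.col0 - rl, 0)
    c1 = min(window.col0 + window.n_cols + rl, frame_k1.shape[1])
    region = frame_k1[r0:r1, c0:c1]
    if region.shape[0] < window.n_rows or region.shape[1] < window.n_cols:
        return (0, 0), float("nan")

    ncc = _ncc_map(region, tpl)
    # offset (i, j) in the map corresponds to shift (lat, ax) below
    ax_shifts = np.arange(ncc.shape[0]) + (r0 - window.row0)
    lat_shifts = np.arange(ncc.shape[1]) + (c0 - window.col0)

    best = np.max(ncc)
    ii, jj = np.nonzero(ncc >= best - 1e-12)
    cand = sorted(
        zip(lat_shifts[jj], ax_shifts[ii]),
        key=lambda s: (s[0] ** 2 + s[1] ** 2, abs(s[0]), abs(s[1]), s[0], s[1]),
    )
    dlat, dax = cand[0]
    score = float(ncc[dax - (r0 - window.row0), dlat - (c0 - window.col0)])
    return (int(dlat), int(dax)), score


@dataclass
class WindowMotion:
    """Affine motion of one window, in pixel units, about the integer shift.

    ``tx_px``/``ty_px`` are the sub-pixel lateral/axial translations;
    the gradients are dimensionless pixel-per-pixel displacement gradients
    (``dux_dx`` = lateral strain, ``duy_dy`` = axial strain, cross terms the
    two shears).
    """

    tx_px: float
    ty_px: float
    dux_dx: float
    dux_dy: float
    duy_dx: float
    duy_dy: float
    converged: bool
    n_iterations: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx_px, self.ty_px, self.dux_dx,
                         self.dux_dy, self.duy_dx, self.duy_dy])


class _SplineFrame:
    """Cubic-spline interpolator of a frame and its two gradients."""

    def __init__(self, frame: np.ndarray, order: int = 3):
        self.order = order
        gy, gx = np.gradient(frame)
        if order > 1:
            self.coef = spline_filter(frame, order=order)
            self.coef_gy = spline_filter(gy, order=order)
            self.coef_gx = spline_filter(gx, order=order)
        else:
            self.coef, self.coef_gy, self.coef_gx = frame, gy, gx

    def sample(self, coef: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return map_coordinates(coef, [rows, cols], order=self.order,
                               mode="nearest", prefilter=False)


def _refine(
    template: np.ndarray,
    interp: _SplineFrame,
    window: SubROIWindow,
    integer_shift: tuple[int, int],
    params: SubROIParams,
) -> WindowMotion | None:
    cy, cx = window.center
    rows, cols = np.mgrid[window.row0:window.row0 + window.n_rows,
                          window.col0:window.col0 + window.n_cols]
    y = (rows - cy).ravel()
    x = (cols - cx).ravel()
    rows = rows.ravel().astype(float)
    cols = cols.ravel().astype(float)
    dlat, dax = integer_shift

    p = np.zeros(6)  # tx, ty, exx, exy, eyx, eyy
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        ux = p[0] + p[2] * x + p[3] * y
        uy = p[1] + p[4] * x + p[5] * y
        r_w = rows + dax + uy
        c_w = cols + dlat + ux
        warped = interp.sample(interp.coef, r_w, c_w)
        gx = interp.sample(interp.coef_gx, r_w, c_w)
        gy = interp.sample(interp.coef_gy, r_w, c_w)
        resid = warped - template.ravel()

        J = np.column_stack([gx, gy, gx * x, gx * y, gy * x, gy * y])
        jtj = J.T @ J
        jtr = J.T @ resid
        try:
            delta = np.linalg.solve(jtj, jtr)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(delta)):
            return None
        p -= delta
        if np.linalg.norm(delta) < params.tolerance:
            converged = True
            break

    return WindowMotion(tx_px=p[0], ty_px=p[1], dux_dx=p[2], dux_dy=p[3],
                        duy_dx=p[4], duy_dy=p[5], converged=converged,
                        n_iterations=it)


def refine_affine(
    frame_k: np.ndarray,
    frame_k1: np.ndarray,
    window: SubROIWindow,
    integer_shift: tuple[int, int],
    params: SubROIParams | None = None,
) -> WindowMotion | None:
    """Sub-pixel affine refinement about an integer shift.

    Solves the linearized brightness-constancy system over the window by
    Gauss–Newton for (t_x, t_y, ∂u_x/∂x, ∂u_x/∂y, ∂u_y/∂x, ∂u_y/∂y), in
    pixel units, iterating until the parameter update norm drops below the
    tolerance (default 1e-4) or the iteration cap (default 20) is reached.
    Returns ``None`` for degenerate (singular) speckle.
    """
    params = params or SubROIParams()
    template = frame_k[window.slice()]
    return _refine(template, _SplineFrame(frame_k1), window, integer_shift, params)


@dataclass
class InstantaneousMotionField:
    """Per-window, per-frame-pair motion in physical units.

    Arrays are shaped ``(n_pairs, n_windows)``; shifts in mm, strains and
    shears in percent.  ``valid`` masks windows whose correlation passed the
    threshold and whose refinement converged.
    """

    lateral_shift_mm: np.ndarray
    axial_shift_mm: np.ndarray
    lateral_strain_pct: np.ndarray
    axial_strain_pct: np.ndarray
    lateral_shear_pct: np.ndarray
    axial_shear_pct: np.ndarray
    valid: np.ndarray
    correlation: np.ndarray
    frame_rate_hz: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.lateral_shift_mm.shape[0]

    @property
    def n_windows(self) -> int:
        return self.lateral_shift_mm.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


CHANNELS = ("lateral_shift_mm", "axial_shift_mm", "lateral_strain_pct",
            "axial_strain_pct", "lateral_shear_pct", "axial_shear_pct")


def window_motion_to_physical(
    motion: WindowMotion,
    integer_shift: tuple[int, int],
    geometry: AcquisitionGeometry,
) -> dict[str, float]:
    """Convert pixel-unit affine parameters to mm / percent.

    Cross gradients mix the two pitches: a lateral displacement gradient
    along the axial direction scales by lateral_pitch/axial_pitch.
    """
    lp, ap = geometry.lateral_pitch_mm, geometry.axial_pitch_mm
    return {
        "lateral_shift_mm": (integer_shift[0] + motion.tx_px) * lp,
        "axial_shift_mm": (integer_shift[1] + motion.ty_px) * ap,
        "lateral_strain_pct": motion.dux_dx * 100.0,
        "axial_strain_pct": motion.duy_dy * 100.0,
        "lateral_shear_pct": motion.dux_dy * (lp / ap) * 100.0,
        "axial_shear_pct": motion.duy_dx * (ap / lp) * 100.0,
    }


def estimate_cineloop(
    cineloop: RFCineloop,
    roi_track: ROITrack,
    params: SubROIParams | None = None,
) -> InstantaneousMotionField:
    """Run match + refine for every window and consecutive frame pair.

    Windows are re-anchored to the tracked ROI on each frame (a Lagrangian
    description: the estimation support follows the pleura).  Refuses
    cineloops whose ROI track failed the adequacy criterion, mirroring the
    exclusion of inadequately tracked cineloops from elastogram computation.
    """
    params = params or SubROIParams()
    if roi_track.adequate is None:
        assess_adequacy(cineloop, roi_track)
    if not roi_track.adequate:
        raise ValueError("ROI track is inadequate; elastogram computation refused")
    if len(roi_track) != cineloop.n_frames:
        raise ValueError("ROI track does not cover the cineloop")

    geom = cineloop.geometry
    search = params.search_radius_px(geom)
    frames = cineloop.frames
    if params.use_envelope:
        frames = np.abs(hilbert(frames, axis=0))

    grids = [partition_subrois(roi_track[k], params, geom, cineloop.shape)
             for k in range(cineloop.n_frames - 1)]
    n_windows = len(grids[0])
    if any(len(g) != n_windows for g in grids):
        raise ValueError("sub-ROI window count changed between frames")

    n_pairs = cineloop.n_frames - 1
    out = {name: np.full((n_pairs, n_windows), np.nan) for name in CHANNELS}
    valid = np.zeros((n_pairs, n_windows), dtype=bool)
    corr = np.full((n_pairs, n_windows), np.nan)

    for k in range(n_pairs):
        f0, f1 = frames[:, :, k], frames[:, :, k + 1]
        interp = _SplineFrame(f1)
        for j, win in enumerate(grids[k].windows):
            shift, score = match_window(f0, f1, win, search)
            corr[k, j] = score
            if not np.isfinite(score) or score < params.correlation_threshold:
                continue
            motion = _refine(f0[win.slice()], interp, win, shift, params)
            if motion is None:
                continue
            phys = window_motion_to_physical(motion, shift, geom)
            if not all(np.isfinite(v) for v in phys.values()):
                continue
            for name in CHANNELS:
                out[name][k, j] = phys[name]
            valid[k, j] = True

    return InstantaneousMotionField(
        **out, valid=valid, correlation=corr, frame_rate_hz=geom.frame_rate_hz,
        metadata={
            "window_lateral_mm": params.window_lateral_mm,
            "overlap": params.overlap,
            "correlation_threshold": params.correlation_threshold,
            "search_lateral_mm": params.search_lateral_mm,
            "search_axial_mm": params.search_axial_mm,
            "use_envelope": params.use_envelope,
            "n_windows": n_windows,
        },
    )
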