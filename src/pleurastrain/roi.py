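"""Fixed-depth region of interest beneath the pleural line.

The pleura is segmented once, on a single reference frame, as a polyline;
the ROI is the band of fixed physical depth (2 mm by default) whose upper
boundary is that polyline.  Across the cineloop the ROI is either advected
by the estimated (or, in simulation mode, ground-truth) pleural motion, or
— when the advected geometry fails an adequacy check — copied unchanged
from the previous frame and flagged.  Adequacy operationalizes the visual
criterion that the bright pleural line stays inside the ROI: per frame and
per lateral column, the maximum of the RF envelope within a search band
around the upper boundary must fall between the ROI boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .simulate import RFCineloop, displacement_at

DEFAULT_DEPTH_MM = 2.0
ADEQUACY_THRESHOLD = 0.9      # fraction of columns with the pleura inside the ROI
SEARCH_BAND_MM = 1.0          # envelope search band around the upper boundary
BOUNDARY_TOLERANCE_MM = 0.1   # ~one pulse length: the pleural line is a band,
                              # not an ideal line, so its envelope peak may sit
                              # within a pulse length of the segmented boundary


@dataclass(frozen=True)
class PleuralSegmentation:
    """Manual pleural-line polyline on one reference frame.

    ``polyline`` is an ordered sequence of (lateral_px, axial_px) vertices
    with strictly increasing lateral coordinates.
    """

    polyline: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
            raise ValueError("polyline must be an (n>=2, 2) array of (lateral, axial)")
        if not np.all(np.diff(poly[:, 0]) > 0):
            raise ValueError("polyline lateral coordinates must be strictly increasing")
        object.__setattr__(self, "polyline", poly)


@dataclass
class ROIGeometry:
    """ROI on one frame: per-column sub-pixel upper boundary + fixed depth."""

    columns: np.ndarray          # integer lateral columns covered
    upper_px: np.ndarray         # sub-pixel axial coordinate per column
    depth_mm: float
    axial_pitch_mm: float
    tracked: bool = True         # False when copied from the previous frame

    @property
    def depth_px(self) -> float:
        return self.depth_mm / self.axial_pitch_mm

    @property
    def lower_px(self) -> np.ndarray:
        return self.upper_px + self.depth_px

    def copy(self, *, tracked: bool) -> "ROIGeometry":
        return ROIGeometry(self.columns.copy(), self.upper_px.copy(),
                           self.depth_mm, self.axial_pitch_mm, tracked)


@dataclass
class ROITrack:
    """Per-frame ROI geometry with adequacy diagnostics."""

    geometries: list[ROIGeometry]
    adequacy_score: np.ndarray = field(default=None)  # type: ignore[assignment]
    adequate: bool | None = None

    def __len__(self) -> int:
        return len(self.geometries)

    def __getitem__(self, k: int) -> ROIGeometry:
        return self.geometries[k]

    @property
    def copied_frames(self) -> list[int]:
        return [k for k, g in enumerate(self.geometries) if not g.tracked]

    @property
    def perfect_tracking(self) -> bool:
        return not self.copied_frames


def build_roi(
    segmentation: PleuralSegmentation,
    depth_mm: float,
    geometry,
    frame_shape: tuple[int, int],
) -> ROIGeometry:
    """Build the fixed-depth ROI under a segmented pleural line.

    The upper boundary is the polyline linearly interpolated over every
    lateral column it covers; the lower boundary sits ``depth_mm`` deeper.
    Rejects ROIs that exit the frame, naming the offending column.
    """
    if depth_mm < 0:
        raise ValueError("ROI depth must be non-negative")
    poly = segmentation.polyline
    n_ax, n_lat = frame_shape
    if poly[:, 0].min() < 0 or poly[:, 0].max() > n_lat - 1:
        raise ValueError("polyline extends outside the frame laterally")
    if poly[:, 1].min() < 0 or poly[:, 1].max() > n_ax - 1:
        raise ValueError("polyline extends outside the frame axially")

    c0 = int(np.ceil(poly[0, 0]))
    c1 = int(np.floor(poly[-1, 0]))
    columns = np.arange(c0, c1 + 1)
    upper = np.interp(columns, poly[:, 0], poly[:, 1])

    depth_px = depth_mm / geometry.axial_pitch_mm
    lower = upper + depth_px
    bad = np.nonzero(lower > n_ax - 1)[0]
    if bad.size:
        raise ValueError(
            f"ROI of depth {depth_mm} mm exits the frame at column {columns[bad[0]]}"
        )
    return ROIGeometry(columns, upper, depth_mm, geometry.axial_pitch_mm)


def _envelope(frame: np.ndarray) -> np.ndarray:
    return np.abs(hilbert(frame, axis=0))


def _adequacy_score(frame: np.ndarray, roi: ROIGeometry) -> float:
    """Fraction of columns whose peak envelope (within the search band
    around the upper boundary) lies between the ROI boundaries."""
    band_px = SEARCH_BAND_MM / roi.axial_pitch_mm
    tol_px = BOUNDARY_TOLERANCE_MM / roi.axial_pitch_mm
    env = _envelope(frame)
    n_ax = frame.shape[0]
    inside = 0
    for c, u, lo in zip(roi.columns, roi.upper_px, roi.lower_px):
        a = int(np.clip(np.floor(u - band_px), 0, n_ax - 1))
        b = int(np.clip(np.ceil(u + band_px), 0, n_ax - 1))
        peak = a + int(np.argmax(env[a:b + 1, c]))
        inside += u - tol_px <= peak <= lo + tol_px
    return inside / len(roi.columns)


def _advect(roi: ROIGeometry, dlat_px: float, dax_px: float) -> ROIGeometry:
    """Shift the upper boundary by an inter-frame pleural displacement."""
    new = roi.copy(tracked=True)
    # lateral advection: resample the boundary height at the pulled-back columns
    new.upper_px = np.interp(roi.columns - dlat_px, roi.columns, roi.upper_px) + dax_px
    return new


def track_roi(
    cineloop: RFCineloop,
    roi0: ROIGeometry,
    motion_source: str = "estimate",
    adequacy_threshold: float = ADEQUACY_THRESHOLD,
) -> ROITrack:
    """Track the ROI across the cineloop, with copy fallback.

    ``motion_source``:

    * ``"estimate"`` — advect by the median of per-sub-ROI displacements
      estimated between consecutive frames (robust to single-window outliers);
    * ``"ground_truth"`` — advect by the simulator's prescribed pleural-line
      displacement (requires ``cineloop.ground_truth``);
    * ``"copy"`` — never advect (the paper's fallback applied throughout).

    If an advected geometry's adequacy score drops below threshold, the
    previous geometry is copied unchanged and the frame flagged.
    """
    geometries = [roi0.copy(tracked=True)]
    fr = cineloop.geometry.frame_rate_hz

    for k in range(1, cineloop.n_frames):
        prev = geometries[-1]
        if motion_source == "copy":
            geometries.append(prev.copy(tracked=False))
            continue
        if motion_source == "ground_truth":
            if cineloop.ground_truth is None:
                raise ValueError("cineloop carries no ground-truth motion")
            # pleural line is at y=0 of the motion field; x=0 at the ROI center
            ux0, uy0 = displacement_at(cineloop.ground_truth, (k - 1) / fr, 0.0, 0.0)
            ux1, uy1 = displacement_at(cineloop.ground_truth, k / fr, 0.0, 0.0)
            dlat = float(ux1 - ux0) / cineloop.geometry.lateral_pitch_mm
            dax = float(uy1 - uy0) / cineloop.geometry.axial_pitch_mm
        elif motion_source == "estimate":
            dlat, dax = _estimate_pleural_shift(cineloop, prev, k - 1)
        else:
            raise ValueError(f"unknown motion_source {motion_source!r}")

        candidate = _advect(prev, dlat, dax)
        score = _adequacy_score(cineloop.frame(k), candidate)
        if score >= adequacy_threshold:
            geometries.append(candidate)
        else:
            geometries.append(prev.copy(tracked=False))

    return ROITrack(geometries=geometries)


def _estimate_pleural_shift(cineloop: RFCineloop, roi: ROIGeometry, k: int) -> tuple[float, float]:
    """Median sub-ROI displacement of the pleural band between frames k, k+1."""
    from .motion import SubROIParams, partition_subrois, match_window, refine_affine

    params = SubROIParams()
    try:
        grid = partition_subrois(roi, params, cineloop.geometry)
    except ValueError:
        return 0.0, 0.0
    f0, f1 = cineloop.frame(k), cineloop.frame(k + 1)
    dlats, daxs = [], []
    for win in grid.windows:
        shift, score = match_window(f0, f1, win, params.search_radius_px(cineloop.geometry))
        if not np.isfinite(score) or score < params.correlation_threshold:
            continue
        res = refine_affine(f0, f1, win, shift, params)
        if res is None:
            continue
        dlats.append(shift[0] + res.tx_px)
        daxs.append(shift[1] + res.ty_px)
    if not dlats:
        return 0.0, 0.0
    return float(np.median(dlats)), float(np.median(daxs))


def assess_adequacy(
    cineloop: RFCineloop,
    track: ROITrack,
    threshold: float = ADEQUACY_THRESHOLD,
) -> ROITrack:
    """Score every frame of a track and set the overall adequacy flag.

    A cineloop is adequate iff the pleural line stays inside the ROI on
    (at least) the threshold fraction of columns in every frame; inadequate
    cineloops are excluded from elastogram computation downstream.
    """
    if len(track) != cineloop.n_frames:
        raise ValueError("track must cover every frame of the cineloop")
    scores = np.array([
        _adequacy_score(cineloop.frame(k), track[k]) for k in range(len(track))
    ])
    track.adequacy_score = scores
    track.adequate = bool(scores.min() >= threshold)
    return track
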