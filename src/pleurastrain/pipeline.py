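"""End-to-end convenience: cineloop + segmentation → six parameters."""

from __future__ import annotations

import numpy as np

from .motion import SubROIParams, estimate_cineloop
from .parameters import ElastographyParameters, compute_parameters
from .roi import DEFAULT_DEPTH_MM, PleuralSegmentation, assess_adequacy, build_roi, track_roi
from .simulate import RFCineloop


def analyze_cineloop(
    cineloop: RFCineloop,
    segmentation: PleuralSegmentation | None = None,
    depth_mm: float = DEFAULT_DEPTH_MM,
    params: SubROIParams | None = None,
    motion_source: str = "estimate",
    margin_columns: int = 8,
) -> ElastographyParameters:
    """Run ROI construction, tracking, motion estimation and cumulation.

    For simulated loops ``segmentation`` may be omitted: a horizontal
    polyline at the known pleural depth is used, inset ``margin_columns``
    from the lateral edges so the search region and windows stay in-frame.
    Raises if ROI tracking is inadequate (the cineloop should be excluded).
    """
    n_ax, n_lat = cineloop.shape
    if segmentation is None:
        segmentation = PleuralSegmentation(polyline=np.array(
            [[margin_columns, cineloop.pleura_depth_px],
             [n_lat - 1 - margin_columns, cineloop.pleura_depth_px]], dtype=float))
    roi0 = build_roi(segmentation, depth_mm, cineloop.geometry, cineloop.shape)
    track = track_roi(cineloop, roi0, motion_source=motion_source)
    assess_adequacy(cineloop, track)
    field = estimate_cineloop(cineloop, track, params)
    out = compute_parameters(field)
    out.metadata["roi_copied_frames"] = len(track.copied_frames)
    out.metadata["perfect_tracking"] = track.perfect_tracking
    out.metadata["min_adequacy_score"] = float(track.adequacy_score.min())
    return out
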