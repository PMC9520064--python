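"""The six per-cineloop elastography parameters.

Per frame pair, instantaneous sub-ROI motion values are averaged over valid
windows two ways: a *signed* mean, and a mean of *absolute* values (absolute
taken per sub-ROI before averaging — the two differ whenever sub-regions
deform in opposite directions, the tidal-recruitment signature).  Running
sums of these per-pair means give cumulative curves over the respiratory
cycle, prepended with 0 at the reference frame; each reported parameter is
the max-minus-min range of one cumulative curve:

* lateral translation (mm) — range of the cumulated signed lateral shift;
* lateral absolute translation (mm) — range of the cumulated absolute
  lateral shift (total path length of the pleura);
* lateral strain (%) — range of the cumulated signed lateral strain;
* lateral absolute strain (%) — range of the cumulated absolute lateral
  strain (total expansion plus contraction);
* lateral absolute shear (%) — range of the cumulated absolute lateral shear;
* Von Mises strain (%) — range of the cumulated per-window Von Mises
  equivalent strain (intrinsically non-negative, so it has no separate
  absolute variant).

Axial-only parameters are not computed: the pleura lies perpendicular to
the beam, so the analysis is restricted to lateral components plus the
bidimensional Von Mises combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .motion import InstantaneousMotionField

COMPLETENESS_THRESHOLD = 0.9

PARAMETER_NAMES = (
    "lateral_translation_mm",
    "lateral_absolute_translation_mm",
    "lateral_strain_pct",
    "lateral_absolute_strain_pct",
    "lateral_absolute_shear_pct",
    "von_mises_strain_pct",
)


def frame_average(
    field_values: np.ndarray,
    valid: np.ndarray,
    mode: str = "signed",
) -> np.ndarray:
    """Average one motion channel over valid windows, per frame pair.

    ``mode="signed"`` averages raw values; ``mode="absolute"`` averages
    per-window absolute values (absolute before the mean).  Frame pairs with
    no valid window yield NaN (a missing entry, propagated downstream).
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    vals = np.where(valid, field_values, np.nan)
    if mode == "absolute":
        vals = np.abs(vals)
    any_valid = valid.any(axis=1)
    out = np.full(field_values.shape[0], np.nan)
    with np.errstate(invalid="ignore"):
        out[any_valid] = np.nanmean(vals[any_valid], axis=1)
    return out


def cumulate(series: np.ndarray) -> np.ndarray:
    """Running sum of a per-frame-pair series, prepended with 0.

    Missing (NaN) entries contribute a zero increment; completeness is
    accounted for separately.  Summation is plain left-to-right arithmetic.
    """
    increments = np.nan_to_num(np.asarray(series, dtype=float), nan=0.0)
    return np.concatenate([[0.0], np.cumsum(increments)])


def range_of(cumulative: np.ndarray) -> float:
    """Max minus min of a cumulative curve (the leading 0 included)."""
    c = np.asarray(cumulative, dtype=float)
    if c.size == 0:
        raise ValueError("empty cumulative series")
    return float(np.max(c) - np.min(c))


def von_mises_instantaneous(
    lateral_strain_pct: np.ndarray,
    axial_strain_pct: np.ndarray,
    lateral_shear_pct: np.ndarray,
    axial_shear_pct: np.ndarray,
) -> np.ndarray:
    """Von Mises equivalent strain (%) from 2-D strain/shear components.

    Uses the plane-strain equivalent ``sqrt(exx² + eyy² − exx·eyy + 3·exy²)``
    with the engineering shear symmetrized as the mean of the two
    displacement cross-gradients.  Always non-negative and invariant under a
    global sign flip of the motion field.
    """
    exx = np.asarray(lateral_strain_pct, dtype=float)
    eyy = np.asarray(axial_strain_pct, dtype=float)
    exy = 0.5 * (np.asarray(lateral_shear_pct, dtype=float)
                 + np.asarray(axial_shear_pct, dtype=float))
    return np.sqrt(exx**2 + eyy**2 - exx * eyy + 3.0 * exy**2)


@dataclass
class InstantaneousSeries:
    """Per-frame-pair ROI-level series feeding the cumulative curves."""

    lateral_shift_signed: np.ndarray
    lateral_shift_absolute: np.ndarray
    lateral_strain_signed: np.ndarray
    lateral_strain_absolute: np.ndarray
    lateral_shear_signed: np.ndarray
    lateral_shear_absolute: np.ndarray
    von_mises: np.ndarray
    completeness: float    # fraction of frame pairs with >= 1 valid window

    @classmethod
    def from_field(cls, motion_field: InstantaneousMotionField) -> "InstantaneousSeries":
        valid = motion_field.valid
        vm = von_mises_instantaneous(
            motion_field.lateral_strain_pct, motion_field.axial_strain_pct,
            motion_field.lateral_shear_pct, motion_field.axial_shear_pct,
        )
        return cls(
            lateral_shift_signed=frame_average(motion_field.lateral_shift_mm, valid, "signed"),
            lateral_shift_absolute=frame_average(motion_field.lateral_shift_mm, valid, "absolute"),
            lateral_strain_signed=frame_average(motion_field.lateral_strain_pct, valid, "signed"),
            lateral_strain_absolute=frame_average(motion_field.lateral_strain_pct, valid, "absolute"),
            lateral_shear_signed=frame_average(motion_field.lateral_shear_pct, valid, "signed"),
            lateral_shear_absolute=frame_average(motion_field.lateral_shear_pct, valid, "absolute"),
            von_mises=frame_average(vm, valid, "signed"),
            completeness=float(valid.any(axis=1).mean()),
        )


@dataclass
class ElastographyParameters:
    """The six scalar per-cineloop outputs, plus quality metadata."""

    lateral_translation_mm: float
    lateral_absolute_translation_mm: float
    lateral_strain_pct: float
    lateral_absolute_strain_pct: float
    lateral_absolute_shear_pct: float
    von_mises_strain_pct: float
    completeness: float = 1.0
    flagged_incomplete: bool = False
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("metadata")
        return d

    def values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])


def cumulative_curves(series: InstantaneousSeries) -> dict[str, np.ndarray]:
    """The six cumulative curves (length n_frames) behind the parameters."""
    return {
        "lateral_translation_mm": cumulate(series.lateral_shift_signed),
        "lateral_absolute_translation_mm": cumulate(series.lateral_shift_absolute),
        "lateral_strain_pct": cumulate(series.lateral_strain_signed),
        "lateral_absolute_strain_pct": cumulate(series.lateral_strain_absolute),
        "lateral_absolute_shear_pct": cumulate(series.lateral_shear_absolute),
        "von_mises_strain_pct": cumulate(series.von_mises),
    }


def compute_parameters(motion_field: InstantaneousMotionField) -> ElastographyParameters:
    """Derive the six elastography parameters from an instantaneous field.

    Frame pairs where every window is invalid contribute zero increments;
    cineloops with fewer than 90% complete frame pairs are flagged (and
    should be treated like the study's excluded low-quality cineloops).
    """
    series = InstantaneousSeries.from_field(motion_field)
    curves = cumulative_curves(series)
    ranges = {name: range_of(curve) for name, curve in curves.items()}
    return ElastographyParameters(
        **ranges,
        completeness=series.completeness,
        flagged_incomplete=series.completeness < COMPLETENESS_THRESHOLD,
        metadata={
            "von_mises_formula": "sqrt(exx^2 + eyy^2 - exx*eyy + 3*exy^2), exy = (dux_dy + duy_dx)/2",
            "range_includes_reference_zero": True,
            **motion_field.metadata,
        },
    )
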