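"""Synthetic multi-patient studies with known dose-response structure.

Emulates the study design: each of ``n_patients`` mechanically ventilated
patients is imaged at 4 anatomical locations (left/right crossed with
gravity-dependent/non-dependent zones), at tidal volumes of 6, 8, 10 and
12 mL/kg predicted body weight, with triplicate cineloops per cell; at
10 mL/kg two extra reliability sessions are acquired (a second observer,
then a test-retest repeat by the first observer).  That is 10 × (4×4×3 +
2×4×3) = 720 records at the study's size.

Responses follow a linear mixed-effects structure on the standardized
tidal-volume scale::

    y = intercept + slope(dependence)·TV_std + left_offset·[left]
        + dependent_offset·[dependent] + u_patient + u_location(patient) + ε

with independent Gaussian random intercepts per patient and per location
nested within patient.  An optional mode attaches, per record, a simulated
RF cineloop whose strain amplitude equals the record's response, so the
full imaging pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry, MotionProfile
from .simulate import RFCineloop, simulate_cineloop

TIDAL_VOLUMES_ML_KG = (6.0, 8.0, 10.0, 12.0)
N_REPLICATES = 3
RELIABILITY_TV = 10.0

LOCATIONS = (
    # (label, side, dependence): 3rd intercostal mid-clavicular = non-dependent,
    # 8th intercostal posterior axillary = dependent, in the supine patient
    ("R3-MCL", "right", "nondependent"),
    ("L3-MCL", "left", "nondependent"),
    ("R8-PAL", "right", "dependent"),
    ("L8-PAL", "left", "dependent"),
)

STUDY_COLUMNS = [
    "patient_id", "location", "side", "dependence", "tidal_volume_ml_kg",
    "replicate", "observer", "session", "response", "quality_flag",
]


@dataclass(frozen=True)
class SyntheticStudyDesign:
    """Ground-truth structure of a simulated study.

    Slopes and offsets are in standardized units per standardized tidal
    volume; noise scales are standard deviations of the Gaussian random
    intercepts and residual.  Defaults give a realistic mid-sized
    dose-response (slope ~0.4 SD per SD of tidal volume, steeper in
    dependent zones) with patient-level heterogeneity comparable to the
    residual scatter.
    """

    n_patients: int = 10
    tidal_volumes: tuple[float, ...] = TIDAL_VOLUMES_ML_KG
    true_slope_nondependent: float = 0.4
    true_slope_dependent: float = 0.6
    left_offset: float = 0.0
    dependent_offset: float = -0.5
    intercept: float = 0.0
    sd_patient: float = 0.5
    sd_location: float = 0.3
    sd_residual: float = 0.5
    seed: int = 0
    reliability_sessions: bool = True
    high_quality_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if min(self.sd_patient, self.sd_location, self.sd_residual) < 0:
            raise ValueError("noise scales must be non-negative")
        if len(self.tidal_volumes) < 2:
            raise ValueError("need at least two tidal-volume levels")

    def tv_standardized(self, tv: np.ndarray) -> np.ndarray:
        """Tidal volume on the generator's standardized scale (population
        mean/SD over the design's TV levels)."""
        levels = np.asarray(self.tidal_volumes, dtype=float)
        return (np.asarray(tv, dtype=float) - levels.mean()) / levels.std()


def planned_records(design: SyntheticStudyDesign) -> int:
    """Cineloops mandated by the protocol for this design."""
    per_patient = len(design.tidal_volumes) * len(LOCATIONS) * N_REPLICATES
    if design.reliability_sessions:
        per_patient += 2 * len(LOCATIONS) * N_REPLICATES
    return design.n_patients * per_patient


def simulate_study(
    design: SyntheticStudyDesign,
    *,
    with_cineloops: bool = False,
    cineloop_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Draw one synthetic study table (one row per planned cineloop).

    The primary session covers every patient × location × tidal volume ×
    replicate; when ``design.reliability_sessions`` is set, two extra
    sessions (``interobserver`` by observer 2, then ``test-retest`` by
    observer 1) repeat the 10 mL/kg acquisitions.  ``quality_flag`` marks a
    random ``high_quality_fraction`` of records as ``high`` (the
    sensitivity-analysis subset), the rest ``standard``.

    With ``with_cineloops=True`` the returned frame gains a ``cineloop``
    column holding an :class:`~pleurastrain.simulate.RFCineloop` per record
    whose lateral strain amplitude equals the record's response (floored at
    a small positive value), for end-to-end pipeline runs.
    """
    rng = np.random.default_rng(design.seed)

    u_patient = rng.normal(0.0, design.sd_patient, design.n_patients)
    u_location = rng.normal(0.0, design.sd_location, (design.n_patients, len(LOCATIONS)))

    sessions: list[tuple[str, int, tuple[float, ...]]] = [
        ("primary", 1, tuple(design.tidal_volumes))
    ]
    if design.reliability_sessions:
        sessions += [("interobserver", 2, (RELIABILITY_TV,)),
                     ("test-retest", 1, (RELIABILITY_TV,))]

    rows = []
    for p in range(design.n_patients):
        for li, (loc, side, dep) in enumerate(LOCATIONS):
            for session, observer, tvs in sessions:
                for tv in tvs:
                    tv_std = float(design.tv_standardized(tv))
                    slope = (design.true_slope_dependent if dep == "dependent"
                             else design.true_slope_nondependent)
                    mean = (design.intercept + slope * tv_std
                            + design.left_offset * (side == "left")
                            + design.dependent_offset * (dep == "dependent")
                            + u_patient[p] + u_location[p, li])
                    for rep in range(1, N_REPLICATES + 1):
                        y = mean + rng.normal(0.0, design.sd_residual)
                        rows.append({
                            "patient_id": f"P{p + 1:02d}",
                            "location": loc,
                            "side": side,
                            "dependence": dep,
                            "tidal_volume_ml_kg": tv,
                            "replicate": rep,
                            "observer": observer,
                            "session": session,
                            "response": y,
                            "quality_flag": "high"
                            if rng.random() < design.high_quality_fraction
                            else "standard",
                        })

    table = pd.DataFrame(rows, columns=STUDY_COLUMNS)

    if with_cineloops:
        kwargs = dict(shape=(160, 64), pleura_row=30, n_frames=30)
        kwargs.update(cineloop_kwargs or {})
        geometry = kwargs.pop("geometry", AcquisitionGeometry())
        loops: list[RFCineloop] = []
        for i, resp in enumerate(table["response"]):
            profile = MotionProfile(strain_amplitude_pct=max(float(resp), 0.05))
            loops.append(simulate_cineloop(geometry, profile,
                                           seed=design.seed * 100003 + i, **kwargs))
        table["cineloop"] = loops

    return table
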