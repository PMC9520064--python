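"""Acquisition geometry and prescribed pleural motion.

Coordinate convention used throughout the package: RF frames are 2-D arrays
indexed ``(row, column) = (axial, lateral)``; row 0 is the shallowest axial
sample, and pixel centers sit at integer coordinates.  "Axial" is the
direction along the ultrasound beam, "lateral" the direction perpendicular
to it (along the pleural line).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Spatial/temporal calibration of an RF acquisition.

    Defaults describe a high-frequency linear probe over the pleura: 12 MHz
    carrier sampled at 40 MHz, sound speed 1540 m/s (hence axial pitch
    c / (2 fs) = 0.01925 mm per RF sample, so a 2 mm ROI spans about 104
    samples), 0.1 mm lateral pitch and a 30 Hz frame rate.
    """

    center_frequency_mhz: float = 12.0
    sampling_frequency_mhz: float = 40.0
    sound_speed_m_s: float = 1540.0
    lateral_pitch_mm: float = 0.1
    depth_cm: float = 4.0
    width_cm: float = 1.28
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.center_frequency_mhz >= self.sampling_frequency_mhz / 2:
            raise ValueError("center frequency must lie below Nyquist")

    @property
    def axial_pitch_mm(self) -> float:
        """Axial sample spacing in mm: one round trip per RF sample."""
        return self.sound_speed_m_s * 1e3 / (2 * self.sampling_frequency_mhz * 1e6)

    @property
    def normalized_carrier(self) -> float:
        """RF carrier frequency in cycles per axial sample."""
        return self.center_frequency_mhz / self.sampling_frequency_mhz

    def to_attrs(self) -> dict:
        d = asdict(self)
        d["axial_pitch_mm"] = self.axial_pitch_mm
        return d

    @classmethod
    def from_attrs(cls, attrs: dict) -> "AcquisitionGeometry":
        names = [f.name for f in cls.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        return cls(**{k: float(attrs[k]) for k in names if k in attrs})


@dataclass(frozen=True)
class MotionProfile:
    """Prescribed respiratory-cycle motion of the pleura.

    The displacement of a material point at lateral offset ``x`` (mm, relative
    to the ROI center) and axial offset ``y`` (mm, relative to the pleural
    line) is purely lateral::

        u_x(x, y, t) = w(t) * (T + (E/100) * x + (S/100) * y)

    with T = ``translation_amplitude_mm``, E = ``strain_amplitude_pct``
    (uniform lateral strain about the ROI center) and S =
    ``shear_amplitude_pct`` (lateral shear, displacement growing with depth).
    ``w(t)`` is a piecewise-linear respiratory waveform rising from 0 to 1
    over the inspiratory fraction of the cycle and returning linearly to 0 at
    end-expiration; with the default 5 s period (respiratory rate 12 per
    minute) and 1:2 inspiration:expiration ratio, inspiration occupies the
    first third of each cycle.
    """

    translation_amplitude_mm: float = 0.0
    strain_amplitude_pct: float = 0.0
    shear_amplitude_pct: float = 0.0
    respiratory_period_s: float = 5.0
    ie_ratio: float = 0.5
    waveform: str = "ramp"

    def __post_init__(self) -> None:
        if min(self.translation_amplitude_mm, self.strain_amplitude_pct,
               self.shear_amplitude_pct) < 0:
            raise ValueError("motion amplitudes must be non-negative")
        if self.respiratory_period_s <= 0 or self.ie_ratio <= 0:
            raise ValueError("respiratory period and I:E ratio must be positive")
        if self.waveform != "ramp":
            raise ValueError(f"unknown waveform {self.waveform!r}")

    @property
    def inspiratory_fraction(self) -> float:
        return self.ie_ratio / (1.0 + self.ie_ratio)

    def to_attrs(self) -> dict:
        return asdict(self)

    @classmethod
    def from_attrs(cls, attrs: dict) -> "MotionProfile":
        kwargs = {}
        for f in cls.__dataclass_fields__.values():  # type: ignore[attr-defined]
            if f.name in attrs:
                v = attrs[f.name]
                if f.name == "waveform":
                    kwargs[f.name] = v.decode() if isinstance(v, bytes) else str(v)
                else:
                    kwargs[f.name] = float(v)
        return cls(**kwargs)
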