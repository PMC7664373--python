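"""Optical recording geometry shared by the simulator and the reconstructor.

An off-axis digital holographic microscope records the interference of an
object wave with a tilted plane reference wave on a pixelated sensor.  The
tilt puts the object information on a spatial-frequency carrier; everything
downstream (hologram formation, demodulation, numerical propagation) needs
the same small set of optical constants, collected here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["OpticalConfig", "carrier_on_grid"]


@dataclass(frozen=True)
class OpticalConfig:
    """Recording geometry of an off-axis digital holographic microscope.

    Parameters
    ----------
    wavelength
        Illumination wavelength in meters (default 532 nm, a green
        solid-state laser typical of transmission DH microscopes).
    pixel_pitch
        Sensor pixel size in meters (default 5.5 um).  The lateral sampling
        step of every field in this package.
    carrier_fx, carrier_fy
        Spatial carrier frequency of the tilted reference wave along the x
        (column) and y (row) axes, in cycles per meter.  May be omitted when
        ``tilt_angle`` is given.
    sensor_ny, sensor_nx
        Sensor dimensions in pixels (rows, columns).
    tilt_angle
        Off-axis angle theta between reference and object beams, in radians.
        When given, the carrier magnitude is sin(theta)/wavelength; if the
        per-axis components are omitted they default to the diagonal split
        fx = fy = sin(theta)/(wavelength*sqrt(2)).

    Raises
    ------
    ValueError
        On non-positive wavelength/pitch, a carrier at or above the Nyquist
        frequency 1/(2*pixel_pitch), an inconsistent (tilt_angle, carrier)
        pair, or a missing carrier.
    """

    wavelength: float = 532e-9
    pixel_pitch: float = 5.5e-6
    carrier_fx: float | None = None
    carrier_fy: float | None = None
    sensor_ny: int = 2048
    sensor_nx: int = 2048
    tilt_angle: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.sensor_ny < 1 or self.sensor_nx < 1:
            raise ValueError("sensor dimensions must be positive integers")
        if self.carrier_fx is None or self.carrier_fy is None:
            if self.tilt_angle is None:
                raise ValueError(
                    "either (carrier_fx, carrier_fy) or tilt_angle is required"
                )
            mag = math.sin(self.tilt_angle) / self.wavelength
            comp = mag / math.sqrt(2.0)
            object.__setattr__(self, "carrier_fx", comp)
            object.__setattr__(self, "carrier_fy", comp)
        elif self.tilt_angle is not None:
            mag = math.sin(self.tilt_angle) / self.wavelength
            if mag > 0 and abs(self.carrier_magnitude - mag) > 1e-12 * mag:
                raise ValueError(
                    "carrier magnitude inconsistent with tilt_angle: "
                    f"{self.carrier_magnitude:g} != sin(theta)/lambda = {mag:g}"
                )
        if self.carrier_magnitude >= self.nyquist_frequency:
            raise ValueError(
                f"carrier magnitude {self.carrier_magnitude:g} c/m violates the "
                f"Nyquist limit 1/(2*pitch) = {self.nyquist_frequency:g} c/m"
            )

    @property
    def carrier_magnitude(self) -> float:
        """sqrt(fx^2 + fy^2) in cycles/meter."""
        return math.hypot(float(self.carrier_fx), float(self.carrier_fy))

    @property
    def nyquist_frequency(self) -> float:
        """Sampling limit 1/(2*pixel_pitch) in cycles/meter."""
        return 1.0 / (2.0 * self.pixel_pitch)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.sensor_ny, self.sensor_nx)

    def to_dict(self) -> dict:
        return {
            "wavelength": float(self.wavelength),
            "pixel_pitch": float(self.pixel_pitch),
            "carrier_fx": float(self.carrier_fx),
            "carrier_fy": float(self.carrier_fy),
            "sensor_ny": int(self.sensor_ny),
            "sensor_nx": int(self.sensor_nx),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)


def carrier_on_grid(
    shape: tuple[int, int],
    pixel_pitch: float,
    cycles_y: int,
    cycles_x: int,
) -> tuple[float, float]:
    """Carrier components with an integer number of fringe cycles per frame.

    Bin-aligned carriers put the +1 diffraction order exactly on an FFT bin
    and make the carrier cross-term average to zero over the frame, which is
    convenient for simulated holograms.

    Returns ``(carrier_fx, carrier_fy)`` in cycles/meter for ``cycles_x``
    cycles across the ``shape[1]`` columns and ``cycles_y`` across the rows.
    """
    ny, nx = shape
    return (
        float(cycles_x) / (nx * pixel_pitch),
        float(cycles_y) / (ny * pixel_pitch),
    )
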