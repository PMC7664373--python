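"""Wrapped-phase primitives.

Quantitative phase maps reconstructed from a single hologram are only known
modulo 2*pi.  The package keeps every phase image in the principal interval
[-pi, pi) ("wrapped quantitative phase image", WQPI) and re-applies the
2*pi-modulation operator after any arithmetic that may leave the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["wrap_phase", "WQPI", "TWO_PI"]

TWO_PI = 2.0 * np.pi


def wrap_phase(values):
    """2*pi-modulation operator: map phase values into [-pi, pi).

    Elementwise ``((v + pi) mod 2*pi) - pi`` with the half-open convention
    wrap(pi) = -pi.  Accepts scalars or arrays; returns the same kind.

    Raises
    ------
    ValueError
        If any input value is not finite.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_phase requires finite phase values")
    out = np.mod(arr + np.pi, TWO_PI) - np.pi
    # Floating-point mod can land exactly on the open endpoint; fold it back.
    out = np.where(out >= np.pi, out - TWO_PI, out)
    if np.isscalar(values) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class WQPI:
    """A wrapped quantitative phase image.

    Attributes
    ----------
    phase
        2D float array of phase values in radians, all in [-pi, pi).
    class_id
        Optional integer class label (None when unassigned).
    pixel_pitch
        Lateral sampling step in meters.
    """

    phase: np.ndarray
    class_id: int | None = None
    pixel_pitch: float = 5.5e-6

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("WQPI phase must be a 2D array")
        if self.phase.size and (
            self.phase.min() < -np.pi or self.phase.max() >= np.pi
        ):
            raise ValueError("WQPI phase values must lie in [-pi, pi)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    def with_class(self, class_id: int) -> "WQPI":
        return WQPI(self.phase.copy(), class_id=class_id, pixel_pitch=self.pixel_pitch)
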