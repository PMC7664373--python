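"""Shared fixtures: small optical configs and synthetic phase objects."""

from __future__ import annotations

import numpy as np
import pytest

from holoplankton import OpticalConfig, PhantomSlide, carrier_on_grid

PITCH = 5.5e-6


def make_optics(n: int, carrier_frac: float = 0.35) -> OpticalConfig:
    """Bin-aligned off-axis optics for an n x n sensor."""
    cyc = round(carrier_frac * n)
    fx, fy = carrier_on_grid((n, n), PITCH, cyc, cyc)
    return OpticalConfig(carrier_fx=fx, carrier_fy=fy, sensor_ny=n, sensor_nx=n)


def gaussian_phase_slide(
    n: int, sigma: float = 24.0, peak: float = 3.0 * np.pi
) -> tuple[PhantomSlide, np.ndarray]:
    """A single smooth Gaussian phase bump; returns (slide, r^2 grid).

    The profile is gentle enough that exp(i psi) is essentially band-limited
    within the demodulation passband, making it the reference object for
    forward-inverse (hologram -> demodulation -> phase) oracle tests.
    """
    yy, xx = np.mgrid[:n, :n].astype(float)
    r2 = (yy - n / 2) ** 2 + (xx - n / 2) ** 2
    psi = peak * np.exp(-r2 / (2.0 * sigma**2))
    slide = PhantomSlide(
        true_phase=psi,
        label_map=(psi > 1e-6).astype(int),
        objects=[],
        rng_seed=0,
    )
    return slide, r2


@pytest.fixture
def optics128() -> OpticalConfig:
    return make_optics(128)


@pytest.fixture
def optics256() -> OpticalConfig:
    return make_optics(256)
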