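"""Numerical reconstruction of off-axis digital holograms.

The processing chain is the classical one for off-axis DH microscopy:

1. **Demodulation** — isolate the +1 diffraction order around the spatial
   carrier in Fourier space and shift it to baseband, recovering the complex
   object wave ``|O| exp(i psi_o)`` at the hologram plane.
2. **Angular Spectrum propagation** — the exact scalar-diffraction transfer
   function ``exp(i 2 pi dz sqrt(1/lambda^2 - fx^2 - fy^2))`` applied in the
   Fourier domain relocates the field to any axial plane z.
3. **Autofocus** — for a pure-phase object the amplitude image is flattest
   at best focus, so the focus plane is found by minimizing the Tamura
   coefficient sqrt(std/mean) of the amplitude over a coarse-to-fine scan of
   propagation distances.
4. **Phase extraction** — the per-pixel argument of the refocused field,
   wrapped to [-pi, pi), is the WQPI used for segmentation and training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import OpticalConfig
from .phase import WQPI, wrap_phase

__all__ = [
    "ComplexField",
    "FocusScanResult",
    "demodulate",
    "propagate",
    "tamura",
    "autofocus",
    "extract_wqpi",
]


@dataclass
class ComplexField:
    """A 2D complex optical field at a stated axial position.

    ``field`` is the complex amplitude sampled at the sensor pitch; ``z`` is
    the axial position in meters relative to the hologram plane.
    """

    field: np.ndarray
    z: float
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=complex)
        if self.field.shape != self.config.shape:
            raise ValueError(
                f"field shape {self.field.shape} does not match sensor "
                f"dimensions {self.config.shape}"
            )
        if not np.isfinite(self.z):
            raise ValueError("axial position z must be finite")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)


@dataclass
class FocusScanResult:
    """Outcome of a coarse-to-fine Tamura focus scan."""

    z_grid: np.ndarray
    tamura_values: np.ndarray
    z_best: float
    refinement_history: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.tamura_values = np.asarray(self.tamura_values, dtype=float)
        if len(self.z_grid) != len(self.tamura_values):
            raise ValueError("z_grid and tamura_values must have equal length")


def _freq_grids(config: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency grids (cycles/meter) matching the FFT layout."""
    fx = np.fft.fftfreq(config.sensor_nx, d=config.pixel_pitch)
    fy = np.fft.fftfreq(config.sensor_ny, d=config.pixel_pitch)
    return fx[np.newaxis, :], fy[:, np.newaxis]


def _carrier_phase(config: OpticalConfig, ref_phase: float = 0.0) -> np.ndarray:
    """Carrier phase 2*pi*(fx*x + fy*y) - phi_R on the sensor grid."""
    p = config.pixel_pitch
    x = np.arange(config.sensor_nx)[np.newaxis, :] * p
    y = np.arange(config.sensor_ny)[:, np.newaxis] * p
    return 2.0 * np.pi * (config.carrier_fx * x + config.carrier_fy * y) - ref_phase


def demodulate(
    hologram,
    filter_radius: float | None = None,
    soft_edge_frac: float = 0.3,
    iterations: int = 2,
) -> ComplexField:
    """Recover the baseband complex object wave from an off-axis hologram.

    The hologram intensity is multiplied by the conjugate carrier (an exact
    shift of the +1 diffraction order to the Fourier origin, valid for any
    carrier, bin-aligned or not) and low-pass filtered with a circular
    bandpass of radius ``filter_radius`` whose outer ``soft_edge_frac``
    fraction rolls off as a raised cosine (a hard edge would imprint
    ringing on the recovered amplitude, which biases contrast-metric
    autofocus).  The result approximates ``|O| exp(i psi_o)`` at z = 0.

    With ``iterations > 0`` the estimate is refined against the forward
    model: the interference intensity implied by the current estimate is
    re-synthesized, and the bandpassed residual is added back.  This
    suppresses the leakage of the DC autocorrelation and twin-image (-1
    order) tails into the passband — significant for strongly defocused
    objects — at the cost of two extra FFT pairs per iteration.

    Parameters
    ----------
    hologram
        A :class:`~holoplankton.simulate.Hologram` (any object with
        ``intensity`` and ``config`` attributes).
    filter_radius
        Bandpass radius in cycles/meter.  Default: half the distance from
        the carrier peak to the DC term.
    soft_edge_frac
        Fraction of the bandpass radius over which the filter rolls off
        (0 gives a hard edge).
    iterations
        Number of forward-model refinement passes (0 = plain single-pass
        demodulation).

    Raises
    ------
    ValueError
        If the bandpass circle reaches the DC autocorrelation term, i.e.
        ``filter_radius >= carrier magnitude``.
    """
    config = hologram.config
    fc = config.carrier_magnitude
    if fc <= 0:
        raise ValueError("off-axis demodulation requires a nonzero carrier")
    r = fc / 2.0 if filter_radius is None else float(filter_radius)
    if r <= 0:
        raise ValueError("filter_radius must be positive")
    if r >= fc:
        raise ValueError(
            f"bandpass radius {r:g} c/m overlaps the DC term (carrier "
            f"magnitude {fc:g} c/m); the +1 order is not separable"
        )
    if not 0.0 <= soft_edge_frac < 1.0:
        raise ValueError("soft_edge_frac must lie in [0, 1)")
    theta = _carrier_phase(config)
    conj_carrier = np.exp(-1j * theta)
    fx, fy = _freq_grids(config)
    rho = np.sqrt(fx**2 + fy**2) / r
    if soft_edge_frac == 0.0:
        mask = (rho <= 1.0).astype(float)
    else:
        flat = 1.0 - soft_edge_frac
        mask = np.where(
            rho <= flat,
            1.0,
            np.where(
                rho < 1.0,
                np.cos(0.5 * np.pi * (rho - flat) / soft_edge_frac) ** 2,
                0.0,
            ),
        )

    intensity = np.asarray(hologram.intensity, dtype=float)

    def bandpass(img: np.ndarray) -> np.ndarray:
        return np.fft.ifft2(np.fft.fft2(img * conj_carrier) * mask)

    obj = bandpass(intensity)
    for _ in range(int(iterations)):
        model = np.abs(conj_carrier + obj) ** 2
        obj = obj + bandpass(intensity - model)
    return ComplexField(obj, z=0.0, config=config)


def propagate(field: ComplexField, dz: float) -> ComplexField:
    """Angular Spectrum propagation of ``field`` by an axial distance ``dz``.

    Applies the transfer function
    ``exp(i 2 pi dz sqrt(1/lambda^2 - fx^2 - fy^2))`` to the field's Fourier
    transform for propagating frequencies (fx^2 + fy^2 <= 1/lambda^2);
    evanescent components are set to zero (this also keeps back-propagation
    dz < 0 numerically stable).
    """
    if not np.isfinite(dz):
        raise ValueError("propagation distance must be finite")
    if dz == 0.0:
        return ComplexField(field.field.copy(), z=field.z, config=field.config)
    config = field.config
    fx, fy = _freq_grids(config)
    inv_lambda_sq = 1.0 / config.wavelength**2
    arg = inv_lambda_sq - fx**2 - fy**2
    propagating = arg >= 0.0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    transfer = np.where(propagating, np.exp(1j * 2.0 * np.pi * dz * kz), 0.0)
    out = np.fft.ifft2(np.fft.fft2(field.field) * transfer)
    return ComplexField(out, z=field.z + dz, config=config)


def tamura(amplitude: np.ndarray) -> float:
    """Tamura coefficient sqrt(std/mean) of an amplitude image.

    Uses the population standard deviation.  For a pure-phase object the
    amplitude is flattest — hence the coefficient smallest — at best focus.

    Raises
    ------
    ValueError
        On an empty image or one with non-positive mean.
    """
    arr = np.asarray(amplitude, dtype=float)
    if arr.size == 0:
        raise ValueError("amplitude image is empty")
    m = arr.mean()
    if m <= 0:
        raise ValueError("amplitude mean must be positive")
    return float(np.sqrt(arr.std() / m))


def autofocus(
    field: ComplexField,
    z_min: float,
    z_max: float,
    n_coarse: int = 21,
    n_refine_levels: int = 3,
) -> FocusScanResult:
    """Find the best-focus propagation distance by Tamura minimization.

    Evaluates ``tamura(|P_z(field)|)`` on a uniform grid of ``n_coarse``
    distances in [z_min, z_max], then refines around the minimum by
    successive grid halving for ``n_refine_levels`` rounds; the bracket
    width after refinement is
    ``(z_max - z_min)/(n_coarse - 1)/2**n_refine_levels``.  A final
    parabolic interpolation through the best point and its bracket
    neighbors is evaluated as one extra candidate, removing most of the
    residual grid-discretization error.  ``z_best`` is the argmin over all
    evaluated distances.

    Warns (does not raise) when the coarse minimum sits on the search
    boundary, which indicates the focus plane may lie outside the range.
    """
    if not z_min < z_max:
        raise ValueError("z_min must be strictly less than z_max")
    if n_coarse < 3:
        raise ValueError("n_coarse must be at least 3")

    def metric(z: float) -> float:
        return tamura(np.abs(propagate(field, z).field))

    z_grid = np.linspace(z_min, z_max, n_coarse)
    values = np.array([metric(z) for z in z_grid])
    i_best = int(np.argmin(values))
    if i_best in (0, n_coarse - 1):
        warnings.warn(
            "Tamura minimum on the search boundary; the focus plane may lie "
            "outside [z_min, z_max]",
            RuntimeWarning,
            stacklevel=2,
        )
    z_best = float(z_grid[i_best])
    t_best = float(values[i_best])
    step = (z_max - z_min) / (n_coarse - 1)
    history: list[tuple[float, float]] = []
    for _ in range(n_refine_levels):
        step /= 2.0
        for z_cand in (z_best - step, z_best + step):
            t_cand = metric(z_cand)
            history.append((float(z_cand), float(t_cand)))
            if t_cand < t_best:
                z_best, t_best = float(z_cand), float(t_cand)
    # Parabolic tip through (z_best - step, z_best, z_best + step); only
    # accepted if the evaluated Tamura value actually improves.
    t_left, t_right = metric(z_best - step), metric(z_best + step)
    curvature = t_left - 2.0 * t_best + t_right
    if curvature > 0.0:
        z_par = z_best + 0.5 * step * (t_left - t_right) / curvature
        t_par = metric(z_par)
        history.append((float(z_par), float(t_par)))
        if t_par < t_best:
            z_best, t_best = float(z_par), float(t_par)
    return FocusScanResult(
        z_grid=z_grid,
        tamura_values=values,
        z_best=z_best,
        refinement_history=history,
    )


def compensate_piston(field: ComplexField) -> ComplexField:
    """Remove the constant (piston) phase offset of a reconstructed field.

    Rotates the field so the argument of its complex mean is zero.  For a
    mostly transparent scene the mean is dominated by the background, so
    the background phase is anchored near zero.  Numerical refocusing by a
    distance z multiplies the whole field by exp(i 2 pi z / lambda) — at
    millimeter distances and sub-micron wavelengths an essentially random
    global offset — and real recordings accumulate comparable offsets from
    the reference arm; this is the constant term of the usual aberration
    compensation, whose *residuals* the phase-bias augmentation models.
    """
    mean = field.field.mean()
    if mean == 0:
        return ComplexField(field.field.copy(), field.z, field.config)
    return ComplexField(
        field.field * np.exp(-1j * np.angle(mean)), field.z, field.config
    )


def extract_wqpi(field: ComplexField, class_id: int | None = None) -> WQPI:
    """Wrapped quantitative phase image: per-pixel argument in [-pi, pi)."""
    return WQPI(
        wrap_phase(np.angle(field.field)),
        class_id=class_id,
        pixel_pitch=field.config.pixel_pitch,
    )
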