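"""Synthetic phase phantoms and off-axis holograms with known ground truth.

The simulator emulates the two recording situations of a diatom test-slide
study: a *dry slide* — many disjoint, in-focus pure-phase objects (one
specimen per species fixed between glass slides) — and *wet samples* —
individual objects suspended in a volume, recorded out of focus with a
little noise and refocused numerically.

Phantom objects are drawn from distinct parametric families that echo
diatom morphology (pennate outlines with striae, centric valves with radial
ornamentation, concentric rings, rectangular valves with transverse ridges)
so that every downstream stage — demodulation, autofocus, segmentation,
augmentation, classification — can be exercised against exact ground truth
without any external data.

A hologram is formed as the interference intensity of the object wave
``O = A exp(i psi_o)`` with a unit-amplitude tilted plane reference wave:

    H = |R + O|^2 = |R|^2 + |O|^2 + 2 |R| |O| cos(2 pi (fx x + fy y) - phi_R + psi_o)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import OpticalConfig
from .reconstruct import ComplexField, propagate

__all__ = [
    "MorphologyConfig",
    "PhantomObject",
    "PhantomSlide",
    "Hologram",
    "make_phantom_slide",
    "form_hologram",
]

FAMILIES = ("pennate", "centric", "concentric", "rect")


@dataclass(frozen=True)
class MorphologyConfig:
    """Shape parameters for phantom diatom rendering.

    ``radius_range`` is the nominal object semi-major axis in pixels; the
    smooth envelope extends its support to 1.6x that, so at the default
    5.5 um pitch overall diameters span roughly 160-210 um, at the upper
    end of the 50-200 um range typical of test-slide diatoms.
    ``peak_phase_range`` is the peak optical phase delay in radians; the
    default exceeds 2*pi so the extracted phase maps genuinely wrap.
    """

    radius_range: tuple[float, float] = (11.0, 14.0)
    aspect_range: tuple[float, float] = (0.6, 1.0)
    peak_phase_range: tuple[float, float] = (6.5, 7.2)
    ridge_period_range: tuple[float, float] = (11.0, 15.0)
    families: tuple[str, ...] = FAMILIES
    margin_px: int = 6


@dataclass(frozen=True)
class PhantomObject:
    class_id: int
    centroid: tuple[float, float]  # (row, col) in pixels
    defocus_z: float  # meters; 0 in dry-slide mode


@dataclass
class PhantomSlide:
    """Ground-truth phantom: unwrapped phase, label map and object table."""

    true_phase: np.ndarray
    label_map: np.ndarray
    objects: list[PhantomObject]
    rng_seed: int

    def class_ids(self) -> list[int]:
        return [o.class_id for o in self.objects]

    def object_patch(self, class_id: int, pad_px: int = 4) -> np.ndarray:
        """Crop of the unwrapped ground-truth phase around one object."""
        rows, cols = np.nonzero(self.label_map == class_id)
        if rows.size == 0:
            raise KeyError(f"class {class_id} not present in label_map")
        ny, nx = self.true_phase.shape
        r0 = max(rows.min() - pad_px, 0)
        r1 = min(rows.max() + 1 + pad_px, ny)
        c0 = max(cols.min() - pad_px, 0)
        c1 = min(cols.max() + 1 + pad_px, nx)
        patch = self.true_phase[r0:r1, c0:c1].copy()
        patch[self.label_map[r0:r1, c0:c1] != class_id] = 0.0
        return patch


@dataclass
class Hologram:
    """Recorded off-axis hologram: non-negative intensity plus optics."""

    intensity: np.ndarray
    config: OpticalConfig
    true_defocus: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.config.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"sensor dimensions {self.config.shape}"
            )
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("hologram intensity must be non-negative")

    @property
    def true_refocus_z(self) -> float:
        """Propagation distance that brings the object back in focus."""
        return -self.true_defocus


# Support extends to _RHO_CUT times the nominal radius; the envelope decays
# continuously to exactly zero there.
_RHO_CUT = 1.6
_ENV_FLAT = 0.15  # flat core extent in normalized radius
_ENV_WIDTH = 0.65  # Gaussian shoulder width in normalized radius


def _soft_support(rho: np.ndarray) -> np.ndarray:
    """Smooth envelope: flat core with a wide Gaussian shoulder.

    The shoulder width keeps the peak phase gradient of a typical object
    well inside the demodulation passband of an off-axis recording with a
    carrier near the Nyquist limit, so that reconstructed amplitudes stay
    close to unity at focus — the regime in which Tamura-based autofocus
    operates.  The profile is shifted and rescaled to reach exactly zero at
    rho = _RHO_CUT (no truncation step, which would ring).
    """
    shoulder = np.clip(rho - _ENV_FLAT, 0.0, None) / _ENV_WIDTH
    edge = math.exp(-(((_RHO_CUT - _ENV_FLAT) / _ENV_WIDTH) ** 2))
    return np.clip((np.exp(-(shoulder**2)) - edge) / (1.0 - edge), 0.0, None)


def _render_object(family: str, rng: np.random.Generator, cfg: MorphologyConfig):
    """Render one phantom object patch (unwrapped phase, radians)."""
    radius = rng.uniform(*cfg.radius_range)
    peak = rng.uniform(*cfg.peak_phase_range)
    period = rng.uniform(*cfg.ridge_period_range)
    orient = rng.uniform(0.0, np.pi)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)

    if family == "centric":
        aspect = 1.0
    else:
        aspect = rng.uniform(*cfg.aspect_range)
    a, b = radius, radius * aspect

    half = int(math.ceil(_RHO_CUT * radius)) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = np.cos(orient) * xx + np.sin(orient) * yy
    yr = -np.sin(orient) * xx + np.cos(orient) * yy

    if family == "rect":
        # exponent 4 keeps the corner radius resolvable by the recording optics
        p = 4.0
        rho = (np.abs(xr / a) ** p + np.abs(yr / b) ** p) ** (1.0 / p)
    else:
        rho = np.hypot(xr / a, yr / b)
    env = _soft_support(rho)

    # Modulation depths and spatial periods are kept gentle enough that the
    # total phase gradient stays within the passband of the off-axis
    # demodulation (carrier near Nyquist, bandpass radius ~ half carrier).
    if family == "pennate":
        mod = 0.85 + 0.15 * np.cos(2.0 * np.pi * xr / period + phase0)
    elif family == "centric":
        m = int(rng.choice([6, 8]))
        # rho^2 weighting removes the azimuthal-gradient singularity at center
        mod = 0.85 + 0.15 * rho**2 * np.cos(m * np.arctan2(yr, xr) + phase0)
    elif family == "concentric":
        mod = 0.85 + 0.15 * np.cos(2.0 * np.pi * rho * radius / period)
    elif family == "rect":
        mod = 0.85 + 0.15 * np.cos(2.0 * np.pi * yr / period + phase0)
    else:
        raise ValueError(f"unknown morphology family {family!r}")

    patch = peak * env * mod
    patch[patch < 1e-6] = 0.0
    return patch


def make_phantom_slide(
    n_classes: int,
    image_shape: tuple[int, int],
    morphology: MorphologyConfig | None = None,
    seed: int = 0,
) -> PhantomSlide:
    """Generate a phantom test slide with one disjoint object per class.

    Objects are laid out on a jittered grid in reading order (class 1 at the
    top-left), mirroring a commercial test slide where one specimen of each
    species sits in its own clear area.  Each class draws its morphology
    family cyclically and its shape parameters from a per-class substream of
    ``seed``, so slides of different sizes reuse identical per-class shapes.

    Raises
    ------
    ValueError
        If ``n_classes`` objects of the configured maximum size cannot be
        placed disjointly on ``image_shape``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be at least 1")
    cfg = morphology or MorphologyConfig()
    ny, nx = int(image_shape[0]), int(image_shape[1])
    ncols = int(math.ceil(math.sqrt(n_classes)))
    nrows = int(math.ceil(n_classes / ncols))
    cell_h, cell_w = ny / nrows, nx / ncols
    r_max = _RHO_CUT * cfg.radius_range[1]
    need = 2.0 * (r_max + cfg.margin_px)
    if min(cell_h, cell_w) < need:
        raise ValueError(
            f"cannot place {n_classes} disjoint objects of radius "
            f"{r_max:.0f}px on a {ny}x{nx} canvas (cell {cell_h:.0f}x{cell_w:.0f}px, "
            f"need >= {need:.0f}px)"
        )

    true_phase = np.zeros((ny, nx))
    label_map = np.zeros((ny, nx), dtype=int)
    objects: list[PhantomObject] = []
    streams = np.random.SeedSequence(seed).spawn(n_classes)
    for k in range(n_classes):
        class_id = k + 1
        rng = np.random.default_rng(streams[k])
        family = cfg.families[k % len(cfg.families)]
        patch = _render_object(family, rng, cfg)
        half = patch.shape[0] // 2
        row_cell, col_cell = divmod(k, ncols)
        cy = (row_cell + 0.5) * cell_h
        cx = (col_cell + 0.5) * cell_w
        slack_y = cell_h / 2.0 - (half + cfg.margin_px)
        slack_x = cell_w / 2.0 - (half + cfg.margin_px)
        cy += rng.uniform(-max(slack_y, 0.0), max(slack_y, 0.0))
        cx += rng.uniform(-max(slack_x, 0.0), max(slack_x, 0.0))
        r0, c0 = int(round(cy)) - half, int(round(cx)) - half
        sl = (slice(r0, r0 + patch.shape[0]), slice(c0, c0 + patch.shape[1]))
        if (label_map[sl][patch > 0] != 0).any():  # pragma: no cover - guarded above
            raise ValueError("object placement collision")
        true_phase[sl][patch > 0] = patch[patch > 0]
        label_map[sl][patch > 0] = class_id
        mask = label_map == class_id
        rows, cols = np.nonzero(mask)
        objects.append(
            PhantomObject(
                class_id=class_id,
                centroid=(float(rows.mean()), float(cols.mean())),
                defocus_z=0.0,
            )
        )
    return PhantomSlide(
        true_phase=true_phase, label_map=label_map, objects=objects, rng_seed=seed
    )


def form_hologram(
    slide: PhantomSlide,
    config: OpticalConfig,
    defocus_z: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    object_amplitude: float = 1.0,
    ref_phase: float = 0.0,
) -> Hologram:
    """Form the off-axis hologram intensity of a phantom slide.

    The object wave ``O = object_amplitude * exp(i psi_o)`` is propagated by
    ``defocus_z`` to the sensor plane, and the recorded intensity is
    ``|R + O|^2`` with the unit-amplitude tilted reference
    ``R = exp(-i [2 pi (fx x + fy y) - phi_R])``.  Optional additive
    Gaussian read noise (standard deviation ``noise_sd``) is clipped at 0.

    With ``defocus_z = 0`` and ``noise_sd = 0`` the result is the textbook
    interference intensity evaluated pointwise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if slide.true_phase.shape != config.shape:
        raise ValueError(
            f"slide shape {slide.true_phase.shape} does not match sensor "
            f"dimensions {config.shape}"
        )
    obj = object_amplitude * np.exp(1j * slide.true_phase)
    if defocus_z != 0.0:
        obj = propagate(ComplexField(obj, 0.0, config), defocus_z).field
    p = config.pixel_pitch
    x = np.arange(config.sensor_nx)[np.newaxis, :] * p
    y = np.arange(config.sensor_ny)[:, np.newaxis] * p
    theta = 2.0 * np.pi * (config.carrier_fx * x + config.carrier_fy * y) - ref_phase
    ref = np.exp(-1j * theta)
    intensity = np.abs(ref + obj) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
        intensity = np.clip(intensity, 0.0, None)
    return Hologram(intensity=intensity, config=config, true_defocus=defocus_z)
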