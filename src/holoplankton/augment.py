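"""Wrapped-phase data augmentation: one generator image per class.

A single wrapped quantitative phase image (WQPI) per class is expanded into
a full training set by three nested deterministic transformations —
anisotropic resizing, rotation, and a constant phase bias — with the
2*pi-modulation operator applied after every step so the image stays a
valid WQPI.  The default lattice is 21 x 21 scales in [-20%, +20%] per
axis, 36 rotations in 10-degree steps, and 11 phase biases evenly spaced on
[0, pi]: 174,636 parameter tuples per class.

The bias dimension models the residual constant phase offsets that real
recordings accumulate (reference-arm drift, imperfect aberration
compensation), which is why a classifier trained on this lattice tolerates
them at test time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .phase import TWO_PI, WQPI, wrap_phase

__all__ = [
    "AugmentationGrid",
    "build_grid",
    "apply_transform",
    "sample_plan",
    "generate_dataset",
    "split_train_val",
    "phase_to_uint8",
    "uint8_to_phase",
]


@dataclass(frozen=True)
class AugmentationGrid:
    """Ordered parameter lists defining the deterministic augmentation lattice.

    ``scales_x`` / ``scales_y`` are relative size changes (0.0 = unchanged,
    0.2 = +20%); ``angles_deg`` rotation angles; ``biases_rad`` constant
    phase offsets.  The lattice is the Cartesian product of the four lists,
    enumerated with ``scales_x`` as the slowest axis and ``biases_rad`` as
    the fastest.
    """

    scales_x: tuple[float, ...]
    scales_y: tuple[float, ...]
    angles_deg: tuple[float, ...]
    biases_rad: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("scales_x", "scales_y", "angles_deg", "biases_rad"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"grid dimension {name} is empty")
            object.__setattr__(self, name, tuple(float(v) for v in vals))

    @property
    def cardinality(self) -> int:
        return (
            len(self.scales_x)
            * len(self.scales_y)
            * len(self.angles_deg)
            * len(self.biases_rad)
        )

    def __len__(self) -> int:
        return self.cardinality

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return (
            len(self.scales_x),
            len(self.scales_y),
            len(self.angles_deg),
            len(self.biases_rad),
        )

    def tuple_at(self, index: int) -> tuple[float, float, float, float]:
        """(scale_x, scale_y, angle_deg, bias_rad) at a flat lattice index."""
        if not 0 <= index < self.cardinality:
            raise IndexError(f"tuple index {index} out of range")
        ix, iy, ia, ib = np.unravel_index(index, self.dims)
        return (
            self.scales_x[ix],
            self.scales_y[iy],
            self.angles_deg[ia],
            self.biases_rad[ib],
        )


def build_grid(
    scale_extent: float = 0.20,
    n_scales: int = 21,
    angle_step_deg: float = 10.0,
    n_biases: int = 11,
    bias_range: tuple[float, float] = (0.0, float(np.pi)),
    random_biases: bool = False,
    seed: int | None = None,
) -> AugmentationGrid:
    """Build the augmentation lattice.

    Defaults reproduce the standard 21 x 21 x 36 x 11 grid (174,636 tuples).
    ``random_biases=True`` draws the biases uniformly at random from
    ``bias_range`` (sorted, deterministic for a fixed ``seed``) instead of
    even spacing.
    """
    if n_scales < 1 or n_biases < 1:
        raise ValueError("grid dimensions must be at least 1")
    if angle_step_deg <= 0 or angle_step_deg > 360:
        raise ValueError("angle_step_deg must lie in (0, 360]")
    scales = tuple(np.linspace(-scale_extent, scale_extent, n_scales))
    angles = tuple(np.arange(0.0, 360.0, angle_step_deg))
    if random_biases:
        rng = np.random.default_rng(seed)
        biases = tuple(np.sort(rng.uniform(*bias_range, size=n_biases)))
    else:
        biases = tuple(np.linspace(bias_range[0], bias_range[1], n_biases))
    return AugmentationGrid(
        scales_x=scales, scales_y=scales, angles_deg=angles, biases_rad=biases
    )


def _trim_support(img: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Trim all-(near-)zero border rows/columns."""
    keep = np.abs(img) > tol
    if not keep.any():
        return img[:0, :0]
    rows = np.nonzero(keep.any(axis=1))[0]
    cols = np.nonzero(keep.any(axis=0))[0]
    return img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def apply_transform(
    gen: WQPI,
    scale_x: float,
    scale_y: float,
    angle_deg: float,
    bias_rad: float,
    out_shape: tuple[int, int] = (256, 256),
) -> WQPI:
    """Apply the nested resize -> rotate -> bias cascade to a generator WQPI.

    1. bilinear resize by (1+scale_y, 1+scale_x) (rows, columns), then wrap;
    2. bilinear rotation by ``angle_deg`` about the image center with
       zero background fill (canvas enlarged so nothing is clipped), then
       wrap;
    3. add ``bias_rad`` to every pixel of the crop, then wrap;
    4. trim the crop to its object support and center-place it onto a
       phase-0 canvas of ``out_shape``.

    Interpolation acts on the wrapped values directly; the re-wrapping after
    each step keeps the output a valid WQPI, at the price of localized
    artifacts where interpolation crosses a wrap discontinuity — the same
    behavior a WQPI-format augmentation pipeline exhibits on real data.

    With identity parameters (0, 0, 0 deg, 0 rad) the output equals the
    input exactly on its support.

    Raises
    ------
    ValueError
        If a scale factor leaves (0.5, 2.0) or the transformed object does
        not fit ``out_shape``.
    """
    fx, fy = 1.0 + scale_x, 1.0 + scale_y
    if not (0.5 <= fx <= 2.0 and 0.5 <= fy <= 2.0):
        raise ValueError(f"scale factors ({fx:g}, {fy:g}) outside the sane range 0.5-2.0")
    img = gen.phase
    if scale_x != 0.0 or scale_y != 0.0:
        new_shape = (
            max(int(round(img.shape[0] * fy)), 1),
            max(int(round(img.shape[1] * fx)), 1),
        )
        img = wrap_phase(
            _sk_resize(
                img,
                new_shape,
                order=1,
                mode="constant",
                cval=0.0,
                anti_aliasing=False,
                preserve_range=True,
            )
        )
    if angle_deg % 360.0 != 0.0:
        img = wrap_phase(
            _sk_rotate(
                img,
                -angle_deg,  # positive angle = clockwise in image coordinates
                resize=True,
                order=1,
                mode="constant",
                cval=0.0,
                preserve_range=True,
            )
        )
    img = _trim_support(img)
    if bias_rad != 0.0:
        img = wrap_phase(img + bias_rad)
    ny, nx = out_shape
    if img.shape[0] > ny or img.shape[1] > nx:
        raise ValueError(
            f"transformed object {img.shape} exceeds output canvas {tuple(out_shape)}"
        )
    canvas = np.zeros((ny, nx))
    r0 = (ny - img.shape[0]) // 2
    c0 = (nx - img.shape[1]) // 2
    canvas[r0 : r0 + img.shape[0], c0 : c0 + img.shape[1]] = img
    return WQPI(canvas, class_id=gen.class_id, pixel_pitch=gen.pixel_pitch)


def sample_plan(
    class_ids: list[int],
    grid: AugmentationGrid,
    per_class: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``per_class`` lattice tuples per class, without replacement.

    Deterministic for a fixed seed (each class uses its own substream, so
    the plan for one class does not depend on which other classes are
    present).  Returns a manifest-plan DataFrame with columns
    ``class_id, tuple_index, scale_x, scale_y, angle_deg, bias_rad``.
    """
    card = grid.cardinality
    if per_class > card:
        raise ValueError(
            f"per_class={per_class} exceeds the grid cardinality {card}"
        )
    frames = []
    for cid in class_ids:
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(cid)]))
        idx = np.sort(rng.choice(card, size=per_class, replace=False))
        ix, iy, ia, ib = np.unravel_index(idx, grid.dims)
        params = np.column_stack(
            [
                np.asarray(grid.scales_x)[ix],
                np.asarray(grid.scales_y)[iy],
                np.asarray(grid.angles_deg)[ia],
                np.asarray(grid.biases_rad)[ib],
            ]
        )
        frames.append(
            pd.DataFrame(
                {
                    "class_id": int(cid),
                    "tuple_index": idx.astype(int),
                    "scale_x": params[:, 0],
                    "scale_y": params[:, 1],
                    "angle_deg": params[:, 2],
                    "bias_rad": params[:, 3],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_dataset(
    generators: list[WQPI],
    grid: AugmentationGrid,
    per_class: int,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
    out_shape: tuple[int, int] = (256, 256),
):
    """Materialize the augmented dataset from one generator per class.

    Returns ``(manifest, images)``.  When ``out_dir`` is None the images are
    returned as a float array of shape (n, ny, nx) in manifest row order;
    otherwise each image is written as an 8-bit PNG under
    ``out_dir/class_{k:02d}/`` (phase mapped linearly from [-pi, pi) to
    0..255), a ``manifest.csv`` is written, and ``images`` is the list of
    file paths.

    Raises
    ------
    ValueError
        On duplicate/unassigned generator class ids or
        ``per_class > grid.cardinality``.
    """
    ids = [g.class_id for g in generators]
    if any(i is None for i in ids) or len(set(ids)) != len(ids):
        raise ValueError("generators must carry distinct, assigned class_ids")
    by_id = {g.class_id: g for g in generators}
    manifest = sample_plan(sorted(by_id), grid, per_class, seed)
    images: list = []
    paths: list[str] = []
    if out_dir is not None:
        import imageio.v3 as iio

        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
    for row in manifest.itertuples(index=True):
        wq = apply_transform(
            by_id[row.class_id],
            row.scale_x,
            row.scale_y,
            row.angle_deg,
            row.bias_rad,
            out_shape=out_shape,
        )
        if out_dir is None:
            images.append(wq.phase)
        else:
            cls_dir = os.path.join(out_dir, f"class_{row.class_id:02d}")
            os.makedirs(cls_dir, exist_ok=True)
            path = os.path.join(cls_dir, f"{row.tuple_index:07d}.png")
            iio.imwrite(path, phase_to_uint8(wq.phase))
            paths.append(path)
    if out_dir is None:
        return manifest, np.stack(images)
    manifest = manifest.assign(path=paths)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest, paths


def split_train_val(
    manifest: pd.DataFrame, train_frac: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class stratified random split of a manifest.

    Each class contributes ``round(train_frac * n_class)`` rows to the
    training side; the split is disjoint and exhaustive and deterministic
    for a fixed seed.

    Raises
    ------
    ValueError
        If ``train_frac`` is not in (0, 1) or any class would end up with an
        empty train or validation side.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for cid, group in manifest.groupby("class_id", sort=True):
        n = len(group)
        n_train = int(round(train_frac * n))
        if n_train == 0 or n_train == n:
            raise ValueError(
                f"class {cid}: split {n_train}/{n - n_train} leaves one side empty"
            )
        perm = rng.permutation(n)
        train_parts.append(group.iloc[perm[:n_train]])
        val_parts.append(group.iloc[perm[n_train:]])
    train = pd.concat(train_parts).sort_index()
    val = pd.concat(val_parts).sort_index()
    return train, val


def phase_to_uint8(phase: np.ndarray) -> np.ndarray:
    """Map wrapped phase [-pi, pi) linearly to 8-bit gray levels 0..255."""
    return np.round((np.asarray(phase) + np.pi) / TWO_PI * 255.0).astype(np.uint8)


def uint8_to_phase(gray: np.ndarray) -> np.ndarray:
    """Inverse of :func:`phase_to_uint8` (up to quantization)."""
    return np.asarray(gray, dtype=float) / 255.0 * TWO_PI - np.pi
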