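"""File I/O: holograms and WQPIs as float32 TIFF with YAML optics sidecars."""

from __future__ import annotations

import os

import numpy as np
import tifffile
import yaml

from .config import OpticalConfig
from .phase import WQPI
from .simulate import Hologram

__all__ = [
    "save_hologram",
    "load_hologram",
    "save_wqpi",
    "load_wqpi",
    "save_focus_scan",
]


def _sidecar(path: str) -> str:
    return os.path.splitext(os.fspath(path))[0] + ".yaml"


def save_hologram(hologram: Hologram, path: str, extra: dict | None = None) -> None:
    """Write intensity as float32 TIFF plus a YAML sidecar with the optics."""
    tifffile.imwrite(path, hologram.intensity.astype(np.float32))
    meta = {
        "optics": hologram.config.to_dict(),
        "true_defocus": float(hologram.true_defocus),
    }
    if extra:
        meta.update(extra)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_hologram(path: str) -> Hologram:
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    return Hologram(
        intensity=np.asarray(tifffile.imread(path), dtype=float),
        config=OpticalConfig.from_dict(meta["optics"]),
        true_defocus=float(meta.get("true_defocus", 0.0)),
    )


def save_wqpi(wqpi: WQPI, path: str) -> None:
    tifffile.imwrite(path, wqpi.phase.astype(np.float32))
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(
            {
                "class_id": None if wqpi.class_id is None else int(wqpi.class_id),
                "pixel_pitch": float(wqpi.pixel_pitch),
            },
            fh,
        )


def load_wqpi(path: str) -> WQPI:
    phase = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = _sidecar(path)
    class_id, pitch = None, 5.5e-6
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        class_id = meta.get("class_id")
        pitch = float(meta.get("pixel_pitch", pitch))
    return WQPI(phase, class_id=class_id, pixel_pitch=pitch)


def save_focus_scan(result, path: str) -> None:
    """Write a focus scan as CSV with z and Tamura-coefficient columns."""
    import pandas as pd

    coarse = pd.DataFrame(
        {"z": result.z_grid, "tamura": result.tamura_values, "stage": "coarse"}
    )
    refine = pd.DataFrame(
        result.refinement_history, columns=["z", "tamura"]
    ).assign(stage="refine")
    pd.concat([coarse, refine], ignore_index=True).to_csv(path, index=False)
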