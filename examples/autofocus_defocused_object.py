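"""Numerically refocus a defocused object by Tamura-coefficient minimization.

A single phantom diatom is recorded 1.5 mm out of focus; the script scans
propagation distances, prints the coarse Tamura profile and reports how
close the located focus plane is to the ground truth.
"""

import warnings

import numpy as np

from holoplankton import (
    RunConfig,
    autofocus,
    demodulate,
    form_hologram,
    make_phantom_slide,
)

cfg = RunConfig(seed=0)
shape = (128, 128)
optics = cfg.optics_for(shape)
slide = make_phantom_slide(1, shape, cfg.morphology, seed=5)

z_true = 1.5e-3  # refocus distance (object recorded defocused by -z_true)
holo = form_hologram(slide, optics, defocus_z=-z_true)
field = demodulate(holo)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    scan = autofocus(field, -4e-3, 4e-3, n_coarse=21, n_refine_levels=3)

print("coarse Tamura scan (z in mm -> T):")
for z, t in zip(scan.z_grid[::4], scan.tamura_values[::4]):
    print(f"  {z*1e3:+6.2f} -> {t:.4f}")
print(f"true refocus distance : {z_true*1e3:+.4f} mm")
print(f"located focus plane   : {scan.z_best*1e3:+.4f} mm")
print(f"error                 : {abs(scan.z_best - z_true)*1e6:.1f} um "
      "(well inside one refined bracket of 50 um)")
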