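"""Simulate a grid-modulated exposure of a labelled mouse phantom and
demodulate it into absorption + directional scatter images.

The printed means show that absorption tracks the phantom's optical depth
while the scatter channels light up only where gold is present.
"""

import numpy as np

from sfhi import (
    AcquisitionSettings, GridSpec, demo_mouse, interior,
    reconstruct, simulate_acquisition, simulate_reference,
)

grid = GridSpec()  # pitch 8 px, 86% mean transmission
acq = AcquisitionSettings(fluence=1e4, rng_seed=7, noise_enabled=True)
phantom = demo_mouse()

reference = simulate_reference(grid, phantom.shape,
                               settings=AcquisitionSettings(1e4, 8, True))
sample = simulate_acquisition(phantom, grid, settings=acq)
rec = reconstruct(sample, reference)

m = rec.margin_px
print(f"reconstructed {rec.shape} images, excluding a {m}-px wrap-around margin")
for name, img in (("absorption", rec.absorption),
                  ("scatter_h", rec.scatter_h),
                  ("scatter_v", rec.scatter_v)):
    roi = img[162:178, 152:168]          # tumor_1 (26 ug/cm^3 gold)
    bg = img[140:156, 60:76]             # body background (no gold)
    print(f"{name:10s} tumor mean {roi.mean():7.4f}   background mean {bg.mean():7.4f}")
print("-> gold shows up strongly in the scatter channels but adds almost no")
print("   absorption contrast; the body outline dominates the absorption image.")
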