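"""Why scatter imaging sees nanoparticle-labelled tumors that absorption
imaging misses.

A tumor loaded with gold nanoparticles scatters strongly but adds almost no
extra attenuation.  The ROI signal enhancement over a control region is
therefore orders of magnitude larger in the scatter channel.
"""

from sfhi import (
    AcquisitionSettings, EllipseRegion, GridSpec, ROI,
    make_mouse_phantom, reconstruct, signal_enhancement,
    simulate_acquisition, simulate_reference,
)

grid = GridSpec()
regions = [
    EllipseRegion("body", center=(128, 128), axes=(110, 85),
                  optical_depth=0.4, gold_ugcm3=2.0),
    EllipseRegion("tumor", center=(170, 160), axes=(14, 14),
                  optical_depth=0.0, gold_ugcm3=26.0),   # pure-scatter lesion
]
phantom = make_mouse_phantom((256, 256), regions, edge_sigma_px=3.0)

ref = simulate_reference(grid, (256, 256),
                         settings=AcquisitionSettings(1e4, 99, True))
rec = reconstruct(
    simulate_acquisition(phantom, grid, settings=AcquisitionSettings(1e4, 5, True)),
    ref)

target = ROI("tumor", center=(170, 160), axes=(8, 8), role="target")
control = ROI("background", center=(128, 70), axes=(12, 12), role="control")
for name, img in (("absorption", rec.absorption), ("scatter_h", rec.scatter_h)):
    e = signal_enhancement(img, target, control)
    print(f"{name:10s}: tumor {e.target_mean:8.4f}  control {e.control_mean:8.4f}"
          f"  enhancement {e.enhancement_pct:8.1f}%")
print("-> the same tumor is invisible in absorption (~0%) but produces a huge")
print("   relative enhancement in the scatter image.")
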