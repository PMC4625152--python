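"""Verify the scatter metric against its Gaussian closed form and recover the
blur width from a noisy acquisition.

For a uniform Gaussian blur of RMS sigma at carrier frequency f0 = 1/pitch the
scatter metric is S = 2 pi^2 sigma^2 f0^2; inverting S gives sigma back.
"""

import numpy as np

from sfhi import (
    AcquisitionSettings, GridSpec, Phantom, interior,
    reconstruct, scatter_to_sigma, simulate_acquisition, simulate_reference,
)

grid = GridSpec()
noise_free = AcquisitionSettings(fluence=1e4, rng_seed=0, noise_enabled=False)
shape = (256, 256)
ref = simulate_reference(grid, shape, settings=noise_free)

print("sigma_true   S_measured   S_closed_form   sigma_recovered")
for sigma in (0.5, 1.0, 1.5):
    ph = Phantom(np.zeros(shape), np.full(shape, sigma**2 / 0.05),
                 scatter_coupling=0.05)
    rec = reconstruct(simulate_acquisition(ph, grid, settings=noise_free), ref)
    S = interior(rec.scatter_h, rec.margin_px).mean()
    S_cf = 2 * np.pi**2 * sigma**2 / grid.pitch_px**2
    print(f"  {sigma:4.1f}      {S:8.5f}      {S_cf:8.5f}       "
          f"{scatter_to_sigma(S, 1 / grid.pitch_px):6.4f}")

# now with Poisson counting noise at fluence 1e5
ph = Phantom(np.full(shape, 0.3), np.full(shape, 1.0**2 / 0.05))
rec = reconstruct(
    simulate_acquisition(ph, grid, settings=AcquisitionSettings(1e5, 3, True)),
    simulate_reference(grid, shape, settings=AcquisitionSettings(1e5, 4, True)))
S = interior(rec.scatter_h, rec.margin_px).mean()
print(f"noisy acquisition (fluence 1e5): sigma_true 1.0, "
      f"recovered {scatter_to_sigma(S, 1 / grid.pitch_px):.4f}")
print("-> the metric follows the closed form and round-trips sigma within a "
      "fraction of a percent.")
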