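# sfhi — spatial-frequency heterodyne x-ray scatter imaging

`sfhi` is a simulation and analysis toolkit for single-grid x-ray dark-field
(scatter) imaging of nanoparticle-labelled tissue.  It targets researchers
evaluating gold-nanoparticle contrast agents for early tumor detection: small
lesions (a few mm) labelled with tens of µg/cm³ of gold are essentially
invisible in conventional absorption radiographs but scatter x-rays strongly,
and a crossed absorption mesh placed between source and object makes that
scatter measurable from a single exposure.

## The method

A mesh of pitch *p* (in detector pixels) imprints carrier peaks at spatial
frequencies (m, n)/p on the recorded image.  Small-angle scattering in the
object blurs the grid shadow, damping the first-order carriers, while
attenuation scales all orders equally.  Writing *M₀₀*, *M₁₀*, *M₀₁* for the
magnitudes of the complex envelopes demodulated from the zero-order and
first-order bands of a sample exposure *I* and a grid-only reference *R*:

```
absorption = −ln[ M₀₀(I) / M₀₀(R) ]                       (Beer–Lambert optical depth)
scatter    = −ln[ (M₁(I)/M₀₀(I)) / (M₁(R)/M₀₀(R)) ]       (per carrier direction)
```

For a Gaussian angular blur of RMS width σ pixels at carrier frequency
f₀ = 1/p, the scatter metric has the closed form **S = 2π²σ²f₀²**, so S is
linear in the blur variance — and, under the simulator's coupling
σ² = k·c, linear in the local gold concentration *c*.  One exposure yields
three images: absorption, horizontal scatter, and vertical scatter.

The package contains:

- `sfhi.grid` / `sfhi.phantom` / `sfhi.acquire` — forward simulation:
  crossed-mesh transmission fields, elliptical tissue phantoms with gold
  maps, Beer–Lambert attenuation, concentration-dependent Gaussian blur of
  the grid shadow, Poisson counting noise;
- `sfhi.demodulate` — harmonic band extraction, carrier-frequency
  estimation, the reconstruction above, and `scatter_to_sigma`;
- `sfhi.quantify` — ROI signal enhancement (percent over a control region),
  integrated optical density of stain channels, enhancement factors, ratio
  tables and biodistribution summaries;
- `sfhi.overlay` — color scatter composited over grayscale absorption;
- `sfhi.cli` / `sfhi.pipeline` — a thin `sfhi` command
  (`simulate | reconstruct | quantify | ratios | overlay | pipeline`) with
  YAML configs, TIFF/PNG I/O and hash manifests for reproducibility.

## Worked example

```python
from sfhi import (GridSpec, AcquisitionSettings, demo_mouse,
                  simulate_acquisition, simulate_reference, reconstruct)

grid = GridSpec()                       # pitch 8 px, 86% mean transmission
phantom = demo_mouse()                  # body + liver + two labelled tumors
ref = simulate_reference(grid, phantom.shape,
                         settings=AcquisitionSettings(1e4, 8, True))
sample = simulate_acquisition(phantom, grid,
                              settings=AcquisitionSettings(1e4, 7, True))
rec = reconstruct(sample, ref)
```

Running `python examples/01_simulate_and_reconstruct.py` prints

```
absorption tumor mean  0.4490   background mean  0.3990
scatter_h  tumor mean  0.3799   background mean  0.0016
```

the tumor (26 µg/cm³ gold) adds ~0.05 of optical depth to the absorption
image — barely above the 0.4 body background — but raises the scatter metric
from ~0 to ~0.4, i.e. the scatter channel carries the contrast.  With ROI
statistics (`examples/03_tumor_enhancement.py`) a pure-scatter tumor shows a
0.0 % absorption enhancement against ~2500 % scatter enhancement.
`examples/02_blur_closed_form.py` verifies the closed form (measured
S = 0.30843 vs 2π²·1²/8² = 0.30843 at σ = 1 px) and recovers σ to 0.2 % from
a noisy acquisition; `examples/04_printed_tables.py` reproduces the published
uptake arithmetic (stain-density factors 11 and 12, tumor ratio 1.33,
liver/spleen factor 4).

The same chain runs from the shell:

```sh
sfhi pipeline --config examples/demo.yaml --out-dir scratch/demo
```

writing reference/sample exposures, the three reconstructions, ROI
quantification JSON, an overlay PNG and a SHA-256 manifest; identical
config + seed reproduces identical hashes.

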