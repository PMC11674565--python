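# mrtbio

Bio-dosimetry of microbeam radiation therapy (MRT) fields from γH2AX
fluorescence microscopy.

MRT delivers synchrotron X-rays as an array of planar beams tens of
micrometres wide ("peaks") separated by hundreds of micrometres of
low-dose gaps ("valleys"). The field is characterised physically by the
peak-to-valley dose ratio, **PVDR = D_peak / D_valley**. Because each
DNA double-strand break (DSB) recruits phosphorylated H2AX into a
visible focus, a two-channel confocal image (nuclear counterstain +
γH2AX) is a spatial dose record: the beam geometry, its effective
width, and the peak/valley damage contrast can all be read back from
cells. `mrtbio` implements that read-back for radiobiologists and
medical physicists working with spatially fractionated beams:

- **Dose-field model** — closed-form lateral dose of a striped field,
  with an optional Gaussian penumbra: dose at any position, peak
  coverage fractions, analytic FWHM (`mrtbio.geometry`).
- **Synthetic microscopy** — a seeded generator of two-channel 16-bit
  images whose per-nucleus focus counts are Poisson with mean
  `background + yield × dose(x_nucleus) × enhancement`, with exact
  ground truth, standing in for experimental data (`mrtbio.simulate`).
- **Foci quantification** — nucleus segmentation, multiscale
  Laplacian-of-Gaussian focus detection, the foci factor
  **FF** (equivalent foci per nucleus, robust to merged foci) and the
  DSB enhancement ratio **DSBER = FF_treatment / FF_control**
  (`mrtbio.quantify`).
- **Beam profiles** — column-averaged lateral intensity traces, peak
  and pitch detection, the 16-segment averaged profile in percent of
  peak intensity, FWHM and percent broadening (`mrtbio.profiles`).
- **Biological PVDR** — peak/valley ROI partition (adaptive
  measured-FWHM or fixed 50 µm widths) and
  **BPVDR = FF_peak / FF_valley**, averaged over replicate images with
  the 2 sd/√n error convention (`mrtbio.pvdr`, `mrtbio.pipeline`).
- **Clonogenic survival** — plating efficiency and surviving fractions
  with the 50–300 colony plate filters (`mrtbio.clonogenic`).

## A worked example

Measure the biological PVDR of a simulated 0.5 Gy (valley-dose) MRT
field — 50 µm beams, 400 µm pitch, physical PVDR 8.9 — from six
replicate synthetic images:

```python
from mrtbio import ImagingConfig, analyze_mrt_images, generate
from mrtbio.fields import mrt_geometry

geometry = mrt_geometry(valley_dose=0.5)
config = ImagingConfig(background_foci_rate=0.0)
pairs = []
for seed in range(1, 7):
    bundle = generate(geometry, config.with_seed(seed))
    pairs.append((bundle.nuclear_channel, bundle.foci_channel))

analysis = analyze_mrt_images(pairs, config.pixel_size,
                              mode="adaptive", physical_pvdr=geometry.pvdr)
print(f"BPVDR = {analysis.result.bpvdr:.2f} ± {analysis.result.sem:.2f}")
print(f"FWHM  = {analysis.profile.fwhm_um:.1f} µm, "
      f"pitch = {analysis.profile.pitch_um:.1f} µm")
```

prints

```
BPVDR = 9.03 ± 0.39
FWHM  = 50.3 µm, pitch = 401.2 µm
```

The biologically measured ratio matches the physical 8.9 within its
error, the recovered beam width matches the 50 µm collimation, and the
recovered spacing matches the 400 µm pitch — the same three
verifications the assay provides on real images. Setting
`enhancement_valley=2.0` in the config (a radiosensitiser that doubles
valley damage) drops the BPVDR to ≈ 4.45, half the physical ratio.

The `examples/` directory holds one short runnable script per
capability; `mrtbio` is also a CLI (`mrtbio simulate | quantify |
profile | pvdr | clonogenic | end2end`) for shell-driven runs.

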