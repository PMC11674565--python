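"""Measure the biological PVDR (BPVDR) from replicate synthetic images.

Runs the full pipeline — segmentation, focus detection, profile-driven
adaptive ROIs, per-image peak/valley foci factors — and averages the
per-image FF_peak/FF_valley ratios.  With no radiosensitiser
enhancement the BPVDR matches the physical PVDR of 8.9; a 2x valley
enhancement halves it.
"""

from mrtbio import ImagingConfig, analyze_mrt_images, generate
from mrtbio.fields import mrt_geometry

geometry = mrt_geometry(valley_dose=0.5)

for enhancement, label in ((1.0, "radiation only"), (2.0, "valley-enhanced 2x")):
    config = ImagingConfig(enhancement_valley=enhancement,
                           background_foci_rate=0.0)
    pairs = []
    for seed in range(1, 7):
        bundle = generate(geometry, config.with_seed(seed))
        pairs.append((bundle.nuclear_channel, bundle.foci_channel))
    analysis = analyze_mrt_images(
        pairs, config.pixel_size, mode="adaptive", physical_pvdr=geometry.pvdr
    )
    res = analysis.result
    print(f"{label:20s}: BPVDR = {res.bpvdr:.2f} ± {res.sem:.2f} "
          f"(physical PVDR {res.physical_pvdr})")
# Radiosensitisers that amplify valley damage pull the BPVDR below the
# physical ratio — the dosimetric signature of local valley dose
# enhancement.
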