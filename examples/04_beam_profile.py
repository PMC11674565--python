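"""Extract the lateral beam profile of a broadened MRT field.

Pools 16 peak segments from replicate images, normalises to percent of
the peak-plateau intensity, and reads off FWHM, pitch and percent
broadening — the bio-dosimetric verification of the collimation.
"""

from mrtbio import (
    ImagingConfig,
    detect_peaks,
    lateral_profile,
    segment_average,
)
from mrtbio.fields import mrt_geometry

geometry = mrt_geometry(valley_dose=5.0, broadening_sigma=23.78)
config = ImagingConfig()

traces, peak_sets = [], []
for seed in range(1, 7):
    from mrtbio import generate

    bundle = generate(geometry, config.with_seed(seed))
    trace = lateral_profile(bundle.foci_channel, config.pixel_size)
    traces.append(trace)
    peak_sets.append(detect_peaks(trace))

profile = segment_average(traces, peak_sets, nominal_width=geometry.peak_width)
print(f"segments averaged : {profile.n_segments}")
print(f"pitch estimate    : {profile.pitch_um:.1f} µm (collimator: 400 µm)")
print(f"FWHM              : {profile.fwhm_um:.1f} µm "
      f"(collimated width 50 µm)")
print(f"broadening        : {profile.broadening_pct:.0f} %")
# A ~24 µm penumbra broadens the biologically measured peak to ~67 µm
# (~34%), the signature of nanoparticle-enhanced dose spill into the
# near-beam transition zones.
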