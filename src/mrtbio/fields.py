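"""Reference beam configurations.

Constants describing the synchrotron beamline setup this package
models: a tungsten-carbide multi-slit collimator producing 25 planar
microbeams of 50 µm width at 400 µm pitch, with a measured
peak-to-valley dose ratio of 8.9, alongside the broadbeam (SBB)
configuration delivered at the same mean energy.  Dose rates are the
delivered instantaneous rates for each field region.
"""

from __future__ import annotations

from .geometry import BeamGeometry

__all__ = [
    "NOMINAL_PEAK_WIDTH_UM",
    "NOMINAL_PITCH_UM",
    "N_BEAMS",
    "MEASURED_PVDR",
    "SBB_DOSE_RATE_GY_S",
    "MRT_PEAK_DOSE_RATE_GY_S",
    "MRT_VALLEY_DOSE_RATE_GY_S",
    "mrt_geometry",
]

#: Collimated microbeam width, µm.
NOMINAL_PEAK_WIDTH_UM = 50.0
#: Centre-to-centre microbeam spacing, µm.
NOMINAL_PITCH_UM = 400.0
#: Number of microbeams in the array.
N_BEAMS = 25
#: Measured peak-to-valley dose ratio of the MRT field.
MEASURED_PVDR = 8.9

#: Synchrotron broadbeam dose rate, Gy/s.
SBB_DOSE_RATE_GY_S = 74.1
#: MRT peak dose rate, Gy/s.
MRT_PEAK_DOSE_RATE_GY_S = 50.3
#: MRT valley dose rate, Gy/s.
MRT_VALLEY_DOSE_RATE_GY_S = 5.7


def mrt_geometry(
    valley_dose: float, *, broadening_sigma: float = 0.0, pvdr: float = MEASURED_PVDR
) -> BeamGeometry:
    """The reference MRT lattice at a prescribed valley dose (Gy)."""
    return BeamGeometry(
        peak_width=NOMINAL_PEAK_WIDTH_UM,
        pitch=NOMINAL_PITCH_UM,
        pvdr=pvdr,
        valley_dose=valley_dose,
        broadening_sigma=broadening_sigma,
        n_beams=N_BEAMS,
    )
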