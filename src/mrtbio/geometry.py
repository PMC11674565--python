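"""Closed-form model of a spatially fractionated (microbeam) dose field.

A microbeam radiation therapy (MRT) field is an array of narrow planar
X-ray beams ("peaks", tens of µm wide) separated by wide low-dose gaps
("valleys", hundreds of µm).  The field is characterised by the
peak-to-valley dose ratio

    PVDR = D_peak / D_valley

and by the collimator lattice: peak width, centre-to-centre pitch, and
number of beams.  This module gives the lateral dose profile of such a
field in closed form, including an optional Gaussian penumbra that
models the roll-off of dose from peaks into the near-beam transition
zones (scatter and secondary electrons blur the ideal rectangular
collimation).

The lattice is treated as periodic along the lateral axis: ``dose_at``
is exactly pitch-periodic, with peak centres at ``phase + k*pitch``.
``n_beams`` bounds the physical extent of the field when images are
rendered (see :mod:`mrtbio.simulate`); it does not truncate the closed
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = [
    "BeamGeometry",
    "DoseProfile",
    "PeaksMergedError",
    "dose_at",
    "peak_fraction",
    "analytic_fwhm",
    "mean_field_dose",
    "sample_profile",
]


class PeaksMergedError(RuntimeError):
    """Broadening is too large for a full width at half-maximum to exist."""


@dataclass(frozen=True)
class BeamGeometry:
    """Physical description of a striped MRT dose field.

    Parameters
    ----------
    peak_width:
        Collimated width of one microbeam, µm.  Must satisfy
        ``0 < peak_width < pitch``.
    pitch:
        Centre-to-centre beam spacing, µm.
    pvdr:
        Peak-to-valley dose ratio, dimensionless, ≥ 1.  The peak dose is
        ``valley_dose * pvdr``.
    valley_dose:
        Prescribed valley dose in Gy (MRT prescriptions quote the valley
        dose; the peaks receive ``pvdr`` times more).
    broadening_sigma:
        Gaussian penumbra scale in µm; 0 means ideal collimation.
    n_beams:
        Number of microbeams in the physical array.
    phase:
        Lateral offset of the first peak centre from the field origin,
        µm.  Defaults to ``pitch / 2`` so a field starting at x = 0
        opens with half a valley.
    """

    peak_width: float
    pitch: float
    pvdr: float
    valley_dose: float
    broadening_sigma: float = 0.0
    n_beams: int = 25
    phase: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.phase is None:
            object.__setattr__(self, "phase", self.pitch / 2.0)
        if not 0 < self.peak_width < self.pitch:
            raise ValueError(
                f"need 0 < peak_width < pitch, got {self.peak_width} / {self.pitch}"
            )
        if self.pvdr < 1:
            raise ValueError(f"pvdr must be >= 1, got {self.pvdr}")
        if self.valley_dose < 0:
            raise ValueError(f"valley_dose must be >= 0, got {self.valley_dose}")
        if self.broadening_sigma < 0:
            raise ValueError(
                f"broadening_sigma must be >= 0, got {self.broadening_sigma}"
            )
        if self.n_beams < 1:
            raise ValueError(f"n_beams must be >= 1, got {self.n_beams}")

    @property
    def peak_dose(self) -> float:
        """Dose inside an unbroadened peak stripe, Gy."""
        return self.valley_dose * self.pvdr

    @property
    def field_span(self) -> float:
        """Lateral extent of the physical beam array, µm (n_beams pitches)."""
        return self.n_beams * self.pitch

    def peak_centres(self, span: float | None = None) -> np.ndarray:
        """Peak-centre positions within ``[0, span)`` µm (default: field_span)."""
        span = self.field_span if span is None else float(span)
        k = np.arange(int(np.ceil((span - self.phase) / self.pitch)) + 1)
        centres = self.phase + k * self.pitch
        return centres[(centres >= 0) & (centres < span)]

    def with_broadening(self, sigma: float) -> "BeamGeometry":
        return replace(self, broadening_sigma=sigma)


@dataclass(frozen=True)
class DoseProfile:
    """A sampled lateral dose profile: strictly increasing positions (µm)
    with a non-negative dose (Gy) at each."""

    positions: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        if pos.shape != dose.shape or pos.ndim != 1:
            raise ValueError("positions and dose must be 1-D arrays of equal length")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(dose < 0):
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dose", dose)


def _fold(geometry: BeamGeometry, x: np.ndarray) -> np.ndarray:
    """Fold lateral positions into [-pitch/2, pitch/2) about the nearest peak."""
    return np.mod(x - geometry.phase + geometry.pitch / 2.0, geometry.pitch) - (
        geometry.pitch / 2.0
    )


def dose_at(geometry: BeamGeometry, x):
    """Absorbed dose (Gy) at lateral position(s) ``x`` µm.

    With ``broadening_sigma == 0`` the profile is the ideal rectangular
    lattice: ``peak_dose`` inside a stripe, ``valley_dose`` outside.
    With ``broadening_sigma > 0`` the ideal lattice is convolved with a
    unit-area Gaussian, evaluated in closed form through the Gaussian
    CDF on each stripe:

        D(x) = D_v + (D_p - D_v) * sum_k [Phi((u-l_k)/s) - Phi((u-r_k)/s)]

    where ``u`` is ``x`` folded about the nearest peak centre and
    ``l_k, r_k`` are stripe edges of the replicas.  Folding makes the
    result exactly pitch-periodic.
    """
    x = np.asarray(x, dtype=float)
    g = geometry
    u = _fold(g, x)
    half = g.peak_width / 2.0
    if g.broadening_sigma == 0:
        out = np.where(np.abs(u) <= half, g.peak_dose, g.valley_dose)
    else:
        s = g.broadening_sigma
        # replicas whose 8-sigma tails reach the folded window
        k_max = int(np.ceil((8.0 * s + half) / g.pitch)) + 1
        acc = np.zeros_like(u)
        for k in range(-k_max, k_max + 1):
            c = k * g.pitch
            acc += ndtr((u - (c - half)) / s) - ndtr((u - (c + half)) / s)
        out = g.valley_dose + (g.peak_dose - g.valley_dose) * acc
    return float(out) if out.ndim == 0 else out


def peak_fraction(geometry: BeamGeometry, effective_width: float) -> float:
    """Fraction of the field (and hence of a uniformly seeded cell
    population) covered by peaks of the given effective width.

    ``effective_width`` may be the nominal collimated width or a
    biologically measured FWHM; the fraction is simply
    ``effective_width / pitch``.
    """
    if not 0 <= effective_width <= geometry.pitch:
        raise ValueError(
            f"effective_width must lie in [0, pitch], got {effective_width}"
        )
    return effective_width / geometry.pitch


def mean_field_dose(geometry: BeamGeometry) -> float:
    """Mean dose over one lattice period, Gy.

    Equals ``valley_dose * (1 + (pvdr - 1) * peak_width / pitch)`` and is
    invariant under Gaussian broadening (convolution with a unit-area
    kernel preserves the mean of a periodic profile).
    """
    g = geometry
    return g.valley_dose * (1.0 + (g.pvdr - 1.0) * g.peak_width / g.pitch)


def analytic_fwhm(geometry: BeamGeometry, *, baseline: str = "valley") -> float:
    """Full width at half-maximum of one broadened peak, µm.

    The half-maximum level is referenced to the valley floor by default
    (``baseline="valley"``): half = valley level + (peak level - valley
    level)/2, where the peak level is the dose at a peak centre and the
    valley level the dose at mid-valley.  ``baseline="zero"`` references
    absolute zero instead.  With ``broadening_sigma == 0`` this returns
    ``peak_width`` exactly.

    Raises
    ------
    PeaksMergedError
        If broadening has washed out the lattice (peak/valley contrast
        below 2%), or, for the zero baseline, if the valley floor sits
        above half-maximum — in either case the FWHM of a single peak is
        not measurable.
    """
    if baseline not in ("valley", "zero"):
        raise ValueError(f"baseline must be 'valley' or 'zero', got {baseline!r}")
    g = geometry
    peak_level = dose_at(g, g.phase)
    valley_level = dose_at(g, g.phase + g.pitch / 2.0)
    if peak_level <= 0 or (peak_level - valley_level) < 0.02 * peak_level:
        raise PeaksMergedError(
            "peak/valley contrast below 2%: adjacent peaks have merged"
        )
    if baseline == "valley":
        half = valley_level + 0.5 * (peak_level - valley_level)
    else:
        half = 0.5 * peak_level
        if valley_level >= half:
            raise PeaksMergedError("valley floor above half-maximum (zero baseline)")
    if g.broadening_sigma == 0:
        return g.peak_width

    def f(d: float) -> float:
        return dose_at(g, g.phase + d) - half

    # f(0) > 0 and f(pitch/2) < 0 by the contrast checks above
    crossing = brentq(f, 0.0, g.pitch / 2.0, xtol=1e-10)
    return 2.0 * crossing


def sample_profile(
    geometry: BeamGeometry, positions=None, *, step: float = 0.5
) -> DoseProfile:
    """Evaluate the closed-form dose on a grid.

    If ``positions`` is omitted, one full lattice period centred on a
    peak is sampled with the given step (µm).
    """
    if positions is None:
        g = geometry
        positions = np.arange(
            g.phase - g.pitch / 2.0, g.phase + g.pitch / 2.0 + step / 2.0, step
        )
    positions = np.asarray(positions, dtype=float)
    return DoseProfile(positions=positions, dose=dose_at(geometry, positions))
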