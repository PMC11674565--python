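"""Peak/valley ROI partitioning and the biological PVDR (BPVDR).

The biological peak-to-valley ratio expresses the physical PVDR in
terms of DNA damage: BPVDR = FF_peak / FF_valley, with the foci factors
measured in peak and valley regions of interest of the same image.
Peak ROIs are either *adaptive* (width = the measured FWHM, so peak
broadening is accounted for) or *fixed* at the nominal 50 µm centred on
each detected peak.  Ratios are computed per image and averaged over
replicates (at least 6 in the reference protocol), with uncertainty
reported as the 95%-confidence standard error of the mean,
2 sd / √n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quantify import FociFactor

__all__ = [
    "RoiPartition",
    "PvdrResult",
    "partition",
    "bpvdr",
    "sem_95",
    "ratio_sem",
]


@dataclass(frozen=True)
class RoiPartition:
    """Disjoint peak / valley / excluded lateral intervals covering a span.

    All intervals are half-open ``[start, end)`` in µm.  In fixed mode
    every peak interval is exactly ``fixed_width`` wide and centred on
    a detected peak.
    """

    mode: str
    peak_intervals: tuple
    valley_intervals: tuple
    excluded_intervals: tuple = ()
    span: tuple = (0.0, 0.0)

    def total_length(self) -> float:
        return sum(
            e - s
            for s, e in (
                *self.peak_intervals,
                *self.valley_intervals,
                *self.excluded_intervals,
            )
        )


@dataclass(frozen=True)
class PvdrResult:
    """Biological PVDR averaged over replicate images."""

    bpvdr: float
    sem: float | None
    n_images: int
    mode: str
    physical_pvdr: float | None = None
    per_image: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.bpvdr <= 0:
            raise ValueError("bpvdr must be > 0")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


def sem_95(values) -> float:
    """Standard error of the mean at the 95% confidence convention:
    two sample standard deviations divided by √n.  Undefined (raises)
    for fewer than two values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("sem_95 undefined for fewer than two values")
    return float(2.0 * arr.std(ddof=1) / np.sqrt(arr.size))


def ratio_sem(numerator, num_sem, denominator, den_sem) -> float:
    """First-order SEM of a ratio from the SEMs of its parts."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("ratio_sem requires positive numerator and denominator")
    rel = np.hypot(num_sem / numerator, den_sem / denominator)
    return float(numerator / denominator * rel)


def partition(
    peak_centres,
    fwhm: float,
    mode: str = "adaptive",
    *,
    pitch: float,
    fixed_width: float = 50.0,
    buffer: float = 0.0,
    span=None,
) -> RoiPartition:
    """Partition a lateral span into peak and valley ROIs.

    Adaptive mode uses the measured FWHM as the peak width (accounting
    for broadening); fixed mode uses ``fixed_width``.  Valleys are the
    complement, minus an optional symmetric exclusion ``buffer`` (µm)
    on each side of every peak.  With ``buffer == 0`` the peak and
    valley intervals tile the span exactly.
    """
    centres = np.sort(np.asarray(peak_centres, dtype=float))
    if centres.size < 1:
        raise ValueError("at least one peak centre is required")
    if mode not in ("adaptive", "fixed"):
        raise ValueError(f"mode must be 'adaptive' or 'fixed', got {mode!r}")
    width = float(fwhm) if mode == "adaptive" else float(fixed_width)
    if width <= 0:
        raise ValueError("peak width must be > 0")
    if width + 2.0 * buffer >= pitch:
        raise ValueError(
            f"peak width {width:.1f} µm (+2x{buffer:.1f} buffer) >= pitch "
            f"{pitch:.1f} µm: peaks merged, partition rejected"
        )
    if span is None:
        span = (float(centres[0] - pitch / 2.0), float(centres[-1] + pitch / 2.0))
    lo, hi = float(span[0]), float(span[1])

    peaks, excluded, valleys = [], [], []
    cursor = lo
    for c in centres:
        p0, p1 = c - width / 2.0, c + width / 2.0
        b0, b1 = p0 - buffer, p1 + buffer
        b0c, p0c = max(b0, lo), max(p0, lo)
        p1c, b1c = min(p1, hi), min(b1, hi)
        if cursor < b0c:
            valleys.append((cursor, b0c))
        if buffer > 0 and b0c < p0c:
            excluded.append((b0c, p0c))
        if p0c < p1c:
            peaks.append((p0c, p1c))
        if buffer > 0 and p1c < b1c:
            excluded.append((p1c, b1c))
        cursor = max(cursor, b1c)
    if cursor < hi:
        valleys.append((cursor, hi))

    return RoiPartition(
        mode=mode,
        peak_intervals=tuple(peaks),
        valley_intervals=tuple(valleys),
        excluded_intervals=tuple(excluded),
        span=(lo, hi),
    )


def bpvdr(
    ff_peaks,
    ff_valleys,
    *,
    mode: str = "adaptive",
    physical_pvdr: float | None = None,
) -> PvdrResult:
    """Biological PVDR from paired per-image peak and valley foci factors.

    Accepts a single :class:`FociFactor` pair or equal-length sequences
    (one pair per replicate image).  The per-image ratios
    ``FF_peak / FF_valley`` are averaged — the average of individual
    ratios, not the ratio of averages — and the SEM is 2 sd / √n over
    those per-image ratios (needs ≥ 2 images; otherwise None).
    """
    if isinstance(ff_peaks, FociFactor):
        ff_peaks = [ff_peaks]
    if isinstance(ff_valleys, FociFactor):
        ff_valleys = [ff_valleys]
    ff_peaks = list(ff_peaks)
    ff_valleys = list(ff_valleys)
    if len(ff_peaks) != len(ff_valleys) or not ff_peaks:
        raise ValueError("need equal, non-empty lists of peak and valley foci factors")
    ratios = []
    for fp, fv in zip(ff_peaks, ff_valleys):
        if fv.ff <= 0:
            raise ValueError("bpvdr undefined: zero valley foci factor")
        ratios.append(fp.ff / fv.ff)
    mean = float(np.mean(ratios))
    sem = sem_95(ratios) if len(ratios) >= 2 else None
    return PvdrResult(
        bpvdr=mean,
        sem=sem,
        n_images=len(ratios),
        mode=mode,
        physical_pvdr=physical_pvdr,
        per_image=tuple(ratios),
    )
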