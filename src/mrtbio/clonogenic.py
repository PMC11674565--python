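"""Clonogenic survival: plating efficiency and surviving fraction.

Plating efficiency (PE) is the ratio of colonies counted (colonies of
at least 50 cells only — an upstream counting convention) to cells
seeded.  Plates with fewer than 50 or more than 300 colonies are
discounted; the boundaries are literal, so 50 and 300 are kept while
49 and 301 are not.  The surviving fraction (SF) of a sample is the
mean PE of its plates divided by the mean PE of the appropriate
unirradiated reference: the cell-only control for 0 Gy points, the
same-treatment 0 Gy sample for irradiated points.  Uncertainty is the
95%-confidence SEM (2 sd / √n) over per-plate SFs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pvdr import sem_95

__all__ = [
    "PlateRecord",
    "SurvivalPoint",
    "filter_plates",
    "plating_efficiency",
    "surviving_fraction",
    "read_plates_csv",
    "survival_table",
]

MIN_COLONIES = 50
MAX_COLONIES = 300


@dataclass(frozen=True)
class PlateRecord:
    plate_id: str
    condition: str
    dose_gy: float
    cells_seeded: int
    colonies_counted: int
    valid: bool = True

    def __post_init__(self) -> None:
        if self.cells_seeded <= 0:
            raise ValueError("cells_seeded must be > 0")
        if self.colonies_counted < 0:
            raise ValueError("colonies_counted must be >= 0")

    @property
    def pe(self) -> float:
        """Plating efficiency of this plate."""
        return self.colonies_counted / self.cells_seeded


@dataclass(frozen=True)
class SurvivalPoint:
    condition: str
    dose_gy: float
    sf: float
    sem: float | None
    n_plates: int


def filter_plates(plates) -> list[PlateRecord]:
    """Apply the colony-count plate filters.

    Plates with fewer than ``MIN_COLONIES`` or more than
    ``MAX_COLONIES`` colonies are marked invalid and dropped.
    Idempotent; an empty input yields an empty output.
    """
    out = []
    for p in plates:
        ok = MIN_COLONIES <= p.colonies_counted <= MAX_COLONIES
        if ok:
            out.append(replace(p, valid=True))
    return out


def plating_efficiency(plates) -> float:
    """Mean per-plate plating efficiency."""
    plates = list(plates)
    if not plates:
        raise ValueError("no plates")
    return float(np.mean([p.pe for p in plates]))


def surviving_fraction(treated, reference, *, irradiated: bool) -> SurvivalPoint:
    """Surviving fraction of ``treated`` plates against ``reference``.

    ``irradiated=True``: treated plates carry dose > 0 and the
    reference must be the matching unirradiated (0 Gy) sample.
    ``irradiated=False``: treated plates are a 0 Gy sample and the
    reference is the cell-only control.  SF is the mean treated PE over
    the mean reference PE; the SEM is taken over per-plate SFs.
    """
    treated = list(treated)
    reference = list(reference)
    if not treated or not reference:
        raise ValueError("treated and reference plate lists must be non-empty")
    if any(p.dose_gy != 0 for p in reference):
        raise ValueError("reference plates must be unirradiated (0 Gy)")
    if irradiated and any(p.dose_gy <= 0 for p in treated):
        raise ValueError("irradiated=True but a treated plate has dose 0")
    if not irradiated and any(p.dose_gy != 0 for p in treated):
        raise ValueError("irradiated=False but a treated plate has dose > 0")
    ref_pe = plating_efficiency(reference)
    if ref_pe <= 0:
        raise ValueError("reference plating efficiency is zero: SF undefined")
    per_plate_sf = [p.pe / ref_pe for p in treated]
    sf = float(np.mean(per_plate_sf))
    sem = sem_95(per_plate_sf) if len(per_plate_sf) >= 2 else None
    return SurvivalPoint(
        condition=treated[0].condition,
        dose_gy=float(treated[0].dose_gy),
        sf=sf,
        sem=sem,
        n_plates=len(treated),
    )


def read_plates_csv(path) -> list[PlateRecord]:
    """Read plates from CSV with columns plate_id, condition, dose_gy,
    cells_seeded, colonies_counted."""
    df = pd.read_csv(Path(path))
    required = {"plate_id", "condition", "dose_gy", "cells_seeded", "colonies_counted"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plates CSV missing columns: {sorted(missing)}")
    return [
        PlateRecord(
            plate_id=str(row.plate_id),
            condition=str(row.condition),
            dose_gy=float(row.dose_gy),
            cells_seeded=int(row.cells_seeded),
            colonies_counted=int(row.colonies_counted),
        )
        for row in df.itertuples()
    ]


def survival_table(plates, *, control_condition: str = "control") -> pd.DataFrame:
    """Full clonogenic analysis of a plate table.

    Filters plates, then computes one :class:`SurvivalPoint` per
    (condition, dose): 0 Gy points against the cell-only control
    (which scores 1 against itself), irradiated points against the
    same condition's 0 Gy plates.  Returns a DataFrame with columns
    condition, dose_gy, sf, sem, n_plates.
    """
    plates = filter_plates(plates)
    groups: dict[tuple[str, float], list[PlateRecord]] = {}
    for p in plates:
        groups.setdefault((p.condition, p.dose_gy), []).append(p)
    control = groups.get((control_condition, 0.0))
    if control is None:
        raise ValueError(f"no 0 Gy plates for control condition {control_condition!r}")
    rows = []
    for (condition, dose), members in sorted(groups.items()):
        if dose == 0:
            point = surviving_fraction(members, control, irradiated=False)
        else:
            ref = groups.get((condition, 0.0))
            if ref is None:
                raise ValueError(f"no 0 Gy reference plates for condition {condition!r}")
            point = surviving_fraction(members, ref, irradiated=True)
        rows.append(
            (point.condition, point.dose_gy, point.sf, point.sem, point.n_plates)
        )
    return pd.DataFrame(rows, columns=["condition", "dose_gy", "sf", "sem", "n_plates"])
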