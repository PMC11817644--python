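"""TLD dosimetry: raw readings -> absorbed dose to water -> conversion
coefficients.

Each thermoluminescent dosimeter carries an individual calibration factor
(µGy per instrument unit, traceable to absorbed dose to water) and a
dimensionless energy-correction factor.  Two dosimeters sit in every
measurement position (drilled hole or eye); the position dose is the mean of
the pair.  Dividing the position dose by the session's total kerma-area
product P_KA gives the conversion coefficient CC = D_w / P_KA in
µGy/(Gy·cm²).
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "DosimetryError",
    "TLDReading",
    "MeasurementSession",
    "PositionDose",
    "PositionCC",
    "DETECTION_LIMIT_UGY",
    "reading_to_dose",
    "pair_position_doses",
    "compute_position_ccs",
    "read_readings_csv",
    "write_readings_csv",
]

log = logging.getLogger(__name__)

#: Smallest detectable dose of the TLD system, µGy.
DETECTION_LIMIT_UGY = 10.0

#: Default warning level for the relative half-range of a dosimeter pair.
PAIR_DISCREPANCY_LIMIT = 0.10

STANDARD_PROJECTIONS = (
    "PA",
    "LAO30",
    "RAO30",
    "CAUD30",
    "CRAN30",
    "LAO30/CAUD30",
    "LAO30/CRAN30",
    "RAO30/CAUD30",
    "RAO30/CRAN30",
)

MODALITIES = ("fluoroscopy", "acquisition")


class DosimetryError(ValueError):
    """Raised for invalid readings, unpaired positions or bad P_KA."""


@dataclass(frozen=True)
class TLDReading:
    """One raw dosimeter read-out with its individual factors."""

    dosimeter_id: str
    position_id: str
    raw_reading: float
    calibration_factor: float  # µGy per instrument unit
    energy_correction: float  # dimensionless
    slice_no: int | None = None  # None for eye positions

    def __post_init__(self) -> None:
        if self.calibration_factor <= 0 or self.energy_correction <= 0:
            raise DosimetryError(
                f"dosimeter {self.dosimeter_id}: calibration and energy-correction "
                "factors must be positive"
            )
        if self.raw_reading < 0:
            raise DosimetryError(f"dosimeter {self.dosimeter_id}: negative raw reading")


@dataclass
class MeasurementSession:
    """One phantom irradiation: projection geometry, modality, total P_KA
    and the TLD readings collected."""

    projection_name: str
    modality: str
    rotation_deg: float
    angulation_deg: float
    total_pka: float  # Gy·cm²
    readings: list[TLDReading] = field(default_factory=list)
    tube_kvp: float | None = None
    sid_cm: float | None = None
    filtration: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DosimetryError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if self.total_pka <= 0:
            raise DosimetryError(f"session {self.projection_name}: total_pka must be > 0")


@dataclass(frozen=True)
class PositionDose:
    """Mean absorbed dose to water of a dosimeter pair at one position."""

    position_id: str
    dose_w: float  # µGy
    pair_discrepancy: float  # |d1 - d2| / (d1 + d2)
    below_detection: bool
    slice_no: int | None = None


@dataclass(frozen=True)
class PositionCC:
    """Conversion coefficient at one position, µGy/(Gy·cm²)."""

    position_id: str
    cc: float
    slice_no: int | None = None


def reading_to_dose(
    reading: TLDReading, detection_limit: float = DETECTION_LIMIT_UGY
) -> tuple[float, bool]:
    """Absorbed dose to water of a single dosimeter.

    Returns ``(dose_w µGy, below_detection)``; the dose is the raw reading
    times the individual calibration and energy-correction factors.
    """
    dose = reading.raw_reading * reading.calibration_factor * reading.energy_correction
    return dose, dose < detection_limit


def pair_position_doses(
    session: MeasurementSession,
    detection_limit: float = DETECTION_LIMIT_UGY,
    discrepancy_limit: float = PAIR_DISCREPANCY_LIMIT,
) -> list[PositionDose]:
    """Combine the two dosimeters at each position into a position dose.

    The position dose is the arithmetic mean of the pair; the discrepancy
    metric |d1-d2|/(d1+d2) (relative half-range) is logged as a warning when
    it exceeds ``discrepancy_limit``.  A position without exactly two
    readings raises DosimetryError naming it.
    """
    by_position: dict[str, list[TLDReading]] = defaultdict(list)
    for r in session.readings:
        by_position[r.position_id].append(r)
    out: list[PositionDose] = []
    for position_id, pair in by_position.items():
        if len(pair) != 2:
            raise DosimetryError(
                f"position {position_id!r} has {len(pair)} readings, expected 2"
            )
        doses_flags = [reading_to_dose(r, detection_limit) for r in pair]
        d1, d2 = (d for d, _ in doses_flags)
        mean = 0.5 * (d1 + d2)
        disc = abs(d1 - d2) / (d1 + d2) if (d1 + d2) > 0 else 0.0
        if disc > discrepancy_limit:
            log.warning(
                "position %s: pair discrepancy %.1f%% exceeds %.0f%% "
                "(doses %.1f / %.1f µGy)",
                position_id, 100 * disc, 100 * discrepancy_limit, d1, d2,
            )
        out.append(
            PositionDose(
                position_id=position_id,
                dose_w=mean,
                pair_discrepancy=disc,
                below_detection=any(flag for _, flag in doses_flags),
                slice_no=pair[0].slice_no,
            )
        )
    return out


def compute_position_ccs(
    doses: list[PositionDose], total_pka: float
) -> list[PositionCC]:
    """CC = D_w / P_KA per position, in µGy/(Gy·cm²)."""
    if total_pka <= 0:
        raise DosimetryError(f"total_pka must be > 0, got {total_pka}")
    return [
        PositionCC(position_id=d.position_id, cc=d.dose_w / total_pka, slice_no=d.slice_no)
        for d in doses
    ]


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

READINGS_COLUMNS = (
    "dosimeter_id",
    "position_id",
    "slice_no",
    "raw_reading",
    "calibration_factor",
    "energy_correction",
)


def write_readings_csv(readings: list[TLDReading], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(READINGS_COLUMNS)
        for r in readings:
            writer.writerow(
                [
                    r.dosimeter_id,
                    r.position_id,
                    "" if r.slice_no is None else r.slice_no,
                    repr(float(r.raw_reading)),
                    repr(float(r.calibration_factor)),
                    repr(float(r.energy_correction)),
                ]
            )


def read_readings_csv(path: str | Path) -> list[TLDReading]:
    readings: list[TLDReading] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(READINGS_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DosimetryError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            readings.append(
                TLDReading(
                    dosimeter_id=row["dosimeter_id"],
                    position_id=row["position_id"],
                    raw_reading=float(row["raw_reading"]),
                    calibration_factor=float(row["calibration_factor"]),
                    energy_correction=float(row["energy_correction"]),
                    slice_no=int(row["slice_no"]) if row["slice_no"] else None,
                )
            )
    return readings
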