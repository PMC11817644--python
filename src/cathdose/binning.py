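"""Clinical irradiation-event filtering and projection binning.

A dose-monitoring-system export holds one row per irradiation event with the
C-arm rotation (positive = LAO, toward the patient's left) and angulation
(positive = cranial), the modality (fluoroscopy or digital image
acquisition) and the event's kerma-area product P_KA.  Events within ±45° on
BOTH axes are kept and placed on a 3x3 grid of 30°-wide bins centred at
-30/0/+30 per axis — one bin per standard projection — separately per
modality.  Each cell's P_KA sum divided by the total in-range P_KA gives the
cell's fraction of clinical use; the 18 fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .tld import MODALITIES

__all__ = [
    "BinningError",
    "EVENT_COLUMNS",
    "BIN_CENTERS",
    "BinTable",
    "FilterResult",
    "validate_events",
    "filter_events",
    "bin_events",
    "bin_fractions",
    "projection_name",
]

EVENT_COLUMNS = ("procedure_id", "modality", "rotation_deg", "angulation_deg", "pka_gycm2")
BIN_CENTERS = (-30, 0, 30)
DEFAULT_ANGLE_LIMIT_DEG = 45.0


class BinningError(ValueError):
    """Raised for invalid event tables or out-of-range events in bin_events."""


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise BinningError(f"event table missing columns {sorted(missing)}")
    bad_mod = set(events["modality"].unique()) - set(MODALITIES)
    if bad_mod:
        raise BinningError(f"unknown modalities {sorted(bad_mod)}; expected {MODALITIES}")
    if (events["pka_gycm2"] <= 0).any():
        raise BinningError("pka_gycm2 must be > 0 for every event")
    return events


@dataclass(frozen=True)
class FilterResult:
    retained: pd.DataFrame
    rejected: pd.DataFrame
    n_total: int
    n_retained: int
    retained_fraction: float
    in_range_pka: float
    out_of_range_pka: float


def filter_events(
    events: pd.DataFrame, limit_deg: float = DEFAULT_ANGLE_LIMIT_DEG
) -> FilterResult:
    """Keep events with |rotation| <= limit AND |angulation| <= limit
    (closed interval); out-of-range events are discarded from binning."""
    events = validate_events(events)
    keep = (events["rotation_deg"].abs() <= limit_deg) & (
        events["angulation_deg"].abs() <= limit_deg
    )
    retained = events[keep]
    rejected = events[~keep]
    n = len(events)
    return FilterResult(
        retained=retained,
        rejected=rejected,
        n_total=n,
        n_retained=len(retained),
        retained_fraction=len(retained) / n if n else float("nan"),
        in_range_pka=float(retained["pka_gycm2"].sum()),
        out_of_range_pka=float(rejected["pka_gycm2"].sum()),
    )


def _bin_center(angle: np.ndarray, limit_deg: float = DEFAULT_ANGLE_LIMIT_DEG) -> np.ndarray:
    """Bin centre per angle: [-45,-15) -> -30, [-15,15) -> 0, [15,45] -> +30."""
    angle = np.asarray(angle, dtype=float)
    if (np.abs(angle) > limit_deg).any():
        raise BinningError("bin_events received events outside the angle limit; filter first")
    center = np.where(angle < -15, -30, np.where(angle < 15, 0, 30))
    return center


@dataclass(frozen=True)
class BinTable:
    """P_KA sums and event counts on the 3x3 projection grid x 2 modalities.

    ``cells`` is indexed by (rotation_bin, angulation_bin, modality) and
    covers all 18 cells (zero-filled where no events fell).
    """

    cells: pd.DataFrame  # columns: pka_sum, event_count
    in_range_pka: float
    out_of_range_pka: float = 0.0

    @property
    def retained_fraction_pka(self) -> float:
        total = self.in_range_pka + self.out_of_range_pka
        return self.in_range_pka / total if total else float("nan")

    def modality_pka(self, modality: str) -> float:
        return float(self.cells.xs(modality, level="modality")["pka_sum"].sum())


def _full_cell_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [BIN_CENTERS, BIN_CENTERS, list(MODALITIES)],
        names=["rotation_bin", "angulation_bin", "modality"],
    )


def bin_events(retained: pd.DataFrame, out_of_range_pka: float = 0.0) -> BinTable:
    """Accumulate P_KA and counts per (rotation bin, angulation bin,
    modality); every input event must already be within ±45° on both axes."""
    retained = validate_events(retained)
    df = retained.assign(
        rotation_bin=_bin_center(retained["rotation_deg"].to_numpy()),
        angulation_bin=_bin_center(retained["angulation_deg"].to_numpy()),
    )
    grouped = df.groupby(["rotation_bin", "angulation_bin", "modality"], sort=True).agg(
        pka_sum=("pka_gycm2", "sum"), event_count=("pka_gycm2", "size")
    )
    cells = grouped.reindex(_full_cell_index(), fill_value=0.0)
    cells["event_count"] = cells["event_count"].astype(int)
    return BinTable(
        cells=cells,
        in_range_pka=float(df["pka_gycm2"].sum()),
        out_of_range_pka=float(out_of_range_pka),
    )


def bin_fractions(table: BinTable) -> pd.Series:
    """Per-cell P_KA fraction of the in-range total; sums to 1 over the 18
    cells."""
    if table.in_range_pka <= 0:
        raise BinningError("in-range P_KA total is zero; cannot form fractions")
    return table.cells["pka_sum"] / table.in_range_pka


def projection_name(rotation_bin: int, angulation_bin: int) -> str:
    """Standard projection label of a bin cell (PA at the centre)."""
    rot = {-30: "RAO30", 0: "", 30: "LAO30"}[int(rotation_bin)]
    ang = {-30: "CAUD30", 0: "", 30: "CRAN30"}[int(angulation_bin)]
    if rot and ang:
        return f"{rot}/{ang}"
    return rot or ang or "PA"


def fractions_by_projection(fractions: pd.Series) -> dict[tuple[str, str], float]:
    """Re-key the 18-cell fraction Series by (projection name, modality)."""
    out: dict[tuple[str, str], float] = {}
    for (rot, ang, modality), frac in fractions.items():
        out[(projection_name(rot, ang), modality)] = float(frac)
    return out


def bin_table_to_csv(table: BinTable, fractions: pd.Series, path) -> None:
    """Long-format export: one row per (rotation_bin, angulation_bin,
    modality) with P_KA sum and fraction."""
    df = table.cells.copy()
    df["fraction"] = fractions
    df = df.reset_index()
    df["projection"] = [
        projection_name(r, a) for r, a in zip(df["rotation_bin"], df["angulation_bin"])
    ]
    df.to_csv(path, index=False)
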