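"""Exposure weighting: fluoroscopy scaling and the clinically weighted CC.

Phantom CCs are measured with digital image acquisition for all nine
standard projections but with fluoroscopy for only one reference projection
(LAO30, the geometry with the most scatter to the operator).  Fluoroscopy
CCs for the remaining projections are obtained by scaling each projection's
acquisition CC with the fluoroscopy/acquisition CC ratio at the reference
projection, per target (brain region or eye).  The weighted CC of a target
is then the P_KA-fraction-weighted sum over all (projection, modality)
cells, representing the average clinical exposure geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .mapping import CC_TABLE_COLUMNS
from .tld import MODALITIES, STANDARD_PROJECTIONS

__all__ = [
    "WeightingError",
    "ModalityCCSet",
    "scale_fluoro_ccs",
    "weighted_cc",
    "weighted_cc_row",
]

FRACTION_SUM_TOL = 1e-9


class WeightingError(ValueError):
    """Raised for invalid references, fractions or missing CC cells."""


def scale_fluoro_ccs(
    acq_ccs: Mapping[str, float],
    fl_ref_cc: float,
    acq_ref_cc: float,
) -> dict[str, float]:
    """Per-projection fluoroscopy CCs from the single measured ratio.

    fl_cc(p) = acq_cc(p) * (fl_ref_cc / acq_ref_cc); at the reference
    projection the scaled value equals ``fl_ref_cc`` exactly.
    """
    if acq_ref_cc <= 0:
        raise WeightingError(f"acquisition reference CC must be > 0, got {acq_ref_cc}")
    if fl_ref_cc < 0:
        raise WeightingError(f"fluoroscopy reference CC must be >= 0, got {fl_ref_cc}")
    ratio = fl_ref_cc / acq_ref_cc
    return {proj: cc * ratio for proj, cc in acq_ccs.items()}


@dataclass
class ModalityCCSet:
    """CCs per (projection, modality) and target, with provenance flags.

    ``ccs`` is indexed by (projection, modality) with one column per target;
    ``provenance`` carries ``measured`` or ``ratio-scaled`` per cell.
    """

    ccs: pd.DataFrame
    provenance: pd.DataFrame

    @classmethod
    def from_acquisition_table(
        cls,
        acq_table: pd.DataFrame,
        fluoro_reference: Mapping[str, float],
        reference_projection: str = "LAO30",
    ) -> "ModalityCCSet":
        """Build the full set from per-projection acquisition CCs and the
        fluoroscopy CCs measured at one reference projection.

        ``acq_table`` is indexed by projection with one column per target
        (brain regions + eyes); ``fluoro_reference`` maps each target to its
        measured fluoroscopy CC at ``reference_projection``.  The ratio is
        per target, not a single shared scalar.
        """
        if reference_projection not in acq_table.index:
            raise WeightingError(
                f"reference projection {reference_projection!r} not in acquisition table"
            )
        targets = list(acq_table.columns)
        missing = set(targets) - set(fluoro_reference)
        if missing:
            raise WeightingError(f"fluoro reference missing targets {sorted(missing)}")
        index = pd.MultiIndex.from_product(
            [list(acq_table.index), list(MODALITIES)], names=["projection", "modality"]
        )
        ccs = pd.DataFrame(index=index, columns=targets, dtype=float)
        prov = pd.DataFrame(index=index, columns=targets, dtype=object)
        for target in targets:
            acq = acq_table[target]
            fl = scale_fluoro_ccs(
                acq.to_dict(),
                fl_ref_cc=float(fluoro_reference[target]),
                acq_ref_cc=float(acq.loc[reference_projection]),
            )
            for proj in acq_table.index:
                ccs.loc[(proj, "acquisition"), target] = float(acq.loc[proj])
                prov.loc[(proj, "acquisition"), target] = "measured"
                ccs.loc[(proj, "fluoroscopy"), target] = fl[proj]
                prov.loc[(proj, "fluoroscopy"), target] = (
                    "measured" if proj == reference_projection else "ratio-scaled"
                )
        return cls(ccs=ccs, provenance=prov)

    def cc(self, projection: str, modality: str, target: str) -> float:
        try:
            return float(self.ccs.loc[(projection, modality), target])
        except KeyError as exc:
            raise WeightingError(
                f"no CC for cell ({projection}, {modality}) target {target!r}"
            ) from exc

    def target_cells(self, target: str) -> dict[tuple[str, str], float]:
        return {
            (proj, mod): float(v)
            for (proj, mod), v in self.ccs[target].items()
        }


def weighted_cc(
    cc_cells: Mapping[tuple[str, str], float],
    fractions: Mapping[tuple[str, str], float],
) -> float:
    """P_KA-fraction-weighted CC: sum of fraction x CC over all cells with
    nonzero fraction.

    Fractions must sum to 1; a nonzero-fraction cell without a CC raises
    WeightingError naming the cell.  The result is convex: it lies within
    [min, max] of the participating CCs.
    """
    total = sum(fractions.values())
    if abs(total - 1.0) > FRACTION_SUM_TOL:
        raise WeightingError(f"fractions sum to {total!r}, expected 1")
    if any(f < 0 for f in fractions.values()):
        raise WeightingError("fractions must be non-negative")
    acc = 0.0
    for cell, frac in fractions.items():
        if frac == 0:
            continue
        if cell not in cc_cells:
            raise WeightingError(f"missing CC for cell {cell} with fraction {frac}")
        acc += frac * cc_cells[cell]
    return acc


def weighted_cc_row(
    cc_set: ModalityCCSet,
    fractions: Mapping[tuple[str, str], float],
    targets: list[str] | None = None,
) -> dict[str, float]:
    """Weighted CC for every target column of the set (full precision)."""
    targets = targets or list(cc_set.ccs.columns)
    return {t: weighted_cc(cc_set.target_cells(t), fractions) for t in targets}
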