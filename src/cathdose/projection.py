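"""Dose projection: annual organ doses, years-to-threshold, shielding.

A weighted conversion coefficient (µGy per Gy·cm² of patient P_KA) times the
annual clinical workload's total P_KA gives the operator's annual organ dose.
Comparing the cumulative dose against tissue-reaction thresholds (0.5 Gy for
cataract induction in the eye lens and for circulatory disease in the brain)
yields the completed working years before the threshold is exceeded.
Shielding scenarios apply multiplicative transmission factors: a correctly
used ceiling-suspended shield transmits at most 25% of the scatter, and
leaded eyewear at most a further 70% to the eyes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ProjectionError",
    "WorkloadItem",
    "WorkloadSpec",
    "ShieldingScenario",
    "DoseReport",
    "EYE_TARGETS",
    "BRAIN_THRESHOLD_GY",
    "EYE_THRESHOLD_GY",
    "annual_pka",
    "annual_dose",
    "reported_dose_mgy",
    "years_to_threshold",
    "build_dose_report",
]

#: Absorbed-dose threshold for circulatory disease in the brain (Gy).
BRAIN_THRESHOLD_GY = 0.5
#: Absorbed-dose threshold for cataract induction in the eye lens (Gy).
EYE_THRESHOLD_GY = 0.5

EYE_TARGETS = frozenset({"left_eye", "right_eye"})

#: Sentinel for thresholds never reached (zero annual dose).
NEVER_REACHED = math.inf


class ProjectionError(ValueError):
    """Raised for invalid workloads or transmission factors."""


@dataclass(frozen=True)
class WorkloadItem:
    procedure_type: str
    annual_count: int
    mean_pka: float  # Gy·cm² per procedure

    def __post_init__(self) -> None:
        if self.annual_count < 0:
            raise ProjectionError(f"{self.procedure_type}: negative annual count")
        if self.mean_pka <= 0:
            raise ProjectionError(f"{self.procedure_type}: mean_pka must be > 0")


@dataclass(frozen=True)
class WorkloadSpec:
    items: tuple[WorkloadItem, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise ProjectionError("workload must contain at least one procedure type")


@dataclass(frozen=True)
class ShieldingScenario:
    """Multiplicative transmission factors per protective device.

    ``ceiling_shield`` applies to every target; ``eyewear`` applies to the
    eye lenses only.  A factor of 1 means the device is not used.
    """

    name: str = "unshielded"
    ceiling_shield: float = 1.0
    eyewear: float = 1.0

    def __post_init__(self) -> None:
        for label, f in (("ceiling_shield", self.ceiling_shield), ("eyewear", self.eyewear)):
            if not (0 < f <= 1):
                raise ProjectionError(f"{label} transmission must be in (0, 1], got {f}")

    def transmission(self, target: str) -> float:
        t = self.ceiling_shield
        if target in EYE_TARGETS:
            t *= self.eyewear
        return t


def annual_pka(workload: WorkloadSpec) -> float:
    """Total annual patient P_KA, Gy·cm²: sum of count x mean P_KA."""
    return sum(item.annual_count * item.mean_pka for item in workload.items)


def annual_dose(
    cc: float,
    annual_pka_gycm2: float,
    scenario: ShieldingScenario | None = None,
    target: str = "whole",
) -> float:
    """Annual organ dose in mGy (full precision): CC x annual P_KA / 1000,
    times the scenario's transmission for the target."""
    if cc < 0:
        raise ProjectionError(f"cc must be >= 0, got {cc}")
    dose = cc * annual_pka_gycm2 / 1000.0
    if scenario is not None:
        dose *= scenario.transmission(target)
    return dose


def reported_dose_mgy(dose_mgy: float) -> int:
    """Doses are reported to the nearest integer mGy (half away from zero)."""
    return int(math.floor(dose_mgy + 0.5))


def years_to_threshold(
    threshold_gy: float, annual_dose_mgy: float, rounding: str = "floor"
) -> float:
    """Completed working years before the cumulative dose exceeds the
    threshold, from the FULL-PRECISION annual dose.

    ``floor`` (default) counts whole years worked without exceedance;
    ``nearest`` rounds half away from zero.  Zero annual dose returns the
    ``NEVER_REACHED`` sentinel (infinity).
    """
    if annual_dose_mgy < 0:
        raise ProjectionError("annual dose must be >= 0")
    if annual_dose_mgy == 0:
        return NEVER_REACHED
    years = threshold_gy * 1000.0 / annual_dose_mgy
    if rounding == "floor":
        return float(math.floor(years))
    if rounding == "nearest":
        return float(math.floor(years + 0.5))
    raise ProjectionError(f"unknown rounding mode {rounding!r}")


@dataclass
class DoseReport:
    """Annual doses and years-to-threshold per target and scenario."""

    annual_pka: float
    #: target -> scenario name -> full-precision annual dose, mGy
    annual_dose_mgy: dict[str, dict[str, float]]
    #: target -> scenario name -> reported integer dose, mGy
    reported_mgy: dict[str, dict[str, int]]
    #: target -> scenario name -> completed years to threshold
    years: dict[str, dict[str, float]]
    thresholds_gy: dict[str, float]
    rounding: str = "floor"

    def to_dict(self) -> dict:
        return {
            "annual_pka_gycm2": self.annual_pka,
            "annual_dose_mgy": self.annual_dose_mgy,
            "reported_mgy": self.reported_mgy,
            "years_to_threshold": {
                t: {s: (None if math.isinf(y) else y) for s, y in sc.items()}
                for t, sc in self.years.items()
            },
            "thresholds_gy": self.thresholds_gy,
            "rounding": self.rounding,
        }

    def to_text(self) -> str:
        lines = [f"Annual P_KA: {self.annual_pka:.0f} Gy cm2", ""]
        scenarios = list(next(iter(self.annual_dose_mgy.values())).keys())
        width = max(24, max(len(s) for s in scenarios) + 2)
        header = f"{'target':<12}" + "".join(f"{s:>{width}}" for s in scenarios)
        lines.append(header + "   (annual mGy / years to threshold)")
        for target, per_scen in self.annual_dose_mgy.items():
            cells = []
            for s in scenarios:
                y = self.years[target][s]
                ytxt = "never" if math.isinf(y) else f"{y:.0f} y"
                cells.append(f"{self.reported_mgy[target][s]} mGy /{ytxt:>7}")
            lines.append(f"{target:<12}" + "".join(f"{c:>{width}}" for c in cells))
        return "\n".join(lines)


def build_dose_report(
    weighted_ccs: Mapping[str, float],
    workload: WorkloadSpec,
    scenarios: Sequence[ShieldingScenario] = (),
    thresholds_gy: Mapping[str, float] | None = None,
    rounding: str = "floor",
) -> DoseReport:
    """Assemble the full dose report for a set of targets.

    ``thresholds_gy`` maps each target to its threshold; targets absent from
    the mapping default to the eye threshold for eye targets and the brain
    threshold otherwise.
    """
    pka = annual_pka(workload)
    all_scenarios = [ShieldingScenario()] + list(scenarios)
    doses: dict[str, dict[str, float]] = {}
    reported: dict[str, dict[str, int]] = {}
    years: dict[str, dict[str, float]] = {}
    thr: dict[str, float] = {}
    for target, cc in weighted_ccs.items():
        threshold = (thresholds_gy or {}).get(
            target, EYE_THRESHOLD_GY if target in EYE_TARGETS else BRAIN_THRESHOLD_GY
        )
        thr[target] = threshold
        doses[target], reported[target], years[target] = {}, {}, {}
        for scen in all_scenarios:
            d = annual_dose(cc, pka, scen, target)
            doses[target][scen.name] = d
            reported[target][scen.name] = reported_dose_mgy(d)
            years[target][scen.name] = years_to_threshold(threshold, d, rounding)
    return DoseReport(
        annual_pka=pka,
        annual_dose_mgy=doses,
        reported_mgy=reported,
        years=years,
        thresholds_gy=thr,
        rounding=rounding,
    )
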