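"""Head-phantom geometry: slices, drilled-hole grid, brain masks, regions.

The operator's head is modelled after an anthropomorphic slice phantom that
is transected horizontally into 2.5 cm slices.  Four consecutive slices carry
TLDs in a grid of drilled holes inside the brain; two more TLD positions sit
on the surface at the left and right eye.  Slice geometry lives on the axial
CT raster of the phantom: pixel coordinates are 0-based, ``x`` is the column
and ``y`` the row, origin at the top-left, matching standard axial CT display
(viewed from the feet, so the patient-left side of the head appears at high
``x``).

The brain is divided into six overlapping half-regions (upper/lower by slice
number, left/right and front/rear by pixel thresholds).  The thresholds are
specific to the CT matrix used and are therefore configuration, not
constants; the defaults correspond to a 512x512 axial matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GeometryError",
    "SliceGeometry",
    "PhantomGrid",
    "RegionThresholds",
    "BRAIN_REGIONS",
    "classify_region",
    "region_mask",
    "load_geometry",
    "save_geometry",
    "mask_to_rle",
    "rle_to_mask",
]

#: Region labels: "whole" plus three binary partitions of the brain.
BRAIN_REGIONS = ("whole", "left", "right", "upper", "lower", "front", "rear")


class GeometryError(ValueError):
    """Raised when phantom geometry or region thresholds are inconsistent."""


@dataclass(frozen=True)
class SliceGeometry:
    """One phantom slice: brain mask raster and TLD hole positions.

    Parameters
    ----------
    slice_no:
        The slice label printed on the phantom (not the array order).
    brain_mask:
        2D boolean raster; True inside the brain.
    hole_positions:
        ``(x, y)`` pixel coordinates of the drilled TLD holes.  Every hole
        must lie inside the brain mask.
    """

    slice_no: int
    brain_mask: np.ndarray
    hole_positions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        mask = np.asarray(self.brain_mask, dtype=bool)
        object.__setattr__(self, "brain_mask", mask)
        object.__setattr__(
            self, "hole_positions", tuple((int(x), int(y)) for x, y in self.hole_positions)
        )
        if mask.ndim != 2 or not mask.any():
            raise GeometryError(f"slice {self.slice_no}: brain mask empty or not 2D")
        rows, cols = mask.shape
        for x, y in self.hole_positions:
            if not (0 <= x < cols and 0 <= y < rows):
                raise GeometryError(
                    f"slice {self.slice_no}: hole ({x}, {y}) outside matrix {mask.shape}"
                )
            if not mask[y, x]:
                raise GeometryError(
                    f"slice {self.slice_no}: hole ({x}, {y}) outside brain mask"
                )

    @property
    def matrix_shape(self) -> tuple[int, int]:
        return self.brain_mask.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PhantomGrid:
    """The full head-phantom coordinate system.

    ``eye_positions`` maps the labels ``left_eye`` and ``right_eye`` to
    surface ``(x, y)`` pixel points; ``pixel_spacing`` is the isotropic
    in-plane spacing in mm and ``slice_thickness`` the slice pitch in mm.
    """

    slices: tuple[SliceGeometry, ...]
    eye_positions: Mapping[str, tuple[int, int]]
    pixel_spacing: float
    slice_thickness: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", tuple(self.slices))
        object.__setattr__(
            self,
            "eye_positions",
            {k: (int(v[0]), int(v[1])) for k, v in dict(self.eye_positions).items()},
        )
        nos = [s.slice_no for s in self.slices]
        if len(set(nos)) != len(nos) or nos != sorted(nos):
            raise GeometryError(f"slice numbers must be unique and ordered, got {nos}")
        if set(self.eye_positions) != {"left_eye", "right_eye"}:
            raise GeometryError(
                f"need exactly left_eye and right_eye, got {sorted(self.eye_positions)}"
            )
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise GeometryError("pixel_spacing and slice_thickness must be positive")

    @property
    def slice_numbers(self) -> tuple[int, ...]:
        return tuple(s.slice_no for s in self.slices)

    def slice_geometry(self, slice_no: int) -> SliceGeometry:
        for s in self.slices:
            if s.slice_no == slice_no:
                return s
        raise GeometryError(f"unknown slice number {slice_no} (have {self.slice_numbers})")

    def position_index(self) -> dict[str, tuple[int | None, tuple[int, int]]]:
        """Map position_id -> (slice_no, (x, y)) for every hole and eye.

        Hole ids follow the convention ``s<slice>_h<idx>`` with ``idx``
        numbering the holes within a slice in storage order; eyes map with
        slice_no ``None``.
        """
        index: dict[str, tuple[int | None, tuple[int, int]]] = {}
        for s in self.slices:
            for i, xy in enumerate(s.hole_positions):
                index[f"s{s.slice_no}_h{i:02d}"] = (s.slice_no, xy)
        for label, xy in self.eye_positions.items():
            index[label] = (None, xy)
        return index


@dataclass(frozen=True)
class RegionThresholds:
    """Rule set dividing the brain into six half-regions.

    Left/right split on the x (column) threshold, front/rear on the y (row)
    threshold, upper/lower on slice number.  The x and y thresholds must be
    adjacent so each axis partitions the mask exhaustively and disjointly.
    Defaults correspond to a 512x512 axial matrix with the head centred.
    """

    upper_slices: frozenset[int] = frozenset({2, 3})
    lower_slices: frozenset[int] = frozenset({4, 5})
    left_min_x: int = 248
    right_max_x: int = 247
    front_max_y: int = 262
    rear_min_y: int = 263

    def __post_init__(self) -> None:
        object.__setattr__(self, "upper_slices", frozenset(self.upper_slices))
        object.__setattr__(self, "lower_slices", frozenset(self.lower_slices))
        if self.upper_slices & self.lower_slices:
            raise GeometryError("upper and lower slice sets must be disjoint")
        if self.right_max_x + 1 != self.left_min_x:
            raise GeometryError("left/right thresholds must be adjacent columns")
        if self.front_max_y + 1 != self.rear_min_y:
            raise GeometryError("front/rear thresholds must be adjacent rows")


def classify_region(
    slice_no: int,
    pixel: tuple[int, int],
    thresholds: RegionThresholds,
    grid: PhantomGrid,
) -> set[str]:
    """Region labels of one pixel: empty outside the brain, else one label
    per axis (upper/lower, left/right, front/rear)."""
    geom = grid.slice_geometry(slice_no)  # raises GeometryError if unknown
    x, y = int(pixel[0]), int(pixel[1])
    rows, cols = geom.matrix_shape
    if not (0 <= x < cols and 0 <= y < rows):
        raise GeometryError(f"pixel ({x}, {y}) outside matrix {geom.matrix_shape}")
    if not geom.brain_mask[y, x]:
        return set()
    if slice_no in thresholds.upper_slices:
        vertical = "upper"
    elif slice_no in thresholds.lower_slices:
        vertical = "lower"
    else:
        raise GeometryError(
            f"slice {slice_no} belongs to neither upper nor lower slice set"
        )
    lateral = "left" if x >= thresholds.left_min_x else "right"
    sagittal = "front" if y <= thresholds.front_max_y else "rear"
    return {vertical, lateral, sagittal}


def region_mask(
    geom: SliceGeometry, region: str, thresholds: RegionThresholds
) -> np.ndarray:
    """Boolean raster of the pixels of ``geom`` belonging to ``region``.

    ``whole`` selects the full brain mask of the slice.  Upper/lower regions
    return an all-False raster when the slice is not in the region's slice
    set.
    """
    mask = geom.brain_mask
    if region == "whole":
        return mask.copy()
    rows, cols = mask.shape
    x = np.arange(cols)[None, :]
    y = np.arange(rows)[:, None]
    if region == "upper":
        return mask if geom.slice_no in thresholds.upper_slices else np.zeros_like(mask)
    if region == "lower":
        return mask if geom.slice_no in thresholds.lower_slices else np.zeros_like(mask)
    if region == "left":
        return mask & (x >= thresholds.left_min_x)
    if region == "right":
        return mask & (x <= thresholds.right_max_x)
    if region == "front":
        return mask & (y <= thresholds.front_max_y)
    if region == "rear":
        return mask & (y >= thresholds.rear_min_y)
    raise GeometryError(f"unknown region {region!r}; expected one of {BRAIN_REGIONS}")


# ---------------------------------------------------------------------------
# Serialization: JSON with run-length-encoded masks (text-only, diffable)
# ---------------------------------------------------------------------------


def mask_to_rle(mask: np.ndarray) -> list[list[int]]:
    """Row run-length encoding: list of [row, start_col, length] runs."""
    runs: list[list[int]] = []
    mask = np.asarray(mask, dtype=bool)
    for r in range(mask.shape[0]):
        row = mask[r]
        # transitions: pad with False on both sides
        diff = np.diff(np.concatenate(([False], row, [False])).astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            runs.append([r, int(s), int(e - s)])
    return runs


def rle_to_mask(runs: Iterable[Iterable[int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, s, n in runs:
        mask[r, s : s + n] = True
    return mask


def save_geometry(grid: PhantomGrid, path: str | Path) -> None:
    """Write a PhantomGrid to the documented JSON schema."""
    doc = {
        "pixel_spacing_mm": grid.pixel_spacing,
        "slice_thickness_mm": grid.slice_thickness,
        "eye_positions": {k: list(v) for k, v in grid.eye_positions.items()},
        "slices": [
            {
                "slice_no": s.slice_no,
                "matrix_shape": list(s.matrix_shape),
                "brain_mask_rle": mask_to_rle(s.brain_mask),
                "hole_positions": [list(p) for p in s.hole_positions],
            }
            for s in grid.slices
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_geometry(path: str | Path) -> PhantomGrid:
    """Read a PhantomGrid from the documented JSON schema, validating all
    invariants; malformed input raises GeometryError naming the offender."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise GeometryError(f"cannot read geometry file {path}: {exc}") from exc
    try:
        slices = tuple(
            SliceGeometry(
                slice_no=int(s["slice_no"]),
                brain_mask=rle_to_mask(s["brain_mask_rle"], tuple(s["matrix_shape"])),
                hole_positions=[tuple(p) for p in s["hole_positions"]],
            )
            for s in doc["slices"]
        )
        return PhantomGrid(
            slices=slices,
            eye_positions={k: tuple(v) for k, v in doc["eye_positions"].items()},
            pixel_spacing=float(doc["pixel_spacing_mm"]),
            slice_thickness=float(doc["slice_thickness_mm"]),
        )
    except (KeyError, TypeError) as exc:
        raise GeometryError(f"malformed geometry schema in {path}: {exc}") from exc
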