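"""Dose mapping: interpolated CC rasters per slice and region/eye means.

The sparse per-hole conversion coefficients of one slice are interpolated
over the slice's brain mask with radial basis functions (thin-plate spline
by default, no smoothing, so the map reproduces the measured values at the
holes).  Mask pixels outside the convex hull of the holes are extrapolated;
negative extrapolation artefacts are clipped to zero and the clipped
fraction recorded.  Region CCs are unweighted means over the mask pixels of
a region, pooled across its slices; the whole-brain CC pools every
TLD-bearing slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay

from .geometry import (
    BRAIN_REGIONS,
    GeometryError,
    PhantomGrid,
    RegionThresholds,
    SliceGeometry,
    region_mask,
)
from .tld import PositionCC, PositionDose

__all__ = [
    "MappingError",
    "InterpolationSettings",
    "CCMap",
    "CCTableRow",
    "interpolate_slice",
    "interpolate_grid",
    "region_mean_cc",
    "eye_cc",
    "assemble_cc_table",
    "column_max",
    "left_right_ratio",
    "hull_mask",
]


class MappingError(ValueError):
    """Raised for degenerate interpolation input or empty regions."""


@dataclass(frozen=True)
class InterpolationSettings:
    """RBF settings; the defaults interpolate (no smoothing) with a
    thin-plate-spline kernel and its implied degree-1 polynomial tail."""

    kernel: str = "thin_plate_spline"
    smoothing: float = 0.0
    degree: int | None = None  # None -> scipy's minimum degree for the kernel


@dataclass
class CCMap:
    """Interpolated CC raster of one slice, defined on the brain mask.

    ``raster`` holds CC values (µGy/Gy·cm²) at mask pixels and NaN outside;
    ``clipped_fraction`` is the fraction of mask pixels whose (negative)
    interpolated value was clipped to zero.
    """

    slice_no: int
    raster: np.ndarray
    interpolator_kind: str
    source_positions: list[PositionCC]
    clipped_fraction: float = 0.0

    def in_mask_values(self) -> np.ndarray:
        return self.raster[np.isfinite(self.raster)]


def _source_points(
    position_ccs: Sequence[PositionCC],
    pixels_by_position: Mapping[str, tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    pts, vals = [], []
    for pcc in position_ccs:
        if pcc.position_id not in pixels_by_position:
            raise MappingError(f"no pixel coordinates for position {pcc.position_id!r}")
        pts.append(pixels_by_position[pcc.position_id])
        vals.append(pcc.cc)
    return np.asarray(pts, dtype=float), np.asarray(vals, dtype=float)


def interpolate_slice(
    position_ccs: Sequence[PositionCC],
    slice_geom: SliceGeometry,
    pixels_by_position: Mapping[str, tuple[int, int]],
    settings: InterpolationSettings | None = None,
) -> CCMap:
    """RBF-interpolate the hole CCs of one slice over its brain mask.

    Requires at least three non-collinear source positions.  The raster
    reproduces the source CCs at the hole pixels (interpolating by default);
    every mask pixel is defined, including outside the convex hull of the
    holes (RBF extrapolation), with negative values clipped at zero.
    """
    settings = settings or InterpolationSettings()
    points, values = _source_points(position_ccs, pixels_by_position)
    if len(points) < 3:
        raise MappingError(
            f"slice {slice_geom.slice_no}: need >= 3 source positions, got {len(points)}"
        )
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise MappingError(f"slice {slice_geom.slice_no}: source positions are collinear")

    rbf = RBFInterpolator(
        points,
        values,
        kernel=settings.kernel,
        smoothing=settings.smoothing,
        **({} if settings.degree is None else {"degree": settings.degree}),
    )
    mask = slice_geom.brain_mask
    yy, xx = np.nonzero(mask)
    est = rbf(np.column_stack([xx, yy]).astype(float))
    n_clip = int((est < 0).sum())
    est = np.clip(est, 0.0, None)
    raster = np.full(mask.shape, np.nan)
    raster[yy, xx] = est
    return CCMap(
        slice_no=slice_geom.slice_no,
        raster=raster,
        interpolator_kind=f"rbf:{settings.kernel}:s={settings.smoothing}",
        source_positions=list(position_ccs),
        clipped_fraction=n_clip / len(est),
    )


def interpolate_grid(
    position_ccs: Sequence[PositionCC],
    grid: PhantomGrid,
    settings: InterpolationSettings | None = None,
) -> list[CCMap]:
    """Build one CCMap per TLD-bearing slice from a mixed position-CC list
    (eye positions, with slice_no None, are ignored here)."""
    index = grid.position_index()
    pixels = {pid: xy for pid, (sno, xy) in index.items()}
    maps = []
    for s in grid.slices:
        slice_ccs = [p for p in position_ccs if p.slice_no == s.slice_no]
        maps.append(interpolate_slice(slice_ccs, s, pixels, settings))
    return maps


def region_mean_cc(
    maps: Iterable[CCMap],
    region: str,
    thresholds: RegionThresholds,
    grid: PhantomGrid,
) -> float:
    """Unweighted mean CC over all mask pixels of ``region`` pooled across
    its slices ("whole" pools every TLD-bearing slice)."""
    total, count = 0.0, 0
    for cc_map in maps:
        geom = grid.slice_geometry(cc_map.slice_no)
        sel = region_mask(geom, region, thresholds)
        if not sel.any():
            continue
        vals = cc_map.raster[sel]
        if not np.isfinite(vals).all():
            raise MappingError(
                f"slice {cc_map.slice_no}: region {region} includes undefined pixels"
            )
        total += float(vals.sum())
        count += vals.size
    if count == 0:
        raise MappingError(f"region {region!r} contains no pixels")
    return total / count


def eye_cc(
    left_eye: PositionDose, right_eye: PositionDose, total_pka: float
) -> tuple[float, float]:
    """Eye-lens CCs from the paired eye doses: mean pair dose / P_KA."""
    if left_eye is None or right_eye is None:
        raise MappingError("both eye positions are required")
    if total_pka <= 0:
        raise MappingError(f"total_pka must be > 0, got {total_pka}")
    return left_eye.dose_w / total_pka, right_eye.dose_w / total_pka


# ---------------------------------------------------------------------------
# The CC table (one row per measurement configuration)
# ---------------------------------------------------------------------------

CC_TABLE_COLUMNS = list(BRAIN_REGIONS) + ["left_eye", "right_eye"]


@dataclass(frozen=True)
class CCTableRow:
    """CCs of one measurement configuration: the seven brain regions and the
    two eye lenses, all in µGy/(Gy·cm²)."""

    configuration: str
    whole: float
    left: float
    right: float
    upper: float
    lower: float
    front: float
    rear: float
    left_eye: float
    right_eye: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CC_TABLE_COLUMNS}


def assemble_cc_table(rows: Sequence[CCTableRow]) -> pd.DataFrame:
    """CC table indexed by configuration label; duplicate labels raise."""
    labels = [r.configuration for r in rows]
    if not rows:
        return pd.DataFrame(
            columns=CC_TABLE_COLUMNS, index=pd.Index([], name="configuration")
        )
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise MappingError(f"duplicate configuration labels: {dupes}")
    frame = pd.DataFrame(
        [r.as_dict() for r in rows], index=pd.Index(labels, name="configuration")
    )
    return frame[CC_TABLE_COLUMNS]


def column_max(table: pd.DataFrame) -> pd.Series:
    """Maximum CC per column over the table's rows."""
    return table.max(axis=0)


def left_right_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row left/right CC ratios for the brain segments and eye lenses."""
    return pd.DataFrame(
        {
            "brain": table["left"] / table["right"],
            "eye": table["left_eye"] / table["right_eye"],
        },
        index=table.index,
    )


def hull_mask(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the pixels inside the convex hull of (x, y) points."""
    tri = Delaunay(np.asarray(points, dtype=float))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = tri.find_simplex(np.column_stack([xx.ravel(), yy.ravel()])) >= 0
    return inside.reshape(shape)


def ccmap_to_csv(cc_map: CCMap, path) -> None:
    """Long-format CSV export of the in-mask pixel values."""
    yy, xx = np.nonzero(np.isfinite(cc_map.raster))
    pd.DataFrame(
        {"x": xx, "y": yy, "cc": cc_map.raster[yy, xx]}
    ).to_csv(path, index=False)
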