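"""Synthetic inputs with known ground truth.

Real inputs to this pipeline are a slice-phantom geometry (from a CT of the
head phantom), TLD reading sets per irradiation session, and a
dose-monitoring-system export of clinical irradiation events.  None of these
ship with the package; this module generates statistically similar stand-ins
with known ground truth so the full pipeline can be exercised and its
parameter recovery verified.

The ground-truth scatter field is an exponential gradient: the operator's
head sees more scatter on the side facing the patient and tube (the
operator's left, lower and front), falling off with an attenuation length
along a fixed direction.  TLD readings are the field value times the
session P_KA, divided by per-dosimeter calibration and energy-correction
factors, with multiplicative lognormal read-out noise.  Event logs draw
C-arm angles from per-bin weights (with optional out-of-range mass) and
per-modality lognormal P_KA values, with the modality mix solved so the
expected fluoroscopy share of total P_KA hits a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import PhantomGrid, RegionThresholds, SliceGeometry
from .tld import MeasurementSession, TLDReading

__all__ = [
    "make_geometry",
    "thresholds_for",
    "ScatterFieldParams",
    "ScatterField",
    "make_scatter_field",
    "simulate_tld_readings",
    "EventLogParams",
    "simulate_event_log",
    "default_sessions",
]


# ---------------------------------------------------------------------------
# Geometry fixture
# ---------------------------------------------------------------------------

def make_geometry(
    matrix_shape: tuple[int, int] = (512, 512),
    slice_nos: tuple[int, ...] = (2, 3, 4, 5),
    pixel_spacing_mm: float = 0.45,
    slice_thickness_mm: float = 25.0,
    center_xy: tuple[float, float] | None = None,
) -> PhantomGrid:
    """Synthetic head-phantom geometry with ellipse-shaped brain masks.

    Four TLD-bearing slices with a regular grid of drilled holes inside
    slightly tapering elliptical brain masks, plus two surface eye points.
    The default matches a 512x512 axial CT matrix with the head centred so
    that the default region thresholds split the mask symmetrically.
    """
    rows, cols = matrix_shape
    if center_xy is None:
        center_xy = (247.5, 262.5) if matrix_shape == (512, 512) else (
            (cols - 1) / 2.0,
            (rows - 1) / 2.0,
        )
    cx, cy = center_xy
    scale = cols / 512.0
    a0, b0 = 120.0 * scale, 150.0 * scale  # semi-axes in pixels (x, y)
    taper = {n: f for n, f in zip(slice_nos, (0.85, 1.0, 1.0, 0.90))}
    hole_spacing = max(8, round(45 * scale))

    yy, xx = np.mgrid[0:rows, 0:cols]
    slices = []
    for n in slice_nos:
        f = taper.get(n, 1.0)
        a, b = a0 * f, b0 * f
        r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
        mask = r2 <= 1.0
        holes = []
        k = int(max(a, b) // hole_spacing) + 1
        offsets = [i * hole_spacing for i in range(-k, k + 1)]
        for dy in offsets:
            for dx in offsets:
                x, y = int(round(cx + dx)), int(round(cy + dy))
                # keep holes clearly interior so the grid resembles a
                # drilled slice phantom
                if ((x - cx) / (0.85 * a)) ** 2 + ((y - cy) / (0.85 * b)) ** 2 <= 1.0:
                    holes.append((x, y))
        slices.append(SliceGeometry(slice_no=n, brain_mask=mask, hole_positions=holes))

    eye_dy = -b0 - 2  # just in front of the forehead surface
    eye_dx = 55 * scale
    eyes = {
        "left_eye": (int(round(cx + eye_dx)), int(round(max(0, cy + eye_dy)))),
        "right_eye": (int(round(cx - eye_dx)), int(round(max(0, cy + eye_dy)))),
    }
    return PhantomGrid(
        slices=tuple(slices),
        eye_positions=eyes,
        pixel_spacing=pixel_spacing_mm,
        slice_thickness=slice_thickness_mm,
    )


def thresholds_for(grid: PhantomGrid, center_xy: tuple[float, float] | None = None) -> RegionThresholds:
    """Region thresholds that split a ``make_geometry`` grid through its
    mask centre, with the first half of the slices as the upper region."""
    if center_xy is None:
        # recover the mask centroid of the largest slice
        geom = max(grid.slices, key=lambda s: s.brain_mask.sum())
        yy, xx = np.nonzero(geom.brain_mask)
        center_xy = (float(xx.mean()), float(yy.mean()))
    cx, cy = center_xy
    nos = grid.slice_numbers
    half = len(nos) // 2
    return RegionThresholds(
        upper_slices=frozenset(nos[:half]),
        lower_slices=frozenset(nos[half:]),
        left_min_x=int(math.floor(cx)) + 1,
        right_max_x=int(math.floor(cx)),
        front_max_y=int(math.floor(cy)),
        rear_min_y=int(math.floor(cy)) + 1,
    )


# ---------------------------------------------------------------------------
# Ground-truth scatter field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatterFieldParams:
    """Parameters of the exponential ground-truth CC field.

    ``gradient_direction`` is the unit direction of dose fall-off in phantom
    coordinates (x, y, z in mm; z grows with slice number, i.e. downward),
    pointing away from the scatter source.  The default falls off toward the
    operator's right-upper-rear, so the field is highest left, lowest in the
    upper rear — the structure seen in measured operator head doses.
    ``reference_cc`` (µGy per Gy·cm²) is the field value at the grid centre.
    """

    reference_cc: float = 1.0
    gradient_direction: tuple[float, float, float] = (-0.67, 0.47, -0.58)
    # fall-off length tuned so the left/right region-mean ratio of the
    # default field approaches the factor ~2 seen in measured head doses
    attenuation_length: float = 60.0  # mm
    noise_cv: float = 0.02  # TLD read-out relative standard uncertainty
    seed: int = 0
    eye_factor: float = 4.0  # surface eye points see several-fold brain dose

    def __post_init__(self) -> None:
        if self.reference_cc <= 0:
            raise ValueError("reference_cc must be > 0")
        if self.attenuation_length <= 0:
            raise ValueError("attenuation_length must be > 0")
        if not (0 <= self.noise_cv < 1):
            raise ValueError("noise_cv must be in [0, 1)")
        g = np.asarray(self.gradient_direction, dtype=float)
        norm = np.linalg.norm(g)
        if norm == 0:
            raise ValueError("gradient_direction must be nonzero")
        object.__setattr__(self, "gradient_direction", tuple(g / norm))


class ScatterField:
    """Deterministic CC field over the phantom: (slice_no, pixel) -> CC."""

    def __init__(self, params: ScatterFieldParams, grid: PhantomGrid):
        self.params = params
        self.grid = grid
        nos = grid.slice_numbers
        # reference point: mask-centre of the grid at the mid slice level
        geom = max(grid.slices, key=lambda s: s.brain_mask.sum())
        yy, xx = np.nonzero(geom.brain_mask)
        self._r0 = np.array(
            [
                xx.mean() * grid.pixel_spacing,
                yy.mean() * grid.pixel_spacing,
                np.mean(nos) * grid.slice_thickness,
            ]
        )
        self._g = np.asarray(params.gradient_direction)
        self._eye_z = nos[min(1, len(nos) - 1)] * grid.slice_thickness

    def _cc_xyz(self, xyz: np.ndarray) -> np.ndarray:
        proj = (xyz - self._r0) @ self._g
        return self.params.reference_cc * np.exp(-proj / self.params.attenuation_length)

    def at(self, slice_no: int, pixel: tuple[float, float]) -> float:
        ps, st = self.grid.pixel_spacing, self.grid.slice_thickness
        return float(
            self._cc_xyz(np.array([pixel[0] * ps, pixel[1] * ps, slice_no * st]))
        )

    def at_array(self, slice_no: int, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        ps, st = self.grid.pixel_spacing, self.grid.slice_thickness
        xyz = np.column_stack(
            [np.asarray(xs) * ps, np.asarray(ys) * ps, np.full(len(xs), slice_no * st)]
        )
        return self._cc_xyz(xyz)

    def at_eye(self, label: str) -> float:
        x, y = self.grid.eye_positions[label]
        ps = self.grid.pixel_spacing
        return self.params.eye_factor * float(
            self._cc_xyz(np.array([x * ps, y * ps, self._eye_z]))
        )

    def __call__(self, slice_no: int, pixel: tuple[float, float]) -> float:
        return self.at(slice_no, pixel)


def make_scatter_field(params: ScatterFieldParams, grid: PhantomGrid) -> ScatterField:
    """Build the deterministic ground-truth CC field on a phantom grid."""
    return ScatterField(params, grid)


# ---------------------------------------------------------------------------
# TLD reading simulation
# ---------------------------------------------------------------------------

def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_tld_readings(
    field: ScatterField,
    grid: PhantomGrid,
    session: MeasurementSession,
    noise_cv: float = 0.0,
    seed: int = 0,
    calibration_spread: float = 0.05,
    energy_spread: float = 0.03,
) -> list[TLDReading]:
    """Two simulated TLD readings per hole and per eye for one session.

    Each raw reading is ``field(position) x P_KA / (calibration x
    energy-correction) x noise`` with unit-mean lognormal noise, so that the
    dosimetry chain recovers ``field(position) x P_KA`` exactly at zero
    noise.  Per-dosimeter factors are drawn uniformly around 1.  Fully
    reproducible for a fixed seed.
    """
    if session.total_pka <= 0:
        raise ValueError("session must have total_pka > 0")
    rng = np.random.default_rng(seed)
    readings: list[TLDReading] = []
    index = grid.position_index()
    for position_id, (slice_no, (x, y)) in index.items():
        if slice_no is None:
            true_cc = field.at_eye(position_id)
        else:
            true_cc = field.at(slice_no, (x, y))
        true_dose = true_cc * session.total_pka  # µGy
        calib = 1.0 + rng.uniform(-calibration_spread, calibration_spread, 2)
        energy = 1.0 + rng.uniform(-energy_spread, energy_spread, 2)
        noise = _lognormal_factors(rng, noise_cv, 2)
        for k in range(2):
            raw = true_dose * noise[k] / (calib[k] * energy[k])
            readings.append(
                TLDReading(
                    dosimeter_id=f"{session.projection_name}:{position_id}:{'ab'[k]}",
                    position_id=position_id,
                    raw_reading=raw,
                    calibration_factor=calib[k],
                    energy_correction=energy[k],
                    slice_no=slice_no,
                )
            )
    return readings


# ---------------------------------------------------------------------------
# Measurement-session defaults
# ---------------------------------------------------------------------------

# projection, modality, rotation, angulation, kVp, SID cm, total P_KA Gy·cm²
_SESSION_SPECS = (
    ("PA", "acquisition", 0, 0, 69, 100, 420.0),
    ("LAO30", "acquisition", 30, 0, 74, 103, 500.0),
    ("RAO30", "acquisition", -30, 0, 68, 102, 430.0),
    ("CAUD30", "acquisition", 0, -30, 70, 108, 450.0),
    ("CRAN30", "acquisition", 0, 30, 71, 103, 460.0),
    ("LAO30/CAUD30", "acquisition", 30, -30, 71, 108, 470.0),
    ("LAO30/CRAN30", "acquisition", 30, 30, 71, 106, 480.0),
    ("RAO30/CAUD30", "acquisition", -30, -30, 72, 113, 490.0),
    ("RAO30/CRAN30", "acquisition", -30, 30, 70, 112, 440.0),
    ("LAO30_XL", "acquisition", 30, 0, 89, 107, 410.0),
    ("LAO30_FL", "fluoroscopy", 30, 0, 88, 102, 310.0),
)


def default_sessions() -> list[MeasurementSession]:
    """The eleven measurement configurations: nine standard projections in
    acquisition mode plus the extra-large-patient and fluoroscopy variants
    of LAO30, with session P_KA values in the 300-500 Gy·cm² range."""
    return [
        MeasurementSession(
            projection_name=name,
            modality=modality,
            rotation_deg=rot,
            angulation_deg=ang,
            total_pka=pka,
            tube_kvp=kvp,
            sid_cm=sid,
            filtration="4.5 mm Al + 0.4 mm Cu" if modality == "fluoroscopy" else "4.5 mm Al + 0.1 mm Cu",
        )
        for name, modality, rot, ang, kvp, sid, pka in _SESSION_SPECS
    ]


# ---------------------------------------------------------------------------
# Clinical event log
# ---------------------------------------------------------------------------

#: Per-bin angle weights (rotation, angulation bin centres) plus the mass of
#: events outside ±45° on at least one axis.  PA and LAO bins dominate, as
#: they do in cardiac practice.
DEFAULT_ANGLE_WEIGHTS: dict[object, float] = {
    (0, 0): 0.31,
    (30, 0): 0.20,
    (-30, 0): 0.07,
    (0, 30): 0.08,
    (0, -30): 0.07,
    (30, 30): 0.06,
    (30, -30): 0.10,
    (-30, 30): 0.05,
    (-30, -30): 0.035,
    "out_of_range": 0.025,
}


@dataclass(frozen=True)
class EventLogParams:
    """Parameters of the simulated dose-monitoring-system export.

    Defaults emulate a two-month cardiac export: 25 552 irradiation events
    from 249 procedures, 64.1% of the in-range P_KA from fluoroscopy, and
    2.5% of events outside ±45°.  P_KA per event is lognormal per modality
    (``pka_lognormal`` maps modality to (median Gy·cm², log-sigma)).
    """

    n_events: int = 25_552
    n_procedures: int = 249
    fluoro_pka_fraction: float = 0.641
    angle_weights: Mapping[object, float] = field(
        default_factory=lambda: dict(DEFAULT_ANGLE_WEIGHTS)
    )
    pka_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"fluoroscopy": (0.10, 1.0), "acquisition": (0.25, 0.8)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not (0 <= self.fluoro_pka_fraction <= 1):
            raise ValueError("fluoro_pka_fraction must be in [0, 1]")
        w = np.array(list(self.angle_weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("angle weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"angle weights must sum to 1, got {w.sum()}")


def _modality_probability(params: EventLogParams) -> float:
    """Per-event fluoroscopy probability such that the EXPECTED fluoroscopy
    share of total P_KA equals the target fraction."""
    med_f, sig_f = params.pka_lognormal["fluoroscopy"]
    med_a, sig_a = params.pka_lognormal["acquisition"]
    mean_f = med_f * math.exp(0.5 * sig_f**2)
    mean_a = med_a * math.exp(0.5 * sig_a**2)
    f = params.fluoro_pka_fraction
    if f == 0:
        return 0.0
    if f == 1:
        return 1.0
    return f * mean_a / ((1 - f) * mean_f + f * mean_a)


def simulate_event_log(params: EventLogParams) -> pd.DataFrame:
    """One row per irradiation event: procedure_id, modality, rotation_deg,
    angulation_deg, pka_gycm2."""
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    keys = list(params.angle_weights.keys())
    probs = np.array([params.angle_weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    choice = rng.choice(len(keys), size=n, p=probs)

    rot = np.empty(n)
    ang = np.empty(n)
    for i, key in enumerate(keys):
        sel = choice == i
        m = int(sel.sum())
        if m == 0:
            continue
        if key == "out_of_range":
            # one axis beyond the limit, the other anywhere in range
            out_axis = rng.integers(0, 2, m).astype(bool)
            out_val = rng.uniform(46.0, 90.0, m) * rng.choice([-1.0, 1.0], m)
            in_val = rng.uniform(-45.0, 45.0, m)
            rot[sel] = np.where(out_axis, out_val, in_val)
            ang[sel] = np.where(out_axis, in_val, out_val)
        else:
            cr, ca = key  # type: ignore[misc]
            rot[sel] = cr + rng.uniform(-15.0, 15.0, m)
            ang[sel] = ca + rng.uniform(-15.0, 15.0, m)

    q = _modality_probability(params)
    is_fluoro = rng.uniform(size=n) < q
    pka = np.empty(n)
    for modality, sel in (("fluoroscopy", is_fluoro), ("acquisition", ~is_fluoro)):
        med, sig = params.pka_lognormal[modality]
        pka[sel] = rng.lognormal(mean=math.log(med), sigma=sig, size=int(sel.sum()))

    proc = rng.integers(0, params.n_procedures, n)
    return pd.DataFrame(
        {
            "procedure_id": [f"P{int(i):03d}" for i in proc],
            "modality": np.where(is_fluoro, "fluoroscopy", "acquisition"),
            "rotation_deg": rot,
            "angulation_deg": ang,
            "pka_gycm2": pka,
        }
    )
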