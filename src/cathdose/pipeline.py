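"""High-level stage drivers wiring the pipeline together.

Stages (each a plain function over the library modules):

1. ``simulate_inputs``   — write synthetic geometry, TLD readings, clinical
                           event log and workload to an input directory.
2. ``build_cc_table``    — dosimetry + mapping: one CC-table row (regions +
                           eyes) per measurement session.
3. ``run_binning``       — filter and bin the clinical event log, P_KA
                           fractions per (projection, modality).
4. ``run_weighting``     — fluoroscopy scaling + exposure-weighted CC row.
5. ``run_projection``    — annual doses, years-to-threshold, shielding.

All interchange is plain text (CSV / JSON / YAML) so outputs diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, binning, mapping, synthetic, tld
from .geometry import PhantomGrid, RegionThresholds, load_geometry, save_geometry
from .projection import (
    DoseReport,
    ShieldingScenario,
    WorkloadItem,
    WorkloadSpec,
    build_dose_report,
)
from .reference import MEASURED_CC_TABLE
from .weighting import ModalityCCSet, weighted_cc_row

__all__ = [
    "simulate_inputs",
    "compute_session_ccs",
    "build_cc_table",
    "run_binning",
    "run_weighting",
    "run_projection",
    "load_sessions",
    "load_workload",
    "save_workload",
    "write_manifest",
]

SESSIONS_FILE = "sessions.csv"
EVENTS_FILE = "events.csv"
GEOMETRY_FILE = "geometry.json"
WORKLOAD_FILE = "workload.yaml"


def _readings_filename(projection_name: str) -> str:
    return "readings_" + projection_name.replace("/", "-") + ".csv"


# ---------------------------------------------------------------------------
# Stage 1: synthetic inputs
# ---------------------------------------------------------------------------

def simulate_inputs(
    outdir: str | Path,
    seed: int = 0,
    matrix_shape: tuple[int, int] = (512, 512),
    noise_cv: float = 0.02,
    n_events: int = 25_552,
) -> dict[str, Path]:
    """Generate and write every input the pipeline needs.

    The ground-truth scatter field of each session is anchored at the
    published whole-brain CC of its projection, so synthetic doses have
    realistic magnitudes; the field's spatial structure (left > right,
    lower > upper, front > rear) is the generator default.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = synthetic.make_geometry(matrix_shape=matrix_shape)
    save_geometry(grid, outdir / GEOMETRY_FILE)

    sessions = synthetic.default_sessions()
    rows = []
    for i, session in enumerate(sessions):
        params = synthetic.ScatterFieldParams(
            reference_cc=float(MEASURED_CC_TABLE.loc[session.projection_name, "whole"]),
            noise_cv=noise_cv,
            seed=seed + i,
        )
        field = synthetic.make_scatter_field(params, grid)
        readings = synthetic.simulate_tld_readings(
            field, grid, session, noise_cv=noise_cv, seed=seed + i
        )
        tld.write_readings_csv(readings, outdir / _readings_filename(session.projection_name))
        rows.append(
            {
                "projection_name": session.projection_name,
                "modality": session.modality,
                "rotation_deg": session.rotation_deg,
                "angulation_deg": session.angulation_deg,
                "total_pka": session.total_pka,
                "tube_kvp": session.tube_kvp,
                "sid_cm": session.sid_cm,
                "filtration": session.filtration,
                "readings_file": _readings_filename(session.projection_name),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / SESSIONS_FILE, index=False)

    events = synthetic.simulate_event_log(
        synthetic.EventLogParams(n_events=n_events, seed=seed + 1000)
    )
    events.to_csv(outdir / EVENTS_FILE, index=False)

    save_workload(_default_workload(), outdir / WORKLOAD_FILE)
    return {
        "geometry": outdir / GEOMETRY_FILE,
        "sessions": outdir / SESSIONS_FILE,
        "events": outdir / EVENTS_FILE,
        "workload": outdir / WORKLOAD_FILE,
    }


def _default_workload() -> WorkloadSpec:
    from .reference import DEFAULT_WORKLOAD

    return DEFAULT_WORKLOAD


def load_sessions(indir: str | Path) -> list[tld.MeasurementSession]:
    """Read sessions.csv plus the per-session readings CSVs."""
    indir = Path(indir)
    frame = pd.read_csv(indir / SESSIONS_FILE)
    sessions = []
    for _, row in frame.iterrows():
        readings = tld.read_readings_csv(indir / row["readings_file"])
        sessions.append(
            tld.MeasurementSession(
                projection_name=row["projection_name"],
                modality=row["modality"],
                rotation_deg=float(row["rotation_deg"]),
                angulation_deg=float(row["angulation_deg"]),
                total_pka=float(row["total_pka"]),
                readings=readings,
                tube_kvp=row.get("tube_kvp"),
                sid_cm=row.get("sid_cm"),
                filtration=row.get("filtration"),
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Stage 2: dosimetry + mapping
# ---------------------------------------------------------------------------

def compute_session_ccs(
    grid: PhantomGrid,
    session: tld.MeasurementSession,
    thresholds: RegionThresholds,
    settings: mapping.InterpolationSettings | None = None,
) -> tuple[mapping.CCTableRow, list[mapping.CCMap]]:
    """Full dosimetry chain for one session: readings -> position doses ->
    CCs -> interpolated maps -> region means and eye CCs."""
    doses = tld.pair_position_doses(session)
    ccs = tld.compute_position_ccs(doses, session.total_pka)
    hole_ccs = [c for c in ccs if c.slice_no is not None]
    maps = mapping.interpolate_grid(hole_ccs, grid, settings)
    by_id = {d.position_id: d for d in doses}
    left_cc, right_cc = mapping.eye_cc(
        by_id["left_eye"], by_id["right_eye"], session.total_pka
    )
    region_vals = {
        region: mapping.region_mean_cc(maps, region, thresholds, grid)
        for region in mapping.BRAIN_REGIONS
    }
    row = mapping.CCTableRow(
        configuration=session.projection_name,
        left_eye=left_cc,
        right_eye=right_cc,
        **region_vals,
    )
    return row, maps


def build_cc_table(
    grid: PhantomGrid,
    sessions: Sequence[tld.MeasurementSession],
    thresholds: RegionThresholds,
    settings: mapping.InterpolationSettings | None = None,
) -> pd.DataFrame:
    rows = [
        compute_session_ccs(grid, s, thresholds, settings)[0] for s in sessions
    ]
    return mapping.assemble_cc_table(rows)


# ---------------------------------------------------------------------------
# Stage 3: clinical binning
# ---------------------------------------------------------------------------

def run_binning(
    events: pd.DataFrame, limit_deg: float = 45.0
) -> tuple[binning.FilterResult, binning.BinTable, dict[tuple[str, str], float]]:
    """Filter, bin and normalize a clinical event table; returns the filter
    stats, the bin table and the fractions keyed by (projection, modality)."""
    result = binning.filter_events(events, limit_deg)
    table = binning.bin_events(result.retained, out_of_range_pka=result.out_of_range_pka)
    fractions = binning.fractions_by_projection(binning.bin_fractions(table))
    return result, table, fractions


# ---------------------------------------------------------------------------
# Stage 4: weighting
# ---------------------------------------------------------------------------

def run_weighting(
    cc_table: pd.DataFrame,
    fractions: Mapping[tuple[str, str], float],
    reference_projection: str = "LAO30",
    fluoro_row: str = "LAO30_FL",
) -> tuple[ModalityCCSet, dict[str, float]]:
    """Scale fluoroscopy CCs from the single fluoroscopy measurement and
    weight all cells by their clinical P_KA fractions.

    The extra-large-patient row (``*_XL``) is a sensitivity measurement and
    is excluded from weighting.
    """
    acq_rows = [
        r
        for r in cc_table.index
        if not (r.endswith("_XL") or r.endswith("_FL"))
    ]
    acq_table = cc_table.loc[acq_rows]
    cc_set = ModalityCCSet.from_acquisition_table(
        acq_table,
        fluoro_reference=cc_table.loc[fluoro_row].to_dict(),
        reference_projection=reference_projection,
    )
    weighted = weighted_cc_row(cc_set, fractions)
    return cc_set, weighted


# ---------------------------------------------------------------------------
# Stage 5: projection
# ---------------------------------------------------------------------------

def run_projection(
    weighted_ccs: Mapping[str, float],
    workload: WorkloadSpec,
    scenarios: Sequence[ShieldingScenario] = (),
) -> DoseReport:
    return build_dose_report(weighted_ccs, workload, scenarios)


# ---------------------------------------------------------------------------
# Workload + manifest I/O
# ---------------------------------------------------------------------------

def save_workload(workload: WorkloadSpec, path: str | Path) -> None:
    doc = {
        "procedures": [
            {
                "procedure_type": i.procedure_type,
                "annual_count": i.annual_count,
                "mean_pka_gycm2": i.mean_pka,
            }
            for i in workload.items
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_workload(path: str | Path) -> WorkloadSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return WorkloadSpec(
        items=tuple(
            WorkloadItem(
                procedure_type=p["procedure_type"],
                annual_count=int(p["annual_count"]),
                mean_pka=float(p["mean_pka_gycm2"]),
            )
            for p in doc["procedures"]
        )
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    stage: str,
    config: Mapping,
    inputs: Sequence[Path] = (),
) -> Path:
    """Record how a stage's outputs were produced: config, package version
    and input checksums."""
    outdir = Path(outdir)
    doc = {
        "stage": stage,
        "package_version": __version__,
        "config": dict(config),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path
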