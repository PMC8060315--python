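"""File formats, run configuration, and the end-to-end pipeline driver.

All tabular outputs are UTF-8 CSV with comma separators, ``.`` decimals,
LF line endings, and a mandatory header.  Landmark files carry one named 3D
point per row (mm, thoracic frame); centerline points use the component
name suffixed with a zero-padded index (``bbh_01`` ...), everything else is
a landmark proper.  Schema violations raise; nothing is silently coerced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__ as _pkg_version
from .defaults import CARDIAC_ANGLE_STATS, PAIR_IDS
from .exceptions import PipelineStageError, SchemaError
from .frames import DEFAULT_ROTATION_ORDER
from .geometry import ANGLE_COLUMNS, CCSGeometry, measure_all_angles
from .regression import InclinationModel, models_to_frame, recover_parameters
from .simulate import (
    SimulationGrid,
    classify_all,
    simulate_transformation,
    standing_lying_comparison,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "write_angle_report",
    "measure_cohort",
    "export_centerlines_obj",
    "GridConfig",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]

_LANDMARK_HEADER = ["name", "x_mm", "y_mm", "z_mm"]
_CENTERLINE_RE = re.compile(r"^(?P<component>.+)_(?P<index>\d{2,})$")


def read_landmarks(path) -> CCSGeometry:
    """Read one heart's geometry from a landmark CSV.

    The heart id is the file stem.  Rows whose name ends in a zero-padded
    numeric suffix are collected into component centerlines (in index
    order); all other rows become landmarks.

    Raises
    ------
    SchemaError
        On a missing/incorrect header, malformed row (with its line
        number), non-finite coordinates, or duplicate names.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or [c.strip() for c in lines[0].split(",")] != _LANDMARK_HEADER:
        raise SchemaError(
            f"{path}: first line must be the header {','.join(_LANDMARK_HEADER)!r}"
        )
    landmarks: dict[str, np.ndarray] = {}
    centerline_pts: dict[str, list[tuple[int, np.ndarray]]] = {}
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [c.strip() for c in line.split(",")]
        if len(fields) != 4:
            raise SchemaError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        name = fields[0]
        if not name:
            raise SchemaError(f"{path}:{lineno}: empty landmark name")
        if name in seen:
            raise SchemaError(f"{path}:{lineno}: duplicate landmark name {name!r}")
        seen.add(name)
        try:
            xyz = np.array([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: non-numeric coordinate ({exc})") from None
        if not np.all(np.isfinite(xyz)):
            raise SchemaError(f"{path}:{lineno}: non-finite coordinate")
        m = _CENTERLINE_RE.match(name)
        if m:
            centerline_pts.setdefault(m["component"], []).append((int(m["index"]), xyz))
        else:
            landmarks[name] = xyz
    centerlines = {
        comp: np.array([p for _, p in sorted(pts, key=lambda t: t[0])])
        for comp, pts in centerline_pts.items()
    }
    return CCSGeometry(heart_id=path.stem, landmarks=landmarks, centerlines=centerlines)


def write_landmarks(geometry: CCSGeometry, path) -> Path:
    """Write one heart's geometry as a landmark CSV.

    Coordinates are printed at 6 decimals and rows are sorted by name, so
    two writes of the same geometry are byte-identical.
    """
    path = Path(path)
    rows: dict[str, np.ndarray] = dict(geometry.landmarks)
    for comp, pts in geometry.centerlines.items():
        width = max(2, len(str(len(pts))))
        for i, p in enumerate(pts, start=1):
            rows[f"{comp}_{i:0{width}d}"] = p
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_LANDMARK_HEADER) + "\n")
        for name in sorted(rows):
            x, y, z = rows[name]
            fh.write(f"{name},{x:.6f},{y:.6f},{z:.6f}\n")
    return path


def write_angle_report(table: pd.DataFrame, path) -> Path:
    """Write an angle report CSV (degrees, 4 decimal places)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["heart_id"] + [c for c in ANGLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.4f", lineterminator="\n")
    return path


def read_angle_report(path) -> pd.DataFrame:
    """Read an angle report CSV, checking the required columns."""
    table = pd.read_csv(path)
    missing = [c for c in ("heart_id", "X_sgt", "X_frt", "X_hzt") if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: angle report is missing columns {missing}")
    return table


def measure_cohort(geometries: list[CCSGeometry]) -> pd.DataFrame:
    """Measure all projection angles for a list of hearts (one row each)."""
    rows = []
    for geom in geometries:
        x, ccs = measure_all_angles(geom)
        row = {"heart_id": geom.heart_id, **x.as_dict(), **ccs.as_dict()}
        rows.append({k: (np.nan if v is None else v) for k, v in row.items()})
    return pd.DataFrame(rows)


def export_centerlines_obj(geometry: CCSGeometry, path) -> Path:
    """Export component centerlines as OBJ polylines (for external viewers)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"o {geometry.heart_id}\n")
        offset = 1
        for comp in sorted(geometry.centerlines):
            pts = geometry.centerlines[comp]
            fh.write(f"g {comp}\n")
            for p in pts:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            idx = " ".join(str(offset + i) for i in range(len(pts)))
            fh.write(f"l {idx}\n")
            offset += len(pts)
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class GridConfig(BaseModel):
    """Simulation-grid section of the run configuration."""

    model_config = ConfigDict(extra="forbid")

    k_values: list[float] = [-2.0, -1.0, 0.0, 1.0, 2.0]
    step_sgt: float = CARDIAC_ANGLE_STATS["X_sgt"][1]
    step_frt: float = CARDIAC_ANGLE_STATS["X_frt"][1]
    step_hzt: float = CARDIAC_ANGLE_STATS["X_hzt"][1]

    def to_grid(self) -> SimulationGrid:
        return SimulationGrid(
            k_values=tuple(self.k_values),
            step_sgt=self.step_sgt,
            step_frt=self.step_frt,
            step_hzt=self.step_hzt,
        )


class RunConfig(BaseModel):
    """Full pipeline configuration; round-trips losslessly through YAML.

    Unknown keys are rejected rather than ignored so that typos fail fast.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n: int = 23
    zero_noise: bool = False
    simulation_mode: str = "regression"
    rotation_order: list[str] = list(DEFAULT_ROTATION_ORDER)
    recover_replicates: int = 200
    export_obj: bool = False
    output_dir: str = "ccsmorph_run"
    verbosity: int = 0
    grid: GridConfig = GridConfig()

    @field_validator("simulation_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("rigid", "regression"):
            raise ValueError("simulation_mode must be 'rigid' or 'regression'")
        return v

    @field_validator("rotation_order")
    @classmethod
    def _check_order(cls, v: list[str]) -> list[str]:
        if sorted(v) != sorted(DEFAULT_ROTATION_ORDER):
            raise ValueError(f"rotation_order must permute {DEFAULT_ROTATION_ORDER}")
        return v

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML (or JSON; YAML is a superset) config file."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config root must be a mapping")
        return cls.model_validate(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: provenance plus per-stage output files."""

    package_version: str
    config_hash: str
    seed: int
    started_utc: str
    finished_utc: Optional[str] = None
    outputs: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _provenance_frame(cohort: list[CCSGeometry]) -> pd.DataFrame:
    rows = []
    for geom in cohort:
        prov = geom.provenance
        row = {"heart_id": geom.heart_id, "seed": prov.get("seed")}
        row.update({k: v for k, v in prov.get("true_angles", {}).items()})
        row.update(
            {f"resid_{k}_deg": v for k, v in prov.get("fit_residuals_deg", {}).items()}
        )
        row.update(prov.get("dims", {}))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, output_dir=None) -> RunManifest:
    """Execute generate -> measure -> fit -> simulate -> recover.

    Everything is reproducible from the config and its seed; timestamps are
    confined to the manifest.  A stage failure aborts the run with the
    stage name and cause; files already written by the failing stage are
    renamed with a ``.partial`` suffix.
    """
    from . import synth  # deferred: synth imports regression

    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.DEBUG if config.verbosity else logging.INFO)

    manifest = RunManifest(
        package_version=_pkg_version,
        config_hash=config.config_hash(),
        seed=config.seed,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )
    if not config.zero_noise:
        manifest.warnings.append(
            "alpha_hzt: printed intercept is inconsistent with printed means; "
            "generator uses the through-the-means intercept (flagged)"
        )

    stage_files: list[Path] = []

    def _record(stage: str, path: Path) -> Path:
        stage_files.append(path)
        manifest.outputs.setdefault(stage, []).append(str(path))
        return path

    current_stage = "generate"
    try:
        # --- generate -----------------------------------------------------
        params = synth.CohortParams.default(
            n=config.n, seed=config.seed, zero_noise=config.zero_noise
        )
        cohort = synth.sample_cohort(params)
        _record("generate", config.to_yaml(out / "config_snapshot.yaml"))
        geo_dir = out / "geometries"
        for geom in cohort:
            _record("generate", write_landmarks(geom, geo_dir / f"{geom.heart_id}.csv"))
            if config.export_obj:
                _record(
                    "generate",
                    export_centerlines_obj(geom, geo_dir / f"{geom.heart_id}.obj"),
                )
        prov = _provenance_frame(cohort)
        prov_path = out / "cohort_provenance.csv"
        prov.to_csv(prov_path, index=False, float_format="%.6f", lineterminator="\n")
        _record("generate", prov_path)
        logger.info("generate: n=%d seed=%d zero_noise=%s", config.n, config.seed, config.zero_noise)

        # --- measure ------------------------------------------------------
        current_stage = "measure"
        stage_files = []
        reread = [read_landmarks(p) for p in sorted(geo_dir.glob("H*.csv"))]
        measured = measure_cohort(reread)
        _record("measure", write_angle_report(measured, out / "angles_measured.csv"))
        generated = prov[["heart_id", *list(CARDIAC_ANGLE_STATS), *PAIR_IDS]]
        _record("measure", write_angle_report(generated, out / "angles_generated.csv"))
        logger.info("measure: %d hearts", len(reread))

        # --- fit ----------------------------------------------------------
        # Fitted on the generated angle table: the geometric reconstruction
        # is exact only for internally consistent angle triples, so the
        # generated angles are the statistically faithful cohort record.
        current_stage = "fit"
        stage_files = []
        results = InclinationModel(generated).fit()
        reg_path = out / "regressions.csv"
        models_to_frame(results.models).to_csv(
            reg_path, index=False, float_format="%.6f", lineterminator="\n"
        )
        _record("fit", reg_path)
        logger.info("fit: %d pairs on n=%d", len(results.models), results.nobs)

        # --- simulate -----------------------------------------------------
        current_stage = "simulate"
        stage_files = []
        base = synth.default_canonical_geometry()
        grid = config.grid.to_grid()
        traj = simulate_transformation(
            base,
            grid,
            mode=config.simulation_mode,
            rotation_order=tuple(config.rotation_order),
        )
        traj_path = out / "trajectory.csv"
        traj.table.to_csv(traj_path, index=False, float_format="%.6f", lineterminator="\n")
        _record("simulate", traj_path)
        dir_path = out / "directions.csv"
        classify_all(traj).to_csv(dir_path, index=False, lineterminator="\n")
        _record("simulate", dir_path)
        comparison = standing_lying_comparison(base, grid, mode=config.simulation_mode)
        disp_path = out / "standing_lying_displacements.csv"
        pd.DataFrame(
            sorted(comparison.displacements.items()), columns=["landmark", "displacement_mm"]
        ).to_csv(disp_path, index=False, float_format="%.6f", lineterminator="\n")
        _record("simulate", disp_path)
        logger.info("simulate: mode=%s positions=%d", config.simulation_mode, traj.n_positions)

        # --- recover ------------------------------------------------------
        current_stage = "recover"
        stage_files = []
        report = recover_parameters(
            params, replicates=config.recover_replicates, seed=config.seed
        )
        rec_path = out / "recovery_report.csv"
        report.table.to_csv(rec_path, index=False, float_format="%.6f", lineterminator="\n")
        _record("recover", rec_path)
        logger.info(
            "recover: %d replicates of n=%d", config.recover_replicates, params.n
        )
    except Exception as exc:
        for p in stage_files:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise PipelineStageError(current_stage, exc) from exc

    manifest.finished_utc = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
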