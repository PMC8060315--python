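"""Stepwise standing-to-lying posture simulation.

The heart is rotated from its mean pose through a grid of composed
three-axis rotations, one position per multiplier ``k`` in units of the
per-axis cohort SD (``mean + k * SD``; standing is ``k = -1``, lying
``k = +1``).  At every position the projection angles of the cardiac axis
and the conduction components are recorded, and each component/plane pair
is classified as rotating *concomitantly* with the heart (positive slope of
component angle against cardiac angle), *counter* to it (negative slope),
or *flat*.

Two simulation modes are provided because they answer different questions:

``rigid``
    The whole heart, conduction system included, rotates as one rigid body
    (what a 3D viewer rotation physically does); component angles are
    re-measured from the rotated geometry.
``regression``
    Component angles at each pose are predicted from the published
    per-plane regression slopes, anchored at the base measurement (what the
    per-plane scatterplot fits describe).  This is the mode in which the
    frontal proximal-AVCA pair counter-rotates (slope -0.733) while every
    sinus-node pair is concomitant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .defaults import CARDIAC_ANGLE_STATS, PAIR_IDS, PAIR_TO_CARDIAC
from .exceptions import DegenerateProjectionError, InvalidInputError, InvalidParamsError
from .frames import DEFAULT_ROTATION_ORDER, compose_rotation_sequence
from .geometry import ANGLE_COLUMNS, CCSGeometry, measure_all_angles
from .regression import RegressionModel

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationGrid",
    "RotationTrajectory",
    "StandingLyingReport",
    "stepwise_positions",
    "simulate_transformation",
    "classify_rotation_direction",
    "classify_all",
    "standing_lying_comparison",
]

#: |slope| below this (deg/deg) classifies as "flat"; a numerical guard.
FLAT_THRESHOLD = 0.01

#: component name -> angle column per plane.
COMPONENT_COLUMNS: dict[str, dict[str, str]] = {
    "cardiac": {"sagittal": "X_sgt", "frontal": "X_frt", "horizontal": "X_hzt"},
    "sn": {"sagittal": "alpha_sgt", "frontal": "alpha_frt", "horizontal": "alpha_hzt"},
    "avca": {"sagittal": "beta_sgt", "frontal": "beta_frt", "horizontal": "beta_hzt"},
    "rbb": {"horizontal": "gamma"},
    "lbb": {"horizontal": "delta"},
}

#: Landmarks whose displacement summarises AV-conduction-axis motion.
AVCA_LANDMARKS = ("compact_node_end", "rbb_branch_point", "rbb_distal_point")


@dataclass(frozen=True)
class SimulationGrid:
    """Rotation grid: SD multipliers and per-axis steps (degrees).

    Defaults are the five published positions ``k = -2 .. +2`` with the
    cohort SDs of the three cardiac angles as step sizes.  A step of zero
    switches that axis off (single-axis experiments).
    """

    k_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    step_sgt: float = CARDIAC_ANGLE_STATS["X_sgt"][1]
    step_frt: float = CARDIAC_ANGLE_STATS["X_frt"][1]
    step_hzt: float = CARDIAC_ANGLE_STATS["X_hzt"][1]
    base_geometry_id: Optional[str] = None

    def __post_init__(self):
        ks = np.asarray(self.k_values, dtype=float)
        if ks.size < 1 or not np.all(np.isfinite(ks)):
            raise InvalidParamsError("k_values must be a non-empty finite sequence")
        if ks.size > 1 and not np.all(np.diff(ks) > 0):
            raise InvalidParamsError("k_values must be strictly increasing")
        for name in ("step_sgt", "step_frt", "step_hzt"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParamsError(f"{name} must be finite and >= 0")

    @property
    def steps(self) -> tuple[float, float, float]:
        return (self.step_sgt, self.step_frt, self.step_hzt)


def stepwise_positions(grid: SimulationGrid) -> list[tuple[float, float, float]]:
    """Rotation increments per position, relative to the ``k = 0`` pose.

    Position ``k`` maps to ``(k * step_sgt, k * step_frt, k * step_hzt)``:
    increments are absolute offsets from the mean pose, not cumulative
    steps between consecutive positions.
    """
    return [
        (k * grid.step_sgt, k * grid.step_frt, k * grid.step_hzt) for k in grid.k_values
    ]


@dataclass
class RotationTrajectory:
    """Measured (or predicted) angle sequences across the rotation grid.

    ``table`` has one row per position with the SD multiplier ``k``, the
    applied increments, the nominal cardiac angles (base measurement plus
    increment), and the per-component angle columns.  Rows where a
    projection degenerated hold NaN for the affected angles.
    """

    grid: SimulationGrid
    mode: str
    base_geometry: CCSGeometry
    table: pd.DataFrame

    @property
    def n_positions(self) -> int:
        return len(self.table)


def _measured_angle_row(geometry: CCSGeometry) -> dict[str, float]:
    x, ccs = measure_all_angles(geometry)
    row = {**x.as_dict(), **ccs.as_dict()}
    return {k: (np.nan if v is None else v) for k, v in row.items()}


def simulate_transformation(
    base_geometry: CCSGeometry,
    grid: SimulationGrid | None = None,
    mode: str = "rigid",
    regression_models: Mapping[str, RegressionModel] | None = None,
    rotation_order: tuple[str, ...] = DEFAULT_ROTATION_ORDER,
) -> RotationTrajectory:
    """Rotate a heart through the grid and record its angle trajectories.

    In ``rigid`` mode the composed rotation (sagittal, then frontal, then
    horizontal, about the fixed thoracic axes) is applied to the whole
    geometry and all angles are re-measured.  In ``regression`` mode the
    cardiac angles are measured from the rotated geometry while each
    component angle is predicted from its regression slope anchored at the
    base measurement, so both modes coincide at ``k = 0``.

    A degenerate projection at some position is recorded as NaN with a
    warning rather than aborting the trajectory.
    """
    if grid is None:
        grid = SimulationGrid()
    if mode not in ("rigid", "regression"):
        raise InvalidInputError(f"mode must be 'rigid' or 'regression', got {mode!r}")
    if mode == "regression" and regression_models is None:
        from .synth import printed_regression_models

        regression_models = printed_regression_models()

    base_row = _measured_angle_row(base_geometry)
    rows = []
    for (inc_s, inc_f, inc_h), k in zip(stepwise_positions(grid), grid.k_values):
        rot = compose_rotation_sequence(inc_s, inc_f, inc_h, order=rotation_order)
        geom_k = base_geometry.transformed(rot)
        row = {
            "position": len(rows) + 1,
            "k": k,
            "inc_sgt": inc_s,
            "inc_frt": inc_f,
            "inc_hzt": inc_h,
            "nominal_X_sgt": base_row["X_sgt"] + inc_s,
            "nominal_X_frt": base_row["X_frt"] + inc_f,
            "nominal_X_hzt": base_row["X_hzt"] + inc_h,
        }
        try:
            measured = _measured_angle_row(geom_k)
        except DegenerateProjectionError as exc:
            logger.warning("position k=%g: %s; angles recorded as NaN", k, exc)
            measured = {c: np.nan for c in ANGLE_COLUMNS}
        if mode == "regression":
            for pair in PAIR_IDS:
                if not np.isfinite(base_row[pair]):
                    measured[pair] = np.nan
                    continue
                m = regression_models[pair]
                xcol = PAIR_TO_CARDIAC[pair]
                measured[pair] = base_row[pair] + m.slope * (measured[xcol] - base_row[xcol])
        row.update(measured)
        rows.append(row)
    return RotationTrajectory(
        grid=grid, mode=mode, base_geometry=base_geometry, table=pd.DataFrame(rows)
    )


def classify_rotation_direction(
    trajectory: RotationTrajectory, component: str, plane: str
) -> str:
    """Classify one component/plane pair as concomitant, counter, or flat.

    The sign of the least-squares slope of the component angle against the
    cardiac angle in the same plane decides: positive means the component
    rotates with the heart (concomitant), negative against it (counter);
    |slope| below 0.01 deg/deg is reported as flat.
    """
    try:
        ycol = COMPONENT_COLUMNS[component][plane]
    except KeyError:
        raise InvalidInputError(
            f"no angle is defined for component {component!r} in the {plane} plane"
        ) from None
    xcol = COMPONENT_COLUMNS["cardiac"][plane]
    sub = trajectory.table[[xcol, ycol]].dropna()
    if len(sub) < 2:
        raise InvalidInputError(
            f"need >= 2 valid positions to classify {component}/{plane}"
        )
    x = sub[xcol].to_numpy()
    y = sub[ycol].to_numpy()
    if np.ptp(x) < 1e-12:
        return "flat"
    slope = np.polyfit(x, y, 1)[0]
    if abs(slope) < FLAT_THRESHOLD:
        return "flat"
    return "concomitant" if slope > 0 else "counter"


def classify_all(trajectory: RotationTrajectory) -> pd.DataFrame:
    """Classification table over all measurable component/plane pairs."""
    rows = []
    for component, planes in COMPONENT_COLUMNS.items():
        if component == "cardiac":
            continue
        for plane, col in planes.items():
            if trajectory.table[col].dropna().empty:
                continue
            rows.append(
                {
                    "component": component,
                    "plane": plane,
                    "classification": classify_rotation_direction(trajectory, component, plane),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StandingLyingReport:
    """Paired standing (k = -1) vs lying (k = +1) comparison.

    ``angles`` holds the two pose rows (nominal and measured angles);
    ``displacements`` the landmark motions between the two poses in mm,
    including ``sn_head`` (sinus-node head) and ``avca_max`` (largest
    motion along the AV conduction axis); ``classifications`` come from the
    full-grid trajectory.
    """

    angles: pd.DataFrame
    displacements: dict[str, float]
    classifications: pd.DataFrame
    mode: str


def standing_lying_comparison(
    base_geometry: CCSGeometry,
    grid: SimulationGrid | None = None,
    mode: str = "rigid",
    regression_models: Mapping[str, RegressionModel] | None = None,
) -> StandingLyingReport:
    """Compare the standing (k = -1) and lying (k = +1) poses of one heart.

    The grid must contain the multipliers -1 and +1.  Landmark
    displacements between the two poses quantify how much each structure
    moves with posture; on the default canonical geometry the distal AV
    conduction axis swings farther than the sinus-node head, whose anchor
    sits closer to the thoracic origin.
    """
    if grid is None:
        grid = SimulationGrid()
    ks = np.asarray(grid.k_values, dtype=float)
    if not ({-1.0, 1.0} <= set(ks.tolist())):
        raise InvalidParamsError("grid must include k = -1 (standing) and k = +1 (lying)")

    traj = simulate_transformation(base_geometry, grid, mode=mode, regression_models=regression_models)
    tab = traj.table
    standing = tab[tab["k"] == -1.0].iloc[0]
    lying = tab[tab["k"] == 1.0].iloc[0]
    angles = pd.DataFrame([standing, lying])
    angles.insert(0, "pose", ["standing", "lying"])

    rots = {
        k: compose_rotation_sequence(k * grid.step_sgt, k * grid.step_frt, k * grid.step_hzt)
        for k in (-1.0, 1.0)
    }
    displacements: dict[str, float] = {}
    for name, p in base_geometry.landmarks.items():
        displacements[name] = float(np.linalg.norm(rots[1.0] @ p - rots[-1.0] @ p))
    displacements["sn_head"] = displacements["sn_head_center"]
    displacements["avca_max"] = max(
        displacements[lm] for lm in AVCA_LANDMARKS if lm in displacements
    )
    return StandingLyingReport(
        angles=angles.reset_index(drop=True),
        displacements=displacements,
        classifications=classify_all(traj),
        mode=mode,
    )
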