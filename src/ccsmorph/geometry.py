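"""Conduction-system geometry containers and reference-axis measurement.

A :class:`CCSGeometry` holds the named landmarks and per-component centerline
polylines of one heart, expressed in the thoracic frame (mm).  Three
reference axes are extracted from the landmarks:

* the **cardiac axis**, from the aortic valve center to the left
  ventricular apex,
* the **sinus-node (SN) axis**, the total-least-squares line through the SN
  head, the top of the terminal crest, and the aortic valve center, oriented
  from the SN head toward the valve,
* the **AV-conduction-axis (AVCA) axis**, from the end of the compact AV
  node to the branching point of the right bundle branch.

Projection angles of these axes in the three body planes form the angle
tuples used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import frames
from .exceptions import DegenerateAxisError, InvalidInputError, MissingLandmarkError
from .frames import (
    FRONTAL,
    HORIZONTAL,
    HORIZONTAL_SAGITTAL_REF,
    SAGITTAL,
    measure_plane_angle,
    unit,
)

__all__ = [
    "CardiacAngles",
    "CCSAngles",
    "CCSGeometry",
    "REQUIRED_LANDMARKS",
    "extract_reference_axes",
    "measure_all_angles",
]

#: Landmarks every geometry must carry for axis extraction.
REQUIRED_LANDMARKS = (
    "aortic_valve_center",
    "lv_apex",
    "sn_head_center",
    "terminal_crest_top",
    "compact_node_end",
    "rbb_branch_point",
)

#: Optional landmarks enabling the bundle-branch horizontal angles.
OPTIONAL_LANDMARKS = ("rbb_distal_point", "lbb_center_point")

ANGLE_COLUMNS = (
    "X_sgt", "X_frt", "X_hzt",
    "alpha_sgt", "alpha_frt", "alpha_hzt",
    "beta_sgt", "beta_frt", "beta_hzt",
    "gamma", "delta",
)


def _check_angle(name: str, value: float) -> float:
    v = float(value)
    if not np.isfinite(v) or not (0.0 <= v < 360.0):
        raise InvalidInputError(f"{name} must lie in [0, 360), got {value!r}")
    return v


@dataclass(frozen=True)
class CardiacAngles:
    """Cardiac-axis projection angles (degrees in [0, 360))."""

    X_sgt: float
    X_frt: float
    X_hzt: float

    def __post_init__(self):
        for k in ("X_sgt", "X_frt", "X_hzt"):
            _check_angle(k, getattr(self, k))

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("X_sgt", "X_frt", "X_hzt")}


@dataclass(frozen=True)
class CCSAngles:
    """Conduction-component projection angles (degrees in [0, 360)).

    ``gamma`` (right bundle branch) and ``delta`` (left bundle branch) are
    horizontal-plane angles only and may be absent.
    """

    alpha_sgt: float
    alpha_frt: float
    alpha_hzt: float
    beta_sgt: float
    beta_frt: float
    beta_hzt: float
    gamma: Optional[float] = None
    delta: Optional[float] = None

    def __post_init__(self):
        for k in ("alpha_sgt", "alpha_frt", "alpha_hzt", "beta_sgt", "beta_frt", "beta_hzt"):
            _check_angle(k, getattr(self, k))
        for k in ("gamma", "delta"):
            v = getattr(self, k)
            if v is not None:
                _check_angle(k, v)

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("alpha_sgt", "alpha_frt", "alpha_hzt",
                      "beta_sgt", "beta_frt", "beta_hzt", "gamma", "delta")
        }


@dataclass
class CCSGeometry:
    """Named landmarks and component centerlines of one heart (mm).

    ``provenance`` records how a synthetic geometry was generated (true
    angles, dimensions, fit residuals, seed); it is empty for geometries
    read from measurement files.
    """

    heart_id: str
    landmarks: dict[str, np.ndarray]
    centerlines: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.landmarks = {
            str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()
        }
        self.centerlines = {
            str(k): np.asarray(v, dtype=float).reshape(-1, 3)
            for k, v in self.centerlines.items()
        }
        for name, p in self.landmarks.items():
            if not np.all(np.isfinite(p)):
                raise InvalidInputError(f"landmark {name!r} has non-finite coordinates")
        for name, p in self.centerlines.items():
            if not np.all(np.isfinite(p)):
                raise InvalidInputError(f"centerline {name!r} has non-finite coordinates")

    def landmark(self, name: str) -> np.ndarray:
        try:
            return self.landmarks[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def arc_length(self, component: str) -> float:
        """Polyline arc length of one component centerline (mm)."""
        pts = self.centerlines[component]
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def all_points(self) -> np.ndarray:
        """All landmark and centerline points stacked as an (n, 3) array."""
        parts = [p[None, :] for _, p in sorted(self.landmarks.items())]
        parts += [self.centerlines[k] for k in sorted(self.centerlines)]
        return np.vstack(parts) if parts else np.empty((0, 3))

    def transformed(self, matrix: np.ndarray, heart_id: str | None = None) -> "CCSGeometry":
        """Apply a rigid rotation (3x3 matrix about the thoracic origin)."""
        m = np.asarray(matrix, dtype=float)
        return CCSGeometry(
            heart_id=heart_id or self.heart_id,
            landmarks={k: m @ v for k, v in self.landmarks.items()},
            centerlines={k: v @ m.T for k, v in self.centerlines.items()},
            provenance=dict(self.provenance),
        )


def _tls_line_direction(points: np.ndarray) -> np.ndarray:
    """Direction of the total-least-squares (orthogonal) line through points."""
    centered = points - points.mean(axis=0)
    # First right singular vector = direction of maximal spread.
    _, s, vt = np.linalg.svd(centered)
    if s[0] < frames.DEGENERATE_NORM:
        raise DegenerateAxisError("landmarks coincide; no line direction defined")
    return vt[0]


def extract_reference_axes(
    geometry: CCSGeometry,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract the cardiac, SN, and AVCA reference axes of one heart.

    Returns unit directions ``(cardiac_axis, sn_axis, avca_axis)`` in the
    thoracic frame.  The SN axis is fitted by orthogonal least squares to
    the three SN line landmarks (exact when they are collinear) and oriented
    from the SN head toward the aortic valve center.

    Raises
    ------
    MissingLandmarkError
        Naming the first absent required landmark.
    DegenerateAxisError
        If defining points coincide.
    """
    for name in REQUIRED_LANDMARKS:
        if name not in geometry.landmarks:
            raise MissingLandmarkError(name)

    valve = geometry.landmark("aortic_valve_center")
    apex = geometry.landmark("lv_apex")
    if np.linalg.norm(apex - valve) < frames.DEGENERATE_NORM:
        raise DegenerateAxisError("lv_apex coincides with aortic_valve_center")
    cardiac = unit(apex - valve)

    sn_pts = np.array(
        [geometry.landmark("sn_head_center"),
         geometry.landmark("terminal_crest_top"),
         valve]
    )
    sn = _tls_line_direction(sn_pts)
    head_to_valve = valve - geometry.landmark("sn_head_center")
    if np.linalg.norm(head_to_valve) < frames.DEGENERATE_NORM:
        raise DegenerateAxisError("sn_head_center coincides with aortic_valve_center")
    if sn @ head_to_valve < 0:
        sn = -sn

    node_end = geometry.landmark("compact_node_end")
    rbb_branch = geometry.landmark("rbb_branch_point")
    if np.linalg.norm(rbb_branch - node_end) < frames.DEGENERATE_NORM:
        raise DegenerateAxisError("rbb_branch_point coincides with compact_node_end")
    avca = unit(rbb_branch - node_end)
    return cardiac, sn, avca


def measure_all_angles(geometry: CCSGeometry) -> tuple[CardiacAngles, CCSAngles]:
    """Measure all projection angles of one heart.

    Cardiac (``X``) and SN (``alpha``) angles use the horizontal-line
    reference in the horizontal view; AVCA (``beta``) and bundle-branch
    (``gamma``, ``delta``) horizontal angles use the sagittal-line
    reference.  ``gamma``/``delta`` are measured only when the distal RBB /
    central LBB landmarks are present.
    """
    cardiac, sn, avca = extract_reference_axes(geometry)

    x = CardiacAngles(
        X_sgt=measure_plane_angle(cardiac, SAGITTAL),
        X_frt=measure_plane_angle(cardiac, FRONTAL),
        X_hzt=measure_plane_angle(cardiac, HORIZONTAL),
    )

    gamma = delta = None
    rbb_branch = geometry.landmark("rbb_branch_point")
    if "rbb_distal_point" in geometry.landmarks:
        rbb_dir = geometry.landmark("rbb_distal_point") - rbb_branch
        gamma = measure_plane_angle(rbb_dir, HORIZONTAL_SAGITTAL_REF)
    if "lbb_center_point" in geometry.landmarks:
        lbb_dir = geometry.landmark("lbb_center_point") - rbb_branch
        delta = measure_plane_angle(lbb_dir, HORIZONTAL_SAGITTAL_REF)

    ccs = CCSAngles(
        alpha_sgt=measure_plane_angle(sn, SAGITTAL),
        alpha_frt=measure_plane_angle(sn, FRONTAL),
        alpha_hzt=measure_plane_angle(sn, HORIZONTAL),
        beta_sgt=measure_plane_angle(avca, SAGITTAL),
        beta_frt=measure_plane_angle(avca, FRONTAL),
        beta_hzt=measure_plane_angle(avca, HORIZONTAL_SAGITTAL_REF),
        gamma=gamma,
        delta=delta,
    )
    return x, ccs
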