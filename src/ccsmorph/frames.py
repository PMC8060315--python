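"""Thoracic body frame, rigid rotations, plane projections, and signed angles.

The thoracic frame is right-handed with its origin at the center of the
aortic valvar orifice: ``+x`` toward the subject's left, ``+y`` dorsal,
``+z`` cranial.  The three body planes and their viewing conventions are

* **sagittal** (y-z plane), viewed from the subject's right; angles are
  measured from the horizontal line (``+y``) increasing toward cranial,
* **frontal** (x-z plane), viewed from the front; angles are measured from
  the vertical/sagittal line (``+z``) increasing toward the subject's left,
* **horizontal** (x-y plane), viewed from above; cardiac and sinus-node
  angles are measured from the horizontal line (``+x``), whereas the AV
  conduction axis and bundle-branch angles are measured from the sagittal
  line (``+y``); both increase in the same rotational sense.

With these conventions, a positive rotation about a plane's normal body
axis increases every angle measured in that plane by exactly the rotation
amount, which is the property the stepwise posture simulation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateProjectionError, InvalidInputError

__all__ = [
    "ThoracicFrame",
    "PlaneView",
    "SAGITTAL",
    "FRONTAL",
    "HORIZONTAL",
    "HORIZONTAL_SAGITTAL_REF",
    "PLANES",
    "wrap_degrees",
    "wrap_signed_degrees",
    "unit",
    "rotation_matrix",
    "rotate_about_body_axis",
    "compose_rotation_sequence",
    "compose_standing_lying_rotation",
    "DEFAULT_ROTATION_ORDER",
    "project_to_plane",
    "measure_plane_angle",
    "in_plane_direction",
    "direction_from_plane_angles",
]

#: Numerical tolerance below which a projected direction is degenerate (mm).
DEGENERATE_NORM = 1e-9


def wrap_degrees(angle):
    """Wrap angle(s) in degrees to the half-open interval [0, 360).

    Guards the seam: a tiny negative angle would otherwise round to
    exactly 360.0 under floating-point modulo.
    """
    wrapped = np.mod(angle, 360.0)
    wrapped = np.where(wrapped >= 360.0, 0.0, wrapped)
    return float(wrapped) if np.ndim(angle) == 0 else wrapped


def wrap_signed_degrees(angle):
    """Wrap angle difference(s) in degrees to the interval [-180, 180)."""
    return np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0


def unit(v: Sequence[float]) -> np.ndarray:
    """Return ``v`` normalised to unit length.

    Raises
    ------
    InvalidInputError
        If ``v`` is non-finite or has (numerically) zero norm.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("direction has non-finite components")
    n = np.linalg.norm(v)
    if n < DEGENERATE_NORM:
        raise InvalidInputError("zero-length vector has no direction")
    return v / n


@dataclass(frozen=True)
class ThoracicFrame:
    """Orthonormal, right-handed body frame anchored at the aortic valve."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_left: tuple[float, float, float] = (1.0, 0.0, 0.0)
    axis_dorsal: tuple[float, float, float] = (0.0, 1.0, 0.0)
    axis_cranial: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        m = np.array([self.axis_left, self.axis_dorsal, self.axis_cranial])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise InvalidInputError("frame axes must be orthonormal")
        if np.linalg.det(m) < 0:
            raise InvalidInputError("frame must be right-handed")


@dataclass(frozen=True)
class PlaneView:
    """One of the three thoracic planes together with its viewing convention.

    ``e_ref`` / ``e_perp`` span the plane in view coordinates: the measured
    angle of a direction ``d`` is ``atan2(d . e_perp, d . e_ref)``; ``normal``
    is the body axis about which a positive rotation increases that angle.
    """

    name: str
    viewer: str
    reference_line: str
    positive_sense: str
    normal: tuple[float, float, float]
    e_ref: tuple[float, float, float]
    e_perp: tuple[float, float, float]


SAGITTAL = PlaneView(
    name="sagittal",
    viewer="right-lateral",
    reference_line="horizontal-line",
    positive_sense="toward cranial",
    normal=(1.0, 0.0, 0.0),
    e_ref=(0.0, 1.0, 0.0),
    e_perp=(0.0, 0.0, 1.0),
)

FRONTAL = PlaneView(
    name="frontal",
    viewer="frontal",
    reference_line="sagittal-line",
    positive_sense="toward subject's left",
    normal=(0.0, 1.0, 0.0),
    e_ref=(0.0, 0.0, 1.0),
    e_perp=(1.0, 0.0, 0.0),
)

HORIZONTAL = PlaneView(
    name="horizontal",
    viewer="superior",
    reference_line="horizontal-line",
    positive_sense="toward dorsal",
    normal=(0.0, 0.0, 1.0),
    e_ref=(1.0, 0.0, 0.0),
    e_perp=(0.0, 1.0, 0.0),
)

#: Horizontal view re-referenced to the sagittal line (+y), same rotational
#: sense; used for the AV conduction axis and bundle-branch angles.
HORIZONTAL_SAGITTAL_REF = PlaneView(
    name="horizontal",
    viewer="superior",
    reference_line="sagittal-line",
    positive_sense="toward subject's right",
    normal=(0.0, 0.0, 1.0),
    e_ref=(0.0, 1.0, 0.0),
    e_perp=(-1.0, 0.0, 0.0),
)

PLANES = {"sagittal": SAGITTAL, "frontal": FRONTAL, "horizontal": HORIZONTAL}

_AXIS_INDEX = {"sagittal": 0, "frontal": 1, "horizontal": 2}


def rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    """Rotation matrix about the body axis normal to the named plane.

    Positive angles follow the right-hand rule about the plane normal
    (``axis_left`` for sagittal, ``axis_dorsal`` for frontal,
    ``axis_cranial`` for horizontal), which is also the positive sense of
    the angles measured in that plane.
    """
    if axis not in _AXIS_INDEX:
        raise InvalidInputError(
            f"axis must be one of {sorted(_AXIS_INDEX)}, got {axis!r}"
        )
    if not np.isfinite(degrees):
        raise InvalidInputError("rotation angle must be finite")
    return Rotation.from_euler("xyz"[_AXIS_INDEX[axis]], degrees, degrees=True).as_matrix()


def rotate_about_body_axis(points, axis: str, degrees: float) -> np.ndarray:
    """Rigidly rotate a direction or an ``(n, 3)`` point set about a body axis.

    The rotation axis passes through the thoracic origin (aortic valve
    center), so norms and pairwise distances are preserved.
    """
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("coordinates must be finite")
    r = rotation_matrix(axis, degrees)
    return pts @ r.T


#: Default application order of the three single-axis posture rotations.
DEFAULT_ROTATION_ORDER = ("sagittal", "frontal", "horizontal")


def compose_rotation_sequence(
    sgt_deg: float,
    frt_deg: float,
    hzt_deg: float,
    order: Sequence[str] = DEFAULT_ROTATION_ORDER,
) -> np.ndarray:
    """Compose extrinsic single-axis rotations in the given order.

    All factors rotate about the fixed thoracic axes; ``order`` must be a
    permutation of the three plane names.  The result is a proper
    orthogonal 3x3 matrix.
    """
    if sorted(order) != sorted(DEFAULT_ROTATION_ORDER):
        raise InvalidInputError(
            f"order must be a permutation of {DEFAULT_ROTATION_ORDER}, got {tuple(order)}"
        )
    by_axis = {"sagittal": sgt_deg, "frontal": frt_deg, "horizontal": hzt_deg}
    for a in by_axis.values():
        if not np.isfinite(a):
            raise InvalidInputError("rotation angles must be finite")
    m = np.eye(3)
    for axis in order:  # later rotations multiply from the left (extrinsic)
        m = rotation_matrix(axis, by_axis[axis]) @ m
    return m


def compose_standing_lying_rotation(
    sgt_deg: float, frt_deg: float, hzt_deg: float
) -> np.ndarray:
    """Composed posture rotation: sagittal, then frontal, then horizontal.

    All three factors are extrinsic rotations about the fixed thoracic axes,
    applied in the documented default order; the result is a proper
    orthogonal 3x3 matrix.
    """
    return compose_rotation_sequence(sgt_deg, frt_deg, hzt_deg)


def project_to_plane(direction, plane: PlaneView) -> np.ndarray:
    """Orthogonal projection of a 3D direction into a plane's view coordinates.

    Returns the 2D vector ``(d . e_ref, d . e_perp)``.  Projecting a vector
    already in the plane preserves its norm, and projecting twice equals
    projecting once.

    Raises
    ------
    DegenerateProjectionError
        If the direction is normal to the plane (projected norm < 1e-9).
    """
    d = np.asarray(direction, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InvalidInputError("direction has non-finite components")
    out = np.array([d @ np.asarray(plane.e_ref), d @ np.asarray(plane.e_perp)])
    if np.linalg.norm(out) < DEGENERATE_NORM:
        raise DegenerateProjectionError(
            f"direction is normal to the {plane.name} plane"
        )
    return out


def measure_plane_angle(direction, plane: PlaneView) -> float:
    """Signed projection angle of a direction in a plane, in degrees [0, 360).

    Measured from the plane's reference line, increasing in the plane's
    positive rotational sense.
    """
    u, v = project_to_plane(direction, plane)
    return float(wrap_degrees(np.degrees(np.arctan2(v, u))))


def in_plane_direction(angle_deg: float, plane: PlaneView) -> np.ndarray:
    """Unit 3D direction lying in ``plane`` at the given measured angle."""
    a = np.radians(angle_deg)
    return np.cos(a) * np.asarray(plane.e_ref) + np.sin(a) * np.asarray(plane.e_perp)


# ---------------------------------------------------------------------------
# Direction reconstruction from plane angles
# ---------------------------------------------------------------------------

def _angles_of(d: np.ndarray, planes: list[PlaneView]) -> np.ndarray:
    """Plane angles of d without degeneracy checks (for fitting residuals)."""
    out = np.empty(len(planes))
    for i, p in enumerate(planes):
        u = d @ np.asarray(p.e_ref)
        v = d @ np.asarray(p.e_perp)
        out[i] = np.degrees(np.arctan2(v, u))
    return out


def _closed_form_pair(kind: str, a: float, b: float) -> np.ndarray | None:
    """Exact direction from two plane angles when jointly consistent.

    ``kind`` names the pair; ``a``/``b`` are in degrees with the horizontal
    angle in horizontal-line reference.  Returns None when the shared
    coordinate's sign conflicts (no direction matches both angles exactly).
    """
    ar, br = np.radians(a), np.radians(b)
    if kind == "sh":  # sagittal + horizontal share y
        s, h = ar, br
        d = np.array(
            [abs(np.cos(s)) * np.cos(h), abs(np.sin(h)) * np.cos(s), abs(np.sin(h)) * np.sin(s)]
        )
    elif kind == "sf":  # sagittal + frontal share z
        s, f = ar, br
        d = np.array(
            [abs(np.sin(s)) * np.sin(f), abs(np.cos(f)) * np.cos(s), abs(np.cos(f)) * np.sin(s)]
        )
    elif kind == "fh":  # frontal + horizontal share x
        f, h = ar, br
        d = np.array(
            [abs(np.cos(h)) * np.sin(f), abs(np.sin(f)) * np.sin(h), abs(np.cos(h)) * np.cos(f)]
        )
    else:  # pragma: no cover - internal misuse
        raise ValueError(kind)
    n = np.linalg.norm(d)
    if n < DEGENERATE_NORM:
        return None
    return d / n


def _fibonacci_sphere(n: int = 32) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def direction_from_plane_angles(
    sagittal: float | None = None,
    frontal: float | None = None,
    horizontal: float | None = None,
    horizontal_reference: str = "horizontal-line",
) -> tuple[np.ndarray, float]:
    """Reconstruct a unit 3D direction from its plane projection angles.

    A direction has two degrees of freedom, so three plane angles are
    over-determined: when the requested triple is internally consistent the
    closed-form reconstruction is exact, otherwise the direction minimising
    the sum of squared circular angle residuals is returned.

    Parameters
    ----------
    sagittal, frontal, horizontal
        Target angles in degrees; at least two must be given.
    horizontal_reference
        ``"horizontal-line"`` (cardiac / sinus-node convention) or
        ``"sagittal-line"`` (AV-conduction-axis convention).

    Returns
    -------
    (direction, residual_deg)
        Unit direction and root-mean-square circular residual in degrees
        (zero, to numerical precision, for consistent inputs).
    """
    if horizontal_reference not in ("horizontal-line", "sagittal-line"):
        raise InvalidInputError(f"unknown horizontal reference {horizontal_reference!r}")
    planes: list[PlaneView] = []
    targets: list[float] = []
    if sagittal is not None:
        planes.append(SAGITTAL)
        targets.append(float(sagittal))
    if frontal is not None:
        planes.append(FRONTAL)
        targets.append(float(frontal))
    hz_hline = None
    if horizontal is not None:
        if horizontal_reference == "sagittal-line":
            planes.append(HORIZONTAL_SAGITTAL_REF)
            hz_hline = float(horizontal) + 90.0
        else:
            planes.append(HORIZONTAL)
            hz_hline = float(horizontal)
        targets.append(float(horizontal))
    if len(planes) < 2:
        raise InvalidInputError("need at least two plane angles to fix a direction")
    t = np.asarray(targets)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("plane angles must be finite")

    def cost(d: np.ndarray) -> float:
        return float(np.sum(wrap_signed_degrees(_angles_of(d, planes) - t) ** 2))

    # Closed-form candidates from each available pair.
    candidates: list[np.ndarray] = []
    if sagittal is not None and hz_hline is not None:
        c = _closed_form_pair("sh", sagittal, hz_hline)
        if c is not None:
            candidates.append(c)
    if sagittal is not None and frontal is not None:
        c = _closed_form_pair("sf", sagittal, frontal)
        if c is not None:
            candidates.append(c)
    if frontal is not None and hz_hline is not None:
        c = _closed_form_pair("fh", frontal, hz_hline)
        if c is not None:
            candidates.append(c)

    best = None
    best_cost = np.inf
    for c in candidates:
        cc = cost(c)
        if cc < best_cost:
            best, best_cost = c, cc
    if best is not None and best_cost < 1e-18:
        return best, float(np.sqrt(best_cost / len(planes)))

    # Over-determined or edge case: circular least squares on the sphere.
    # Rank the candidate starts by raw cost and refine only the best few;
    # the cost surface is smooth with a handful of basins, so this keeps
    # the global optimum while bounding the optimiser calls per axis.
    pool = candidates + list(_fibonacci_sphere())
    pool.sort(key=cost)
    starts = pool[:6]

    def residuals(x: np.ndarray) -> np.ndarray:
        th, ph = x
        d = np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        return wrap_signed_degrees(_angles_of(d, planes) - t)

    for s in starts:
        th0 = float(np.arccos(np.clip(s[2], -1.0, 1.0)))
        ph0 = float(np.arctan2(s[1], s[0]))
        sol = least_squares(
            residuals, np.array([th0, ph0]), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        th, ph = sol.x
        d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        cc = cost(d)
        if cc < best_cost:
            best, best_cost = d, cc
            if best_cost < 1e-18:
                break
    assert best is not None

    # A badly inconsistent triple can be optimised onto a view pole, where
    # one projection degenerates.  Nudge the direction off the pole with a
    # tiny in-plane component at that plane's target angle: the cost changes
    # only at O(1e-5) while every requested angle stays measurable.
    for p, target in zip(planes, t):
        u = best @ np.asarray(p.e_ref)
        v = best @ np.asarray(p.e_perp)
        if np.hypot(u, v) < 1e-6:
            best = best + 1e-5 * in_plane_direction(target, p)
            best /= np.linalg.norm(best)
    return best, float(np.sqrt(cost(best) / len(planes)))
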