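"""Rotation, projection, and angle-measurement primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccsmorph import (
    FRONTAL,
    HORIZONTAL,
    HORIZONTAL_SAGITTAL_REF,
    SAGITTAL,
    DegenerateProjectionError,
    InvalidInputError,
    compose_rotation_sequence,
    compose_standing_lying_rotation,
    direction_from_plane_angles,
    in_plane_direction,
    measure_plane_angle,
    project_to_plane,
    rotate_about_body_axis,
    wrap_degrees,
)
from ccsmorph.frames import rotation_matrix

PLANES = {"sagittal": SAGITTAL, "frontal": FRONTAL, "horizontal": HORIZONTAL}


def _oracle_axis_matrix(axis: str, deg: float) -> np.ndarray:
    """Hand-built single-axis rotation matrices (independent of scipy)."""
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    if axis == "sagittal":  # about +x
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "frontal":  # about +y
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])  # about +z


def circ_diff(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


class TestRotation:
    def test_zero_and_full_turn_are_identity(self, rng):
        pts = rng.normal(scale=30, size=(6, 3))
        assert np.allclose(rotate_about_body_axis(pts, "sagittal", 0.0), pts)
        assert np.allclose(rotate_about_body_axis(pts, "frontal", 360.0), pts, atol=1e-9)

    @pytest.mark.parametrize("axis", ["sagittal", "frontal", "horizontal"])
    def test_matches_hand_built_matrix(self, axis, rng):
        d = rng.normal(size=3)
        got = rotate_about_body_axis(d, axis, 37.5)
        assert np.allclose(got, _oracle_axis_matrix(axis, 37.5) @ d, atol=1e-12)

    @pytest.mark.parametrize("axis", ["sagittal", "frontal", "horizontal"])
    def test_in_plane_angle_shifts_by_rotation(self, axis, rng):
        """Rotating about a plane's normal adds the angle in that plane."""
        plane = PLANES[axis]
        d = rng.normal(size=3)
        before = measure_plane_angle(d, plane)
        after = measure_plane_angle(rotate_about_body_axis(d, axis, 10.0), plane)
        assert circ_diff(after, before + 10.0) < 1e-9

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.floats(-720, 720),
        st.sampled_from(["sagittal", "frontal", "horizontal"]),
        st.integers(0, 2**31 - 1),
    )
    def test_preserves_norms_and_distances(self, deg, axis, seed):
        pts = np.random.default_rng(seed).normal(scale=50, size=(5, 3))
        rot = rotate_about_body_axis(pts, axis, deg)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(rot[:, None] - rot[None], axis=-1)
        assert np.allclose(d1, d0, rtol=1e-9, atol=1e-9)
        assert np.allclose(
            np.linalg.norm(rot, axis=1), np.linalg.norm(pts, axis=1), rtol=1e-9
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidInputError):
            rotate_about_body_axis([np.nan, 0, 0], "sagittal", 10)
        with pytest.raises(InvalidInputError):
            rotate_about_body_axis([1, 0, 0], "sagittal", np.inf)
        with pytest.raises(InvalidInputError):
            rotate_about_body_axis([1, 0, 0], "coronal", 10)


class TestCompose:
    def test_identity_and_inverse(self):
        assert np.allclose(compose_standing_lying_rotation(0, 0, 0), np.eye(3))
        r = compose_standing_lying_rotation(33.3, 0, 0)
        rinv = compose_standing_lying_rotation(-33.3, 0, 0)
        assert np.allclose(rinv @ r, np.eye(3), atol=1e-12)

    def test_matches_matrix_product_oracle(self, rng):
        """Documented order: sagittal, then frontal, then horizontal."""
        for sgt, frt, hzt in rng.uniform(-180, 180, size=(10, 3)):
            expected = (
                _oracle_axis_matrix("horizontal", hzt)
                @ _oracle_axis_matrix("frontal", frt)
                @ _oracle_axis_matrix("sagittal", sgt)
            )
            got = compose_standing_lying_rotation(sgt, frt, hzt)
            assert np.allclose(got, expected, atol=1e-12)
            assert np.isclose(np.linalg.det(got), 1.0)
            assert np.allclose(got @ got.T, np.eye(3), atol=1e-12)

    def test_configurable_order(self):
        got = compose_rotation_sequence(10, 20, 30, order=("horizontal", "frontal", "sagittal"))
        expected = (
            _oracle_axis_matrix("sagittal", 10)
            @ _oracle_axis_matrix("frontal", 20)
            @ _oracle_axis_matrix("horizontal", 30)
        )
        assert np.allclose(got, expected, atol=1e-12)
        with pytest.raises(InvalidInputError):
            compose_rotation_sequence(1, 2, 3, order=("sagittal", "sagittal", "frontal"))


class TestProjection:
    def test_normal_direction_is_degenerate(self):
        with pytest.raises(DegenerateProjectionError):
            project_to_plane([0, 0, 1], HORIZONTAL)

    def test_in_plane_vector_unchanged_and_idempotent(self):
        v = np.array([0.0, 0.6, 0.8])  # lies in the sagittal plane
        uv = project_to_plane(v, SAGITTAL)
        assert np.isclose(np.linalg.norm(uv), 1.0)
        d3 = uv[0] * np.asarray(SAGITTAL.e_ref) + uv[1] * np.asarray(SAGITTAL.e_perp)
        assert np.allclose(project_to_plane(d3, SAGITTAL), uv)

    def test_oblique_unit_vector_keeps_unit_norm_in_frontal_plane(self):
        v = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)  # 45 deg between left and cranial
        assert np.isclose(np.linalg.norm(project_to_plane(v, FRONTAL)), 1.0)


class TestMeasureAngle:
    @pytest.mark.parametrize(
        "plane", [SAGITTAL, FRONTAL, HORIZONTAL, HORIZONTAL_SAGITTAL_REF]
    )
    def test_reference_and_perpendicular(self, plane):
        assert measure_plane_angle(np.asarray(plane.e_ref), plane) == pytest.approx(0.0)
        assert measure_plane_angle(np.asarray(plane.e_perp), plane) == pytest.approx(90.0)

    @pytest.mark.parametrize("plane_name", ["sagittal", "frontal", "horizontal"])
    def test_round_trip_with_rotation(self, plane_name):
        plane = PLANES[plane_name]
        d0 = np.asarray(plane.e_ref)
        d = rotate_about_body_axis(d0, plane_name, 123.4)
        assert measure_plane_angle(d, plane) == pytest.approx(123.4, abs=1e-9)

    def test_wrap_seam_guard(self):
        assert 0.0 <= wrap_degrees(-1e-16) < 360.0
        assert wrap_degrees(725.0) == pytest.approx(5.0)


class TestDirectionFromAngles:
    def test_consistent_triples_round_trip_exactly(self, rng):
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            s = measure_plane_angle(d, SAGITTAL)
            f = measure_plane_angle(d, FRONTAL)
            h = measure_plane_angle(d, HORIZONTAL)
            got, resid = direction_from_plane_angles(s, f, h)
            assert resid < 1e-9
            assert np.abs(got @ d) > 1 - 1e-12

    def test_sagittal_line_reference_variant(self, rng):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        s = measure_plane_angle(d, SAGITTAL)
        f = measure_plane_angle(d, FRONTAL)
        h = measure_plane_angle(d, HORIZONTAL_SAGITTAL_REF)
        got, resid = direction_from_plane_angles(
            s, f, h, horizontal_reference="sagittal-line"
        )
        assert resid < 1e-9
        assert np.abs(got @ d) > 1 - 1e-12

    def test_two_angles_suffice(self, rng):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        s = measure_plane_angle(d, SAGITTAL)
        h = measure_plane_angle(d, HORIZONTAL)
        got, resid = direction_from_plane_angles(sagittal=s, horizontal=h)
        assert resid < 1e-9
        assert np.abs(got @ d) > 1 - 1e-10

    def test_inconsistent_triple_reports_residual_and_stays_measurable(self):
        # The published mean SN triple is over-determined by ~28 deg RMS.
        got, resid = direction_from_plane_angles(87.8, 49.4, 272.4)
        assert resid > 1.0
        for plane in (SAGITTAL, FRONTAL, HORIZONTAL):
            measure_plane_angle(got, plane)  # must not be degenerate

    def test_requires_two_angles(self):
        with pytest.raises(InvalidInputError):
            direction_from_plane_angles(sagittal=10.0)

    def test_in_plane_direction_round_trip(self):
        for plane in (SAGITTAL, FRONTAL, HORIZONTAL, HORIZONTAL_SAGITTAL_REF):
            assert measure_plane_angle(in_plane_direction(211.25, plane), plane) == pytest.approx(
                211.25, abs=1e-9
            )
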