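"""Stepwise standing-to-lying rotation simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from ccsmorph import (
    InvalidInputError,
    InvalidParamsError,
    RotationTrajectory,
    SimulationGrid,
    classify_all,
    classify_rotation_direction,
    compose_standing_lying_rotation,
    extract_reference_axes,
    measure_plane_angle,
    simulate_transformation,
    standing_lying_comparison,
    stepwise_positions,
)
from ccsmorph.frames import HORIZONTAL, FRONTAL, SAGITTAL


def circ_diff(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


class TestGrid:
    def test_default_positions_are_k_times_sd(self):
        pos = stepwise_positions(SimulationGrid())
        assert pos[0] == (-2 * 12.1, -2 * 8.1, -2 * 13.4)
        assert pos[2] == (0.0, 0.0, 0.0)
        assert pos[3] == (12.1, 8.1, 13.4)
        assert len(pos) == 5

    def test_validation(self):
        with pytest.raises(InvalidParamsError):
            SimulationGrid(k_values=(1.0, 0.0))
        with pytest.raises(InvalidParamsError):
            SimulationGrid(step_sgt=-1.0)
        SimulationGrid(step_sgt=0.0)  # zero steps switch an axis off


class TestSimulateTransformation:
    def test_single_k0_equals_base_measurement(self, canonical):
        traj = simulate_transformation(canonical, SimulationGrid(k_values=(0.0,)))
        from ccsmorph import measure_all_angles

        x, ccs = measure_all_angles(canonical)
        row = traj.table.iloc[0]
        for key, want in {**x.as_dict(), **ccs.as_dict()}.items():
            assert row[key] == pytest.approx(want, abs=1e-12)

    def test_rigid_mode_conserves_distances_at_every_position(self, canonical):
        base_d = pdist(canonical.all_points())
        for inc in stepwise_positions(SimulationGrid()):
            rot = compose_standing_lying_rotation(*inc)
            moved = canonical.transformed(rot)
            assert np.allclose(pdist(moved.all_points()), base_d, rtol=1e-9, atol=1e-9)

    def test_horizontal_only_steps_shift_horizontal_angles_exactly(self, canonical):
        grid = SimulationGrid(step_sgt=0.0, step_frt=0.0, step_hzt=13.4)
        traj = simulate_transformation(canonical, grid, mode="rigid")
        base = traj.table[traj.table.k == 0].iloc[0]
        for _, row in traj.table.iterrows():
            for col in ("X_hzt", "alpha_hzt", "beta_hzt", "gamma", "delta"):
                assert circ_diff(row[col], base[col] + row["inc_hzt"]) < 1e-9

    def test_cardiac_angles_match_rigid_rotation_oracle(self, canonical):
        """Trajectory X columns equal angles of the explicitly rotated axis."""
        cardiac, _, _ = extract_reference_axes(canonical)
        traj = simulate_transformation(canonical, SimulationGrid(), mode="rigid")
        for _, row in traj.table.iterrows():
            rot = compose_standing_lying_rotation(row.inc_sgt, row.inc_frt, row.inc_hzt)
            d = rot @ cardiac
            assert circ_diff(row.X_sgt, measure_plane_angle(d, SAGITTAL)) < 1e-9
            assert circ_diff(row.X_frt, measure_plane_angle(d, FRONTAL)) < 1e-9
            assert circ_diff(row.X_hzt, measure_plane_angle(d, HORIZONTAL)) < 1e-9

    def test_sagittal_sequence_is_monotone_on_canonical(self, canonical):
        traj = simulate_transformation(canonical, SimulationGrid(), mode="rigid")
        assert (np.diff(traj.table["X_sgt"]) > 0).all()

    def test_modes_agree_at_k0(self, canonical):
        rigid = simulate_transformation(canonical, mode="rigid").table
        regr = simulate_transformation(canonical, mode="regression").table
        r0, g0 = rigid[rigid.k == 0].iloc[0], regr[regr.k == 0].iloc[0]
        for col in ("alpha_sgt", "alpha_frt", "beta_frt", "gamma", "delta"):
            assert r0[col] == pytest.approx(g0[col], abs=1e-12)

    def test_unknown_mode_rejected(self, canonical):
        with pytest.raises(InvalidInputError):
            simulate_transformation(canonical, mode="hybrid")


class TestClassification:
    def _dummy(self, canonical, x, y):
        table = pd.DataFrame({"X_frt": x, "beta_frt": y})
        return RotationTrajectory(
            grid=SimulationGrid(), mode="rigid", base_geometry=canonical, table=table
        )

    def test_identical_sequence_is_concomitant(self, canonical):
        x = np.array([10.0, 20, 30, 40])
        assert classify_rotation_direction(self._dummy(canonical, x, x), "avca", "frontal") == "concomitant"

    def test_mirrored_sequence_is_counter(self, canonical):
        x = np.array([10.0, 20, 30, 40])
        assert (
            classify_rotation_direction(self._dummy(canonical, x, 100.0 - x), "avca", "frontal")
            == "counter"
        )

    def test_constant_sequence_is_flat(self, canonical):
        x = np.array([10.0, 20, 30, 40])
        assert (
            classify_rotation_direction(self._dummy(canonical, x, np.full(4, 7.0)), "avca", "frontal")
            == "flat"
        )

    def test_regression_mode_reproduces_published_pattern(self, canonical):
        """Frontal AVCA counter-rotates; every SN pair is concomitant."""
        traj = simulate_transformation(canonical, mode="regression")
        assert classify_rotation_direction(traj, "avca", "frontal") == "counter"
        for plane in ("sagittal", "frontal", "horizontal"):
            assert classify_rotation_direction(traj, "sn", plane) == "concomitant"

    def test_invalid_component_plane_pair(self, canonical):
        traj = simulate_transformation(canonical, SimulationGrid(k_values=(0.0, 1.0)))
        with pytest.raises(InvalidInputError):
            classify_rotation_direction(traj, "rbb", "sagittal")

    def test_classify_all_covers_measurable_pairs(self, canonical):
        table = classify_all(simulate_transformation(canonical, mode="regression"))
        assert len(table) == 8  # 3 SN + 3 AVCA + gamma + delta
        assert set(table["classification"]) <= {"concomitant", "counter", "flat"}


class TestStandingLying:
    def test_zero_steps_give_identical_poses_and_zero_displacement(self, canonical):
        grid = SimulationGrid(step_sgt=0.0, step_frt=0.0, step_hzt=0.0)
        rep = standing_lying_comparison(canonical, grid)
        a = rep.angles
        assert a.loc[0, "X_sgt"] == pytest.approx(a.loc[1, "X_sgt"], abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rep.displacements.values())

    def test_avca_swings_farther_than_sn_head(self, canonical):
        rep = standing_lying_comparison(canonical)
        assert rep.displacements["avca_max"] >= rep.displacements["sn_head"]

    def test_nominal_horizontal_span_is_two_sds(self, canonical):
        rep = standing_lying_comparison(canonical)
        got = rep.angles.loc[1, "nominal_X_hzt"] - rep.angles.loc[0, "nominal_X_hzt"]
        assert got == pytest.approx(2 * 13.4, abs=1e-12)

    def test_grid_must_contain_both_poses(self, canonical):
        with pytest.raises(InvalidParamsError):
            standing_lying_comparison(canonical, SimulationGrid(k_values=(0.0, 2.0)))
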