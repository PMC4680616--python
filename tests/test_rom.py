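"""Range-of-motion estimation: feasibility, search, extrapolation."""

import numpy as np
import pytest

from vertmech.geometry import RigidTransform
from vertmech.rom import (RoMConstraints, estimate_rom, pose_feasible,
                          rom_sweep_oracle, sensitivity_analysis,
                          trunk_rom_extrapolation)
from vertmech.synthetic import make_column


class TestPoseFeasible:
    def test_neutral_pose_is_legal(self, generic_joint):
        ok, codes = pose_feasible(generic_joint,
                                  RigidTransform.identity())
        assert ok and not codes

    def test_gross_lateral_rotation_fails(self, generic_joint):
        T = RigidTransform.from_axis_angle([0, 0, 1], 90.0,
                                           center=generic_joint.cor)
        ok, codes = pose_feasible(generic_joint, T)
        assert not ok
        assert codes & {"CI", "ZI", "ZDl", "ZDd", "ZDc"}

    def test_partial_slide_violates_min_overlap(self, generic_joint):
        """A caudal slide leaving ~0.4 overlap passes at min_overlap 0 but
        fails at 0.5 with a craniocaudal disarticulation code."""
        fd = generic_joint.caudal.params.facet_diameter
        T = RigidTransform.from_translation([0.0, -0.6 * fd, 0.0])
        ok0, _ = pose_feasible(generic_joint, T,
                               RoMConstraints(min_overlap=0.0))
        ok5, codes = pose_feasible(generic_joint, T,
                                   RoMConstraints(min_overlap=0.5))
        assert ok0 and not ok5
        assert "ZDc" in codes

    def test_dorsal_lift_flags_dv_separation(self, generic_joint):
        fd = generic_joint.caudal.params.facet_diameter
        T = RigidTransform.from_translation([0.0, 0.0, 0.5 * fd])
        ok, codes = pose_feasible(generic_joint, T)
        assert not ok and "ZDd" in codes


ZERO_BUDGET = RoMConstraints(translation_budget=0.0, torsion_budget=0.0)


class TestEstimateRom:
    def test_matches_fine_sweep_oracle(self, generic_joint):
        for d in ("DE", "LF_left"):
            est = estimate_rom(generic_joint, d, ZERO_BUDGET)
            orc = rom_sweep_oracle(generic_joint, d, ZERO_BUDGET, step=0.02)
            assert abs(est.angle - orc.angle) <= 0.1

    def test_left_right_symmetry(self, generic_joint):
        left = estimate_rom(generic_joint, "LF_left")
        right = estimate_rom(generic_joint, "LF_right")
        assert abs(left.angle - right.angle) <= 0.1

    def test_monotone_in_translation_budget(self, generic_joint):
        angles = [estimate_rom(generic_joint, "DE",
                               RoMConstraints(translation_budget=b)).angle
                  for b in (0.0, 0.015, 0.03)]
        assert angles == sorted(angles)

    def test_deterministic(self, generic_joint):
        a = estimate_rom(generic_joint, "VF")
        b = estimate_rom(generic_joint, "VF")
        assert a.angle == b.angle and a.limit_codes == b.limit_codes

    def test_limit_codes_nonempty_below_ceiling(self, generic_joint):
        r = estimate_rom(generic_joint, "AR_left")
        assert r.angle < 90.0
        assert r.limit_codes

    def test_invalid_direction_rejected(self, generic_joint):
        with pytest.raises(ValueError):
            estimate_rom(generic_joint, "sideways")


class TestSweepOracle:
    def test_grid_refinement_bound(self, generic_joint):
        coarse = rom_sweep_oracle(generic_joint, "LF_left", ZERO_BUDGET,
                                  step=0.5)
        fine = rom_sweep_oracle(generic_joint, "LF_left", ZERO_BUDGET,
                                step=0.1)
        assert coarse.angle <= fine.angle + 0.5


class TestSensitivityAnalysis:
    def test_degenerate_grid_equals_estimate(self, generic_joint):
        df = sensitivity_analysis(generic_joint, ["condyle_or_ivd"],
                                  [0.015], coarse_step=2.0)
        direct = estimate_rom(generic_joint, "DE",
                              RoMConstraints(translation_budget=0.015),
                              coarse_step=2.0)
        col = ("condyle_or_ivd", 0.015)
        assert df.loc["DE", col] == pytest.approx(direct.angle, abs=1e-9)
        four = [df.loc[k, col] for k in ("ML", "DE", "VF", "AR")]
        assert df.loc["average", col] == pytest.approx(np.mean(four),
                                                       abs=1e-9)

    def test_empty_grid_rejected(self, generic_joint):
        with pytest.raises(ValueError):
            sensitivity_analysis(generic_joint, [], [0.015])


class TestTrunkExtrapolation:
    @staticmethod
    def _column(n):
        return make_column("protosuchus", n_vertebrae=n, resolution=220)

    def test_hand_computed_assignment(self):
        # 15 vertebrae -> 14 joints (last one lumbosacral); tests at joints
        # 4 and 9 (0-based) with 10 and 20 degrees
        col = self._column(15)
        per = {4: {"LF": 10.0}, 9: {"LF": 20.0}}
        assigned, totals = trunk_rom_extrapolation(per, col)
        np.testing.assert_allclose(assigned["LF"][:7], 10.0)   # joints 0-6
        np.testing.assert_allclose(assigned["LF"][7:], 20.0)   # joints 7-13
        assert totals["LF"] == pytest.approx(10 * 7 + 20 * 7)

    def test_single_tested_joint_fills_column(self):
        col = self._column(6)
        assigned, totals = trunk_rom_extrapolation({1: {"DE": 8.0}}, col)
        assert (assigned["DE"] == 8.0).all()
        assert totals["DE"] == pytest.approx(col.n_joints * 8.0)

    def test_lumbosacral_value_used_exactly_once(self):
        col = self._column(6)          # joints 0..4, joint 4 lumbosacral
        per = {1: {"LF": 10.0}, 4: {"LF": 5.0}}
        assigned, totals = trunk_rom_extrapolation(per, col)
        assert assigned.loc[4, "LF"] == 5.0
        assert (assigned.loc[:3, "LF"] == 10.0).all()
        assert totals["LF"] == pytest.approx(4 * 10.0 + 5.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trunk_rom_extrapolation({}, self._column(4))
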