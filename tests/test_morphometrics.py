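"""Morphometric measurement, allometric normalization, stiffness scores."""

import numpy as np
import pandas as pd
import pytest

from vertmech.morphometrics import (DV_SIGNS, ML_SIGNS, NormalizationError,
                                    allometric_normalize, iv_space_fraction,
                                    lumbar_length, measure_vertebra,
                                    stiffness_correlate_scores)
from vertmech.synthetic import VertebraParams, make_column, make_vertebra


def cohort_frame(scales, b=1.0, n_per=7):
    """Synthetic cohort where every measurement follows M = c * L0^b."""
    rows = []
    for i, s in enumerate(scales):
        factor = s ** b
        for j in range(n_per):
            rows.append(dict(
                specimen=f"s{i}", vertebra_index=j,
                region="lumbar" if j >= n_per - 5 else "thoracic",
                CL=20 * s, CW=5 * factor, CH=5 * factor, LW=3 * factor,
                NSH=8 * factor, NSL=7 * factor, TPW=20 * factor,
                PZW=6 * factor, IZL=15 * factor,
                A_PZ=140.0, A_NS=90.0, A_TPD=90.0, A_TPC=90.0))
    return pd.DataFrame(rows)


class TestMeasureVertebra:
    def test_roundtrips_generator_parameters(self, generic_vertebra):
        p = VertebraParams()
        r = measure_vertebra(generic_vertebra)
        for name in ("CL", "CW", "CH", "TPW", "PZW", "LW", "NSH", "NSL"):
            assert getattr(r, name) == pytest.approx(
                getattr(p, name), rel=0.01), name
        assert r.A_PZ == pytest.approx(p.A_PZ, abs=1.0)

    def test_horizontal_facet_angle(self):
        v = make_vertebra(VertebraParams(A_PZ=179.9), resolution=300)
        r = measure_vertebra(v)
        assert r.A_PZ == pytest.approx(179.9, abs=1.0)

    def test_relative_centrum_length_formula(self):
        from vertmech.morphometrics import MorphometricRecord
        r = MorphometricRecord("s", 0, CL=2.0, CW=1.0, CH=1.0)
        assert r.CL_rel == pytest.approx(2.0, abs=1e-12)

    def test_measurement_invariant_to_pose(self, generic_vertebra):
        from vertmech.geometry import RigidTransform
        T = RigidTransform.from_axis_angle([1, 2, 0.5], 77.0,
                                           center=[4, -9, 2])
        a = measure_vertebra(generic_vertebra)
        b = measure_vertebra(generic_vertebra.transformed(T))
        for name in ("CL", "CW", "CH", "TPW", "PZW", "A_PZ"):
            assert getattr(a, name) == pytest.approx(
                getattr(b, name), rel=1e-6), name


class TestAllometricNormalize:
    def test_isometric_cohort_recovers_slope_one(self):
        df = cohort_frame([1.0, 1.7, 2.4], b=1.0)
        norm, model = allometric_normalize(df)
        for m, b in model.slopes.items():
            assert b == pytest.approx(1.0, abs=1e-6), m
        # all specimens normalize to identical values
        assert norm.groupby("specimen")["CW"].mean().round(9).nunique() == 1

    @pytest.mark.parametrize("b_true", [0.5, 1.5])
    def test_recovers_constructed_slope(self, b_true):
        df = cohort_frame([1.0, 1.6, 2.5], b=b_true)
        _, model = allometric_normalize(df)
        # CL itself scales isometrically (it defines L0); others follow b
        assert model.slopes["CW"] == pytest.approx(b_true, abs=1e-6)
        assert model.slopes["NSH"] == pytest.approx(b_true, abs=1e-6)

    def test_specimen_at_reference_length_unchanged(self):
        df = cohort_frame([1.0, 2.0])
        L0 = lumbar_length(df)
        norm, _ = allometric_normalize(df, Ls=float(L0["s0"]))
        s0 = df["specimen"] == "s0"
        for m in ("CW", "NSH", "TPW"):
            np.testing.assert_allclose(norm.loc[s0, m], df.loc[s0, m],
                                       atol=1e-9)

    def test_angles_pass_through_untouched(self):
        df = cohort_frame([1.0, 1.5, 2.0], b=0.8)
        norm, _ = allometric_normalize(df)
        for a in ("A_PZ", "A_NS", "A_TPD", "A_TPC"):
            assert (norm[a] == df[a]).all()

    def test_common_rescaling_is_equivariant(self):
        df = cohort_frame([1.0, 1.5, 2.0], b=0.7)
        norm, _ = allometric_normalize(df)
        scaled = df.copy()
        for m in ("CL", "CW", "CH", "LW", "NSH", "NSL", "TPW", "PZW",
                  "IZL"):
            scaled[m] *= 3.0
        norm2, _ = allometric_normalize(scaled)
        np.testing.assert_allclose(norm2["CW"], 3.0 * norm["CW"],
                                   rtol=1e-9)

    def test_single_specimen_slope_undefined(self):
        df = cohort_frame([1.0])
        with pytest.raises(NormalizationError):
            allometric_normalize(df)


class TestStiffnessScores:
    def test_cohort_mean_vertebra_scores_zero(self):
        """A probe vertebra sitting exactly at the cohort mean on every
        scored measurement gets ml = dv = 0."""
        df = cohort_frame([1.0, 2.0], b=1.0)
        mean_row = df.select_dtypes("number").mean()
        probe = df.iloc[[0]].copy()
        for c in set(ML_SIGNS) | set(DV_SIGNS):
            if c in probe:
                probe[c] = mean_row[c]
        combined = pd.concat([df, probe], ignore_index=True)
        s = stiffness_correlate_scores(combined).iloc[-1]
        assert s["ml_score"] == pytest.approx(0.0, abs=1e-9)
        assert s["dv_score"] == pytest.approx(0.0, abs=1e-9)

    def test_raising_facet_angle_moves_scores_oppositely(self):
        df = cohort_frame([1.0, 1.5], b=1.0)
        bumped = df.copy()
        bumped.loc[0, "A_PZ"] += 20.0
        base = stiffness_correlate_scores(df).iloc[0]
        high = stiffness_correlate_scores(bumped).iloc[0]
        assert high["ml_score"] < base["ml_score"]
        assert high["dv_score"] > base["dv_score"]

    def test_swapping_sign_tables_flips_contrast(self):
        df = cohort_frame([1.0, 1.4, 2.1], b=0.6)
        df["CW"] *= np.linspace(0.8, 1.2, len(df))   # add spread
        scored = stiffness_correlate_scores(df)
        import vertmech.morphometrics as mm
        orig_ml, orig_dv = mm.ML_SIGNS, mm.DV_SIGNS
        try:
            mm.ML_SIGNS, mm.DV_SIGNS = orig_dv, orig_ml
            swapped = stiffness_correlate_scores(df)
        finally:
            mm.ML_SIGNS, mm.DV_SIGNS = orig_ml, orig_dv
        np.testing.assert_allclose(swapped["contrast"],
                                   -scored["contrast"], atol=1e-9)

    def test_all_missing_rejected(self):
        df = pd.DataFrame({"specimen": ["a"], "vertebra_index": [0]})
        with pytest.raises(ValueError):
            stiffness_correlate_scores(df)


class TestIvSpaceFraction:
    def test_matches_generator_fraction(self, croc_column):
        df, summary = iv_space_fraction(croc_column)
        body = df[~df["lumbosacral"]]
        np.testing.assert_allclose(body["fraction"], 0.19, rtol=0.01)
        assert summary["n_joints"] == len(body)

    def test_lumbosacral_excluded_from_summary(self, croc_column):
        df, summary = iv_space_fraction(croc_column)
        assert df["lumbosacral"].sum() == 1
        assert summary["n_joints"] == croc_column.n_joints - 1

    def test_summary_brackets_per_joint_values(self):
        col = make_column("pelagosaurus", n_vertebrae=4, resolution=300)
        df, summary = iv_space_fraction(col)
        body = df[~df["lumbosacral"]]["fraction"]
        assert summary["min"] <= body.min() + 1e-12
        assert summary["max"] >= body.max() - 1e-12
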