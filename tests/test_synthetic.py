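"""Synthetic vertebra/column generator and bending-trial simulator."""

import numpy as np
import pytest

from vertmech.geometry import fit_sphere
from vertmech.mechanics import fit_stiffness
from vertmech.synthetic import (DEFAULT_MASSES, GenerationError,
                                SimulationError, TAXA, VertebraParams,
                                make_column, make_vertebra,
                                mirror_symmetry_error, simulate_bending_trials,
                                taxon_preset)


class TestMakeVertebra:
    def test_watertight_and_symmetric(self, generic_vertebra):
        assert generic_vertebra.mesh.is_watertight()
        assert mirror_symmetry_error(generic_vertebra.mesh) <= 1e-6

    def test_procoelous_condyle_is_spherical(self, procoelous_vertebra):
        s = fit_sphere(procoelous_vertebra.landmarks["condyle_points"])
        assert s.rms <= 1e-3
        assert s.radius == pytest.approx(0.45 * 10.0, rel=1e-6)

    def test_horizontal_facets_at_extreme_angle(self):
        v = make_vertebra(VertebraParams(A_PZ=179.9999), resolution=400)
        n = v.landmarks["prezyg_left"].normal
        assert np.allclose(n, [0, 0, 1], atol=1e-5)

    def test_deterministic_given_seed(self):
        a = make_vertebra(VertebraParams(), resolution=400, seed=3)
        b = make_vertebra(VertebraParams(), resolution=400, seed=3)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.faces, b.mesh.faces)

    @pytest.mark.parametrize("kw", [
        dict(CL=-1), dict(A_PZ=0), dict(A_PZ=180),
        dict(facet_diameter=25, CL=20),
        dict(LW=4, canal_radius=2.5),       # lamina narrower than canal
        dict(TPW=5, LW=7),                  # processes inside lamina
    ])
    def test_invalid_params_raise(self, kw):
        with pytest.raises(GenerationError):
            VertebraParams(**kw)


class TestTaxonPresets:
    def test_ordinal_contrasts(self):
        croc = taxon_preset("crocodylus").base
        terr = taxon_preset("terrestrisuchus").base
        metr = taxon_preset("metriorhynchus").base
        assert croc.PZW > terr.PZW
        assert croc.A_PZ > terr.A_PZ
        assert terr.TPW == min(taxon_preset(t).base.TPW for t in TAXA)
        thal = ("pelagosaurus", "steneosaurus", "metriorhynchus")
        assert metr.CH == max(taxon_preset(t).base.CH for t in thal)
        assert metr.CW == max(taxon_preset(t).base.CW for t in thal)

    def test_iv_space_fraction_defaults(self):
        assert taxon_preset("crocodylus").iv_space_fraction == 0.19
        assert taxon_preset("terrestrisuchus").iv_space_fraction == 0.04

    @pytest.mark.parametrize("name", TAXA)
    def test_all_presets_valid_along_trunk(self, name):
        prof = taxon_preset(name)
        for t in (0.0, 0.5, 1.0):
            p = prof.params_at(t)       # raises if invariants are broken
            assert p.CL > 0 and 0 < p.A_PZ < 180

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            taxon_preset("stegosaurus")


class TestMakeColumn:
    def test_gap_construction(self):
        col = make_column("protosuchus", n_vertebrae=4, resolution=400,
                          iv_space_fraction=0.1)
        assert col.n_joints == 3
        for j in range(col.n_joints):
            cl = col.vertebrae[j + 1].centrum_length
            assert col.iv_space[j] == pytest.approx(0.1 * cl, abs=1e-9)

    def test_deterministic(self):
        a = make_column("pelagosaurus", n_vertebrae=3, resolution=400,
                        seed=7)
        b = make_column("pelagosaurus", n_vertebrae=3, resolution=400,
                        seed=7)
        for va, vb in zip(a.vertebrae, b.vertebrae):
            assert np.array_equal(va.mesh.vertices, vb.mesh.vertices)

    def test_region_labels_end_with_sacral(self, croc_column):
        regions = croc_column.regions
        assert regions[-1] == "sacral"
        assert croc_column.is_lumbosacral(croc_column.n_joints - 1)
        assert not croc_column.is_lumbosacral(0)

    def test_manifest_roundtrip(self, tmp_path, generic_column):
        from vertmech.synthetic import (load_column_manifest,
                                        write_column_manifest)
        write_column_manifest(generic_column, tmp_path)
        back = load_column_manifest(tmp_path)
        assert len(back.vertebrae) == len(generic_column.vertebrae)
        np.testing.assert_allclose(back.iv_space, generic_column.iv_space)
        v0 = back.vertebrae[0]
        assert "prezyg_left" in v0.landmarks
        np.testing.assert_allclose(
            v0.landmarks["cranial_face_center"],
            generic_column.vertebrae[0].landmarks["cranial_face_center"],
            atol=1e-6)


class TestBendingTrials:
    def test_noiseless_trials_invert_exactly(self):
        trials = simulate_bending_trials(0.15, 150.0, 0.95, 0.4)
        fit = fit_stiffness(trials)
        assert fit.slope == pytest.approx(0.15, abs=1e-6)
        assert fit.x_intercept == pytest.approx(150.0, abs=1e-4)

    def test_one_trial_per_mass(self):
        trials = simulate_bending_trials(0.1, 150.0, 0.5, 0.4,
                                         masses=(0.3,))
        assert len(trials) == 1
        trials = simulate_bending_trials(0.1, 150.0, 0.5, 0.4)
        assert len(trials) == len(DEFAULT_MASSES)

    def test_monte_carlo_slope_recovery(self):
        """Mean fitted slope over noisy replicates stays close to truth
        when the deflection range (~35 degrees, as in the real bending
        curves) dominates the 2-degree angle noise."""
        masses = tuple(4 * m for m in DEFAULT_MASSES)
        slopes = []
        for seed in range(60):
            trials = simulate_bending_trials(0.15, 150.0, 0.95, 0.4,
                                             masses=masses, noise_sd=2.0,
                                             seed=seed)
            slopes.append(fit_stiffness(trials).slope)
        assert abs(np.mean(slopes) - 0.15) / 0.15 < 0.05

    def test_invalid_stiffness_raises(self):
        with pytest.raises(SimulationError):
            simulate_bending_trials(0.0, 150.0, 0.5, 0.4)
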