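import numpy as np
import pytest
import trimesh

from cardioshape.geometry import BivMesh
from cardioshape.measures_atlas import (GlobalMeasures, build_atlas,
                                        global_measures, project,
                                        region_volume, variance_explained)
from cardioshape.meshfit import BiventricularModel


def _sphere_model(radius=10.0, subdiv=3, scale_axes=None):
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    v = m.vertices * radius
    if scale_axes is not None:
        v = m.vertices * np.asarray(scale_axes)
    mesh = BivMesh(vertices=v, faces=m.faces,
                   face_region=np.full(len(m.faces), "lv_endo"),
                   closed_regions={"lv_endo": m.faces})
    return BiventricularModel(template=mesh, vertices=v, phase="ED")


class TestRegionVolume:
    def test_icosphere_volume(self):
        model = _sphere_model(radius=10.0, subdiv=3)
        vol = region_volume(model, "lv_endo")
        assert vol == pytest.approx(4.0 / 3.0 * np.pi, rel=0.02)  # 4.19 mL

    def test_ellipsoid_volume(self):
        model = _sphere_model(subdiv=4, scale_axes=(30.0, 20.0, 20.0))
        vol = region_volume(model, "lv_endo")
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 30 * 20 * 20 / 1000,
                                    rel=0.01)  # 50.27 mL

    def test_orientation_flip_negates(self):
        model = _sphere_model()
        flipped = _sphere_model()
        flipped.template.closed_regions["lv_endo"] = \
            np.flip(model.template.closed_regions["lv_endo"], axis=1)
        assert region_volume(flipped, "lv_endo") == pytest.approx(
            -region_volume(model, "lv_endo"))

    def test_open_surface_rejected(self):
        model = _sphere_model()
        model.template.closed_regions["lv_endo"] = \
            model.template.closed_regions["lv_endo"][:-1]
        with pytest.raises(ValueError, match="open surface"):
            region_volume(model, "lv_endo")


class TestGlobalMeasures:
    def test_identities_and_phantom_recovery(self, default_truth, oracle_models):
        ed, es = oracle_models
        gm = global_measures(ed, es)
        assert gm.lv_sv == pytest.approx(gm.lv_edv - gm.lv_esv, abs=1e-12)
        assert gm.lv_ef == pytest.approx(100 * gm.lv_sv / gm.lv_edv, abs=1e-12)
        truth_edv = default_truth.analytic_volumes[("lv_cavity", 0)]
        assert gm.lv_edv == pytest.approx(truth_edv, rel=0.10)
        assert abs(gm.lv_ef - 100 * default_truth.params.ef_target_fraction) < 5

    def test_wall_volume_additivity(self, oracle_models):
        ed, _ = oracle_models
        epi = region_volume(ed, "epicardium")
        parts = (region_volume(ed, "lv_endo") + region_volume(ed, "rv_endo")
                 + (region_volume(ed, "lv_epi") - region_volume(ed, "lv_endo"))
                 + (epi - region_volume(ed, "lv_epi") - region_volume(ed, "rv_endo")))
        assert parts == pytest.approx(epi, rel=0.01)

    def test_equal_phases_give_zero_stroke_volume(self, oracle_models):
        ed, _ = oracle_models
        gm = global_measures(ed, ed)
        assert gm.lv_sv == 0.0 and gm.lv_ef == 0.0

    def test_negative_ef_warns_not_raises(self, oracle_models):
        ed, es = oracle_models
        with pytest.warns(UserWarning, match="negative"):
            gm = global_measures(es, ed)  # swapped phases
        assert gm.lv_ef < 0

    def test_table_row_names(self):
        gm = GlobalMeasures(*(float(i) for i in range(10)))
        assert "LV EDV (mL)" in gm.as_rows()
        assert len(gm.as_rows()) == 10


def _noise_pair(template, rng, scale=1.0):
    ed = BiventricularModel(template, template.vertices
                            + scale * rng.normal(0, 1, template.vertices.shape))
    es = BiventricularModel(template, 0.9 * template.vertices
                            + scale * rng.normal(0, 1, template.vertices.shape),
                            phase="ES")
    return ed, es


class TestAtlas:
    def test_identical_population_has_zero_variance(self, template):
        pair = (BiventricularModel(template, template.vertices),
                BiventricularModel(template, 0.9 * template.vertices, "ES"))
        atlas = build_atlas([pair, pair, pair])
        assert atlas.n_modes == 0 or np.all(atlas.eigenvalues < 1e-10)

    def test_two_subject_zscore(self, template, rng):
        p1 = _noise_pair(template, rng)
        p2 = _noise_pair(template, rng)
        atlas = build_atlas([p1, p2])
        z1 = project(atlas, p1)
        assert abs(abs(z1.z[0]) - 1 / np.sqrt(2)) < 1e-6

    def test_training_scores_standardized(self, template, rng):
        pairs = [_noise_pair(template, rng) for _ in range(6)]
        atlas = build_atlas(pairs)
        z = np.stack([project(atlas, p).z for p in pairs])
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-6)

    def test_mean_projects_to_zero_and_training_reconstructs(self, template, rng):
        pairs = [_noise_pair(template, rng) for _ in range(5)]
        atlas = build_atlas(pairs)
        nv = atlas.n_vertices
        mean_pair = (BiventricularModel(template,
                                        atlas.mean_shape[:3 * nv].reshape(-1, 3)),
                     BiventricularModel(template,
                                        atlas.mean_shape[3 * nv:].reshape(-1, 3),
                                        "ES"))
        assert np.abs(project(atlas, mean_pair).z).max() < 1e-8
        # full-mode reconstruction of a training shape
        z = project(atlas, pairs[0])
        recon = atlas.mean_shape + atlas.modes @ (z.z * np.sqrt(atlas.eigenvalues))
        from cardioshape.measures_atlas import _align_pair, _pair_vector
        ed_a, es_a = _align_pair(pairs[0][0].vertices, pairs[0][1].vertices,
                                 atlas.mean_ed_vertices())
        np.testing.assert_allclose(recon, _pair_vector(ed_a, es_a), atol=1e-6)

    def test_rigid_invariance_of_scores(self, template, rng):
        pairs = [_noise_pair(template, rng) for _ in range(4)]
        atlas = build_atlas(pairs)
        z0 = project(atlas, pairs[1]).z
        a = np.deg2rad(25)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        moved = (BiventricularModel(template, pairs[1][0].vertices @ rot.T + 5),
                 BiventricularModel(template, pairs[1][1].vertices @ rot.T + 5,
                                    "ES"))
        np.testing.assert_allclose(project(atlas, moved).z, z0, atol=1e-6)

    def test_variance_explained(self, template, rng):
        pairs = [_noise_pair(template, rng) for _ in range(5)]
        atlas = build_atlas(pairs)
        assert variance_explained(atlas, atlas.n_modes) == pytest.approx(1.0)
        assert variance_explained(atlas, 1) <= 1.0
        with pytest.raises(ValueError):
            variance_explained(atlas, 0)

    def test_orthonormal_modes_descending_eigenvalues(self, template, rng):
        pairs = [_noise_pair(template, rng) for _ in range(5)]
        atlas = build_atlas(pairs)
        gram = atlas.modes.T @ atlas.modes
        np.testing.assert_allclose(gram, np.eye(atlas.n_modes), atol=1e-8)
        assert np.all(np.diff(atlas.eigenvalues) <= 1e-12)
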