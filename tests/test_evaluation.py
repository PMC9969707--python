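import numpy as np
import pytest

from cardioshape import evaluation as ev
from cardioshape.meshfit import BiventricularModel


class TestDice:
    def test_examples(self):
        a = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        assert ev.dice(a, a) == 1.0
        b = np.zeros((4, 4), bool)
        b[1:3, 2:4] = True
        assert ev.dice(a, b) == 0.5           # overlap 2, sizes 4+4
        assert ev.dice(a, np.zeros((4, 4), bool)) == 0.0
        with pytest.warns(UserWarning):
            assert ev.dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0
        with pytest.raises(ValueError):
            ev.dice(a, np.zeros((5, 5), bool))

    def test_brute_force_oracle(self, rng):
        for _ in range(1000):
            a = rng.uniform(size=(16, 16)) > 0.6
            b = rng.uniform(size=(16, 16)) > 0.6
            inter = sum(1 for i in range(16) for j in range(16) if a[i, j] and b[i, j])
            if a.sum() + b.sum() == 0:
                continue
            assert ev.dice(a, b) == 2 * inter / (int(a.sum()) + int(b.sum()))


class TestHausdorff:
    def test_examples(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert ev.hausdorff(pts, pts) == 0.0
        assert ev.hausdorff([[0.0, 0.0]], [[3.0, 4.0]]) == 5.0
        with pytest.raises(ValueError):
            ev.hausdorff(np.empty((0, 2)), pts)

    def test_brute_force_oracle(self, rng):
        for _ in range(1000):
            a = rng.uniform(0, 10, size=(50, 2))
            b = rng.uniform(0, 10, size=(50, 2))
            d = np.linalg.norm(a[:, None] - b[None], axis=2)
            expected = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert ev.hausdorff(a, b) == pytest.approx(expected, abs=1e-12)

    def test_percentile_variant_bounded_by_max(self, rng):
        a = rng.uniform(size=(40, 2))
        b = rng.uniform(size=(40, 2))
        assert ev.hausdorff_percentile(a, b, 95) <= ev.hausdorff(a, b) + 1e-12


class TestAAFD:
    def test_examples(self):
        assert ev.aafd([3, 7, 9], [3, 7, 9]) == 0.0
        assert ev.aafd([10, 12], [11, 14]) == 1.5
        assert ev.aafd([5, 6, 7], [8, 9, 10]) == 3.0
        with pytest.raises(ValueError):
            ev.aafd([1, 2], [1])


class TestRigidAlign:
    def test_exact_recovery(self, oracle_models):
        ed, _ = oracle_models
        a = np.deg2rad(40)
        rot = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0],
                        [-np.sin(a), 0, np.cos(a)]])
        moved = BiventricularModel(ed.template, ed.vertices @ rot.T + [4, 5, 6])
        _tf, aligned = ev.rigid_align_models(moved, ed)
        rmsd = np.sqrt(((aligned.vertices - ed.vertices) ** 2).sum(1).mean())
        assert rmsd < 1e-8

    def test_identity_for_equal_models(self, oracle_models):
        ed, _ = oracle_models
        tf, _ = ev.rigid_align_models(ed, ed)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-8)

    def test_reflection_forced_to_proper_rotation(self, oracle_models):
        ed, _ = oracle_models
        mirrored = BiventricularModel(ed.template, ed.vertices * [-1, 1, 1])
        tf, aligned = ev.rigid_align_models(mirrored, ed)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        resid = np.sqrt(((aligned.vertices - ed.vertices) ** 2).sum(1).mean())
        assert resid > 1.0  # reflection cannot be absorbed


class TestProjectionDistances:
    def test_self_comparison_is_zero(self, oracle_models):
        ed, _ = oracle_models
        rep = ev.projection_distances(ed, ed)
        assert rep.mae["Global"][0] < 1e-9
        for region in ev.SURFACE_REGIONS:
            assert abs(rep.signed_mean[region]) < 1e-9

    def test_inflated_surface_has_positive_signed_mean(self, oracle_models):
        ed, _ = oracle_models
        mesh = ed.mesh()
        faces = mesh.closed_regions["epicardium"]
        v = ed.vertices.copy()
        # area-weighted vertex normals of the epicardial region
        tri = v[faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        vids = np.unique(faces)
        v[vids] += vn[vids] / norms[vids]
        inflated = BiventricularModel(ed.template, v)
        rep = ev.projection_distances(inflated, ed, aligned=True)
        assert rep.signed_mean["epicardium"] == pytest.approx(1.0, abs=0.1)

    def test_matches_brute_force_on_small_mesh(self, rng):
        import trimesh
        from cardioshape.meshfit import closest_point_on_surface, _closest_on_triangles
        m = trimesh.creation.icosphere(subdivisions=1, radius=10)  # 80 faces
        pts = rng.normal(0, 12, (200, 3))
        d, _, _, _ = closest_point_on_surface(pts, m.vertices, m.faces)
        tris = m.vertices[m.faces]
        for i in range(0, 200, 10):
            cp, _ = _closest_on_triangles(np.repeat(pts[i][None], len(tris), 0), tris)
            bf = np.linalg.norm(pts[i] - cp, axis=1).min()
            assert d[i] == pytest.approx(bf, abs=1e-9)


class TestPlaneAngulation:
    def test_examples(self):
        n = np.array([0.0, 0.0, 1.0])
        a = np.array([[0, 0, 0], [1, 0, 0.0]])
        b = np.array([[0, 0, 0], [1, 1, 0.0]])
        assert ev.plane_angulation_error(a, a, n) == pytest.approx(0.0)
        assert ev.plane_angulation_error(a, b, n) == pytest.approx(45.0)
        swapped = b[::-1]
        assert ev.plane_angulation_error(a, swapped, n) == pytest.approx(45.0)
        with pytest.raises(ValueError):
            ev.plane_angulation_error(np.zeros((2, 3)), b, n)

    def test_angle_in_upper_range_maps_below_90(self):
        n = np.array([0.0, 0.0, 1.0])
        a = np.array([[0, 0, 0], [1, 0, 0.0]])
        c = np.array([[0, 0, 0], [-1, 0.2, 0.0]])
        assert ev.plane_angulation_error(a, c, n) < 90.0


class TestBlandAltman:
    def test_examples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ev.bland_altman(x, x)
        assert res.bias == 0.0
        assert res.limits_of_agreement == (0.0, 0.0)
        assert res.r_squared == pytest.approx(1.0)
        res2 = ev.bland_altman(x, x + 2)
        assert res2.bias == 2.0

    def test_monte_carlo_limits(self, rng):
        x = rng.uniform(50, 150, 1000)
        y = x + rng.normal(0, 1.0, 1000)
        res = ev.bland_altman(x, y)
        assert abs(res.limits_of_agreement[0] - (res.bias - 1.96)) < 0.15
        assert abs(res.limits_of_agreement[1] - (res.bias + 1.96)) < 0.15


class TestZScoreTools:
    def test_holm_bonferroni_stepwise_example(self):
        reject = ev.holm_bonferroni([0.001, 0.02, 0.04], alpha=0.05)
        assert reject.tolist() == [True, True, True]
        reject2 = ev.holm_bonferroni([0.001, 0.03, 0.04], alpha=0.05)
        assert reject2.tolist() == [True, False, False]

    def test_identical_pairs_zero_difference(self, template, rng):
        from cardioshape.measures_atlas import build_atlas
        pairs = []
        for _ in range(4):
            pairs.append((BiventricularModel(template, template.vertices
                                             + rng.normal(0, 1, template.vertices.shape)),
                          BiventricularModel(template, 0.9 * template.vertices
                                             + rng.normal(0, 1, template.vertices.shape),
                                             "ES")))
        atlas = build_atlas(pairs)
        res = ev.zscore_difference(atlas, pairs, pairs, n_modes=3)
        np.testing.assert_allclose(res["mean_abs_dz"], 0, atol=1e-10)
        assert not res["reject"].any()

    def test_perturbation_shows_up(self, template, rng):
        from cardioshape.measures_atlas import build_atlas
        pairs = []
        for _ in range(4):
            pairs.append((BiventricularModel(template, template.vertices
                                             + rng.normal(0, 1, template.vertices.shape)),
                          BiventricularModel(template, 0.9 * template.vertices,
                                             "ES")))
        atlas = build_atlas(pairs)
        other = [(BiventricularModel(template,
                                     p[0].vertices + rng.normal(0, 0.5,
                                                                p[0].vertices.shape)),
                  p[1]) for p in pairs]
        res = ev.zscore_difference(atlas, pairs, other, n_modes=3)
        assert res["mean_abs_dz"].max() > 0
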