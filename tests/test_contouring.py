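import numpy as np
import pytest

from cardioshape.contouring import (assemble_guide_points, extract_contours,
                                    lift_to_3d)
from cardioshape.imaging_io import ImagePlaneMeta
from cardioshape.meshfit import closest_point_on_surface
from cardioshape.oracle import oracle_guides


def _disk(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


class TestExtractContours:
    def test_concentric_disks_radii(self):
        mask = np.zeros((96, 96), dtype=np.uint8)
        mask[_disk(mask.shape, (48, 48), 30)] = 2   # myocardium
        mask[_disk(mask.shape, (48, 48), 20)] = 1   # cavity
        cs = extract_contours(mask, "2Ch LT")
        endo = cs.points("lv_endo")
        epi = cs.points("epicardium")
        r_endo = np.linalg.norm(endo - [48, 48], axis=1)
        r_epi = np.linalg.norm(epi - [48, 48], axis=1)
        assert np.abs(r_endo - 20).max() < 1.0
        assert np.abs(r_epi - 30).max() < 1.0
        assert "septum" not in cs.contours

    def test_papillary_island_merged_into_cavity(self):
        mask = np.zeros((96, 96), dtype=np.uint8)
        mask[_disk(mask.shape, (48, 48), 30)] = 2
        mask[_disk(mask.shape, (48, 48), 20)] = 1
        mask[_disk(mask.shape, (48, 48), 4)] = 0  # papillary-like hole
        cs = extract_contours(mask, "2Ch LT")
        r = np.linalg.norm(cs.points("lv_endo") - [48, 48], axis=1)
        assert r.min() > 15  # the island boundary was not traced

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            cs = extract_contours(np.zeros((32, 32), dtype=np.uint8), "SAx")
        assert cs.total_points() == 0

    def test_septum_lies_between_cavities_and_avoids_epicardium(self):
        # two cavities sharing a wall, like a simplified 4Ch section
        mask = np.zeros((96, 128), dtype=np.uint8)
        mask[20:80, 20:90] = 2                      # LV myocardial block
        mask[30:70, 30:60] = 1                      # LV cavity
        mask[25:75, 95:120] = 4                     # RV myocardium
        mask[30:70, 98:116] = 3                     # RV cavity
        mask[25:75, 90:95] = 2                      # shared wall is LV myo
        cs = extract_contours(mask, "4Ch")
        sept = cs.points("septum")
        epi = cs.points("epicardium")
        assert len(sept) > 0
        # septal points hug the LV-side boundary next to the RV
        assert sept[:, 1].min() > 80
        sep_set = {tuple(np.round(p, 3)) for p in sept}
        epi_set = {tuple(np.round(p, 3)) for p in epi}
        assert not (sep_set & epi_set)

    def test_unsegmented_views_rejected(self):
        with pytest.raises(ValueError):
            extract_contours(np.zeros((8, 8), dtype=np.uint8), "LVOT")


class TestLiftTo3D:
    def test_planar_lift_preserves_distances(self):
        meta = ImagePlaneMeta(origin_mm=[5, -3, 10], row_dir=[0, 0, -1],
                              col_dir=[1, 0, 0], row_spacing_mm=1.4,
                              col_spacing_mm=1.4)
        pts = np.array([[0.0, 0.0], [3.0, 4.0], [10.0, 0.0]])
        c3, l3 = lift_to_3d(None, {"A": pts[0], "B": pts[1]}, meta)
        d2 = np.linalg.norm(pts[1] - pts[0]) * 1.4
        assert np.linalg.norm(l3["B"] - l3["A"]) == pytest.approx(d2, abs=1e-9)

    def test_identity_plane_constant_z(self):
        meta = ImagePlaneMeta(origin_mm=[0, 0, 7], row_dir=[0, 1, 0],
                              col_dir=[1, 0, 0], row_spacing_mm=2,
                              col_spacing_mm=2)
        _c3, l3 = lift_to_3d(None, {"A": (3, 4), "B": (8, 1)}, meta)
        assert l3["A"][2] == 7 and l3["B"][2] == 7


class TestGuideAssembly:
    def test_oracle_guides_lie_on_true_surfaces(self, default_truth):
        ged, _ges = oracle_guides(default_truth)
        mesh = default_truth.true_surfaces[0]
        voxel = default_truth.params.in_plane_spacing_mm
        for cls in ("lv_endo", "rv_endo", "septum", "epicardium"):
            d, _, _, _ = closest_point_on_surface(
                ged.contour_points[cls], mesh.vertices, mesh.match_surfaces[cls])
            assert np.median(d) <= voxel, f"{cls}: median {np.median(d):.2f}"

    def test_all_valve_pairs_present(self, default_truth):
        ged, ges = oracle_guides(default_truth)
        for gset in (ged, ges):
            by = gset.landmarks_by_name()
            for name in ("MV1", "MV2", "AV1", "AV2", "TV1", "TV2",
                         "PV1", "PV2", "LV_APEX", "RV1", "RV2"):
                assert name in by, name
        assert set(ged.registration_targets()) == {
            "MV_CENTER", "AV_CENTER", "TV_CENTER", "PV_CENTER", "LV_APEX"}

    def test_es_set_uses_phantom_es_frame(self, default_truth):
        _ged, ges = oracle_guides(default_truth)
        assert ges.phase == "ES"
        # the ES guide cloud is smaller than ED for the contracted LV
        ged, _ = oracle_guides(default_truth)
        assert ges.n_contour_points() < ged.n_contour_points()

    def test_json_round_trip(self, default_truth):
        ged, _ = oracle_guides(default_truth)
        g2 = type(ged).from_json(ged.to_json())
        assert g2.phase == ged.phase
        for cls, pts in ged.contour_points.items():
            np.testing.assert_allclose(g2.contour_points[cls], pts)
        assert len(g2.landmark_points) == len(ged.landmark_points)

    def test_requires_optimal_sax(self, default_truth):
        meta = default_truth.study.series[0].meta
        info = [{"series_id": "a", "view": "4Ch", "meta": meta, "masks": {},
                 "landmarks": {}}]
        with pytest.raises(ValueError, match="optimal SAx"):
            assemble_guide_points(info, es_frame=10)
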