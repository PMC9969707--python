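"""Synthetic biventricular cine CMR studies with complete ground truth.

Every phantom is a multi-series cine study rendered from the analytic
geometry in :mod:`cardioshape.geometry`: seven cardiac view planes
(2Ch LT, 2Ch RT, 3Ch, 4Ch, LVOT, RVOT and a short-axis stack spanning
beyond apex and base) plus axial "other" series, imaged over a full
cardiac cycle with a raised-cosine contraction whose minimum cavity
volume falls exactly on the requested end-systolic frame and whose
volume excursion matches the requested ejection fraction by
construction.  Blood pool renders bright, myocardium mid-gray,
background dark, with additive Gaussian noise.

Alongside the images the generator returns everything a human analyst
would have annotated: view labels, optimal-slice flags, the ES frame,
per-view landmark pixel coordinates, label masks, analytic cavity/wall
volumes, and ground-truth surface meshes in patient coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import geometry as geo
from .imaging_io import CineSeries, CineStudy, ImagePlaneMeta, patient_to_pixel

__all__ = ["PhantomParams", "PhantomTruth", "make_phantom", "sample_population"]

VIEW_2CH_LT = "2Ch LT"
VIEW_2CH_RT = "2Ch RT"
VIEW_3CH = "3Ch"
VIEW_4CH = "4Ch"
VIEW_LVOT = "LVOT"
VIEW_RVOT = "RVOT"
VIEW_SAX = "SAx"
VIEW_OTHER = "OTHER"

# tissue intensity rendering (arbitrary units in [0, 1])
_INTENSITY = {"bg": 0.05, "torso": 0.30, "myo": 0.55, "blood": 0.92}

# structures retained in the ground-truth masks of each segmented view
_VIEW_KEEP = {
    VIEW_2CH_LT: (geo.LV_CAV, geo.LV_MYO),
    VIEW_2CH_RT: (geo.RV_CAV, geo.RV_MYO),
    VIEW_RVOT: (geo.RV_CAV, geo.RV_MYO),
    VIEW_3CH: (geo.LV_CAV, geo.LV_MYO, geo.RV_CAV, geo.RV_MYO),
    VIEW_4CH: (geo.LV_CAV, geo.LV_MYO, geo.RV_CAV, geo.RV_MYO),
    VIEW_SAX: (geo.LV_CAV, geo.LV_MYO, geo.RV_CAV, geo.RV_MYO),
}


@dataclass
class PhantomParams:
    """Anatomical, functional and imaging parameters of one phantom."""

    lv_long_axis_mm: float = 80.0
    lv_short_radius_mm: float = 25.0
    lv_wall_mm: float = 9.0
    rv_crescent_extent_rad: float = 2.0943951023931953
    rv_depth_mm: float = 18.0
    rv_wall_mm: float = 5.0
    ef_target_fraction: float = 0.5
    es_frame: int = 12
    n_frames: int = 30
    sax_spacing_mm: float = 8.0
    in_plane_spacing_mm: float = 1.4
    noise_sd: float = 0.03
    seed: int = 0
    image_size: int = 128
    slice_thickness_mm: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ef_target_fraction < 1.0):
            raise ValueError("ef_target_fraction must be in (0, 1)")
        if not (0 < self.es_frame < self.n_frames):
            raise ValueError("es_frame must lie strictly inside [1, n_frames)")
        if min(self.sax_spacing_mm, self.in_plane_spacing_mm) <= 0:
            raise ValueError("spacings must be positive")
        # geometric feasibility (raises for wall >= radius)
        self.geometry()

    def geometry(self) -> geo.BivGeometry:
        return geo.BivGeometry(
            lv_long_axis_mm=self.lv_long_axis_mm,
            lv_short_radius_mm=self.lv_short_radius_mm,
            lv_wall_mm=self.lv_wall_mm,
            rv_crescent_extent_rad=self.rv_crescent_extent_rad,
            rv_depth_mm=self.rv_depth_mm,
            rv_wall_mm=self.rv_wall_mm,
        )


@dataclass
class PhantomTruth:
    """A generated study plus every ground-truth label it was built from.

    ``masks`` follow the per-view labeling convention (only the
    structures annotated in that view are present); ``full_masks`` keep
    all structures and are what segmentation training consumes.
    """

    study: CineStudy
    params: PhantomParams
    view_labels: dict[str, str]
    optimal_flags: dict[str, bool]
    es_frame: int
    landmarks_px: dict[tuple[str, str, int], np.ndarray]
    masks: dict[tuple[str, int], np.ndarray]
    full_masks: dict[tuple[str, int], np.ndarray]
    analytic_volumes: dict[tuple[str, int], float]
    true_surfaces: dict[int, geo.BivMesh]
    pose_rotation: np.ndarray
    pose_translation: np.ndarray
    lam: np.ndarray
    mu: np.ndarray

    @property
    def geometry(self) -> geo.BivGeometry:
        return self.params.geometry()

    def landmarks_for(self, series_id: str, frame: int) -> dict[str, np.ndarray]:
        return {name: rc for (sid, name, f), rc in self.landmarks_px.items()
                if sid == series_id and f == frame}

    def sax_series_ids(self) -> list[str]:
        return [sid for sid, v in self.view_labels.items() if v == VIEW_SAX]

    def optimal_sax_ids(self) -> list[str]:
        return [sid for sid in self.sax_series_ids() if self.optimal_flags[sid]]

    def heart_to_patient(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.pose_rotation.T + self.pose_translation

    def patient_to_heart(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.pose_translation) @ self.pose_rotation

    def true_surface(self, region: str, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(vertices, faces) of a region's closed ground-truth surface."""
        mesh = self.true_surfaces[frame]
        return mesh.vertices, mesh.closed_regions[region]


def _pose(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Heart-to-patient pose: a typical oblique cardiac orientation with a
    small random jitter so no two phantoms are identically posed."""
    ang = np.array([0.20, 0.70, 0.35]) + rng.uniform(-0.05, 0.05, 3)
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    trans = np.array([-30.0, -20.0, 40.0]) + rng.uniform(-5, 5, 3)
    return rot, trans


def _plane_meta(center_h, row_h, col_h, n_px, spacing, rot, trans,
                thickness) -> ImagePlaneMeta:
    row_dir = rot @ np.asarray(row_h, dtype=float)
    col_dir = rot @ np.asarray(col_h, dtype=float)
    center = rot @ np.asarray(center_h, dtype=float) + trans
    origin = (center - (n_px - 1) / 2 * spacing * row_dir
              - (n_px - 1) / 2 * spacing * col_dir)
    return ImagePlaneMeta(origin_mm=origin, row_dir=row_dir, col_dir=col_dir,
                          row_spacing_mm=spacing, col_spacing_mm=spacing,
                          slice_thickness_mm=thickness)


def _long_axis_basis(azimuth: float, tilt: float = 0.0):
    """(row, col) in-plane basis of a long-axis plane at the given azimuth;
    a nonzero tilt rotates the row direction off the long axis."""
    col = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    row = np.array([0.0, 0.0, -1.0])
    if tilt:
        n = np.cross(row, col)
        row = np.cos(tilt) * row + np.sin(tilt) * n
    return row, col


def _stable_pair_order(px: np.ndarray) -> np.ndarray:
    """Name an insert pair along its dominant image axis.

    Sorting by the axis with the larger separation is invariant to the
    small in-plane prescription jitter, so each landmark name refers to
    the same anatomical side in every phantom.
    """
    d = np.abs(px[1] - px[0])
    axis = 0 if d[0] >= d[1] else 1
    return np.argsort(px[:, axis])


def _project_to_plane(point, plane_point, normal):
    normal = normal / np.linalg.norm(normal)
    return point - ((point - plane_point) @ normal) * normal


def make_phantom(params: PhantomParams, frames: str = "all") -> PhantomTruth:
    """Generate one synthetic study with complete ground truth.

    ``frames="all"`` renders every cine frame; ``frames="edes"`` renders
    only the temporal neighborhoods of ED and ES (frames t-2..t+2 around
    each, cyclically) and leaves the remaining frames zero — sufficient
    for landmark/segmentation work and roughly three times faster.
    Masks and landmarks are always provided for rendered frames only.
    """
    if frames not in ("all", "edes"):
        raise ValueError("frames must be 'all' or 'edes'")
    g = params.geometry()
    rng = np.random.default_rng(params.seed)
    rot, trans = _pose(rng)
    n_px = params.image_size
    sp = params.in_plane_spacing_mm
    nt = params.n_frames

    t = np.arange(nt)
    w = geo.contraction_weight(t, params.es_frame, nt)
    lam = 1.0 - (1.0 - g.lv_scale_for_ef(params.ef_target_fraction)) * w
    mu = 1.0 - (1.0 - g.rv_scale_for_ef(params.ef_target_fraction)) * w

    if frames == "all":
        rendered = list(range(nt))
    else:
        rendered = sorted({(f + k) % nt for f in (0, params.es_frame)
                           for k in (-2, -1, 0, 1, 2)})

    heart_center_h = np.array([0.0, 0.0, -g.l_epi / 2])
    torso_center = rot @ heart_center_h + trans + np.array([0.0, 30.0, 0.0])

    # ---- view plane definitions (heart frame) ----
    planes: list[tuple[str, str, ImagePlaneMeta]] = []  # (series_id, view, meta)

    def jitter_plane(row, col, center):
        """Operator imprecision: small in-plane rotation and shift."""
        n = np.cross(row, col)
        n = n / np.linalg.norm(n)
        ang = rng.uniform(-0.14, 0.14)  # ~±8 deg about the plane normal
        row = np.cos(ang) * row + np.sin(ang) * np.cross(n, row)
        col = np.cos(ang) * col + np.sin(ang) * np.cross(n, col)
        shift = rng.uniform(-4.0, 4.0, 2)
        center = center + shift[0] * row + shift[1] * col
        return row, col, center

    def add_long_axis(series_id, view, azimuth, tilt=0.0, through=None, offset=0.0):
        row, col = _long_axis_basis(azimuth, tilt)
        center = heart_center_h.copy()
        if through is not None:
            n = np.cross(row, col)
            center = _project_to_plane(heart_center_h, through, n)
        if offset:
            n = np.cross(row, col)
            n = n / np.linalg.norm(n)
            rvdir = np.array([np.cos(g.theta0), np.sin(g.theta0), 0.0])
            if n @ rvdir < 0:
                n = -n
            center = center + offset * n
        row, col, center = jitter_plane(row, col, center)
        planes.append((series_id, view,
                       _plane_meta(center, row, col, n_px, sp, rot, trans,
                                   params.slice_thickness_mm)))

    add_long_axis("4Ch", VIEW_4CH, g.theta0)
    add_long_axis("3Ch", VIEW_3CH, g.av_azimuth)
    add_long_axis("2ChLT", VIEW_2CH_LT, g.theta0 + np.pi / 2)
    add_long_axis("2ChRT", VIEW_2CH_RT, g.theta0 + np.deg2rad(35), offset=16.0)
    add_long_axis("LVOT", VIEW_LVOT, g.av_azimuth, tilt=np.deg2rad(20),
                  through=g.valve_circle("AV")[0])
    add_long_axis("RVOT", VIEW_RVOT, g.pv_azimuth, tilt=np.deg2rad(25),
                  through=g.valve_circle("PV")[0])

    # short-axis stack: from above the base to below the apex
    sax_z = []
    z = 1.7 * params.sax_spacing_mm
    while z > -g.l_epi - 1.8 * params.sax_spacing_mm:
        sax_z.append(z)
        z -= params.sax_spacing_mm
    # one prescription (jitter) for the whole stack
    sax_row, sax_col, sax_c0 = jitter_plane(np.array([0.0, 1.0, 0.0]),
                                            np.array([1.0, 0.0, 0.0]),
                                            np.zeros(3))
    for i, zs in enumerate(sax_z):
        planes.append((f"SAx{i:02d}", VIEW_SAX,
                       _plane_meta(sax_c0 + [0.0, 0.0, zs], sax_row, sax_col,
                                   n_px, sp, rot, trans, params.sax_spacing_mm)))

    # "other": axial scanner-frame planes through the torso
    for j, dz in enumerate((70.0, -80.0)):
        origin_center = torso_center + np.array([0.0, 0.0, dz])
        row_dir = np.array([0.0, 1.0, 0.0])
        col_dir = np.array([1.0, 0.0, 0.0])
        spacing = 2.5
        origin = origin_center - (n_px - 1) / 2 * spacing * (row_dir + col_dir)
        planes.append((f"OTHER{j}", VIEW_OTHER,
                       ImagePlaneMeta(origin_mm=origin, row_dir=row_dir,
                                      col_dir=col_dir, row_spacing_mm=spacing,
                                      col_spacing_mm=spacing,
                                      slice_thickness_mm=8.0)))

    # ---- rendering ----
    series_list, view_labels = [], {}
    masks: dict[tuple[str, int], np.ndarray] = {}
    full_masks: dict[tuple[str, int], np.ndarray] = {}

    rr, cc = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    for series_id, view, meta in planes:
        pts = (meta.origin_mm
               + rr[..., None] * meta.row_spacing_mm * meta.row_dir
               + cc[..., None] * meta.col_spacing_mm * meta.col_dir)
        pts_flat = pts.reshape(-1, 3)
        pts_h = (pts_flat - trans) @ rot  # heart frame
        d = pts_flat - torso_center
        in_torso = ((d[:, 0] / 170.0) ** 2 + (d[:, 1] / 120.0) ** 2 <= 1.0) \
            & (np.abs(d[:, 2]) <= 200.0)
        stack = np.zeros((nt, n_px, n_px), dtype=np.float32)
        for ti in rendered:
            labels = g.classify(pts_h, lam=lam[ti], mu=mu[ti], vessels=True)
            img = np.full(labels.shape, _INTENSITY["bg"], dtype=np.float32)
            img[in_torso] = _INTENSITY["torso"]
            img[(labels == geo.LV_MYO) | (labels == geo.RV_MYO)
                | (labels == geo.VESSEL_WALL)] = _INTENSITY["myo"]
            img[(labels == geo.LV_CAV) | (labels == geo.RV_CAV)
                | (labels == geo.VESSEL_BLOOD)] = _INTENSITY["blood"]
            if params.noise_sd > 0:
                img = img + rng.normal(0.0, params.noise_sd, img.shape).astype(np.float32)
            stack[ti] = img.reshape(n_px, n_px)
            # great vessels are rendering detail, not segmentation truth
            labels = np.where(labels <= geo.RV_MYO, labels, geo.BG)
            lab_img = labels.reshape(n_px, n_px).astype(np.uint8)
            full_masks[(series_id, ti)] = lab_img
            if view in _VIEW_KEEP:
                keep = _VIEW_KEEP[view]
                masks[(series_id, ti)] = np.where(
                    np.isin(lab_img, keep), lab_img, 0).astype(np.uint8)
        series_list.append(CineSeries(frames=stack, meta=meta, series_id=series_id))
        view_labels[series_id] = view

    study = CineStudy(series=series_list, study_id=f"phantom{params.seed}")

    # ---- optimal-slice flags: planes crossing the LV cavity between the
    # apex and the base (valve) plane ----
    optimal_flags = {}
    for i, zs in enumerate(sax_z):
        optimal_flags[f"SAx{i:02d}"] = bool(-g.l_endo < zs < 0.0)

    # ---- landmarks (pixel coordinates per frame) ----
    landmarks_px: dict[tuple[str, str, int], np.ndarray] = {}
    metas = {sid: m for sid, _v, m in planes}

    def add_insert_pair(series_id, valve, names, ti):
        meta = metas[series_id]
        p0_h = (meta.origin_mm - trans) @ rot
        n_h = rot.T @ meta.normal
        pts = g.circle_plane_intersection(valve, p0_h, n_h,
                                          lam=lam[ti], mu=mu[ti])
        if pts is None:
            return
        px = patient_to_pixel(meta, pts @ rot.T + trans)
        order = _stable_pair_order(px)
        for name, k in zip(names, order):
            landmarks_px[(series_id, name, ti)] = px[k]

    for ti in rendered:
        add_insert_pair("3Ch", "MV", ("MV1", "MV2"), ti)
        add_insert_pair("3Ch", "AV", ("AV1", "AV2"), ti)
        add_insert_pair("4Ch", "MV", ("MV1", "MV2"), ti)
        add_insert_pair("4Ch", "TV", ("TV1", "TV2"), ti)
        add_insert_pair("RVOT", "PV", ("PV1", "PV2"), ti)
        apex = g.apex(lam[ti]) @ rot.T + trans
        landmarks_px[("4Ch", "LV_APEX", ti)] = patient_to_pixel(metas["4Ch"], apex)
        for i, zs in enumerate(sax_z):
            sid = f"SAx{i:02d}"
            if optimal_flags[sid] and zs > -0.98 * g.l_rv:
                ins = g.rv_inserts(zs) @ rot.T + trans
                px = patient_to_pixel(metas[sid], ins)
                order = _stable_pair_order(px)
                landmarks_px[(sid, "RV1", ti)] = px[order[0]]
                landmarks_px[(sid, "RV2", ti)] = px[order[1]]

    # ---- analytic volumes (mL) ----
    analytic_volumes = {}
    for ti in range(nt):
        analytic_volumes[("lv_cavity", ti)] = g.lv_cavity_volume(lam[ti]) / 1000.0
        analytic_volumes[("rv_cavity", ti)] = g.rv_cavity_volume(mu[ti]) / 1000.0
        analytic_volumes[("lv_wall", ti)] = g.lv_wall_volume(lam[ti]) / 1000.0
        analytic_volumes[("rv_wall", ti)] = g.rv_wall_volume(mu[ti]) / 1000.0

    # ---- ground-truth surfaces at ED and ES (patient coordinates) ----
    true_surfaces = {}
    for ti in {0, params.es_frame}:
        mesh = geo.build_surface_mesh(g, lam=lam[ti], mu=mu[ti])
        true_surfaces[ti] = mesh.with_vertices(mesh.vertices @ rot.T + trans)

    return PhantomTruth(
        study=study, params=params, view_labels=view_labels,
        optimal_flags=optimal_flags, es_frame=params.es_frame,
        landmarks_px=landmarks_px, masks=masks, full_masks=full_masks,
        analytic_volumes=analytic_volumes, true_surfaces=true_surfaces,
        pose_rotation=rot, pose_translation=trans, lam=lam, mu=mu,
    )


def sample_population(n: int, param_ranges: dict[str, tuple[float, float]] | None = None,
                      seed: int = 0, frames: str = "all",
                      ) -> tuple[list[PhantomTruth], pd.DataFrame]:
    """Draw ``n`` phantoms with parameters uniform over the given ranges.

    Unspecified fields keep their defaults.  Returns the phantoms and
    the drawn parameter table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    param_ranges = dict(param_ranges or {})
    valid = {f.name for f in fields(PhantomParams)}
    int_fields = {"es_frame", "n_frames", "image_size", "seed"}
    for k, (lo, hi) in param_ranges.items():
        if k not in valid:
            raise ValueError(f"unknown parameter: {k}")
        if hi < lo:
            raise ValueError(f"empty range for {k}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    rows, truths = [], []
    for _ in range(n):
        kw = {}
        for k, (lo, hi) in param_ranges.items():
            if k in int_fields:
                kw[k] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                kw[k] = float(rng.uniform(lo, hi))
        kw.setdefault("seed", int(rng.integers(0, 2**31 - 1)))
        p = PhantomParams(**kw)
        rows.append({f.name: getattr(p, f.name) for f in fields(PhantomParams)})
        truths.append(make_phantom(p, frames=frames))
    return truths, pd.DataFrame(rows)
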