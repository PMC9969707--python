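"""Parametric biventricular anatomy.

A single analytic geometry underlies the whole package: the left
ventricle is a thick-walled half-ellipsoid (apex down, flat base/valve
plane at z = 0 in the heart frame), and the right ventricle is a
crescent-shaped cavity wrapped around the LV epicardium over a limited
angular extent, with a thin free wall.  Contraction scales the LV
cavity about the base-plane center by ``lam`` and the RV crescent depth
by ``mu``; both are driven by a periodic raised-cosine weight whose
peak defines end-systole.

The same geometry provides: implicit point classification (used to
render images and masks), closed-form/quadrature cavity and wall
volumes, valve-ring circles, and a parametric surface mesh builder with
fixed topology (used both for per-phantom ground-truth surfaces and for
the fitting template, so all models share topology by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "BivGeometry",
    "BivMesh",
    "contraction_weight",
    "signed_volume",
    "build_surface_mesh",
    "MESH_N_THETA_WINDOW",
    "MESH_N_THETA_OUTSIDE",
    "MESH_N_RINGS",
    "MESH_RV_ROW",
    "RV_LENGTH_FRAC",
]

# Fixed mesh topology parameters: every mesh built by build_surface_mesh
# shares vertex/face counts and connectivity, regardless of the geometry's
# metric parameters (the RV angular window is always spanned by the same
# number of columns).
MESH_N_THETA_WINDOW = 12   # columns across the RV crescent window
MESH_N_THETA_OUTSIDE = 24  # columns outside the window
MESH_N_RINGS = 14          # latitude rings from apex to base
MESH_RV_ROW = 6            # ring index where the RV crescent begins (apexward)
# RV long-axis extent as a fraction of the epicardial long axis; tied to the
# mesh latitude grid so the crescent's apical rim falls exactly on a ring.
RV_LENGTH_FRAC = float(np.cos(MESH_RV_ROW * (np.pi / 2) / MESH_N_RINGS))

# Background / tissue class codes used in all label images.  Codes 5/6 are
# great-vessel blood/wall: rendered for realism (they make the outflow-tract
# and three-chamber views identifiable) but never part of the segmentation
# ground truth, which covers only the four cavity/myocardium structures.
BG, LV_CAV, LV_MYO, RV_CAV, RV_MYO, VESSEL_BLOOD, VESSEL_WALL = 0, 1, 2, 3, 4, 5, 6
CLASS_NAMES = {BG: "background", LV_CAV: "LV cavity", LV_MYO: "LV myocardium",
               RV_CAV: "RV cavity", RV_MYO: "RV myocardium",
               VESSEL_BLOOD: "vessel blood", VESSEL_WALL: "vessel wall"}


def contraction_weight(t, es_frame: int, n_frames: int):
    """Periodic raised-cosine contraction weight.

    0 at frame 0 (end-diastole), rising smoothly to exactly 1 at
    ``es_frame`` and back to 0 at frame ``n_frames`` (== frame 0 of the
    next cycle): piecewise raised cosine on the systolic and diastolic
    limbs.
    """
    t = np.asarray(t, dtype=float)
    if not (0 < es_frame < n_frames):
        raise ValueError("es_frame must lie strictly inside the cycle")
    w = np.where(
        t <= es_frame,
        0.5 * (1.0 - np.cos(np.pi * t / es_frame)),
        0.5 * (1.0 + np.cos(np.pi * (t - es_frame) / (n_frames - es_frame))),
    )
    return w if w.ndim else float(w)


@dataclass
class BivGeometry:
    """Metric parameters of the biventricular anatomy (heart frame, mm)."""

    lv_long_axis_mm: float = 80.0      # endocardial long semi-axis at ED
    lv_short_radius_mm: float = 25.0   # endocardial short radius at ED
    lv_wall_mm: float = 9.0
    rv_crescent_extent_rad: float = 2.0943951023931953  # 120 deg
    rv_depth_mm: float = 18.0          # max crescent depth at ED
    rv_wall_mm: float = 5.0
    theta0: float = 0.0                # azimuth of the crescent center
    av_azimuth: float = -0.8726646259971648  # -50 deg, 3Ch/LVOT direction

    def __post_init__(self) -> None:
        if self.lv_wall_mm <= 0:
            raise ValueError("lv_wall_mm must be positive")
        if self.lv_wall_mm >= self.lv_short_radius_mm:
            raise ValueError(
                "infeasible geometry: wall thickness must be smaller than the "
                "LV short radius")
        if not (0 < self.rv_crescent_extent_rad < 2 * np.pi):
            raise ValueError("rv_crescent_extent_rad must be in (0, 2*pi)")
        if self.rv_wall_mm <= 0 or self.rv_depth_mm <= 0:
            raise ValueError("RV wall/depth must be positive")

    # -- derived lengths -------------------------------------------------
    @property
    def r_endo(self) -> float:
        return self.lv_short_radius_mm

    @property
    def l_endo(self) -> float:
        return self.lv_long_axis_mm

    @property
    def r_epi(self) -> float:
        return self.lv_short_radius_mm + self.lv_wall_mm

    @property
    def l_epi(self) -> float:
        return self.lv_long_axis_mm + self.lv_wall_mm

    @property
    def l_rv(self) -> float:
        return RV_LENGTH_FRAC * self.l_epi

    # -- field helpers ---------------------------------------------------
    def rho_lv_epi(self, z):
        """LV epicardial radius at height z (0 outside [-l_epi, 0])."""
        z = np.asarray(z, dtype=float)
        return self.r_epi * np.sqrt(np.clip(1.0 - (z / self.l_epi) ** 2, 0.0, None))

    def crescent_profile(self, theta, z):
        """Unit crescent profile g(theta, z) in [0, 1].

        Cosine taper across the angular window, elliptic taper toward the
        crescent's apical rim; zero outside the window / z-range.
        """
        theta = np.asarray(theta, dtype=float)
        z = np.asarray(z, dtype=float)
        half = self.rv_crescent_extent_rad / 2.0
        dth = np.mod(theta - self.theta0 + np.pi, 2 * np.pi) - np.pi
        ang = np.where(np.abs(dth) < half, np.cos(np.pi * dth / self.rv_crescent_extent_rad), 0.0)
        tau = np.sqrt(np.clip(1.0 - (z / self.l_rv) ** 2, 0.0, None))
        tau = np.where((z <= 0) & (z >= -self.l_rv), tau, 0.0)
        return ang * tau

    # -- implicit classification ----------------------------------------
    def classify(self, points: np.ndarray, lam: float = 1.0, mu: float = 1.0,
                 vessels: bool = False) -> np.ndarray:
        """Tissue class of heart-frame points (..., 3).

        Returns integer labels per CLASS_NAMES.  ``lam`` scales the LV
        cavity (about the base center), ``mu`` the RV crescent depth.
        ``vessels`` additionally paints the aortic root and pulmonary
        trunk (straight tubes rising from the AV/PV rings) — rendering
        detail only, never segmentation ground truth.
        """
        p = np.asarray(points, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        rho2 = x * x + y * y
        out = np.zeros(x.shape, dtype=np.uint8)
        below_base = z <= 0.0

        in_endo = below_base & (
            rho2 / (lam * self.r_endo) ** 2 + (z / (lam * self.l_endo)) ** 2 <= 1.0)
        in_epi = below_base & (
            rho2 / self.r_epi ** 2 + (z / self.l_epi) ** 2 <= 1.0)

        theta = np.arctan2(y, x)
        g = self.crescent_profile(theta, z)
        rho = np.sqrt(rho2)
        rho_epi = self.rho_lv_epi(z)
        in_rv_cav = below_base & (g > 0) & (rho > rho_epi) & (
            rho <= rho_epi + mu * self.rv_depth_mm * g)
        in_rv_myo = below_base & (g > 0) & ~in_rv_cav & (rho > rho_epi) & (
            rho <= rho_epi + (mu * self.rv_depth_mm + self.rv_wall_mm) * g)

        out[in_rv_myo] = RV_MYO
        out[in_rv_cav] = RV_CAV
        out[in_epi] = LV_MYO
        out[in_endo] = LV_CAV

        if vessels:
            # atria: bright blood pools above the base plane.  They give the
            # two/four-chamber views their defining appearance but, like the
            # great vessels, are rendering detail only.
            for c_a, semi in self._atria():
                rel = (p - c_a) / semi
                q = np.einsum("...i,...i->...", rel, rel)
                rel_w = (p - c_a) / (semi + 2.5)
                qw = np.einsum("...i,...i->...", rel_w, rel_w)
                above = z >= -1e-9
                out[(qw <= 1.0) & (out == BG) & above] = VESSEL_WALL
                out[(q <= 1.0) & ((out == BG) | (out == VESSEL_WALL)) & above] = VESSEL_BLOOD
            for name, wall in (("AV", 2.5), ("PV", 2.5)):
                c, r = self.valve_circle(name, lam=1.0, mu=mu)
                az = self.av_azimuth if name == "AV" else self.pv_azimuth
                d = np.array([0.3 * np.cos(az), 0.3 * np.sin(az), 1.0])
                d /= np.linalg.norm(d)
                rel = p - c
                t_ax = rel @ d
                radial = rel - t_ax[..., None] * d
                rr = np.sqrt(np.einsum("...i,...i->...", radial, radial))
                seg = (t_ax >= 0.0) & (t_ax <= 45.0) & (out == BG)
                out[seg & (rr <= r + wall)] = VESSEL_WALL
                out[seg & (rr <= r)] = VESSEL_BLOOD
        return out

    # -- analytic volumes (mm^3) ----------------------------------------
    def lv_cavity_volume(self, lam: float = 1.0) -> float:
        """Half-ellipsoid cavity volume: (2/3) pi (lam r)^2 (lam l)."""
        return (2.0 / 3.0) * np.pi * (lam * self.r_endo) ** 2 * (lam * self.l_endo)

    def lv_wall_volume(self, lam: float = 1.0) -> float:
        return (2.0 / 3.0) * np.pi * self.r_epi ** 2 * self.l_epi - self.lv_cavity_volume(lam)

    def _rv_integrals(self) -> tuple[float, float]:
        """(I_rho_tau, I_tau2): z-integrals used by the RV volume formulas."""
        lrv = self.l_rv

        def rho_tau(z):
            return self.rho_lv_epi(z) * np.sqrt(max(0.0, 1.0 - (z / lrv) ** 2))

        i1 = quad(rho_tau, -lrv, 0.0, limit=200)[0]
        i2 = 2.0 * lrv / 3.0  # integral of tau^2
        return i1, i2

    def rv_cavity_volume(self, mu: float = 1.0) -> float:
        """Crescent cavity volume; linear+quadratic in the depth scale mu."""
        ext, d = self.rv_crescent_extent_rad, self.rv_depth_mm
        i1, i2 = self._rv_integrals()
        a = d * (2.0 * ext / np.pi) * i1
        b = d * d * (ext / 4.0) * i2
        return a * mu + b * mu * mu

    def rv_wall_volume(self, mu: float = 1.0) -> float:
        ext, d, w = self.rv_crescent_extent_rad, self.rv_depth_mm, self.rv_wall_mm
        i1, i2 = self._rv_integrals()
        return w * (2.0 * ext / np.pi) * i1 + (w * w + 2.0 * mu * d * w) * (ext / 4.0) * i2

    # -- contraction schedules -------------------------------------------
    def lv_scale_for_ef(self, ef: float) -> float:
        """End-systolic LV cavity scale giving exactly the requested EF."""
        if not (0 < ef < 1):
            raise ValueError("ejection fraction must be in (0, 1)")
        return (1.0 - ef) ** (1.0 / 3.0)

    def rv_scale_for_ef(self, ef: float) -> float:
        """End-systolic RV depth scale: solves the quadratic volume law."""
        if not (0 < ef < 1):
            raise ValueError("ejection fraction must be in (0, 1)")
        ext, d = self.rv_crescent_extent_rad, self.rv_depth_mm
        i1, i2 = self._rv_integrals()
        a = d * (2.0 * ext / np.pi) * i1
        b = d * d * (ext / 4.0) * i2
        target = (1.0 - ef) * (a + b)
        return (-a + np.sqrt(a * a + 4.0 * b * target)) / (2.0 * b)

    # -- valve rings ------------------------------------------------------
    def valve_circle(self, name: str, lam: float = 1.0, mu: float = 1.0
                     ) -> tuple[np.ndarray, float]:
        """(center, radius) of a valve ring circle in the base plane."""
        ext, d = self.rv_crescent_extent_rad, self.rv_depth_mm

        def u(az):
            return np.array([np.cos(az), np.sin(az), 0.0])

        if name == "MV":
            return np.zeros(3), lam * self.r_endo
        if name == "AV":
            return 0.40 * self.r_endo * u(self.av_azimuth), 0.22 * self.r_endo
        if name == "TV":
            return (self.r_epi + 0.5 * mu * d) * u(self.theta0), 0.35 * mu * d
        if name == "PV":
            az = self.theta0 + 0.6 * ext / 2.0
            depth = mu * d * np.cos(0.6 * np.pi / 2.0)
            return (self.r_epi + 0.5 * depth) * u(az), 0.2 * mu * d
        raise KeyError(name)

    def _atria(self):
        """(center, semi-axes) of the left and right atrial ellipsoids."""
        r = self.r_endo
        u_la = np.array([np.cos(self.av_azimuth + np.pi),
                         np.sin(self.av_azimuth + np.pi), 0.0])
        la = (0.45 * r * u_la + np.array([0.0, 0.0, 0.55 * r]),
              np.array([0.70 * r, 0.70 * r, 0.55 * r]))
        u_ra = np.array([np.cos(self.theta0), np.sin(self.theta0), 0.0])
        ra = ((self.r_epi + 0.5 * self.rv_depth_mm) * u_ra
              + np.array([0.0, 0.0, 0.5 * r]),
              np.array([0.62 * r, 0.62 * r, 0.5 * r]))
        return [la, ra]

    @property
    def pv_azimuth(self) -> float:
        return self.theta0 + 0.6 * self.rv_crescent_extent_rad / 2.0

    def apex(self, lam: float = 1.0) -> np.ndarray:
        """Endocardial LV apex."""
        return np.array([0.0, 0.0, -lam * self.l_endo])

    def rv_inserts(self, z: float) -> np.ndarray:
        """RV insertion points (free wall meets septum) on a SAx plane."""
        half = self.rv_crescent_extent_rad / 2.0
        rho = float(self.rho_lv_epi(z))
        return np.array([
            [rho * np.cos(self.theta0 - half), rho * np.sin(self.theta0 - half), z],
            [rho * np.cos(self.theta0 + half), rho * np.sin(self.theta0 + half), z],
        ])

    def circle_plane_intersection(self, name: str, point: np.ndarray,
                                  normal: np.ndarray, lam: float = 1.0,
                                  mu: float = 1.0) -> np.ndarray | None:
        """Intersect a valve-ring circle with a plane; (2, 3) or None.

        The circle lies in the base plane z = 0 of the heart frame; the
        query plane is given by a point and normal in the same frame.
        """
        c, r = self.valve_circle(name, lam, mu)
        u1 = np.array([1.0, 0.0, 0.0])
        u2 = np.array([0.0, 1.0, 0.0])
        normal = np.asarray(normal, dtype=float)
        a = r * float(normal @ u1)
        b = r * float(normal @ u2)
        rhs = float(normal @ (np.asarray(point, dtype=float) - c))
        amp = np.hypot(a, b)
        if amp < 1e-12 or abs(rhs) > amp:
            return None
        phi0 = np.arctan2(b, a)
        delta = np.arccos(np.clip(rhs / amp, -1.0, 1.0))
        pts = []
        for phi in (phi0 + delta, phi0 - delta):
            pts.append(c + r * (np.cos(phi) * u1 + np.sin(phi) * u2))
        return np.asarray(pts)

    def voxelized_lv_cavity_volume(self, lam: float = 1.0,
                                   spacing_mm: float = 1.4) -> float:
        """Voxel-count LV cavity volume on an isotropic grid (mm^3)."""
        r = lam * self.r_endo + 2 * spacing_mm
        xs = np.arange(-r, r, spacing_mm)
        zs = np.arange(-lam * self.l_endo - 2 * spacing_mm, spacing_mm, spacing_mm)
        xg, yg, zg = np.meshgrid(xs, xs, zs, indexing="ij")
        pts = np.stack([xg, yg, zg], axis=-1)
        labels = self.classify(pts.reshape(-1, 3), lam=lam)
        return float(np.count_nonzero(labels == LV_CAV)) * spacing_mm ** 3


# ---------------------------------------------------------------------------
# mesh construction


@dataclass
class BivMesh:
    """Labeled biventricular surface mesh with fixed shared topology.

    ``faces``/``face_region`` hold every patch once; ``closed_regions``
    re-assembles the watertight, outward-oriented boundary of each
    anatomical region; ``match_surfaces`` are the open sheets guide
    points are matched against.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_region: np.ndarray                    # str label per face
    closed_regions: dict = field(default_factory=dict)   # name -> (nf,3) faces
    match_surfaces: dict = field(default_factory=dict)   # name -> (nf,3) faces
    valve_rings: dict = field(default_factory=dict)      # name -> vertex loop
    ring_centers: dict = field(default_factory=dict)     # name -> vertex index
    landmark_vertices: dict = field(default_factory=dict)

    def copy(self) -> "BivMesh":
        return BivMesh(self.vertices.copy(), self.faces, self.face_region,
                       self.closed_regions, self.match_surfaces,
                       self.valve_rings, self.ring_centers,
                       self.landmark_vertices)

    def with_vertices(self, vertices: np.ndarray) -> "BivMesh":
        m = self.copy()
        m.vertices = np.asarray(vertices, dtype=float)
        return m

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def landmark_points(self) -> dict[str, np.ndarray]:
        return {k: self.vertices[v] for k, v in self.landmark_vertices.items()}

    def edges(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Divergence-theorem signed volume of a closed oriented surface (mm^3)."""
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


class _Builder:
    def __init__(self) -> None:
        self.verts: list[np.ndarray] = []

    def add(self, p) -> int:
        self.verts.append(np.asarray(p, dtype=float))
        return len(self.verts) - 1

    def array(self) -> np.ndarray:
        return np.asarray(self.verts)


def _strip(row0, row1, close: bool = False):
    faces = []
    n = len(row0)
    rng = range(n) if close else range(n - 1)
    for j in rng:
        a, b = row0[j], row0[(j + 1) % n]
        c, d = row1[j], row1[(j + 1) % n]
        # two triangles per quad; skip degenerates (shared boundary nodes)
        if len({a, b, d}) == 3:
            faces.append((a, b, d))
        if len({a, d, c}) == 3:
            faces.append((a, d, c))
    return faces


def build_surface_mesh(geom: BivGeometry, lam: float = 1.0, mu: float = 1.0) -> BivMesh:
    """Build the labeled biventricular surface mesh at contraction (lam, mu).

    Topology is identical for every (geom, lam, mu): the RV angular
    window is always spanned by MESH_N_THETA_WINDOW columns and begins at
    latitude ring MESH_RV_ROW.
    """
    nw, no, nu, krv = (MESH_N_THETA_WINDOW, MESH_N_THETA_OUTSIDE,
                       MESH_N_RINGS, MESH_RV_ROW)
    half = geom.rv_crescent_extent_rad / 2.0
    # theta columns: window columns first (m = 0..nw), then outside interior
    th_win = geom.theta0 - half + np.arange(nw + 1) * (2 * half / nw)
    th_out = (geom.theta0 + half
              + np.arange(1, no) * ((2 * np.pi - 2 * half) / no))
    thetas = np.concatenate([th_win, th_out])          # N = nw + no columns
    N = len(thetas)
    alphas = np.arange(1, nu + 1) * (np.pi / 2) / nu   # rings 1..nu (no pole)

    b = _Builder()

    # --- LV endocardium (scaled by lam) ---
    pole_endo = b.add([0.0, 0.0, -lam * geom.l_endo])
    endo = np.empty((nu, N), dtype=int)
    for i, al in enumerate(alphas):
        r = lam * geom.r_endo * np.sin(al)
        z = -lam * geom.l_endo * np.cos(al)
        for m, th in enumerate(thetas):
            endo[i, m] = b.add([r * np.cos(th), r * np.sin(th), z])

    # --- outer (epicardial) surface with crescent bulge ---
    pole_epi = b.add([0.0, 0.0, -geom.l_epi])
    outer = np.empty((nu, N), dtype=int)
    for i, al in enumerate(alphas):
        z = -geom.l_epi * np.cos(al)
        r = geom.r_epi * np.sin(al)
        for m, th in enumerate(thetas):
            g = float(geom.crescent_profile(th, z))
            rho = r + (mu * geom.rv_depth_mm + geom.rv_wall_mm) * g
            outer[i, m] = b.add([rho * np.cos(th), rho * np.sin(th), z])

    # --- septal sheet and RV free-wall inner sheet over the window ---
    # shares boundary vertices with the outer grid where the crescent
    # profile vanishes (window edge columns and the apical rim row krv-1).
    sep = np.empty((nu, nw + 1), dtype=int)
    fw = np.empty((nu, nw + 1), dtype=int)
    for i, al in enumerate(alphas):
        z = -geom.l_epi * np.cos(al)
        r = geom.r_epi * np.sin(al)
        for m in range(nw + 1):
            th = thetas[m]
            g = float(geom.crescent_profile(th, z))
            if g <= 1e-12:
                sep[i, m] = outer[i, m]
                fw[i, m] = outer[i, m]
            else:
                sep[i, m] = b.add([r * np.cos(th), r * np.sin(th), z])
                rho = r + mu * geom.rv_depth_mm * g
                fw[i, m] = b.add([rho * np.cos(th), rho * np.sin(th), z])

    # --- lateral faces ---
    endo_lat = _strip([pole_endo] * N, endo[0], close=True)
    for i in range(nu - 1):
        endo_lat += _strip(endo[i], endo[i + 1], close=True)
    outer_lat = _strip([pole_epi] * N, outer[0], close=True)
    for i in range(nu - 1):
        outer_lat += _strip(outer[i], outer[i + 1], close=True)
    # outer-grid (shared) vertex set: sheet triangles whose vertices are all
    # shared belong to the outer surface only — emitting them here would
    # duplicate faces where the crescent pinches to zero thickness.
    outer_set = set(int(v) for v in outer.ravel()) | {pole_epi}
    sep_faces, fw_faces = [], []
    for i in range(krv - 1, nu - 1):
        sep_faces += [f for f in _strip(sep[i], sep[i + 1])
                      if not all(v in outer_set for v in f)]
        fw_faces += [f for f in _strip(fw[i], fw[i + 1])
                     if not all(v in outer_set for v in f)]

    # --- caps in the base plane (z = 0) ---
    base_center = b.add([0.0, 0.0, 0.0])

    def radial_cap(boundary_idx, n_rings: int = 2):
        """Fan from base_center to a closed boundary loop with inner rings."""
        bound = b.array()[boundary_idx]
        faces = []
        ring_idx = []
        for s in np.linspace(0, 1, n_rings + 2)[1:-1]:
            ring_idx.append([b.add(s * p) for p in bound])
        prev: list[int] | None = None
        for ring in ring_idx + [list(boundary_idx)]:
            if prev is None:
                # fan wound opposite to the strips so the cap is
                # internally consistent
                for j in range(len(ring)):
                    a, c = ring[j], ring[(j + 1) % len(ring)]
                    faces.append((base_center, c, a))
            else:
                faces += _strip(prev, ring, close=True)
            prev = ring
        # flip the whole cap so its boundary traversal opposes the
        # lateral strips it closes against
        return [(f[0], f[2], f[1]) for f in faces]

    endo_cap = radial_cap(endo[nu - 1])
    # LV epicardial base circle: septal nodes inside the window, outer
    # nodes outside (all at radius r_epi).
    lv_epi_base = [sep[nu - 1, m] if m <= nw else outer[nu - 1, m] for m in range(N)]
    lv_epi_cap = radial_cap(np.array(lv_epi_base))
    epi_cap = radial_cap(outer[nu - 1])

    # crescent cap between the septal and free-wall base arcs
    inner_arc = [sep[nu - 1, m] for m in range(nw + 1)]
    outer_arc = [fw[nu - 1, m] for m in range(nw + 1)]
    mid_arc = []
    V = b.array()
    for m in range(nw + 1):
        if inner_arc[m] == outer_arc[m]:
            mid_arc.append(inner_arc[m])
        else:
            mid_arc.append(b.add(0.5 * (V[inner_arc[m]] + V[outer_arc[m]])))
    crescent_cap = _strip(inner_arc, mid_arc) + _strip(mid_arc, outer_arc)

    # --- valve disks (AV, TV, PV): 12-gon fans in the base plane ---
    disks = {}
    disk_faces = []
    for name in ("AV", "TV", "PV"):
        c, r = geom.valve_circle(name, lam=lam, mu=mu)
        center = b.add(c)
        ring = [b.add(c + r * np.array([np.cos(a), np.sin(a), 0.0]))
                for a in np.arange(12) * (2 * np.pi / 12)]
        for j in range(12):
            disk_faces.append((center, ring[j], ring[(j + 1) % 12]))
        disks[name] = (center, ring)

    vertices = b.array()

    def F(lst):
        return np.asarray(lst, dtype=int)

    def oriented(face_lists_flips):
        """Assemble a closed region; flip globally if volume is negative."""
        parts = [np.flip(F(f), axis=1) if fl else F(f) for f, fl in face_lists_flips]
        faces = np.concatenate(parts)
        if signed_volume(vertices, faces) < 0:
            faces = np.flip(faces, axis=1)
        return faces

    # outer-grid vertices strictly inside the crescent window (bulged away
    # from the LV epicardial surface)
    win_distinct = {int(outer[i, m]) for i in range(nu)
                    for m in range(nw + 1) if outer[i, m] != sep[i, m]}
    outer_outside = [f for f in outer_lat
                     if not any(v in win_distinct for v in f)]
    lv_endo_closed = oriented([(endo_lat, False), (endo_cap, False)])
    epi_closed = oriented([(outer_lat, False), (epi_cap, False)])
    rv_closed = oriented([(sep_faces, True), (fw_faces, False),
                          (crescent_cap, True)])
    lv_epi_closed = oriented([(outer_outside, False), (sep_faces, False),
                              (lv_epi_cap, False)])

    # canonical single-copy face array with labels
    groups = [
        (F(endo_lat), "lv_endo"),
        (F(outer_lat), "epicardium"),
        (F(sep_faces), "septum"),
        (F(fw_faces), "rv_endo"),
        (F(endo_cap), "cap"),
        (F(lv_epi_cap), "cap"),
        (F(epi_cap), "cap"),
        (F(crescent_cap), "cap"),
        (F(disk_faces), "cap"),
    ]
    faces = np.concatenate([g[0] for g in groups])
    face_region = np.concatenate([np.full(len(g[0]), g[1]) for g in groups])

    def _subset(closed, patch):
        """Faces of `patch` with the winding used in `closed`."""
        patch_sets = {frozenset(f) for f in patch}
        return np.asarray([f for f in closed if frozenset(f) in patch_sets])

    match_surfaces = {
        "lv_endo": _subset(lv_endo_closed, endo_lat),
        "epicardium": _subset(epi_closed, outer_lat),
        "septum": _subset(lv_epi_closed, sep_faces),
        "rv_endo": _subset(rv_closed, fw_faces),
    }

    mesh = BivMesh(
        vertices=vertices,
        faces=faces,
        face_region=face_region,
        closed_regions={
            "lv_endo": lv_endo_closed,
            "rv_endo": rv_closed,
            "epicardium": epi_closed,
            "lv_epi": lv_epi_closed,
        },
        match_surfaces=match_surfaces,
        valve_rings={
            "MV": endo[nu - 1].copy(),
            "AV": np.asarray(disks["AV"][1]),
            "TV": np.asarray(disks["TV"][1]),
            "PV": np.asarray(disks["PV"][1]),
        },
        ring_centers={
            "MV": base_center,
            "AV": disks["AV"][0],
            "TV": disks["TV"][0],
            "PV": disks["PV"][0],
        },
        landmark_vertices={
            "LV_APEX": pole_endo,
            "MV_CENTER": base_center,
            "AV_CENTER": disks["AV"][0],
            "TV_CENTER": disks["TV"][0],
            "PV_CENTER": disks["PV"][0],
        },
    )
    return mesh
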