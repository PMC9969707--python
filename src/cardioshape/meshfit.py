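"""Biventricular template-mesh fitting to guide points.

A fixed-topology template (generated from the phantom's mean geometry)
is first placed by a closed-form similarity registration of named
anatomical landmarks (valve-ring centers and the LV apex), then
deformed by a regularized non-rigid iterative-closest-point fit: each
guide point is matched to the nearest point on the template surface of
the same class, a linear least-squares displacement field with a graph
Laplacian smoothness penalty is solved over all vertices, and
per-iteration displacements are capped to keep the deformation gentle
and fold-free in practice.  Valve-insert guide points pull their ring
vertices with a separate (higher) landmark weight, reflecting that
landmarks are sparse but authoritative for valve placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, identity as sp_identity
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .geometry import BivGeometry, BivMesh, build_surface_mesh
from .contouring import GuidePointSet

__all__ = [
    "TemplateMesh", "BiventricularModel", "FitConfig", "Similarity",
    "default_template", "landmark_register", "nonrigid_fit", "fit_guides",
    "subdivide", "closest_point_on_surface", "save_ply", "save_model",
]

# The template type is the shared labeled-mesh container.
TemplateMesh = BivMesh


@dataclass
class FitConfig:
    smoothness_weight: float = 1.0
    landmark_weight: float = 10.0
    n_iterations: int = 20
    max_step_mm: float = 2.0
    seed: int = 0
    contour_weights: dict = field(default_factory=dict)  # per-class overrides
    # robust trimming: matches farther than max(trim_multiplier * class
    # median, trim_floor_mm) get zero weight this iteration, making the fit
    # tolerant of stray guide points (e.g. contour fragments along the
    # valve-plane cut or segmentation errors)
    trim_multiplier: float = 4.0
    trim_floor_mm: float = 3.0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.smoothness_weight < 0 or self.landmark_weight < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class BiventricularModel:
    """A deformed template: same topology, patient-specific vertices."""

    template: TemplateMesh
    vertices: np.ndarray
    phase: str = "ED"
    fit_log: list = field(default_factory=list)

    @property
    def faces(self) -> np.ndarray:
        return self.template.faces

    def mesh(self) -> BivMesh:
        return self.template.with_vertices(self.vertices)

    def region_faces(self, region: str) -> np.ndarray:
        return self.template.closed_regions[region]

    def copy(self) -> "BiventricularModel":
        return BiventricularModel(self.template, self.vertices.copy(),
                                  self.phase, list(self.fit_log))


def default_template(geom: BivGeometry | None = None) -> TemplateMesh:
    """The package's template mesh: the phantom mean geometry at ED."""
    return build_surface_mesh(geom or BivGeometry())


# ---------------------------------------------------------------------------
# similarity / rigid transforms


@dataclass
class Similarity:
    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points) @ self.rotation.T + self.translation


def _umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool) -> Similarity:
    """Least-squares similarity (or rigid) transform src -> dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    sgn = np.diag([1.0, 1.0, d])
    rot = u @ sgn @ vt
    if with_scale:
        var = (sc ** 2).sum() / len(src)
        scale = float(np.trace(np.diag(s) @ sgn) / var)
    else:
        scale = 1.0
    trans = mu_d - scale * rot @ mu_s
    return Similarity(scale=scale, rotation=rot, translation=trans)


def landmark_register(template: TemplateMesh, landmarks: dict[str, np.ndarray]
                      ) -> tuple[Similarity, float]:
    """Similarity transform mapping template landmarks onto named targets.

    Requires at least three shared, non-collinear landmark names.
    Returns the transform and the residual RMS in mm.
    """
    tpts = template.landmark_points()
    names = sorted(set(tpts) & set(landmarks))
    if len(names) < 3:
        raise ValueError(f"need >= 3 shared landmarks, got {len(names)}")
    src = np.asarray([tpts[n] for n in names])
    dst = np.asarray([landmarks[n] for n in names])
    sing = np.linalg.svd(dst - dst.mean(axis=0), compute_uv=False)
    if sing[1] < 1e-9 * max(sing[0], 1.0):
        raise ValueError("landmarks are collinear; registration is degenerate")
    tf = _umeyama(src, dst, with_scale=True)
    rms = float(np.sqrt(((tf.apply(src) - dst) ** 2).sum(axis=1).mean()))
    return tf, rms


# ---------------------------------------------------------------------------
# exact point-to-triangle projection


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle for each query (paired, (M,3)).

    Returns (closest points, barycentric coordinates).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    u = np.zeros(len(p))
    v = np.zeros(len(p))
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    done |= m                                    # at A: u=v=0
    m = (d3 >= 0) & (d4 <= d3) & ~done
    u[m] = 1.0
    done |= m                                    # at B
    m = (d6 >= 0) & (d5 <= d6) & ~done
    v[m] = 1.0
    done |= m                                    # at C

    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        u[m] = (d1 / (d1 - d3))[m]               # edge AB
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        v[m] = (d2 / (d2 - d6))[m]               # edge AC
    done |= m
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ = ((d4 - d3) / ((d4 - d3) + (d5 - d6)))[m]
    u[m] = 1.0 - w_
    v[m] = w_                                    # edge BC
    done |= m

    m = ~done                                    # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        u[m] = (vb / denom)[m]
        v[m] = (vc / denom)[m]
    closest = a + u[:, None] * ab + v[:, None] * ac
    bary = np.stack([1.0 - u - v, u, v], axis=1)
    return closest, bary


def closest_point_on_surface(points: np.ndarray, vertices: np.ndarray,
                             faces: np.ndarray, exact: bool = True
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact nearest point on a triangle surface for each query point.

    Returns (distances, closest points, face indices, barycentrics).
    Small surfaces are scanned exhaustively; larger ones are pruned with
    a centroid k-d tree and a circumradius-guaranteed candidate ball, so
    the result equals the brute-force minimum.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = vertices[faces]                       # (F, 3, 3)
    nf = len(faces)
    n = len(points)
    if nf <= 256 or not exact:
        if nf <= 256:
            pp = np.repeat(points, nf, axis=0)
            tt = np.tile(tris, (n, 1, 1))
            cp, bc = _closest_on_triangles(pp, tt)
            d = np.linalg.norm(pp - cp, axis=1).reshape(n, nf)
            fi = np.argmin(d, axis=1)
            sel = fi + np.arange(n) * nf
            return (d[np.arange(n), fi], cp[sel], fi, bc[sel])
    centroids = tris.mean(axis=1)
    rmax = float(np.linalg.norm(tris - centroids[:, None], axis=2).max())
    tree = cKDTree(centroids)
    k = min(12, nf)
    _dc, ci = tree.query(points, k=k)
    ci = np.atleast_2d(ci)
    # exact distance among the k nearest-centroid candidates
    pp = np.repeat(points, k, axis=0)
    cp0, bc0 = _closest_on_triangles(pp, tris[ci.ravel()])
    d0 = np.linalg.norm(pp - cp0, axis=1).reshape(n, k)
    dbest = d0.min(axis=1)
    if not exact:
        jbest = np.argmin(d0, axis=1)
        sel = np.arange(n) * k + jbest
        return (dbest, cp0[sel], ci[np.arange(n), jbest], bc0[sel])
    # guaranteed candidate set: any closer triangle has its centroid
    # within dbest + rmax
    out_d = np.empty(n)
    out_p = np.empty((n, 3))
    out_f = np.empty(n, dtype=int)
    out_b = np.empty((n, 3))
    balls = tree.query_ball_point(points, dbest + rmax + 1e-9)
    for i in range(n):
        cand = np.asarray(balls[i], dtype=int)
        cp, bc = _closest_on_triangles(np.repeat(points[i][None], len(cand), axis=0),
                                       tris[cand])
        d = np.linalg.norm(points[i] - cp, axis=1)
        j = int(np.argmin(d))
        out_d[i], out_p[i], out_f[i], out_b[i] = d[j], cp[j], cand[j], bc[j]
    return out_d, out_p, out_f, out_b


# ---------------------------------------------------------------------------
# non-rigid fit


_CLASS_TO_SURFACE = {"lv_endo": "lv_endo", "rv_endo": "rv_endo",
                     "epicardium": "epicardium", "septum": "septum"}


def _graph_laplacian(n: int, edges: np.ndarray):
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    adj = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    from scipy.sparse import diags
    return diags(deg) - adj


def nonrigid_fit(template: TemplateMesh, guides: GuidePointSet,
                 config: FitConfig | None = None) -> BiventricularModel:
    """Regularized non-rigid ICP of a (registered) template to guides.

    The template must already be posed by :func:`landmark_register`
    (see :func:`fit_guides` for the combined operation).
    """
    config = config or FitConfig()
    if config.smoothness_weight <= 0:
        raise ValueError(
            "smoothness_weight must be positive: with sparse guides the "
            "unregularized system is ill-conditioned")
    classes = [c for c in guides.contour_points if c in _CLASS_TO_SURFACE
               and len(guides.contour_points[c])]
    if len(classes) < 2:
        raise ValueError("guides must cover at least two contour classes")

    V = template.vertices.copy()
    nv = len(V)
    L = _graph_laplacian(nv, template.edges()).tocsr()
    LtL = (L.T @ L).tocsc()

    # fixed landmark correspondences (vertex index -> target)
    lm_rows: list[tuple[int, np.ndarray]] = []
    by_name = guides.landmarks_by_name()
    for name, pts in by_name.items():
        if name == "LV_APEX":
            vi = template.landmark_vertices["LV_APEX"]
            for p in pts:
                lm_rows.append((vi, p))
        elif name[:2] in ("MV", "AV", "TV", "PV") and name[2:] in ("1", "2"):
            ring = template.valve_rings[name[:2]]
            for p in pts:
                vi = int(ring[np.argmin(np.linalg.norm(V[ring] - p, axis=1))])
                lm_rows.append((vi, p))
    for cname, target in guides.registration_targets().items():
        if cname.endswith("_CENTER"):
            lm_rows.append((template.ring_centers[cname[:2]], target))

    log = []
    for _it in range(config.n_iterations):
        rows_i, rows_j, rows_w, targets, weights = [], [], [], [], []
        r = 0
        guide_res = []
        for cls in classes:
            pts = guides.contour_points[cls]
            faces = template.match_surfaces[_CLASS_TO_SURFACE[cls]]
            d, _cp, fi, bc = closest_point_on_surface(pts, V, faces, exact=False)
            thr = max(config.trim_multiplier * float(np.median(d)),
                      config.trim_floor_mm)
            inlier = d <= thr
            guide_res.append(d[inlier])
            wcls = float(config.contour_weights.get(cls, 1.0))
            for kk in range(3):
                rows_i.append(np.arange(r, r + len(pts)))
                rows_j.append(faces[fi, kk])
                rows_w.append(bc[:, kk])
            targets.append(pts)
            weights.append(np.where(inlier, wcls, 0.0))
            r += len(pts)
        for vi, p in lm_rows:
            rows_i.append(np.array([r]))
            rows_j.append(np.array([vi]))
            rows_w.append(np.array([1.0]))
            targets.append(p[None])
            weights.append(np.array([config.landmark_weight]))
            r += 1

        i = np.concatenate(rows_i)
        j = np.concatenate(rows_j)
        w = np.concatenate(rows_w)
        tgt = np.concatenate(targets)
        sw = np.sqrt(np.concatenate(weights))
        A = coo_matrix((w, (i, j)), shape=(r, nv)).tocsr()
        Aw = A.multiply(sw[:, None]).tocsr()
        resid = (tgt - A @ V) * sw[:, None]

        M = (Aw.T @ Aw + config.smoothness_weight * LtL
             + 1e-9 * sp_identity(nv)).tocsc()
        solver = splu(M)
        disp = np.column_stack([solver.solve(np.asarray(Aw.T @ resid[:, k]).ravel())
                                for k in range(3)])
        # cap the per-vertex step
        norms = np.linalg.norm(disp, axis=1)
        over = norms > config.max_step_mm
        if over.any():
            disp[over] *= (config.max_step_mm / norms[over])[:, None]
        V = V + disp

        rms = float(np.sqrt(np.mean(np.concatenate(guide_res) ** 2)))
        log.append(rms)
        step = float(np.sqrt((disp ** 2).sum(axis=1).mean()))
        if step < 0.01:
            break
    return BiventricularModel(template=template, vertices=V,
                              phase=guides.phase, fit_log=log)


def fit_guides(template: TemplateMesh, guides: GuidePointSet,
               config: FitConfig | None = None
               ) -> tuple[BiventricularModel, Similarity]:
    """Landmark registration followed by the non-rigid fit."""
    tf, _rms = landmark_register(template, guides.registration_targets())
    posed = template.with_vertices(tf.apply(template.vertices))
    model = nonrigid_fit(posed, guides, config)
    return model, tf


# ---------------------------------------------------------------------------
# mesh I/O


def save_ply(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    """Write an ASCII PLY triangle mesh."""
    from pathlib import Path
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = ["ply", "format ascii 1.0",
             f"element vertex {len(vertices)}",
             "property float x", "property float y", "property float z",
             f"element face {len(faces)}",
             "property list uchar int vertex_indices", "end_header"]
    lines += [f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}" for v in vertices]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in faces]
    Path(path).write_text("\n".join(lines) + "\n")


def save_model(model: BiventricularModel, path_stem) -> None:
    """Fitted model as PLY plus a JSON sidecar (regions, rings, landmarks)."""
    import json
    from pathlib import Path
    stem = Path(path_stem)
    save_ply(model.vertices, model.template.faces, stem.with_suffix(".ply"))
    side = {
        "phase": model.phase,
        "face_region": model.template.face_region.tolist(),
        "closed_regions": {k: v.tolist()
                           for k, v in model.template.closed_regions.items()},
        "valve_rings": {k: v.tolist()
                        for k, v in model.template.valve_rings.items()},
        "landmark_vertices": {k: int(v) for k, v in
                              model.template.landmark_vertices.items()},
        "fit_rms_mm": model.fit_log,
    }
    stem.with_suffix(".json").write_text(json.dumps(side))


# ---------------------------------------------------------------------------
# Loop subdivision


def subdivide(vertices: np.ndarray, faces: np.ndarray, levels: int = 1,
              face_labels: np.ndarray | None = None):
    """Loop subdivision of a closed, manifold, labeled triangle mesh.

    Each level quadruples the face count; face labels propagate to the
    four children; watertightness and orientation are preserved.
    Raises on non-manifold input (an edge not shared by exactly two
    faces).
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=int)
    lab = None if face_labels is None else np.asarray(face_labels)
    if levels < 0:
        raise ValueError("levels must be >= 0")
    for _ in range(levels):
        V, F, lab = _loop_once(V, F, lab)
    return (V, F) if face_labels is None else (V, F, lab)


def _loop_once(V, F, lab):
    ne_dir = F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    e_sorted = np.sort(ne_dir, axis=1)
    edges, inv, counts = np.unique(e_sorted, axis=0, return_inverse=True,
                                   return_counts=True)
    if not np.all(counts == 2):
        raise ValueError("non-manifold mesh: an edge is not shared by exactly 2 faces")
    nv, nf, ned = len(V), len(F), len(edges)

    # opposite vertices per edge (from its two adjacent faces)
    opp = np.full((ned, 2), -1, dtype=int)
    face_of_edge = np.repeat(np.arange(nf), 3)
    corner = np.tile([2, 0, 1], nf)  # vertex opposite each face edge
    slot = np.zeros(ned, dtype=int)
    for idx in range(3 * nf):
        e = inv[idx]
        opp[e, slot[e]] = F[face_of_edge[idx], corner[idx]]
        slot[e] += 1

    # odd (edge) vertices
    a, b = V[edges[:, 0]], V[edges[:, 1]]
    c, d = V[opp[:, 0]], V[opp[:, 1]]
    evert = 0.375 * (a + b) + 0.125 * (c + d)

    # even (original) vertices: Loop beta rule
    neigh_count = np.zeros(nv)
    neigh_sum = np.zeros((nv, 3))
    np.add.at(neigh_count, edges[:, 0], 1)
    np.add.at(neigh_count, edges[:, 1], 1)
    np.add.at(neigh_sum, edges[:, 0], V[edges[:, 1]])
    np.add.at(neigh_sum, edges[:, 1], V[edges[:, 0]])
    k = np.maximum(neigh_count, 3)
    beta = (1.0 / k) * (0.625 - (0.375 + 0.25 * np.cos(2 * np.pi / k)) ** 2)
    Vnew = (1.0 - k * beta)[:, None] * V + beta[:, None] * neigh_sum

    eid = inv.reshape(nf, 3) + nv  # edge-vertex ids per face (01, 12, 20)
    f0, f1, f2 = F[:, 0], F[:, 1], F[:, 2]
    e01, e12, e20 = eid[:, 0], eid[:, 1], eid[:, 2]
    # children of each parent are contiguous so labels propagate by repeat
    Fnew = np.concatenate([np.stack([f0, e01, e20], axis=1)[:, None],
                           np.stack([f1, e12, e01], axis=1)[:, None],
                           np.stack([f2, e20, e12], axis=1)[:, None],
                           np.stack([e01, e12, e20], axis=1)[:, None]],
                          axis=1).reshape(-1, 3)
    labnew = None if lab is None else np.repeat(lab, 4)
    return np.concatenate([Vnew, evert]), Fnew, labnew
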