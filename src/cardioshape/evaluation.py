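"""Comparison metrics for segmentations, landmarks, phases and models.

Implements the evaluation toolbox used throughout: Dice overlap,
Hausdorff distance, average absolute frame difference (AAFD) for phase
selection, landmark plane-angulation errors, rigid model alignment,
signed point-to-surface projection distances with global/regional
mean absolute errors, Bland-Altman agreement summaries, and per-mode
shape-atlas Z-score differences with Kolmogorov-Smirnov tests under
Holm-Bonferroni correction.

Sign convention for projection distances: positive means the vertex
lies outside the reference surface along its outward normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import directed_hausdorff

from .measures_atlas import ShapeAtlas, project
from .meshfit import (BiventricularModel, Similarity, _umeyama,
                      closest_point_on_surface)

__all__ = [
    "RegionalErrorReport", "BlandAltmanSummary",
    "dice", "hausdorff", "aafd", "rigid_align_models",
    "projection_distances", "plane_angulation_error", "bland_altman",
    "zscore_difference", "holm_bonferroni",
]

SURFACE_REGIONS = ("lv_endo", "rv_endo", "septum", "epicardium")
VALVE_REGIONS = ("MV", "AV", "TV", "PV")


@dataclass
class RegionalErrorReport:
    """Global and per-region projection-distance summaries (mm).

    The global MAE is the mean over all surface points, not the mean of
    the regional MAEs.
    """

    mae: dict[str, tuple[float, float]] = field(default_factory=dict)
    signed_mean: dict[str, float] = field(default_factory=dict)
    per_vertex: dict[str, np.ndarray] = field(default_factory=dict)

    def as_rows(self) -> dict[str, float]:
        pretty = {"Global": "Global", "lv_endo": "LV Endocardium",
                  "rv_endo": "RV Endocardium", "septum": "Septum",
                  "epicardium": "Epicardium", "MV": "MV", "AV": "AV",
                  "TV": "TV", "PV": "PV"}
        return {pretty.get(k, k): v[0] for k, v in self.mae.items()}


@dataclass
class BlandAltmanSummary:
    bias: float
    limits_of_agreement: tuple[float, float]
    r_squared: float
    p_value: float


# ---------------------------------------------------------------------------
# overlap / distance metrics


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty: Dice defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be nonempty")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def hausdorff_percentile(a: np.ndarray, b: np.ndarray, q: float = 95.0) -> float:
    """Percentile variant: q-th percentile of both directed NN distances."""
    from scipy.spatial import cKDTree
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    da = cKDTree(b).query(a)[0]
    db = cKDTree(a).query(b)[0]
    return float(np.percentile(np.concatenate([da, db]), q))


def aafd(predicted, truth) -> float:
    """Average absolute frame difference between phase-index lists."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("lists must be nonempty and of equal length")
    return float(np.abs(p - t).mean())


# ---------------------------------------------------------------------------
# model alignment and projection distances


def rigid_align_models(moving: BiventricularModel, fixed: BiventricularModel
                       ) -> tuple[Similarity, BiventricularModel]:
    """Closed-form least-squares rotation+translation (no scale, proper
    rotation enforced) over corresponding vertices."""
    if moving.vertices.shape != fixed.vertices.shape:
        raise ValueError("models must share template topology")
    tf = _umeyama(moving.vertices, fixed.vertices, with_scale=False)
    aligned = moving.copy()
    aligned.vertices = tf.apply(moving.vertices)
    return tf, aligned


def _region_vertex_ids(model: BiventricularModel, region: str) -> np.ndarray:
    return np.unique(model.template.match_surfaces[region])


def projection_distances(auto: BiventricularModel, manual: BiventricularModel,
                         aligned: bool = True) -> RegionalErrorReport:
    """Signed point-to-surface distances from auto vertices to the manual
    model, summarized per region and globally.

    Surface regions use exact point-to-triangle projection against the
    same-named (outward-oriented) surface; valve regions compare ring
    vertices to the manual ring polyline (unsigned).  Call
    :func:`rigid_align_models` first; pass ``aligned=False`` to
    acknowledge deliberately unaligned input.
    """
    if auto.vertices.shape != manual.vertices.shape:
        raise ValueError("models must share template topology")
    if not aligned:
        warnings.warn("models flagged as unaligned: distances include pose error")
    report = RegionalErrorReport()
    all_abs = []
    for region in SURFACE_REGIONS:
        vids = _region_vertex_ids(auto, region)
        pts = auto.vertices[vids]
        faces = manual.template.match_surfaces[region]
        d, cp, fi, _bc = closest_point_on_surface(pts, manual.vertices, faces)
        tri = manual.vertices[faces[fi]]
        nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        sign = np.sign(np.einsum("ij,ij->i", pts - cp, nrm))
        sign[sign == 0] = 1.0
        signed = d * sign
        report.per_vertex[region] = signed
        report.mae[region] = (float(np.abs(signed).mean()), float(np.abs(signed).std()))
        report.signed_mean[region] = float(signed.mean())
        all_abs.append(np.abs(signed))
    for valve in VALVE_REGIONS:
        ring_a = auto.vertices[auto.template.valve_rings[valve]]
        ring_m = manual.vertices[manual.template.valve_rings[valve]]
        d = _points_to_polyline(ring_a, ring_m)
        report.per_vertex[valve] = d
        report.mae[valve] = (float(d.mean()), float(d.std()))
        all_abs.append(d)
    g = np.concatenate(all_abs)
    report.mae["Global"] = (float(g.mean()), float(g.std()))
    return report


def _points_to_polyline(pts: np.ndarray, loop: np.ndarray) -> np.ndarray:
    """Min distance from each point to a closed polyline (segment-exact)."""
    a = loop
    b = np.roll(loop, -1, axis=0)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        t = np.clip(np.einsum("ij,ij->i", ab, p - a) / np.maximum(denom, 1e-12),
                    0.0, 1.0)
        proj = a + t[:, None] * ab
        out[i] = np.linalg.norm(p - proj, axis=1).min()
    return out


# ---------------------------------------------------------------------------
# landmark plane angulation


def plane_angulation_error(pred_pair: np.ndarray, truth_pair: np.ndarray,
                           plane_normal: np.ndarray) -> float:
    """Angle (degrees, in [0, 90]) between the in-plane insert lines."""
    pred_pair = np.asarray(pred_pair, dtype=float)
    truth_pair = np.asarray(truth_pair, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)

    def in_plane_dir(pair):
        v = pair[1] - pair[0]
        v = v - (v @ n) * n
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError("coincident insert points define no line")
        return v / nv

    c = abs(float(in_plane_dir(pred_pair) @ in_plane_dir(truth_pair)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# agreement statistics


def bland_altman(x, y) -> BlandAltmanSummary:
    """Bias, 95% limits of agreement, regression r², paired-t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length measurement lists (n >= 3)")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r2 = 1.0 if np.allclose(diff, diff[0]) else 0.0
    else:
        r2 = float(stats.linregress(x, y).rvalue ** 2)
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_rel(y, x).pvalue)
    return BlandAltmanSummary(bias=bias, limits_of_agreement=(lo, hi),
                              r_squared=r2, p_value=p)


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni rejection decisions."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def zscore_difference(atlas: ShapeAtlas, pairs_a, pairs_b, n_modes: int = 20,
                      alpha: float = 0.05) -> dict:
    """Per-mode mean |Δz| between paired model sets, with per-mode
    two-sample Kolmogorov-Smirnov tests under Holm-Bonferroni."""
    if len(pairs_a) != len(pairs_b):
        raise ValueError("paired lists must have equal length")
    za = np.stack([project(atlas, p).z for p in pairs_a])
    zb = np.stack([project(atlas, p).z for p in pairs_b])
    k = min(n_modes, za.shape[1])
    za, zb = za[:, :k], zb[:, :k]
    mean_abs_dz = np.abs(za - zb).mean(axis=0)
    ks_stat = np.empty(k)
    ks_p = np.empty(k)
    for i in range(k):
        if np.allclose(za[:, i], zb[:, i]):
            ks_stat[i], ks_p[i] = 0.0, 1.0
        else:
            res = stats.ks_2samp(za[:, i], zb[:, i])
            ks_stat[i], ks_p[i] = res.statistic, res.pvalue
    return {
        "mean_abs_dz": mean_abs_dz,
        "ks_statistic": ks_stat,
        "ks_pvalue": ks_p,
        "reject": holm_bonferroni(ks_p, alpha),
        "n_modes": k,
    }
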