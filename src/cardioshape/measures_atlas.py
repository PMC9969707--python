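"""Global ventricular measures and the ED/ES PCA shape atlas.

Volumes come from divergence-theorem integration over each region's
closed, outward-oriented surface; masses use the standard myocardial
density of 1.05 g/mL with septal mass assigned to the LV.  The shape
atlas is built by rigid (no-scaling) Procrustes alignment of each
subject's ED model to the evolving population mean — the same
transform is applied to that subject's ES model — followed by PCA of
the concatenated ED+ES vertex coordinates with the 1/(n-1) covariance
convention.  A shape's Z-score along mode k is its mode coefficient
divided by sqrt(lambda_k), i.e. expressed in standard deviations of
the training population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import signed_volume
from .meshfit import BiventricularModel, _umeyama

__all__ = ["GlobalMeasures", "ShapeAtlas", "ZScores", "region_volume",
           "global_measures", "build_atlas", "project", "variance_explained",
           "MYOCARDIAL_DENSITY_G_PER_ML"]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class GlobalMeasures:
    lv_edv: float
    lv_esv: float
    lv_sv: float
    lv_ef: float
    lv_mass: float
    rv_edv: float
    rv_esv: float
    rv_sv: float
    rv_ef: float
    rv_mass: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)

    # row names as conventionally tabulated
    ROW_NAMES = ["LV EDV (mL)", "LV ESV (mL)", "LV SV (mL)", "LV EF (%)",
                 "LV Mass (g)", "RV EDV (mL)", "RV ESV (mL)", "RV SV (mL)",
                 "RV EF (%)", "RV Mass (g)"]

    def as_rows(self) -> dict[str, float]:
        vals = [self.lv_edv, self.lv_esv, self.lv_sv, self.lv_ef, self.lv_mass,
                self.rv_edv, self.rv_esv, self.rv_sv, self.rv_ef, self.rv_mass]
        return dict(zip(self.ROW_NAMES, vals))


def _check_closed(faces: np.ndarray) -> None:
    e = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    eu = np.sort(e, axis=1)
    _uniq, counts = np.unique(eu, axis=0, return_counts=True)
    if not np.all(counts == 2):
        bad = _uniq[counts != 2]
        raise ValueError(f"open surface: {len(bad)} boundary edges, e.g. {bad[:3].tolist()}")


def region_volume(model: BiventricularModel, region: str) -> float:
    """Signed divergence-theorem volume of a closed region surface (mL)."""
    faces = model.template.closed_regions[region]
    _check_closed(faces)
    return signed_volume(model.vertices, faces) / 1000.0


def global_measures(ed: BiventricularModel, es: BiventricularModel) -> GlobalMeasures:
    """LV/RV volumes, masses, stroke volumes and ejection fractions.

    Masses are computed at ED; the septal wall is counted in the LV
    mass.  EDV <= ESV is reported (negative EF) with a warning rather
    than raised — dysfunction is representable.
    """
    if ed.template.faces.shape != es.template.faces.shape:
        raise ValueError("ED and ES models must share template topology")
    lv_edv = region_volume(ed, "lv_endo")
    lv_esv = region_volume(es, "lv_endo")
    rv_edv = region_volume(ed, "rv_endo")
    rv_esv = region_volume(es, "rv_endo")
    epi = region_volume(ed, "epicardium")
    lv_epi = region_volume(ed, "lv_epi")
    lv_mass = (lv_epi - lv_edv) * MYOCARDIAL_DENSITY_G_PER_ML
    rv_mass = (epi - lv_epi - rv_edv) * MYOCARDIAL_DENSITY_G_PER_ML
    if lv_edv <= lv_esv or rv_edv <= rv_esv:
        warnings.warn("EDV <= ESV: negative ejection fraction reported")
    return GlobalMeasures(
        lv_edv=lv_edv, lv_esv=lv_esv, lv_sv=lv_edv - lv_esv,
        lv_ef=100.0 * (lv_edv - lv_esv) / lv_edv, lv_mass=lv_mass,
        rv_edv=rv_edv, rv_esv=rv_esv, rv_sv=rv_edv - rv_esv,
        rv_ef=100.0 * (rv_edv - rv_esv) / rv_edv, rv_mass=rv_mass,
    )


# ---------------------------------------------------------------------------
# shape atlas


@dataclass
class ShapeAtlas:
    """Mean shape + orthonormal PCA modes over concatenated ED/ES vertices."""

    mean_shape: np.ndarray       # (6 * n_vertices,)
    modes: np.ndarray            # (6 * n_vertices, n_modes), orthonormal
    eigenvalues: np.ndarray      # descending, same length as n_modes
    n_subjects: int
    n_vertices: int

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mean_ed_vertices(self) -> np.ndarray:
        return self.mean_shape[:3 * self.n_vertices].reshape(-1, 3)


@dataclass
class ZScores:
    z: np.ndarray
    mode_indices: np.ndarray     # atlas mode index of each entry

    def first(self, k: int) -> np.ndarray:
        sel = self.mode_indices < k
        return self.z[sel]


def _pair_vector(ed_v: np.ndarray, es_v: np.ndarray) -> np.ndarray:
    return np.concatenate([ed_v.ravel(), es_v.ravel()])


def _align_pair(ed_v, es_v, ref_ed):
    """Rigid-align ED to a reference; apply the same transform to ES."""
    tf = _umeyama(ed_v, ref_ed, with_scale=False)
    return tf.apply(ed_v), tf.apply(es_v)


def build_atlas(pairs: list[tuple[BiventricularModel, BiventricularModel]],
                n_align_iters: int = 5) -> ShapeAtlas:
    """ED/ES shape atlas from fitted model pairs (generalized Procrustes
    without scaling, then PCA with the 1/(n-1) covariance convention)."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 subjects")
    shapes = [(p[0].vertices.copy(), p[1].vertices.copy()) for p in pairs]
    nv = len(shapes[0][0])
    for ed, es in shapes:
        if len(ed) != nv or len(es) != nv:
            raise ValueError("all models must share template topology")

    ref = shapes[0][0]
    aligned = list(shapes)
    for _ in range(n_align_iters):
        aligned = [_align_pair(ed, es, ref) for ed, es in aligned]
        new_ref = np.mean([a[0] for a in aligned], axis=0)
        if np.abs(new_ref - ref).max() < 1e-10:
            ref = new_ref
            break
        ref = new_ref
    # final pass against the converged mean
    aligned = [_align_pair(ed, es, ref) for ed, es in aligned]

    X = np.stack([_pair_vector(ed, es) for ed, es in aligned])
    mean = X.mean(axis=0)
    n = len(X)
    _u, s, vt = np.linalg.svd((X - mean) / np.sqrt(n - 1), full_matrices=False)
    lam = s ** 2
    keep = lam > max(1e-12, 1e-12 * (lam[0] if lam.size else 1.0))
    return ShapeAtlas(mean_shape=mean, modes=vt[keep].T,
                      eigenvalues=lam[keep], n_subjects=n, n_vertices=nv)


def project(atlas: ShapeAtlas, pair: tuple[BiventricularModel, BiventricularModel]
            ) -> ZScores:
    """Z-scores of an ED/ES model pair in the atlas.

    The pair is aligned to the atlas mean with the same rule used at
    build time; modes with eigenvalue below 1e-12 are excluded with a
    warning.
    """
    ed, es = pair
    nv = atlas.n_vertices
    if len(ed.vertices) != nv:
        raise ValueError("model topology does not match the atlas")
    ed_a, es_a = _align_pair(ed.vertices, es.vertices, atlas.mean_ed_vertices())
    s = _pair_vector(ed_a, es_a)
    b = atlas.modes.T @ (s - atlas.mean_shape)
    good = atlas.eigenvalues > 1e-12
    if not good.all():
        warnings.warn(f"excluding {int((~good).sum())} near-zero-variance modes")
    z = b[good] / np.sqrt(atlas.eigenvalues[good])
    return ZScores(z=z, mode_indices=np.flatnonzero(good))


def variance_explained(atlas: ShapeAtlas, k: int) -> float:
    """Fraction of total variance captured by the first k modes."""
    if not (1 <= k <= atlas.n_modes):
        raise ValueError("k out of range")
    lam = atlas.eigenvalues
    return float(lam[:k].sum() / lam.sum())
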