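"""From per-view masks and landmarks to labeled 3D guide points.

Segmentation masks are traced into ordered sub-pixel contour polylines
for four classes — LV endocardium, RV endocardium, epicardium, and
septum — following the conventions used in guide-point modeling:
papillary-muscle/trabecular islands are merged into the blood pool
before tracing, the septum is represented by the LV-side interface
polyline, and the epicardium is the outer boundary of the union of all
myocardium and cavity labels.  Contours and decoded landmarks are then
lifted through each plane's affine into patient coordinates and pooled
across views into one guide-point set per cardiac phase (ED and ES).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours

from .imaging_io import ImagePlaneMeta, pixel_to_patient
from .stage_models import encode_segmentation_classes, landmark_set_for_view, _as_view

__all__ = ["ContourSet2D", "GuidePointSet", "extract_contours",
           "lift_to_3d", "assemble_guide_points", "CONTOUR_CLASSES"]

CONTOUR_CLASSES = ("lv_endo", "rv_endo", "epicardium", "septum")

# global tissue codes (shared with phantom/stage_models)
_LV_CAV, _LV_MYO, _RV_CAV, _RV_MYO = 1, 2, 3, 4


@dataclass
class ContourSet2D:
    """Ordered sub-pixel contour polylines per class for one view/frame."""

    contours: dict[str, list[np.ndarray]]
    view: str
    frame: int = 0

    def points(self, cls: str) -> np.ndarray:
        lst = self.contours.get(cls, [])
        return np.concatenate(lst) if lst else np.empty((0, 2))

    def total_points(self) -> int:
        return sum(len(p) for lst in self.contours.values() for p in lst)


@dataclass
class GuidePointSet:
    """Labeled 3D contour points and named landmarks for one phase."""

    contour_points: dict[str, np.ndarray] = field(default_factory=dict)
    landmark_points: list[tuple[str, np.ndarray, str]] = field(default_factory=list)
    phase: str = "ED"

    def add_contours(self, cls: str, pts: np.ndarray) -> None:
        if len(pts) == 0:
            return
        cur = self.contour_points.get(cls)
        self.contour_points[cls] = pts if cur is None else np.concatenate([cur, pts])

    def n_contour_points(self) -> int:
        return sum(len(v) for v in self.contour_points.values())

    def landmarks_by_name(self) -> dict[str, list[np.ndarray]]:
        out: dict[str, list[np.ndarray]] = {}
        for name, xyz, _src in self.landmark_points:
            out.setdefault(name, []).append(xyz)
        return out

    def to_json(self) -> str:
        import json
        return json.dumps({
            "phase": self.phase,
            "contours": {k: v.tolist() for k, v in self.contour_points.items()},
            "landmarks": [{"name": n, "xyz": p.tolist(), "source": s}
                          for n, p, s in self.landmark_points],
        })

    @classmethod
    def from_json(cls, text: str) -> "GuidePointSet":
        import json
        d = json.loads(text)
        g = cls(phase=d["phase"])
        for k, v in d["contours"].items():
            g.contour_points[k] = np.asarray(v, dtype=float)
        for rec in d["landmarks"]:
            g.landmark_points.append((rec["name"],
                                      np.asarray(rec["xyz"], dtype=float),
                                      rec["source"]))
        return g

    def registration_targets(self) -> dict[str, np.ndarray]:
        """Named targets for landmark registration.

        Valve centers are the midpoints of each view's insert pair,
        averaged across views; the apex is averaged directly.
        """
        by = self.landmarks_by_name()
        out: dict[str, np.ndarray] = {}
        for valve in ("MV", "AV", "TV", "PV"):
            a, b = by.get(valve + "1", []), by.get(valve + "2", [])
            mids = [(p + q) / 2 for p, q in zip(a, b)]
            if mids:
                out[valve + "_CENTER"] = np.mean(mids, axis=0)
        if "LV_APEX" in by:
            out["LV_APEX"] = np.mean(by["LV_APEX"], axis=0)
        return out


def _trace(binary: np.ndarray) -> list[np.ndarray]:
    """Sub-pixel boundary polylines of a binary mask (holes filled)."""
    filled = ndi.binary_fill_holes(binary)
    if not filled.any():
        return []
    return [c for c in find_contours(filled.astype(float), 0.5) if len(c) >= 4]


def _resample(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline to roughly uniform arc-length spacing."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= spacing:
        return poly[[0]]
    si = np.arange(0.0, s[-1], spacing)
    out = np.empty((len(si), poly.shape[1]))
    for d in range(poly.shape[1]):
        out[:, d] = np.interp(si, s, poly[:, d])
    return out


def _near_label(points: np.ndarray, labelmask: np.ndarray, radius: float = 1.8
                ) -> np.ndarray:
    """Boolean: polyline points lying within ``radius`` px of a label."""
    if not labelmask.any():
        return np.zeros(len(points), dtype=bool)
    dist = ndi.distance_transform_edt(~labelmask)
    rc = np.clip(np.round(points).astype(int), 0,
                 np.asarray(labelmask.shape) - 1)
    return dist[rc[:, 0], rc[:, 1]] <= radius


def extract_contours(mask: np.ndarray, view, min_spacing_px: float = 0.0,
                     frame: int = 0) -> ContourSet2D:
    """Trace the view's contour classes from an integer label mask.

    Missing expected structures produce a warning and an absent class,
    not an error.  ``min_spacing_px`` optionally thins the polylines to
    a uniform arc-length spacing (0 keeps the raw tracing density).
    """
    v = _as_view(view)
    classes = encode_segmentation_classes(v)  # validates the view
    mask = np.asarray(mask)
    out: dict[str, list[np.ndarray]] = {}

    has_lv = _LV_CAV in classes
    has_rv = _RV_CAV in classes
    lv_group = np.isin(mask, (_LV_CAV, _LV_MYO))
    rv_group = np.isin(mask, (_RV_CAV, _RV_MYO))

    def keep(cls: str, polys: list[np.ndarray]):
        polys = [p for p in polys if len(p)]
        if polys:
            if min_spacing_px > 0:
                polys = [_resample(p, min_spacing_px) for p in polys]
            out[cls] = polys
        else:
            warnings.warn(f"{v}: no {cls} contour found")

    if has_lv:
        keep("lv_endo", _trace(mask == _LV_CAV))
        # septum: LV-side boundary adjacent to RV blood or muscle, and
        # interior (never on the outer/epicardial outline)
        sept = []
        if has_rv:
            for poly in _trace(lv_group):
                adj = _near_label(poly, rv_group) \
                    & ~_near_label(poly, mask == 0, radius=1.2)
                if adj.any():
                    # split into contiguous runs of septal points
                    runs = np.split(np.arange(len(poly)),
                                    np.where(np.diff(adj.astype(int)) != 0)[0] + 1)
                    sept += [poly[r] for r in runs if adj[r[0]] and len(r) >= 2]
        if sept:
            out["septum"] = ([_resample(p, min_spacing_px) for p in sept]
                             if min_spacing_px > 0 else sept)

    if has_rv:
        rv_polys = []
        for poly in _trace(mask == _RV_CAV):
            if has_lv:
                adj = _near_label(poly, np.isin(mask, (_LV_MYO,)), radius=1.8)
                if adj.any():
                    runs = np.split(np.arange(len(poly)),
                                    np.where(np.diff(adj.astype(int)) != 0)[0] + 1)
                    rv_polys += [poly[r] for r in runs
                                 if not adj[r[0]] and len(r) >= 2]
                else:
                    rv_polys.append(poly)
            else:
                rv_polys.append(poly)
        keep("rv_endo", rv_polys)

    keep("epicardium", _trace(mask > 0))
    return ContourSet2D(contours=out, view=v, frame=frame)


def lift_to_3d(contours: ContourSet2D | None, landmarks_px: dict[str, np.ndarray] | None,
               meta: ImagePlaneMeta) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Map 2D contour polylines and named landmarks into patient mm."""
    contour3d: dict[str, np.ndarray] = {}
    if contours is not None:
        for cls, polys in contours.contours.items():
            pts = np.concatenate(polys)
            contour3d[cls] = pixel_to_patient(meta, pts)
    landmark3d: dict[str, np.ndarray] = {}
    if landmarks_px:
        for name, rc in landmarks_px.items():
            landmark3d[name] = pixel_to_patient(meta, np.asarray(rc, dtype=float))
    return contour3d, landmark3d


def assemble_guide_points(series_info: list[dict], es_frame: int,
                          contour_spacing_mm: float = 2.0
                          ) -> tuple[GuidePointSet, GuidePointSet]:
    """Merge per-series predictions into ED and ES guide-point sets.

    ``series_info`` entries carry: ``series_id``, ``view``, ``meta``
    (ImagePlaneMeta), optional ``masks`` {frame: label image}, optional
    ``landmarks`` {frame: {name: (row, col)}}, and for SAx series an
    ``optimal`` flag.  ED is frame 0; ES is ``es_frame``.
    """
    sax_ok = [s for s in series_info
              if _as_view(s["view"]) == "SAx" and s.get("optimal")]
    if not sax_ok:
        raise ValueError("no optimal SAx slices: a model cannot be fitted")
    la_views = {_as_view(s["view"]) for s in series_info} - {"SAx", "OTHER"}
    if not la_views:
        raise ValueError("at least one long-axis view is required")

    sets = {"ED": GuidePointSet(phase="ED"), "ES": GuidePointSet(phase="ES")}
    for info in series_info:
        v = _as_view(info["view"])
        if v in ("LVOT", "OTHER"):
            continue
        if v == "SAx" and not info.get("optimal"):
            continue
        meta = info["meta"]
        spacing_px = contour_spacing_mm / meta.row_spacing_mm
        for phase, frame in (("ED", 0), ("ES", es_frame)):
            gset = sets[phase]
            mask = info.get("masks", {}).get(frame)
            if mask is not None:
                cs = extract_contours(mask, v, min_spacing_px=spacing_px,
                                      frame=frame)
                c3, _ = lift_to_3d(cs, None, meta)
                for cls, pts in c3.items():
                    gset.add_contours(cls, pts)
            lms = info.get("landmarks", {}).get(frame)
            if lms:
                try:
                    valid_names = set(landmark_set_for_view(v))
                except ValueError:
                    valid_names = set()
                _, l3 = lift_to_3d(None, {k: rc for k, rc in lms.items()
                                          if k in valid_names}, meta)
                for name, xyz in l3.items():
                    gset.landmark_points.append((name, xyz, info["series_id"]))
    return sets["ED"], sets["ES"]
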