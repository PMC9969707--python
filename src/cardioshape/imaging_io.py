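"""Study/series containers, plane geometry, and image preprocessing.

A cine CMR study is a set of series; each series is a stack of 2D frames
acquired on a fixed imaging plane.  Plane geometry follows the DICOM
patient-coordinate convention: a right-handed LPS frame in millimetres,
with pixel indices 0-based ``(row, col)`` referring to pixel centers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImagePlaneMeta",
    "CineSeries",
    "CineStudy",
    "pixel_to_patient",
    "patient_to_pixel",
    "resize_bicubic",
    "minmax_normalize",
    "standardize",
    "pad_cine",
    "stack_temporal_channels",
    "save_study",
    "load_study",
]


@dataclass
class ImagePlaneMeta:
    """Geometry of one imaging plane.

    ``origin_mm`` is the patient-space position of the center of pixel
    (0, 0); ``row_dir``/``col_dir`` are unit vectors along increasing row
    and column index.
    """

    origin_mm: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    row_spacing_mm: float
    col_spacing_mm: float
    slice_thickness_mm: float = 6.0

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.row_dir = np.asarray(self.row_dir, dtype=float)
        self.col_dir = np.asarray(self.col_dir, dtype=float)
        for v, name in ((self.row_dir, "row_dir"), (self.col_dir, "col_dir")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a unit vector")
        if abs(float(self.row_dir @ self.col_dir)) > 1e-6:
            raise ValueError("row_dir and col_dir must be orthogonal")
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Unit plane normal (row_dir x col_dir)."""
        return np.cross(self.row_dir, self.col_dir)

    def to_dict(self) -> dict:
        return {
            "origin_mm": self.origin_mm.tolist(),
            "row_dir": self.row_dir.tolist(),
            "col_dir": self.col_dir.tolist(),
            "row_spacing_mm": self.row_spacing_mm,
            "col_spacing_mm": self.col_spacing_mm,
            "slice_thickness_mm": self.slice_thickness_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImagePlaneMeta":
        return cls(
            origin_mm=np.array(d["origin_mm"]),
            row_dir=np.array(d["row_dir"]),
            col_dir=np.array(d["col_dir"]),
            row_spacing_mm=float(d["row_spacing_mm"]),
            col_spacing_mm=float(d["col_spacing_mm"]),
            slice_thickness_mm=float(d["slice_thickness_mm"]),
        )


@dataclass
class CineSeries:
    """One cine acquisition: ``frames`` of shape (n_frames, rows, cols)."""

    frames: np.ndarray
    meta: ImagePlaneMeta
    series_id: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (n_frames, rows, cols) with n_frames >= 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class CineStudy:
    series: list[CineSeries] = field(default_factory=list)
    study_id: str = "study"

    def __post_init__(self) -> None:
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValueError("series_ids must be unique")

    def get(self, series_id: str) -> CineSeries:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise KeyError(series_id)

    @property
    def series_ids(self) -> list[str]:
        return [s.series_id for s in self.series]


# ---------------------------------------------------------------------------
# coordinate transforms


def pixel_to_patient(meta: ImagePlaneMeta, p) -> np.ndarray:
    """Map 0-based (row, col) pixel coordinates to patient mm.

    Accepts a single point or an (N, 2) array; affine in p.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite pixel coordinates")
    single = p.ndim == 1
    p = np.atleast_2d(p)
    out = (
        meta.origin_mm
        + p[:, :1] * meta.row_spacing_mm * meta.row_dir
        + p[:, 1:2] * meta.col_spacing_mm * meta.col_dir
    )
    return out[0] if single else out


def patient_to_pixel(meta: ImagePlaneMeta, q) -> np.ndarray:
    """Inverse of :func:`pixel_to_patient` for in-plane points.

    Off-plane components are discarded (orthogonal projection onto the
    plane), so the round trip is exact only for in-plane points.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q) - meta.origin_mm
    rows = (q @ meta.row_dir) / meta.row_spacing_mm
    cols = (q @ meta.col_dir) / meta.col_spacing_mm
    out = np.stack([rows, cols], axis=-1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# preprocessing


def resize_bicubic(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bicubic resize of a 2D image to ``target`` (H, W); no crop."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if target[0] <= 0 or target[1] <= 0:
        raise ValueError("target shape must be positive")
    if tuple(image.shape) == tuple(target):
        return image.copy()
    return _sk_resize(image, target, order=3, mode="edge", anti_aliasing=False)


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Affinely rescale so min -> 0 and max -> 1.

    A constant image maps to all zeros (with a warning).
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi - lo == 0.0:
        warnings.warn("minmax_normalize: constant image, returning zeros")
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def standardize(image: np.ndarray) -> np.ndarray:
    """Zero-center to mean 0, sd 1 (the classifier-input normalization)."""
    image = np.asarray(image, dtype=float)
    sd = image.std()
    if sd == 0:
        return image - image.mean()
    return (image - image.mean()) / sd


def pad_cine(cine: CineSeries | np.ndarray, n: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad a cine stack along time to ``n`` frames.

    Returns ``(frames, validity)`` where validity is a boolean mask of the
    original (true) frames.  Truncation is refused.
    """
    frames = cine.frames if isinstance(cine, CineSeries) else np.asarray(cine)
    t = frames.shape[0]
    if t > n:
        raise ValueError(f"cine has {t} frames > requested {n}; refusing to truncate")
    out = np.zeros((n,) + frames.shape[1:], dtype=frames.dtype)
    out[:t] = frames
    validity = np.zeros(n, dtype=bool)
    validity[:t] = True
    return out, validity


def stack_temporal_channels(cine: CineSeries | np.ndarray, t: int) -> np.ndarray:
    """5-channel temporal context image for frame ``t``.

    Channels are frames (t-2, t-1, t, t+1, t+2) with cyclic indexing
    (cine acquisitions are periodic over the cardiac cycle).
    """
    frames = cine.frames if isinstance(cine, CineSeries) else np.asarray(cine)
    n = frames.shape[0]
    idx = [(t + k) % n for k in (-2, -1, 0, 1, 2)]
    return frames[idx]


# ---------------------------------------------------------------------------
# study I/O: one NIfTI per series + a JSON manifest


def _series_affine(meta: ImagePlaneMeta) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, 0] = meta.row_spacing_mm * meta.row_dir
    aff[:3, 1] = meta.col_spacing_mm * meta.col_dir
    aff[:3, 2] = meta.slice_thickness_mm * meta.normal
    aff[:3, 3] = meta.origin_mm
    return aff


def save_study(study: CineStudy, out_dir: str | Path,
               view_labels: dict[str, str] | None = None) -> Path:
    """Write each series as ``<series_id>.nii.gz`` plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"study_id": study.study_id, "series": []}
    for s in study.series:
        fname = f"{s.series_id}.nii.gz"
        # store as (rows, cols, frames) so the affine's first two axes are spatial
        data = np.moveaxis(s.frames.astype(np.float32), 0, -1)
        nib.save(nib.Nifti1Image(data, _series_affine(s.meta)), str(out_dir / fname))
        entry = {"series_id": s.series_id, "file": fname, "meta": s.meta.to_dict()}
        if view_labels and s.series_id in view_labels:
            entry["view"] = view_labels[s.series_id]
        manifest["series"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def load_study(in_dir: str | Path) -> tuple[CineStudy, dict[str, str]]:
    """Read a study written by :func:`save_study`.

    Returns the study and any view labels recorded in the manifest.
    """
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    series, views = [], {}
    for entry in manifest["series"]:
        img = nib.load(str(in_dir / entry["file"]))
        frames = np.moveaxis(np.asarray(img.dataobj), -1, 0)
        series.append(CineSeries(frames=frames,
                                 meta=ImagePlaneMeta.from_dict(entry["meta"]),
                                 series_id=entry["series_id"]))
        if "view" in entry:
            views[entry["series_id"]] = entry["view"]
    return CineStudy(series=series, study_id=manifest["study_id"]), views
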