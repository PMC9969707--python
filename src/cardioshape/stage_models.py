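"""Supervision codecs and trainable models for the five pipeline stages.

The pipeline automates five image-analysis steps: view classification
(8 classes), short-axis slice selection (optimal / non-optimal),
end-systolic phase selection (a peak-normalized Gaussian phase curve,
sigma 4 frames), anatomical landmark localization (peak-normalized
Gaussian heatmaps, sigma 12 px), and myocardial segmentation
(per-view cavity/myocardium class maps, papillary muscles and
trabeculae counted as blood pool).

Each stage pairs a label codec (encode/decode) with a small CPU
network from :mod:`cardioshape.nn` honouring the stage's input/output
contract: softmax classifier heads for view/slice, a convolutional
per-frame encoder feeding a bidirectional recurrence for the phase
curve, and an encoder-decoder with skip connections for heatmaps and
segmentations.  All are trained with stochastic gradient descent with
momentum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from . import nn
from .imaging_io import minmax_normalize, resize_bicubic, standardize, pad_cine

__all__ = [
    "ViewLabel", "PhaseCurve", "HeatmapStack", "TrainConfig", "StageModel",
    "LANDMARK_NAMES", "SEG_CLASS_NAMES",
    "encode_phase_curve", "decode_es_phase",
    "encode_landmark_heatmap", "decode_heatmap",
    "encode_segmentation_classes", "landmark_set_for_view",
    "train_stage", "augment", "save_model", "load_model",
]


class ViewLabel(Enum):
    TWO_CH_LT = "2Ch LT"
    TWO_CH_RT = "2Ch RT"
    THREE_CH = "3Ch"
    FOUR_CH = "4Ch"
    LVOT = "LVOT"
    RVOT = "RVOT"
    SAX = "SAx"
    OTHER = "OTHER"


VIEW_ORDER = [v.value for v in ViewLabel]

# union of all landmark channels (per-view subsets below)
LANDMARK_NAMES = ["MV1", "MV2", "AV1", "AV2", "TV1", "TV2",
                  "PV1", "PV2", "LV_APEX", "RV1", "RV2"]

# global tissue codes shared with the phantom generator
SEG_CLASS_NAMES = {0: "background", 1: "LV cavity", 2: "LV myocardium",
                   3: "RV cavity", 4: "RV myocardium"}

STAGES = ("view", "slice", "phase", "landmark", "segment")


def _as_view(view) -> str:
    return view.value if isinstance(view, ViewLabel) else str(view)


def landmark_set_for_view(view) -> list[str]:
    """Landmark names annotated in a given view."""
    v = _as_view(view)
    table = {
        "3Ch": ["MV1", "MV2", "AV1", "AV2"],
        "4Ch": ["MV1", "MV2", "TV1", "TV2", "LV_APEX"],
        "RVOT": ["PV1", "PV2"],
        "SAx": ["RV1", "RV2"],
    }
    if v not in table:
        raise ValueError(f"view {v!r} carries no landmarks")
    return table[v]


def encode_segmentation_classes(view) -> dict[int, str]:
    """Structure classes labeled in a view (global code -> name)."""
    v = _as_view(view)
    if v in ("LVOT", "OTHER"):
        raise ValueError(f"view {v!r} is not segmented")
    keep = {
        "2Ch LT": (1, 2),
        "2Ch RT": (3, 4),
        "RVOT": (3, 4),
        "3Ch": (1, 2, 3, 4),
        "4Ch": (1, 2, 3, 4),
        "SAx": (1, 2, 3, 4),
    }[v]
    out = {0: SEG_CLASS_NAMES[0]}
    out.update({k: SEG_CLASS_NAMES[k] for k in keep})
    return out


# ---------------------------------------------------------------------------
# phase codec


@dataclass
class PhaseCurve:
    """Peak-normalized Gaussian phase label: 1 at ES, ~0 in diastole."""

    values: np.ndarray
    n_frames: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("phase curve values must lie in [0, 1]")


def encode_phase_curve(es_frame: int, n_frames: int, sigma: float = 4.0) -> PhaseCurve:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (0 <= es_frame < n_frames):
        raise ValueError("es_frame out of range")
    t = np.arange(n_frames)
    return PhaseCurve(np.exp(-((t - es_frame) ** 2) / (2.0 * sigma ** 2)), n_frames)


def decode_es_phase(curves, validity=None) -> int:
    """ES frame from one or more predicted phase curves.

    Curves are averaged across slices over their valid frames and the
    argmax is returned; exact ties break toward the earliest frame.
    """
    arrs = [np.asarray(c.values if isinstance(c, PhaseCurve) else c, dtype=float)
            for c in (curves if isinstance(curves, (list, tuple)) else [curves])]
    if not arrs:
        raise ValueError("no curves supplied")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("curves must share n_frames")
    if validity is None:
        masks = [np.ones(n, dtype=bool)] * len(arrs)
    else:
        masks = [np.asarray(m, dtype=bool) for m in
                 (validity if isinstance(validity, (list, tuple)) else [validity])]
    total = np.zeros(n)
    count = np.zeros(n)
    for a, m in zip(arrs, masks):
        total[m] += a[m]
        count[m] += 1
    if not count.any():
        raise ValueError("all frames invalid")
    mean = np.where(count > 0, total / np.maximum(count, 1), -np.inf)
    finite = mean[np.isfinite(mean)]
    if finite.max() - finite.min() < 1e-12:
        warnings.warn("flat phase curve: low-confidence ES estimate")
    return int(np.argmax(mean))


# ---------------------------------------------------------------------------
# landmark heatmap codec


@dataclass
class HeatmapStack:
    maps: np.ndarray          # (K, H, W), each peak-normalized to 1
    names: list[str]

    def __post_init__(self):
        if len(self.maps) != len(self.names):
            raise ValueError("one map per landmark name required")


def encode_landmark_heatmap(points: dict[str, np.ndarray], shape: tuple[int, int],
                            sigma: float = 12.0) -> HeatmapStack:
    """Peak-normalized Gaussian heatmap per named landmark."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    maps, names = [], []
    for name, rc in points.items():
        r, c = float(rc[0]), float(rc[1])
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"landmark {name} at ({r:.1f}, {c:.1f}) outside image")
        maps.append(np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma ** 2)))
        names.append(name)
    return HeatmapStack(np.asarray(maps), names)


def decode_heatmap(map2d: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Landmark position and confidence from one heatmap.

    Finds the global maximum, keeps its connected component above half
    the maximum, and returns that blob's intensity-weighted centroid;
    confidence is the maximum value.  An all-zero (or negative) map
    yields (None, 0.0).
    """
    m = np.asarray(map2d, dtype=float)
    peak = float(m.max())
    if peak <= 0.0:
        return None, 0.0
    mask = m >= 0.5 * peak
    comp = cc_label(mask, connectivity=2)
    pk = np.unravel_index(int(np.argmax(m)), m.shape)
    blob = comp == comp[pk]
    wgt = np.where(blob, m, 0.0)
    rr, cc = np.mgrid[0:m.shape[0], 0:m.shape[1]]
    s = wgt.sum()
    return np.array([(wgt * rr).sum() / s, (wgt * cc).sum() / s]), peak


# ---------------------------------------------------------------------------
# training configuration and models

# Defaults for the package's own compact architectures; learning rates are
# per stage because the losses live on very different scales.
_DEFAULT_LR = {"view": 0.05, "slice": 0.05, "phase": 0.05,
               "landmark": 0.05, "segment": 0.1}
_DEFAULT_AUG = {
    "view": {"rotation": 10.0, "zoom": 0.2, "translation": 0.1},
    "slice": {"rotation": 30.0, "zoom": 0.2, "translation": 0.1},
    "phase": {"time-roll": 1, "brightness": 0.1, "contrast": 0.05},
    "landmark": {"rotation": 10.0, "zoom": 0.2, "translation": 0.1},
    "segment": {"rotation": 10.0, "zoom": 0.2, "brightness": 0.15,
                "contrast": 0.15, "noise": 0.02},
}


@dataclass
class TrainConfig:
    stage: str
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float | None = None
    momentum: float = 0.9
    seed: int = 0
    augmentation: dict | None = None
    input_size: int = 128

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate is None:
            self.learning_rate = _DEFAULT_LR[self.stage]
        if self.augmentation is None:
            self.augmentation = dict(_DEFAULT_AUG[self.stage])


class _ClassifierNet(nn.Layer):
    """Downsample -> 3 conv blocks -> global average pool -> softmax head."""

    def __init__(self, n_classes: int, rng, input_size: int = 128):
        self.pre = nn.AvgPoolK(max(1, input_size // 64))
        self.body = nn.Sequential(
            nn.Conv2d(1, 8, rng=rng), nn.InstanceNorm2d(8), nn.LeakyReLU(),
            nn.AvgPool2(),
            nn.Conv2d(8, 16, rng=rng), nn.InstanceNorm2d(16), nn.LeakyReLU(),
            nn.AvgPool2(),
            nn.Conv2d(16, 32, rng=rng), nn.InstanceNorm2d(32), nn.LeakyReLU(),
            nn.AvgPool2(),
            nn.Conv2d(32, 32, rng=rng), nn.InstanceNorm2d(32), nn.LeakyReLU(),
            nn.GlobalAvgPool())
        self.head = nn.Linear(32, n_classes, rng=rng)

    def params(self):
        return self.body.params() + self.head.params()

    def forward(self, x):
        return self.head.forward(self.body.forward(self.pre.forward(x)))

    def backward(self, d):
        return self.pre.backward(self.body.backward(self.head.backward(d)))


class _PhaseNet(nn.Layer):
    """Shared per-frame conv encoder + bidirectional recurrence -> curve."""

    def __init__(self, rng, input_size: int = 128, feat: int = 16, hidden: int = 24):
        self.pre = nn.AvgPoolK(max(1, input_size // 32))
        self.enc = nn.Sequential(
            nn.Conv2d(1, 8, rng=rng), nn.InstanceNorm2d(8), nn.LeakyReLU(),
            nn.AvgPool2(),
            nn.Conv2d(8, feat, rng=rng), nn.InstanceNorm2d(feat), nn.LeakyReLU(),
            nn.AvgPool2(),
            nn.Conv2d(feat, feat, rng=rng), nn.ReLU(), nn.GlobalAvgPool())
        self.rnn = nn.BiRNN(feat, hidden, rng=rng)
        self.head = nn.Linear(2 * hidden, 1, rng=rng)
        self.feat = feat

    def params(self):
        return self.enc.params() + self.rnn.params() + self.head.params()

    def forward(self, x):           # x: (N, T, H, W)
        n, t, h, w = x.shape
        self._nt = (n, t)
        f = self.enc.forward(self.pre.forward(x.reshape(n * t, 1, h, w)))
        hcat = self.rnn.forward(f.reshape(n, t, self.feat))
        z = self.head.forward(hcat.reshape(n * t, -1)).reshape(n, t)
        self._z = z
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, d):
        n, t = self._nt
        s = 1.0 / (1.0 + np.exp(-self._z))
        dz = (d * s * (1.0 - s)).astype(nn.F32)
        dh = self.head.backward(dz.reshape(n * t, 1)).reshape(n, t, -1)
        dseq = self.rnn.backward(dh)
        dflat = self.enc.backward(dseq.reshape(n * t, self.feat))
        return self.pre.backward(dflat)


class _DenseMapNet(nn.Layer):
    """Half-resolution encoder-decoder + full-resolution output head.

    Used for both landmark heatmaps (MSE) and segmentation (CE + Dice);
    the heavy U-shaped part runs at half the input resolution.
    """

    def __init__(self, cin: int, cout: int, rng, widths=(8, 16, 24),
                 coords: bool = False):
        self.pool = nn.AvgPool2()
        self.coords = coords
        # coordinate channels disambiguate left/right members of otherwise
        # symmetric landmark pairs (a purely convolutional net has no
        # notion of absolute image position)
        self.ed = nn.EncoderDecoder(cin + (2 if coords else 0), widths[0],
                                    rng=rng, widths=widths)
        self.up = nn.Up2()
        # leaky activation: a plain ReLU here can die globally early in
        # training, freezing the output at a constant map
        self.act = nn.LeakyReLU()
        self.out = nn.Conv2d(widths[0], cout, rng=rng)

    def params(self):
        return self.ed.params() + self.out.params()

    def forward(self, x):
        x = self.pool.forward(x)
        if self.coords:
            n, _c, h, w = x.shape
            rr, cc = np.meshgrid(np.linspace(-1, 1, h, dtype=nn.F32),
                                 np.linspace(-1, 1, w, dtype=nn.F32),
                                 indexing="ij")
            grids = np.broadcast_to(np.stack([rr, cc])[None], (n, 2, h, w))
            x = np.concatenate([x, grids.astype(x.dtype)], axis=1)
        y = self.ed.forward(x)
        return self.out.forward(self.act.forward(self.up.forward(y)))

    def backward(self, d):
        dy = self.up.backward(self.act.backward(self.out.backward(d)))
        dx = self.ed.backward(dy)
        if self.coords:
            dx = dx[:, :-2]
        return self.pool.backward(dx)


@dataclass
class StageModel:
    """A trained stage network plus its input/output contract."""

    stage: str
    net: nn.Layer
    meta: dict
    config: TrainConfig
    log: list = field(default_factory=list)

    # ---- per-stage prediction API ----
    def _prep_cls(self, image) -> np.ndarray:
        s = self.meta["input_size"]
        img = standardize(resize_bicubic(np.asarray(image, dtype=float), (s, s)))
        return img[None, None].astype(nn.F32)

    def predict_view(self, image) -> tuple[ViewLabel, np.ndarray]:
        probs = nn.softmax(self.net.forward(self._prep_cls(image)), axis=1)[0]
        return ViewLabel(VIEW_ORDER[int(np.argmax(probs))]), probs

    def predict_slice(self, image) -> tuple[bool, np.ndarray]:
        """True for an optimal SAx slice; exact ties resolve non-optimal."""
        probs = nn.softmax(self.net.forward(self._prep_cls(image)), axis=1)[0]
        return bool(probs[1] > probs[0]), probs

    def predict_phase(self, frames, n_pad: int = 30) -> tuple[PhaseCurve, np.ndarray]:
        padded, validity = pad_cine(np.asarray(frames, dtype=float), n_pad)
        s = self.meta["input_size"]
        imgs = np.stack([standardize(resize_bicubic(f, (s, s))) if v else
                         np.zeros((s, s)) for f, v in zip(padded, validity)])
        curve = self.net.forward(imgs[None].astype(nn.F32))[0]
        return PhaseCurve(np.clip(curve, 0, 1), n_pad), validity

    def predict_heatmaps(self, image5) -> HeatmapStack:
        x = np.asarray(image5, dtype=float)
        s = self.meta["input_size"]
        x = np.stack([minmax_normalize(resize_bicubic(ch, (s, s))) for ch in x])
        maps = self.net.forward(x[None].astype(nn.F32))[0]
        return HeatmapStack(np.clip(maps, 0, None), list(self.meta["names"]))

    def predict_segmentation(self, image, view=None) -> np.ndarray:
        x = np.asarray(image, dtype=float)
        s = self.meta["input_size"]
        xr = minmax_normalize(resize_bicubic(x, (s, s)))
        logits = self.net.forward(xr[None, None].astype(nn.F32))[0]
        if view is not None:
            allowed = set(encode_segmentation_classes(view))
            for k in range(logits.shape[0]):
                if k not in allowed:
                    logits[k] = -np.inf
        pred = np.argmax(logits, axis=0).astype(np.uint8)
        if pred.shape != x.shape:
            zoomf = (x.shape[0] / pred.shape[0], x.shape[1] / pred.shape[1])
            pred = ndi.zoom(pred, zoomf, order=0)
        return pred


# ---------------------------------------------------------------------------
# augmentation


_KNOWN_AUG = {"rotation", "zoom", "translation", "brightness", "contrast",
              "noise", "crop", "time-roll", "mirror"}


def _affine_params(spec: dict, rng) -> tuple[float, float, np.ndarray]:
    ang = np.deg2rad(rng.uniform(-1, 1) * spec.get("rotation", 0.0))
    zoom = 1.0 + rng.uniform(-1, 1) * spec.get("zoom", 0.0)
    tr = rng.uniform(-1, 1, 2) * spec.get("translation", 0.0)
    return ang, zoom, tr


def _apply_affine_img(img, ang, zoom, tr_px, order):
    c = (np.asarray(img.shape, dtype=float) - 1) / 2
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    a = np.linalg.inv(rot * zoom)
    off = c - a @ (c + tr_px)
    return ndi.affine_transform(img, a, offset=off, order=order, mode="nearest")


def _apply_affine_pts(pts, ang, zoom, tr_px, shape):
    c = (np.asarray(shape, dtype=float) - 1) / 2
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return (np.asarray(pts, dtype=float) - c) @ (rot * zoom).T + c + tr_px


def augment(image, label, spec: dict, seed: int | np.random.Generator = 0):
    """Jointly augment an image (or cine stack) and its spatial label.

    ``spec`` maps augmentation names (rotation [deg], zoom, translation
    [fraction], brightness, contrast, noise [sd], crop [fraction],
    time-roll [bool], mirror [bool]) to magnitudes.  Geometric
    transforms are applied identically to the image and to heatmap
    stacks, integer masks, or point dictionaries; ``time-roll`` shifts
    a cine stack and its phase label together.
    """
    unknown = set(spec) - _KNOWN_AUG
    if unknown:
        raise ValueError(f"unknown augmentation(s): {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(image, dtype=float).copy()
    is_stack = img.ndim == 3

    # temporal roll first (cine + phase label move together)
    if spec.get("time-roll") and is_stack:
        k = int(rng.integers(0, img.shape[0]))
        img = np.roll(img, k, axis=0)
        if isinstance(label, PhaseCurve):
            label = PhaseCurve(np.roll(label.values, k), label.n_frames)
        elif isinstance(label, (int, np.integer)):
            label = int((label + k) % img.shape[0])

    shape2d = img.shape[-2:]
    ang, zoom, trf = _affine_params(spec, rng)
    tr_px = trf * np.asarray(shape2d)
    do_geom = any(k in spec for k in ("rotation", "zoom", "translation")) and (
        abs(ang) > 0 or zoom != 1.0 or np.any(tr_px != 0))
    mirror = bool(spec.get("mirror")) and bool(rng.integers(0, 2))

    if spec.get("crop"):
        # random crop re-expressed as an extra zoom + shift
        frac = rng.uniform(0, spec["crop"])
        if frac > 0:
            zoom = zoom / (1.0 - frac)
            do_geom = True

    def geom_img(a, order):
        if mirror:
            a = a[..., ::-1]
        if not do_geom:
            return np.ascontiguousarray(a)
        if a.ndim == 2:
            return _apply_affine_img(a, ang, zoom, tr_px, order)
        return np.stack([_apply_affine_img(f, ang, zoom, tr_px, order) for f in a])

    def geom_pts(pts):
        p = np.asarray(pts, dtype=float)
        if mirror:
            p = np.array([p[0], shape2d[1] - 1 - p[1]])
        if not do_geom:
            return p
        return _apply_affine_pts(p, ang, zoom, tr_px, shape2d)

    img = geom_img(img, order=1)

    if label is None or isinstance(label, (int, np.integer, PhaseCurve)):
        out_label = label
    elif isinstance(label, HeatmapStack):
        out_label = HeatmapStack(np.clip(geom_img(label.maps, 1), 0, 1), label.names)
    elif isinstance(label, dict):
        out_label = {k: geom_pts(v) for k, v in label.items()}
    elif isinstance(label, np.ndarray) and np.issubdtype(label.dtype, np.integer):
        out_label = geom_img(label.astype(float), order=0).astype(label.dtype)
    else:
        out_label = geom_img(np.asarray(label, dtype=float), order=1)

    if spec.get("brightness"):
        img = img + rng.uniform(-1, 1) * spec["brightness"] * (img.max() - img.min())
    if spec.get("contrast"):
        img = img.mean() + (img - img.mean()) * (1 + rng.uniform(-1, 1) * spec["contrast"])
    if spec.get("noise"):
        img = img + rng.normal(0, spec["noise"], img.shape)
    return img, out_label


# ---------------------------------------------------------------------------
# training


def _build_net(stage: str, meta: dict, seed: int) -> nn.Layer:
    rng = np.random.default_rng(seed)
    s = meta["input_size"]
    if stage == "view":
        return _ClassifierNet(8, rng, s)
    if stage == "slice":
        return _ClassifierNet(2, rng, s)
    if stage == "phase":
        return _PhaseNet(rng, s)
    if stage == "landmark":
        return _DenseMapNet(5, len(meta["names"]), rng, widths=(12, 24, 32),
                            coords=True)
    if stage == "segment":
        return _DenseMapNet(1, len(SEG_CLASS_NAMES), rng)
    raise ValueError(stage)


def _prep_sample(stage: str, sample, size: int, aug: dict, rng,
                 aug_names: list[str] | None = None):
    """One (input, target, weight) training example, augmented."""
    if stage in ("view", "slice"):
        img, lab = sample
        img = resize_bicubic(np.asarray(img, dtype=float), (size, size))
        if aug:
            img, _ = augment(img, None, aug, rng)
        return standardize(img)[None], int(lab), None
    if stage == "phase":
        frames, es = sample
        frames = np.asarray(frames, dtype=float)
        nv = frames.shape[0]
        curve = encode_phase_curve(es, nv)
        if aug:
            frames, curve = augment(frames, curve, aug, rng)
        padded, validity = pad_cine(frames, 30)
        target = np.zeros(30)
        target[:nv] = curve.values
        imgs = np.stack([standardize(resize_bicubic(f, (size, size))) if v
                         else np.zeros((size, size)) for f, v in zip(padded, validity)])
        return imgs, target, validity.astype(float)
    if stage == "landmark":
        image5, points = sample
        names = aug_names  # channel order fixed by the model's contract
        image5 = np.stack([resize_bicubic(np.asarray(ch, dtype=float), (size, size))
                           for ch in image5])
        if aug:
            image5, points = augment(image5, dict(points), aug, rng)
        image5 = np.stack([minmax_normalize(ch) for ch in image5])
        target = np.zeros((len(names), size, size))
        wgt = np.zeros((len(names), 1, 1))
        inb = {k: v for k, v in points.items()
               if k in names and 0 <= v[0] < size and 0 <= v[1] < size}
        if inb:
            hm = encode_landmark_heatmap(inb, (size, size))
            for name, m in zip(hm.names, hm.maps):
                ch = names.index(name)
                target[ch] = m
                wgt[ch, 0, 0] = 1.0
        # emphasize the peak neighbourhood over the empty background
        pos = 1.0 + 9.0 * (target > 0.1)
        return image5, target, wgt * pos
    if stage == "segment":
        img, mask = sample
        img = resize_bicubic(np.asarray(img, dtype=float), (size, size))
        mask = np.asarray(mask)
        if mask.shape != (size, size):
            zoomf = (size / mask.shape[0], size / mask.shape[1])
            mask = ndi.zoom(mask, zoomf, order=0)
        if aug:
            img, mask = augment(img, mask.astype(np.int64), aug, rng)
        return minmax_normalize(img)[None], np.asarray(mask, dtype=np.int64), None
    raise ValueError(stage)


def train_stage(stage: str, dataset: list, config: TrainConfig) -> StageModel:
    """Train one stage network; deterministic for a fixed config seed."""
    if stage != config.stage:
        raise ValueError("config.stage does not match requested stage")
    if not dataset:
        raise ValueError("empty dataset")
    size = config.input_size
    meta = {"input_size": size}
    if stage == "landmark":
        # one network per landmark set: the output channels are exactly the
        # names present in the dataset (per-view training keeps a name's
        # meaning consistent — one channel must not serve conflicting
        # appearances across views)
        present = {n for _img, pts in dataset for n in pts}
        meta["names"] = [n for n in LANDMARK_NAMES if n in present]
        if not meta["names"]:
            raise ValueError("landmark dataset carries no known landmark names")
    if stage == "segment":
        meta["classes"] = dict(SEG_CLASS_NAMES)
    net = _build_net(stage, meta, config.seed)
    opt = nn.SGD(net.params(), lr=config.learning_rate, momentum=config.momentum)
    rng = np.random.default_rng(config.seed + 1)
    log = []
    n = len(dataset)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xs, ys, ws = [], [], []
            for i in idx:
                x, y, wgt = _prep_sample(stage, dataset[i], size,
                                         config.augmentation, rng,
                                         aug_names=meta.get("names"))
                xs.append(x)
                ys.append(y)
                ws.append(wgt)
            x = np.asarray(xs, dtype=nn.F32)
            out = net.forward(x)
            if stage in ("view", "slice"):
                loss, d = nn.softmax_cross_entropy(out, np.asarray(ys))
            elif stage == "phase":
                loss, d = nn.mse_loss(out, np.asarray(ys, dtype=nn.F32),
                                      np.asarray(ws, dtype=nn.F32))
            elif stage == "landmark":
                loss, d = nn.mse_loss(out, np.asarray(ys, dtype=nn.F32),
                                      np.asarray(ws, dtype=nn.F32))
            else:
                loss, d = nn.cross_entropy_dice(out, np.asarray(ys))
            opt.zero_grad()
            net.backward(d)
            opt.step()
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return StageModel(stage=stage, net=net, meta=meta, config=config, log=log)


def landmark_train_decode_error(model: StageModel, dataset: list,
                                max_samples: int = 24) -> float:
    """Mean decoded landmark error (px) on training samples.

    Used for restart selection: a run that confused two landmarks can
    have *lower* regression loss than a correct one, but its decoded
    training error exposes the confusion immediately.  No held-out data
    is involved.
    """
    errs = []
    for img5, pts in dataset[:max_samples]:
        hm = model.predict_heatmaps(np.asarray(img5, dtype=float))
        for name, rc in pts.items():
            if name not in hm.names:
                continue
            pt, _conf = decode_heatmap(hm.maps[hm.names.index(name)])
            if pt is not None:
                errs.append(float(np.linalg.norm(pt - np.asarray(rc, dtype=float))))
    return float(np.mean(errs)) if errs else np.inf


def train_landmark_with_restarts(dataset: list, config: TrainConfig,
                                 restarts: int = 2) -> StageModel:
    """Train the landmark stage ``restarts`` times from different
    initializations and keep the run with the lowest decoded error on
    its own training samples."""
    best = None
    best_err = np.inf
    for k in range(restarts):
        cfg = TrainConfig(stage=config.stage, epochs=config.epochs,
                          batch_size=config.batch_size,
                          learning_rate=config.learning_rate,
                          momentum=config.momentum,
                          seed=config.seed + 137 * k,
                          augmentation=dict(config.augmentation),
                          input_size=config.input_size)
        model = train_stage("landmark", dataset, cfg)
        err = landmark_train_decode_error(model, dataset)
        model.meta["train_decode_error_px"] = err
        if err < best_err:
            best, best_err = model, err
    return best


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: StageModel, path: str | Path) -> None:
    """Save weights (.npz) with a JSON sidecar describing the contract."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params())}
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    side = {"stage": model.stage, "meta": model.meta,
            "config": asdict(model.config), "log": model.log}
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_model(path: str | Path) -> StageModel:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    meta = side["meta"]
    if "classes" in meta:
        meta["classes"] = {int(k): v for k, v in meta["classes"].items()}
    config = TrainConfig(**side["config"])
    net = _build_net(side["stage"], meta, config.seed)
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(net.params()):
        p.value[...] = data[f"p{i}"]
    return StageModel(stage=side["stage"], net=net, meta=meta,
                      config=config, log=side["log"])
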