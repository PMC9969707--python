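"""Phantom-derived training datasets for the five stage models.

Each builder converts a population of phantoms into the (input, label)
pairs the corresponding stage consumes: single frames with view labels,
SAx frames with optimal/non-optimal flags, full SAx cines with the ES
frame, 5-channel temporal stacks with landmark pixel coordinates, and
single frames with full-anatomy label masks (the per-view class filter
is applied at decode time, so supervision stays consistent across
views).
"""

from __future__ import annotations

import numpy as np

from .imaging_io import stack_temporal_channels
from .phantom import PhantomTruth, sample_population

__all__ = ["make_stage_dataset", "default_population_ranges", "split_dataset"]

# Modest anatomical/functional spread around the default phantom: the
# population the stage models are trained and evaluated on.
def default_population_ranges() -> dict[str, tuple[float, float]]:
    return {
        "lv_long_axis_mm": (70.0, 90.0),
        "lv_short_radius_mm": (22.0, 29.0),
        "lv_wall_mm": (7.0, 11.0),
        "rv_depth_mm": (15.0, 21.0),
        "ef_target_fraction": (0.35, 0.6),
        "es_frame": (10, 14),
        "noise_sd": (0.02, 0.05),
    }


def _truths(stage: str, n_phantoms: int, seed: int,
            truths: list[PhantomTruth] | None) -> list[PhantomTruth]:
    if truths is not None:
        return truths
    frames = "all" if stage == "phase" else "edes"
    out, _table = sample_population(n_phantoms, default_population_ranges(),
                                    seed=seed, frames=frames)
    return out


def make_stage_dataset(stage: str, n_phantoms: int = 12, seed: int = 0,
                       truths: list[PhantomTruth] | None = None,
                       view: str | None = None) -> list:
    """Build the labeled examples for one stage from phantom truths.

    For the landmark stage, pass ``view`` to restrict to one cardiac
    view — landmark networks are trained per view so that each output
    channel keeps a single anatomical meaning.
    """
    truths = _truths(stage, n_phantoms, seed, truths)
    data: list = []
    if stage == "view":
        from .stage_models import VIEW_ORDER
        for t in truths:
            # balance classes: the SAx stack would otherwise dominate
            sax = t.sax_series_ids()
            keep_sax = {sax[len(sax) // 4], sax[len(sax) // 2], sax[-len(sax) // 4]}
            for s in t.study.series:
                v = t.view_labels[s.series_id]
                if v == "SAx" and s.series_id not in keep_sax:
                    continue
                data.append((s.frames[0], VIEW_ORDER.index(v)))
    elif stage == "slice":
        for t in truths:
            for sid in t.sax_series_ids():
                data.append((t.study.get(sid).frames[0], int(t.optimal_flags[sid])))
    elif stage == "phase":
        for t in truths:
            for sid in t.optimal_sax_ids():
                data.append((t.study.get(sid).frames, t.es_frame))
    elif stage == "landmark":
        for t in truths:
            for (sid, frame) in sorted({(s, f) for (s, _n, f) in t.landmarks_px
                                        if f in (0, t.es_frame)}):
                if view is not None and t.view_labels[sid] != view:
                    continue
                pts = t.landmarks_for(sid, frame)
                x5 = stack_temporal_channels(t.study.get(sid), frame)
                data.append((x5, pts))
    elif stage == "segment":
        for t in truths:
            for sid, view in t.view_labels.items():
                if view in ("LVOT", "OTHER"):
                    continue
                if view == "SAx" and not t.optimal_flags[sid]:
                    continue
                for frame in (0, t.es_frame):
                    data.append((t.study.get(sid).frames[frame],
                                 t.full_masks[(sid, frame)]))
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return data


def split_dataset(data: list, holdout_frac: float = 0.25, seed: int = 0):
    """Deterministic train/held-out split."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(data))
    k = max(1, int(round(holdout_frac * len(data))))
    test = [data[i] for i in idx[:k]]
    train = [data[i] for i in idx[k:]]
    return train, test
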