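"""End-to-end orchestration of the automated shape-modeling workflow.

The stages run in a fixed order — view classification, slice selection,
phase selection, landmark localization, myocardial segmentation — then
contour extraction, guide-point assembly, template-mesh fitting, global
measurements and (optionally) atlas Z-score projection.  Every stage's
output can be replaced by a user-supplied override before the next
stage runs; all overrides are recorded in a ledger with per-landmark
intervention counts.  With a full set of oracle overrides the pipeline
runs without any trained model, which is how ground-truth round trips
are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import CineStudy, stack_temporal_channels
from .stage_models import (StageModel, decode_es_phase, decode_heatmap,
                           landmark_set_for_view, _as_view)
from .contouring import assemble_guide_points
from .meshfit import FitConfig, TemplateMesh, default_template, fit_guides
from .measures_atlas import GlobalMeasures, ShapeAtlas, ZScores, global_measures, project
from . import evaluation

__all__ = ["PipelineConfig", "OverrideLedger", "StageError",
           "run_pipeline", "evaluate_against_reference", "PipelineResult"]

STAGE_ORDER = ("view", "slice", "phase", "landmark", "segment")

LANDMARK_VIEWS = ("3Ch", "4Ch", "RVOT", "SAx")
SEGMENT_VIEWS = ("2Ch LT", "2Ch RT", "3Ch", "4Ch", "RVOT", "SAx")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    models: dict[str, StageModel] = field(default_factory=dict)
    fit_config: FitConfig = field(default_factory=FitConfig)
    template: TemplateMesh | None = None
    atlas: ShapeAtlas | None = None
    seed: int = 0
    contour_spacing_mm: float = 2.0


@dataclass
class OverrideLedger:
    """Record of manual interventions, per stage and per landmark."""

    entries: list[tuple[str, str, object, object, str]] = field(default_factory=list)
    presented: dict[str, int] = field(default_factory=dict)
    overridden: dict[str, int] = field(default_factory=dict)

    def present(self, item: str, n: int = 1) -> None:
        self.presented[item] = self.presented.get(item, 0) + n

    def record(self, stage: str, item: str, original, new, source: str = "override") -> None:
        self.entries.append((stage, item, original, new, source))
        self.overridden[item] = self.overridden.get(item, 0) + 1

    def rates(self) -> dict[str, tuple[int, int, float]]:
        """item -> (overrides, presented, percent)."""
        out = {}
        for item, n in self.presented.items():
            k = self.overridden.get(item, 0)
            out[item] = (k, n, 100.0 * k / n if n else 0.0)
        return out


@dataclass
class PipelineResult:
    ed_model: object
    es_model: object
    measures: GlobalMeasures
    zscores: ZScores | None
    ledger: OverrideLedger
    report: dict


def _stage_io(stage: str, models: dict, overrides: dict):
    ov = (overrides or {}).get(stage, None)
    model = models.get(stage)
    if model is None and ov is None:
        raise StageError(stage, "no trained model and no override supplied")
    return model, ov


def run_pipeline(study: CineStudy, config: PipelineConfig,
                 overrides: dict | None = None) -> PipelineResult:
    """Run the five automated stages plus fitting and measurement.

    ``overrides`` may carry per-stage replacements: ``view`` (series_id
    -> view name), ``slice`` (series_id -> bool), ``phase`` (int),
    ``landmark`` ((series_id, frame) -> {name: (row, col)}),
    ``segment`` ((series_id, frame) -> label mask).  A stage with no
    model and no override raises a StageError naming the stage;
    downstream stages do not run.
    """
    overrides = overrides or {}
    ledger = OverrideLedger()
    report: dict = {"stages": {}}

    # ---- 1. view classification ----
    model, ov = _stage_io("view", config.models, overrides)
    views: dict[str, str] = {}
    confidence: dict[str, float] = {}
    for s in study.series:
        ledger.present("view")
        if model is not None:
            lab, probs = model.predict_view(s.frames[0])
            views[s.series_id] = lab.value
            confidence[s.series_id] = float(probs.max())
        else:
            confidence[s.series_id] = 1.0
        if ov and s.series_id in ov:
            if model is not None and views[s.series_id] != _as_view(ov[s.series_id]):
                ledger.record("view", "view", views.get(s.series_id),
                              _as_view(ov[s.series_id]))
            views[s.series_id] = _as_view(ov[s.series_id])
            confidence[s.series_id] = 1.0
    missing = [sid for sid in study.series_ids if sid not in views]
    if missing:
        raise StageError("view", f"no view available for series {missing}")
    sax_ids = [sid for sid, v in views.items() if v == "SAx"]
    if not sax_ids:
        raise StageError("slice", "study contains no SAx series")
    # duplicate long-axis predictions: keep the highest-confidence series
    chosen: dict[str, str] = {}
    for sid, v in views.items():
        if v in ("SAx", "OTHER"):
            continue
        if v not in chosen or confidence[sid] > confidence[chosen[v]]:
            chosen[v] = sid
    report["stages"]["view"] = dict(views)

    # ---- 2. slice selection ----
    model, ov = _stage_io("slice", config.models, overrides)
    optimal: dict[str, bool] = {}
    for sid in sax_ids:
        ledger.present("slice")
        if model is not None:
            optimal[sid], _p = model.predict_slice(study.get(sid).frames[0])
        if ov and sid in ov:
            if model is not None and optimal[sid] != bool(ov[sid]):
                ledger.record("slice", "slice", optimal[sid], bool(ov[sid]))
            optimal[sid] = bool(ov[sid])
    selected = [sid for sid in sax_ids if optimal.get(sid)]
    if not selected:
        raise StageError("slice", "no optimal SAx slices selected")
    report["stages"]["slice"] = dict(optimal)

    # ---- 3. phase selection ----
    model, ov = _stage_io("phase", config.models, overrides)
    if model is not None:
        curves, vmasks = [], []
        for sid in selected:
            c, v = model.predict_phase(study.get(sid).frames)
            curves.append(c)
            vmasks.append(v)
        es_frame = decode_es_phase(curves, vmasks)
    else:
        es_frame = None
    ledger.present("phase")
    if "phase" in overrides:
        if es_frame is not None and es_frame != int(overrides["phase"]):
            ledger.record("phase", "phase", es_frame, int(overrides["phase"]))
        es_frame = int(overrides["phase"])
    n_frames = min(study.get(sid).n_frames for sid in selected)
    es_frame = int(np.clip(es_frame, 1, n_frames - 1))
    report["stages"]["phase"] = es_frame

    # ---- 4. landmark localization (ED and ES frames only) ----
    # landmark models are per view: a dict {view: StageModel}; a single
    # model is accepted and used for every view
    model, ov = _stage_io("landmark", config.models, overrides)
    landmarks: dict[tuple[str, int], dict] = {}
    lm_series = [(chosen.get("3Ch"), "3Ch"), (chosen.get("4Ch"), "4Ch"),
                 (chosen.get("RVOT"), "RVOT")] + [(sid, "SAx") for sid in selected]
    for sid, v in lm_series:
        if sid is None:
            continue
        names = landmark_set_for_view(v)
        vmodel = model.get(v) if isinstance(model, dict) else model
        for frame in (0, es_frame):
            found: dict[str, np.ndarray] = {}
            if vmodel is not None:
                x5 = stack_temporal_channels(study.get(sid), frame)
                hm = vmodel.predict_heatmaps(x5)
                scale = np.asarray(study.get(sid).shape, dtype=float) / np.asarray(
                    hm.maps.shape[1:], dtype=float)
                for name in names:
                    m = hm.maps[hm.names.index(name)]
                    pt, conf = decode_heatmap(m)
                    if pt is not None:
                        found[name] = pt * scale
            ovmap = (ov or {}).get((sid, frame), {})
            for name in names:
                ledger.present(name)
                if name in ovmap:
                    if vmodel is not None and name in found:
                        orig = found[name]
                        new = np.asarray(ovmap[name], dtype=float)
                        if np.linalg.norm(orig - new) > 1e-9:
                            ledger.record("landmark", name, orig.tolist(),
                                          new.tolist(), sid)
                    found[name] = np.asarray(ovmap[name], dtype=float)
            if found:
                landmarks[(sid, frame)] = found
    report["stages"]["landmark"] = {f"{sid}@{fr}": sorted(d)
                                    for (sid, fr), d in landmarks.items()}

    # ---- 5. segmentation (ED and ES frames only) ----
    model, ov = _stage_io("segment", config.models, overrides)
    seg_series = [(chosen.get(v), v) for v in
                  ("2Ch LT", "2Ch RT", "3Ch", "4Ch", "RVOT")] \
        + [(sid, "SAx") for sid in selected]
    masks: dict[tuple[str, int], np.ndarray] = {}
    for sid, v in seg_series:
        if sid is None:
            continue
        for frame in (0, es_frame):
            ledger.present("segment")
            m = None
            if model is not None:
                m = model.predict_segmentation(study.get(sid).frames[frame], view=v)
            if ov and (sid, frame) in ov:
                if m is not None and not np.array_equal(m, ov[(sid, frame)]):
                    ledger.record("segment", "segment", None, (sid, frame))
                m = np.asarray(ov[(sid, frame)])
            if m is not None:
                masks[(sid, frame)] = m

    # ---- contouring + guide points ----
    view_of = dict(views)
    series_info = []
    for sid in study.series_ids:
        v = view_of[sid]
        if v in ("LVOT", "OTHER"):
            continue
        if v != "SAx" and chosen.get(v) != sid:
            continue
        info = {"series_id": sid, "view": v, "meta": study.get(sid).meta,
                "optimal": optimal.get(sid, False),
                "masks": {fr: masks[(sid, fr)] for fr in (0, es_frame)
                          if (sid, fr) in masks},
                "landmarks": {fr: landmarks[(sid, fr)] for fr in (0, es_frame)
                              if (sid, fr) in landmarks}}
        series_info.append(info)
    try:
        guides_ed, guides_es = assemble_guide_points(
            series_info, es_frame, contour_spacing_mm=config.contour_spacing_mm)
    except ValueError as e:
        raise StageError("contouring", str(e)) from e

    # ---- fitting, measures, atlas ----
    template = config.template or default_template()
    try:
        ed_model, _tf_ed = fit_guides(template, guides_ed, config.fit_config)
        es_model, _tf_es = fit_guides(template, guides_es, config.fit_config)
    except ValueError as e:
        raise StageError("meshfit", str(e)) from e
    measures = global_measures(ed_model, es_model)
    z = None
    if config.atlas is not None:
        z = project(config.atlas, (ed_model, es_model))
    report["measures"] = measures.as_rows()
    report["override_rates"] = ledger.rates()
    report["es_frame"] = es_frame
    report["fit_rms"] = {"ED": ed_model.fit_log, "ES": es_model.fit_log}
    return PipelineResult(ed_model=ed_model, es_model=es_model,
                          measures=measures, zscores=z, ledger=ledger,
                          report=report)


def evaluate_against_reference(results: list[PipelineResult],
                               references: list[tuple],
                               atlas: ShapeAtlas | None = None) -> dict:
    """Compare pipeline outputs against reference (e.g. oracle) models.

    ``references`` holds (ED, ES) BiventricularModel pairs sharing the
    results' template topology.  Returns per-case regional MAE reports,
    population Bland-Altman summaries of the global measures, and, when
    an atlas is given, per-mode Z-score differences.
    """
    if len(results) != len(references):
        raise ValueError("results and references must pair one-to-one")
    if not results:
        raise ValueError("nothing to evaluate")
    per_case = []
    for res, (ref_ed, ref_es) in zip(results, references):
        row = {}
        for phase, auto, ref in (("ED", res.ed_model, ref_ed),
                                 ("ES", res.es_model, ref_es)):
            _tf, aligned = evaluation.rigid_align_models(auto, ref)
            row[phase] = evaluation.projection_distances(aligned, ref)
        row["measures_auto"] = res.measures.as_dict()
        row["measures_ref"] = global_measures(ref_ed, ref_es).as_dict()
        per_case.append(row)

    ba = {}
    names = list(per_case[0]["measures_auto"])
    if len(per_case) >= 3:
        for name in names:
            x = [c["measures_ref"][name] for c in per_case]
            y = [c["measures_auto"][name] for c in per_case]
            ba[name] = evaluation.bland_altman(x, y)
    out = {
        "per_case": per_case,
        "bland_altman": ba,
        "mae_global_ed": float(np.mean([c["ED"].mae["Global"][0] for c in per_case])),
        "mae_global_es": float(np.mean([c["ES"].mae["Global"][0] for c in per_case])),
        "override_rates": [r.ledger.rates() for r in results],
    }
    if atlas is not None:
        pairs_a = [(r.ed_model, r.es_model) for r in results]
        out["zscore_difference"] = evaluation.zscore_difference(
            atlas, pairs_a, references)
    return out
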