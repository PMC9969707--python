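"""Ground-truth ("oracle") substitutions for every pipeline stage.

A phantom carries the labels a human analyst would have produced;
these helpers package them either as pipeline overrides (exercising
the full orchestration with no trained networks) or directly as
guide-point sets for the mesh fitter (the fast path for population
experiments such as atlas construction).
"""

from __future__ import annotations

import numpy as np

from .contouring import GuidePointSet, assemble_guide_points
from .meshfit import BiventricularModel, FitConfig, TemplateMesh, default_template, fit_guides
from .phantom import PhantomTruth, sample_population

__all__ = ["oracle_overrides", "oracle_guides", "oracle_fit",
           "oracle_fit_population"]


def oracle_overrides(truth: PhantomTruth) -> dict:
    """Pipeline override patches carrying the phantom's ground truth."""
    es = truth.es_frame
    ov: dict = {
        "view": dict(truth.view_labels),
        "slice": dict(truth.optimal_flags),
        "phase": es,
        "landmark": {},
        "segment": {},
    }
    for (sid, frame), mask in truth.masks.items():
        if frame in (0, es):
            ov["segment"][(sid, frame)] = mask
    for (sid, name, frame), rc in truth.landmarks_px.items():
        if frame in (0, es):
            ov["landmark"].setdefault((sid, frame), {})[name] = np.asarray(rc)
    return ov


def oracle_guides(truth: PhantomTruth, contour_spacing_mm: float = 2.0
                  ) -> tuple[GuidePointSet, GuidePointSet]:
    """ED/ES guide points assembled from the phantom's own masks and
    landmarks (no trained model involved)."""
    es = truth.es_frame
    series_info = []
    for sid, view in truth.view_labels.items():
        if view in ("LVOT", "OTHER"):
            continue
        info = {"series_id": sid, "view": view,
                "meta": truth.study.get(sid).meta,
                "optimal": truth.optimal_flags.get(sid, False),
                "masks": {f: truth.masks[(sid, f)] for f in (0, es)
                          if (sid, f) in truth.masks},
                "landmarks": {f: truth.landmarks_for(sid, f) for f in (0, es)}}
        series_info.append(info)
    return assemble_guide_points(series_info, es,
                                 contour_spacing_mm=contour_spacing_mm)


def oracle_fit(truth: PhantomTruth, config: FitConfig | None = None,
               template: TemplateMesh | None = None
               ) -> tuple[BiventricularModel, BiventricularModel]:
    """Fit the template to a phantom's oracle guide points (ED and ES)."""
    template = template or default_template()
    guides_ed, guides_es = oracle_guides(truth)
    ed, _ = fit_guides(template, guides_ed, config)
    es, _ = fit_guides(template, guides_es, config)
    return ed, es


def oracle_fit_population(n: int, seed: int = 0,
                          param_ranges: dict | None = None,
                          config: FitConfig | None = None):
    """Oracle-fitted (ED, ES) model pairs for a phantom population."""
    if param_ranges is None:
        from .training_data import default_population_ranges
        param_ranges = default_population_ranges()
    truths, table = sample_population(n, param_ranges, seed=seed, frames="edes")
    template = default_template()
    pairs = [oracle_fit(t, config, template) for t in truths]
    return pairs, (truths, table)
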