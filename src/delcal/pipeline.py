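"""Four-step IRT co-calibration of the delirium severity instruments.

Step 1 fits a unidimensional 2PL to each instrument's dichotomized shared
items. Step 2 refits each instrument on all dichotomized items with the
shared items' parameters fixed at their step-1 values, so the non-shared
items are estimated on the metric anchored by the shared ones. Step 3
places the MDAS and CAM-S binary parameters on the DRS-R-98 metric by
Haebara linking through the instrument-pair anchor lists. Step 4 fits the
graded (polytomous) model per instrument with each item's loading and its
dichotomization-cut threshold fixed at the linked binary values, freeing
only the remaining thresholds — a two-stage scheme that stabilizes the
sparse top-category thresholds.

The result carries every instrument's polytomous parameters and EAP factor
scores on the common reference metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .instruments import (
    AnchorMaps,
    InstrumentSpec,
    Item,
    ResponseTable,
    build_anchor_maps,
    dichotomize,
    load_bundled_specs,
)
from .irt import CalibrationResult, ItemParams, eap_scores, fit_grm
from .linking import LinkingTransform, haebara_link, transform_params
from .quadrature import Quadrature, normal_quadrature

__all__ = [
    "PipelineConfig",
    "HarmonizedModel",
    "step1_shared",
    "step2_all_items",
    "step3_link",
    "step4_polytomous",
    "run_pipeline",
]

logger = logging.getLogger("delcal.pipeline")


@dataclass
class PipelineConfig:
    reference: str = "DRS-R-98"
    n_quadrature: int = 61
    quadrature_bound: float = 6.0
    tol: float = 1e-4
    max_iter: int = 500
    #: which polytomous threshold is constrained in step 4: the threshold at
    #: the item's dichotomization cut ("cut", default) or literally the first
    #: threshold ("first"). They differ only for sleep-disturbance items.
    step4_fixed_threshold: str = "cut"
    #: include the binary acute onset/fluctuation item in the IRT models
    #: (it always contributes to CAM-S sum scores either way).
    include_onset_item: bool = True
    anchor_domains: Mapping | None = None

    def quadrature(self) -> Quadrature:
        return normal_quadrature(self.n_quadrature, self.quadrature_bound)


def _model_spec(spec: InstrumentSpec, config: PipelineConfig) -> InstrumentSpec:
    """The item set entering the IRT models (may drop the binary onset item)."""
    if config.include_onset_item:
        return spec
    items = tuple(
        it for it in spec.items if it.domain != "acute_onset_fluctuation"
    )
    return InstrumentSpec(name=spec.name, items=items)


def _subspec(spec: InstrumentSpec, item_ids: tuple[str, ...]) -> InstrumentSpec:
    items = tuple(spec.item(i) for i in item_ids)
    return InstrumentSpec(name=spec.name, items=items)


def step1_shared(
    tables: Mapping[str, ResponseTable],
    specs: Mapping[str, InstrumentSpec],
    anchors: AnchorMaps,
    config: PipelineConfig | None = None,
) -> dict[str, CalibrationResult]:
    """2PL calibration of each instrument's seven dichotomized shared items."""
    config = config or PipelineConfig()
    quad = config.quadrature()
    out: dict[str, CalibrationResult] = {}
    for name, table in tables.items():
        spec = specs[name]
        shared_ids = anchors.shared_items[name]
        sub = _subspec(spec, shared_ids).dichotomized()
        binary = dichotomize(table, _subspec(spec, shared_ids))
        res = fit_grm(binary, sub, quadrature=quad,
                      tol=config.tol, max_iter=config.max_iter)
        logger.info("step1 %s: loglik=%.3f iter=%d converged=%s",
                    name, res.loglik, res.n_iter, res.converged)
        out[name] = res
    return out


def step2_all_items(
    tables: Mapping[str, ResponseTable],
    specs: Mapping[str, InstrumentSpec],
    step1_results: Mapping[str, CalibrationResult],
    config: PipelineConfig | None = None,
) -> dict[str, CalibrationResult]:
    """All-item binary calibration with shared items fixed at step-1 values."""
    config = config or PipelineConfig()
    quad = config.quadrature()
    out: dict[str, CalibrationResult] = {}
    for name, table in tables.items():
        spec = _model_spec(specs[name], config)
        constraints = [
            replace(p, fixed_loading=True,
                    fixed_thresholds=frozenset(range(len(p.thresholds))))
            for p in step1_results[name].params
        ]
        binary = dichotomize(table, spec)
        res = fit_grm(binary, spec.dichotomized(), constraints=constraints,
                      quadrature=quad, tol=config.tol,
                      max_iter=config.max_iter)
        logger.info("step2 %s: loglik=%.3f iter=%d converged=%s",
                    name, res.loglik, res.n_iter, res.converged)
        out[name] = res
    return out


def step3_link(
    step2_results: Mapping[str, CalibrationResult],
    anchors: AnchorMaps,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, LinkingTransform], dict[str, list[ItemParams]]]:
    """Haebara-link each instrument onto the reference metric.

    Returns the transforms and every instrument's binary parameters on the
    common metric (the reference passes through untransformed).
    """
    config = config or PipelineConfig()
    quad = config.quadrature()
    ref = anchors.reference
    transforms: dict[str, LinkingTransform] = {}
    linked: dict[str, list[ItemParams]] = {
        ref: list(step2_results[ref].params)
    }
    ref_params = step2_results[ref].params
    for name, amap in anchors.pairwise.items():
        t = haebara_link(
            anchors_ref=ref_params,
            anchors_target=step2_results[name].params,
            anchor_map=amap,
            quadrature=quad,
        )
        transforms[name] = t
        linked[name] = transform_params(step2_results[name].params, t)
        logger.info("step3 %s->%s: A=%.4f B=%.4f criterion=%.3e",
                    name, ref, t.A, t.B, t.criterion_value)
    return transforms, linked


def step4_polytomous(
    tables: Mapping[str, ResponseTable],
    specs: Mapping[str, InstrumentSpec],
    linked_binary: Mapping[str, list[ItemParams]],
    config: PipelineConfig | None = None,
) -> dict[str, CalibrationResult]:
    """Graded-model fit with loadings and cut thresholds fixed at linked values.

    For each item the loading and the threshold at its dichotomization cut
    (or literally the first threshold, per config) are fixed to the linked
    binary parameters; remaining thresholds are freely estimated with
    ordering maintained around the fixed one. Binary items have nothing free
    and pass through unchanged.
    """
    config = config or PipelineConfig()
    quad = config.quadrature()
    out: dict[str, CalibrationResult] = {}
    for name, table in tables.items():
        spec = _model_spec(specs[name], config)
        by_id = {p.item_id: p for p in linked_binary[name]}
        constraints = []
        for it in spec.items:
            b = by_id[it.item_id]
            if config.step4_fixed_threshold == "first":
                fix_idx = 0
            else:
                fix_idx = it.dichotomization_cut - 1
            tau = np.full(it.n_categories - 1, np.nan)
            tau[fix_idx] = b.thresholds[0]
            constraints.append(
                ItemParams(
                    item_id=it.item_id,
                    loading=b.loading,
                    thresholds=tuple(tau),
                    fixed_loading=True,
                    fixed_thresholds=frozenset({fix_idx}),
                )
            )
        res = fit_grm(table, spec, constraints=constraints, quadrature=quad,
                      tol=config.tol, max_iter=config.max_iter)
        logger.info("step4 %s: loglik=%.3f iter=%d converged=%s",
                    name, res.loglik, res.n_iter, res.converged)
        out[name] = res
    return out


@dataclass
class HarmonizedModel:
    """All instruments' polytomous parameters and scores on one metric."""

    reference: str
    specs: dict[str, InstrumentSpec]
    instruments: dict[str, list[ItemParams]]
    step1: dict[str, CalibrationResult] | None
    step2: dict[str, CalibrationResult] | None
    transforms: dict[str, LinkingTransform]
    scores: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    def params_by_id(self, instrument: str) -> dict[str, ItemParams]:
        return {p.item_id: p for p in self.instruments[instrument]}

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "specs": {n: s.to_dict() for n, s in self.specs.items()},
            "instruments": {
                n: [p.to_dict() for p in ps]
                for n, ps in self.instruments.items()
            },
            "transforms": {
                n: t.to_dict() for n, t in self.transforms.items()
            },
            "scores": self.scores.to_dict(orient="list"),
            "log": self.log,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: Mapping) -> "HarmonizedModel":
        from .instruments import _spec_from_dict

        return cls(
            reference=d["reference"],
            specs={
                n: _spec_from_dict(s, n) for n, s in d["specs"].items()
            },
            instruments={
                n: [ItemParams.from_dict(p) for p in ps]
                for n, ps in d["instruments"].items()
            },
            step1=None,
            step2=None,
            transforms={
                n: LinkingTransform.from_dict(t)
                for n, t in d["transforms"].items()
            },
            scores=pd.DataFrame(d["scores"]),
            log=list(d.get("log", [])),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def run_pipeline(
    tables: Mapping[str, ResponseTable],
    specs: Mapping[str, InstrumentSpec] | None = None,
    config: PipelineConfig | None = None,
    short_form: tuple[str, str] | None = ("CAM-S-long", "CAM-S-short"),
) -> HarmonizedModel:
    """Execute steps 1-4 and score every assessment on the common metric.

    ``short_form`` names (long, short) instruments where the short form is a
    reduced item set of the long form: it is scored from the long-form
    calibration restricted to its items rather than calibrated separately.
    Deterministic given data and config.
    """
    config = config or PipelineConfig()
    if specs is None:
        all_specs = load_bundled_specs()
        specs = {n: all_specs[n] for n in tables}
    specs = dict(specs)
    missing = set(tables) - set(specs)
    if missing:
        raise ValueError(f"no specs for instruments {sorted(missing)}")
    anchors = build_anchor_maps(
        {n: specs[n] for n in tables},
        reference=config.reference,
        anchor_domains=config.anchor_domains,
    )
    log: list[dict] = []

    def _log(step: str, results: Mapping[str, CalibrationResult]) -> None:
        for name, res in results.items():
            log.append(
                {
                    "step": step,
                    "instrument": name,
                    "loglik": res.loglik,
                    "n_iter": res.n_iter,
                    "converged": res.converged,
                    "flags": dict(res.flags),
                }
            )

    try:
        s1 = step1_shared(tables, specs, anchors, config)
        _log("step1", s1)
    except Exception as exc:
        raise RuntimeError(f"step1_shared failed: {exc}") from exc
    try:
        s2 = step2_all_items(tables, specs, s1, config)
        _log("step2", s2)
    except Exception as exc:
        raise RuntimeError(f"step2_all_items failed: {exc}") from exc
    try:
        transforms, linked = step3_link(s2, anchors, config)
        for name, t in transforms.items():
            log.append({"step": "step3", "instrument": name, **t.to_dict()})
    except Exception as exc:
        raise RuntimeError(f"step3_link failed: {exc}") from exc
    try:
        s4 = step4_polytomous(tables, specs, linked, config)
        _log("step4", s4)
    except Exception as exc:
        raise RuntimeError(f"step4_polytomous failed: {exc}") from exc

    instruments = {name: list(res.params) for name, res in s4.items()}
    model_specs = {
        name: _model_spec(specs[name], config) for name in tables
    }

    # short form: reduced item set of the long form, no separate calibration
    if short_form is not None:
        long_name, short_name = short_form
        if long_name in instruments:
            bundled = load_bundled_specs([short_name])[short_name]
            short_spec = specs.get(short_name, bundled)
            short_model_spec = _model_spec(short_spec, config)
            long_by_id = {p.item_id: p for p in instruments[long_name]}
            instruments[short_name] = [
                long_by_id[i] for i in short_model_spec.item_ids
            ]
            specs[short_name] = short_spec
            model_specs[short_name] = short_model_spec

    quad = config.quadrature()
    scores: pd.DataFrame | None = None
    for name, params in instruments.items():
        src = tables.get(name) or tables[short_form[0]]
        sc = eap_scores(src, params, quad)
        sc = sc.rename(
            columns={"theta": f"theta_{name}", "theta_sd": f"sd_{name}"}
        )
        scores = sc if scores is None else scores.merge(
            sc, on=["person_id", "day"], how="outer"
        )

    return HarmonizedModel(
        reference=config.reference,
        specs=specs,
        instruments=instruments,
        step1=s1,
        step2=s2,
        transforms=transforms,
        scores=scores,
        log=log,
    )
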