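"""End-to-end orchestration: occurrences + per-scenario raster stacks in,
selection/model/suitability/area/change/centroid reports out.

Stages (in order): load & clean occurrences → spatial thinning → 75/25 split
→ preliminary model on all candidate variables → zero-contribution prescreen
→ correlation screening at the thinned presence points → final model fit on
the selected variables → per-scenario suitability prediction, four-class
classification and area report → change matrix against the baseline scenario
→ centroid-migration track.  Every numeric setting (thinning distance,
correlation threshold, train fraction, class thresholds, suitable cutoff,
seeds) comes from the config; a manifest with config snapshot, seeds, output
hashes and timings makes runs self-describing and reproducible.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .geo import GridMismatchError, RasterStack, extract_values, read_asc, write_asc
from .habitat import (ClassificationScheme, change_matrix, class_areas,
                      classify, migration_track)
from .maxent import DEFAULT_BACKGROUND_SIZE, MaxEnt, SplitConfig, split
from .occurrences import clean, read_occurrences_csv, thin, write_occurrences_csv
from .selection import (CorrelationMatrix, VariableImportance, prescreen,
                        select_variables)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_stack_dir"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    occurrences: str
    scenarios: dict[str, str]            # label -> directory of .asc layers
    baseline: str
    output_dir: str
    thinning_min_km: float = 10.0
    thinning_seed: int = 42
    correlation_threshold: float = 0.8
    feature_classes: tuple[str, ...] | None = None
    beta_multiplier: float = 1.0
    link: str = "cloglog"
    background_size: int = DEFAULT_BACKGROUND_SIZE
    train_fraction: float = 0.75
    model_seed: int = 42
    class_t1: float = 0.2
    class_t2: float = 0.4
    class_t3: float = 0.6
    suitable_cutoff: float = 0.2
    centroid_weight_by_p: bool = False

    def __post_init__(self) -> None:
        if self.baseline not in self.scenarios:
            raise ValueError(
                f"baseline {self.baseline!r} not among scenarios "
                f"{sorted(self.scenarios)}")
        if not (0 < self.class_t1 < self.class_t2 < self.class_t3 < 1):
            raise ValueError("classification thresholds must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thin_cfg = raw.pop("thinning", {})
        mx = raw.pop("maxent", {})
        cls_cfg = raw.pop("classification", {})
        fc = mx.get("feature_classes")
        return cls(
            occurrences=raw["occurrences"],
            scenarios=dict(raw["scenarios"]),
            baseline=raw["baseline"],
            output_dir=raw.get("output_dir", "out"),
            thinning_min_km=thin_cfg.get("min_km", 10.0),
            thinning_seed=thin_cfg.get("seed", 42),
            correlation_threshold=raw.get("correlation_threshold", 0.8),
            feature_classes=tuple(fc) if fc else None,
            beta_multiplier=mx.get("beta_multiplier", 1.0),
            link=mx.get("link", "cloglog"),
            background_size=mx.get("background_size", DEFAULT_BACKGROUND_SIZE),
            train_fraction=mx.get("train_fraction", 0.75),
            model_seed=mx.get("seed", 42),
            class_t1=cls_cfg.get("t1", 0.2),
            class_t2=cls_cfg.get("t2", 0.4),
            class_t3=cls_cfg.get("t3", 0.6),
            suitable_cutoff=raw.get("suitable_cutoff", 0.2),
            centroid_weight_by_p=raw.get("centroid_weight_by_p", False),
        )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["feature_classes"] = (list(self.feature_classes)
                                if self.feature_classes else None)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # name -> sha256
    timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"version": self.version, "config": self.config,
                "stages": self.stages, "outputs": self.outputs,
                "timings_s": self.timings_s}


def load_stack_dir(path: str) -> RasterStack:
    """Load every ``*.asc`` in a directory (sorted by name) as one stack."""
    files = sorted(glob.glob(os.path.join(path, "*.asc")),
                   key=lambda p: _layer_sort_key(os.path.basename(p)))
    if not files:
        raise FileNotFoundError(f"no .asc layers found in {path!r}")
    return RasterStack([read_asc(f) for f in files])


def _layer_sort_key(name: str):
    # bio2 sorts before bio10
    import re
    m = re.match(r"(\D*)(\d+)", name)
    return (m.group(1), int(m.group(2))) if m else (name, 0)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage; any failure aborts with the failing stage named."""
    os.makedirs(config.output_dir, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    out = config.output_dir
    outputs: list[str] = []

    def stage(name):
        t0 = time.time()
        logger.info("stage %s", name)
        return name, t0

    def done(tag, **info):
        name, t0 = tag
        manifest.stages[name] = info
        manifest.timings_s[name] = round(time.time() - t0, 3)

    # --- load rasters -----------------------------------------------------
    tag = stage("load_stacks")
    stacks = {label: load_stack_dir(path)
              for label, path in config.scenarios.items()}
    base_stack = stacks[config.baseline]
    for label, st in stacks.items():
        if st.grid != base_stack.grid:
            raise GridMismatchError(
                f"scenario {label!r} grid differs from baseline")
        if st.names != base_stack.names:
            raise ValueError(f"scenario {label!r} has different layer names")
    done(tag, scenarios=sorted(stacks), n_layers=len(base_stack),
         grid=[base_stack.grid.n_rows, base_stack.grid.n_cols])

    # --- occurrences ------------------------------------------------------
    tag = stage("thin")
    occ_df = read_occurrences_csv(config.occurrences)
    occ = clean(occ_df, mask_stack=base_stack)
    thinned = thin(occ, min_km=config.thinning_min_km, seed=config.thinning_seed)
    if len(thinned) < 4:
        raise ValueError(f"only {len(thinned)} occurrences after thinning; need >= 4")
    thin_path = os.path.join(out, "occurrences_thinned.csv")
    write_occurrences_csv(thinned, thin_path)
    outputs.append(thin_path)
    done(tag, records_in=len(occ_df), cleaned=len(occ), thinned=len(thinned))

    # --- split + preliminary model ----------------------------------------
    tag = stage("select")
    train, test = split(thinned, SplitConfig(config.train_fraction,
                                             config.model_seed))
    pre = MaxEnt.from_occurrences(
        train, base_stack, background_size=config.background_size,
        seed=config.model_seed, feature_classes=config.feature_classes,
        beta_multiplier=config.beta_multiplier).fit()
    importance = VariableImportance(pre.importance(seed=config.model_seed))
    candidates = prescreen(importance)

    pres_vals = extract_values(base_stack.subset(candidates), thinned.points())
    pres_vals = pres_vals.loc[pres_vals["valid"], candidates]
    corr = CorrelationMatrix.from_values(pres_vals)
    imp_sub = VariableImportance(importance.table.loc[candidates])
    selected, report = select_variables(
        corr, imp_sub, threshold=config.correlation_threshold, return_report=True)
    sel_path = os.path.join(out, "selection.json")
    payload = report.to_dict()
    payload["prescreen_retained"] = candidates
    payload["importance"] = {v: {"contribution_pct": importance.contribution(v),
                                 "permutation_pct": importance.permutation(v)}
                             for v in importance.variables}
    _write_json(payload, sel_path)
    outputs.append(sel_path)
    done(tag, candidates=len(candidates), selected=len(selected),
         train=len(train), test=len(test))

    # --- final model ------------------------------------------------------
    tag = stage("fit")
    model = MaxEnt.from_occurrences(
        train, base_stack, variables=selected,
        background_size=config.background_size, seed=config.model_seed,
        feature_classes=config.feature_classes,
        beta_multiplier=config.beta_multiplier)
    res = model.fit()
    test_vals = extract_values(base_stack.subset(selected), test.points())
    test_vals = test_vals.loc[test_vals["valid"], selected]
    ev = res.evaluate(test_vals if len(test_vals) else None)
    model_path = os.path.join(out, "model.json")
    state = res.to_dict()
    state["auc_train"] = ev.auc_train
    state["auc_test"] = ev.auc_test
    state["link"] = config.link
    _write_json(state, model_path)
    outputs.append(model_path)
    done(tag, gain=res.gain, auc_train=ev.auc_train, auc_test=ev.auc_test,
         converged=res.converged)

    # --- per-scenario prediction, classification, areas --------------------
    tag = stage("predict")
    scheme = ClassificationScheme(config.class_t1, config.class_t2, config.class_t3)
    suit_maps = {}
    for label in sorted(stacks):
        suit = res.predict(stacks[label], link=config.link)
        suit_maps[label] = suit
        sp = os.path.join(out, f"suit_{label}.asc")
        write_asc(suit, sp)
        outputs.append(sp)
        cls_map = classify(suit, scheme)
        cp = os.path.join(out, f"classes_{label}.asc")
        write_asc(cls_map.to_layer(), cp)
        outputs.append(cp)
        ap = os.path.join(out, f"areas_{label}.json")
        _write_json(class_areas(cls_map).to_dict(), ap)
        outputs.append(ap)
    done(tag, scenarios=sorted(stacks))

    # --- change matrices vs baseline ---------------------------------------
    tag = stage("change")
    base_suit = suit_maps[config.baseline]
    for label in sorted(stacks):
        if label == config.baseline:
            continue
        rep = change_matrix(base_suit, suit_maps[label],
                            cutoff=config.suitable_cutoff)
        cp = os.path.join(out, f"change_{label}.json")
        _write_json(rep.to_dict(), cp)
        outputs.append(cp)
    done(tag)

    # --- centroid track -----------------------------------------------------
    tag = stage("centroid")
    track = migration_track(suit_maps, config.baseline,
                            cutoff=config.suitable_cutoff,
                            weight_by_p=config.centroid_weight_by_p)
    tp = os.path.join(out, "track.csv")
    track.to_csv(tp)
    outputs.append(tp)
    done(tag)

    for path in outputs:
        manifest.outputs[os.path.basename(path)] = _sha256(path)
    _write_json(manifest.to_dict(), os.path.join(out, "manifest.json"))
    return manifest
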