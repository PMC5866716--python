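"""Configuration-driven end-to-end habitat-change experiment.

``run_experiment`` ties every stage together on synthetic scenes: scene
generation, feature stacking, sample extraction, the classifier roster,
accuracy assessment, McNemar screening, both vote ensembles, and the
two-date change analysis. Everything derives from one global seed: each
stage draws its own seed by stable hashing of the stage name, so a rerun
with the same configuration is reproducible file-for-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .accuracy import (accuracy_report, confusion_matrix, pairwise_mcnemar,
                       screen_classifiers)
from .change import change_summary, class_areas, percent_change, transition_matrix
from .classification import ClassifierSpec, ROSTER, predict_map, train
from .ensemble import majority_vote, weighted_vote
from .preprocess import build_feature_stack
from .raster import write_habitat_map, write_cube
from .sampling import extract_samples
from .synthetic import (DATE1_PROPORTIONS, DATE2_PROPORTIONS, two_date_scenario)

log = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "assess", "ensemble", "change")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed by stable hashing of the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Everything an end-to-end synthetic experiment needs."""

    rows: int = 120
    cols: int = 120
    noise_sd: float = 0.02
    patch_scale: float = 6.0
    n_areas_per_class: int = 30
    min_area: int = 2
    max_area: int = 9
    proportions_date1: Mapping[int, float] = field(
        default_factory=lambda: dict(DATE1_PROPORTIONS))
    proportions_date2: Mapping[int, float] = field(
        default_factory=lambda: dict(DATE2_PROPORTIONS))
    field_persistence: float = 0.9
    algorithms: Sequence[str] = field(default_factory=lambda: sorted(ROSTER))
    hyperparameters: Mapping[str, Mapping] = field(default_factory=dict)
    alpha: float = 0.05
    continuity_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [a for a in self.algorithms if a not in ROSTER]
        if unknown:
            raise ValueError(f"unknown algorithms {unknown}; roster: {sorted(ROSTER)}")
        if len(self.algorithms) == 0:
            raise ValueError("need at least one classifier")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("proportions_date1", "proportions_date2"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["algorithms"] = list(d["algorithms"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_experiment(cfg: PipelineConfig, out_dir: str | Path | None = None,
                   through: str = "change") -> dict:
    """Run the pipeline through the requested stage and return the bundle.

    The bundle maps stage names to in-memory results; with ``out_dir`` set,
    CSV/GeoTIFF/GeoJSON artifacts and a manifest are also written. Errors
    propagate annotated with the failing stage and date.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; stages: {STAGES}")
    last = STAGES.index(through)
    bundle: dict = {"config": cfg.as_dict(), "dates": {}}
    t0 = time.perf_counter()

    scenes = _stage("simulate", "", lambda: two_date_scenario(
        stage_seed(cfg.seed, "simulate"), rows=cfg.rows, cols=cfg.cols,
        noise_sd=cfg.noise_sd, patch_scale=cfg.patch_scale,
        n_areas_per_class=cfg.n_areas_per_class, min_area=cfg.min_area,
        max_area=cfg.max_area, field_persistence=cfg.field_persistence,
        proportions_date1=dict(cfg.proportions_date1),
        proportions_date2=dict(cfg.proportions_date2)))
    # the scenario helper applies the configured per-date proportions
    bundle["scenes"] = scenes
    log.info("simulate: %d dates, %.1fs", len(scenes), time.perf_counter() - t0)

    for date, scene in scenes.items():
        dres: dict = {"scene": scene}
        bundle["dates"][date] = dres
        if last < STAGES.index("classify"):
            continue
        stack = _stage("classify", date, lambda: build_feature_stack(scene.cube))
        samples = _stage("classify", date, lambda: extract_samples(stack, scene.reference))
        dres["stack"], dres["samples"] = stack, samples
        maps, models = {}, {}
        for alg in cfg.algorithms:
            spec = ClassifierSpec(alg, cfg.hyperparameters.get(alg, {}),
                                  seed=stage_seed(cfg.seed, f"train:{date}:{alg}"))
            model = _stage("classify", f"{date}:{alg}", lambda: train(samples, spec))
            maps[alg] = _stage("classify", f"{date}:{alg}",
                               lambda: predict_map(model, stack))
            models[alg] = model
        dres["maps"], dres["models"] = maps, models
        if last < STAGES.index("assess"):
            continue

        val = samples.subset("validation")
        preds = {alg: maps[alg].labels[val.rows, val.cols] for alg in maps}
        reports = {alg: accuracy_report(confusion_matrix(maps[alg], samples))
                   for alg in maps}
        dres["reports"] = reports
        if len(maps) >= 2:
            pvals = _stage("assess", date, lambda: pairwise_mcnemar(
                preds, val.y, continuity=cfg.continuity_correction))
            retained = _stage("assess", date, lambda: screen_classifiers(
                reports, pvals, alpha=cfg.alpha))
        else:
            warnings.warn(f"{date}: single classifier; McNemar screening skipped")
            pvals = pd.DataFrame([[1.0]], index=list(maps), columns=list(maps))
            retained = list(maps)
        dres["pvals"], dres["retained"] = pvals, retained
        if last < STAGES.index("ensemble"):
            continue

        oa = [reports[a].overall_accuracy for a in retained]
        member_maps = [maps[a] for a in retained]
        ens_sv = _stage("ensemble", date, lambda: majority_vote(
            member_maps, member_ids=retained, accuracies=oa))
        ens_wv = _stage("ensemble", date, lambda: weighted_vote(
            member_maps, oa, member_ids=retained))
        dres["ensembles"] = {"Ens_SV": ens_sv, "Ens_WV": ens_wv}
        dres["ensemble_reports"] = {
            name: accuracy_report(confusion_matrix(res.voted_map, samples))
            for name, res in dres["ensembles"].items()}

    if last >= STAGES.index("change") and len(scenes) >= 2:
        d1, d2 = list(scenes)[:2]
        change: dict = {}
        for rule in ("Ens_SV", "Ens_WV"):
            tm = _stage("change", rule, lambda: transition_matrix(
                bundle["dates"][d1]["ensembles"][rule].voted_map,
                bundle["dates"][d2]["ensembles"][rule].voted_map,
                date_from=d1, date_to=d2))
            change[rule] = {"transition": tm,
                            "percent_change": percent_change(tm),
                            "summary": change_summary(tm)}
        areas_rows = []
        for date in scenes:
            for alg, m in bundle["dates"][date]["maps"].items():
                for cid, ha in class_areas(m).items():
                    areas_rows.append({"date": date, "algorithm": alg,
                                       "class_id": cid,
                                       "class_name": m.legend.get(cid, str(cid)),
                                       "hectares": ha})
            for name, res in bundle["dates"][date]["ensembles"].items():
                for cid, ha in class_areas(res.voted_map).items():
                    areas_rows.append({"date": date, "algorithm": name,
                                       "class_id": cid,
                                       "class_name":
                                           res.voted_map.legend.get(cid, str(cid)),
                                       "hectares": ha})
        change["areas_by_algorithm"] = pd.DataFrame(areas_rows)
        bundle["change"] = change

    if out_dir is not None:
        _export(bundle, cfg, Path(out_dir), through)
    log.info("pipeline through %s: %.1fs", through, time.perf_counter() - t0)
    return bundle


def _stage(stage: str, context: str, fn):
    try:
        return fn()
    except Exception as e:
        where = f"{stage}" + (f" [{context}]" if context else "")
        raise RuntimeError(f"pipeline stage {where} failed: {e}") from e


def _export(bundle: dict, cfg: PipelineConfig, out: Path, through: str) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def reg(path: Path) -> Path:
        files.append(str(path.relative_to(out)))
        return path

    cfg.to_yaml(reg(out / "config.yaml"))
    for date, dres in bundle["dates"].items():
        ddir = out / date
        ddir.mkdir(exist_ok=True)
        scene = dres["scene"]
        write_habitat_map(reg(ddir / "truth.tif"), scene.truth)
        files.append(str((ddir / "truth.tif.aux.json").relative_to(out)))
        write_cube(reg(ddir / "reflectance.tif"), scene.cube)
        files.append(str((ddir / "reflectance.tif.aux.json").relative_to(out)))
        scene.reference.to_geojson(reg(ddir / "reference_areas.geojson"))
        if "maps" in dres:
            for alg, m in dres["maps"].items():
                write_habitat_map(reg(ddir / f"map_{alg}.tif"), m)
                files.append(str((ddir / f"map_{alg}.tif.aux.json").relative_to(out)))
        if "reports" in dres:
            _accuracy_tables(dres, reg, ddir)
        if "ensembles" in dres:
            for name, res in dres["ensembles"].items():
                write_habitat_map(reg(ddir / f"map_{name}.tif"), res.voted_map)
                files.append(str((ddir / f"map_{name}.tif.aux.json").relative_to(out)))

    if "change" in bundle:
        ch = bundle["change"]
        for rule in ("Ens_SV", "Ens_WV"):
            ch[rule]["transition"].to_dataframe().to_csv(
                reg(out / f"transition_{rule}.csv"))
            ch[rule]["summary"].to_csv(
                reg(out / f"percent_change_{rule}.csv"), index=False)
        ch["areas_by_algorithm"].to_csv(
            reg(out / "areas_by_algorithm.csv"), index=False)

    from importlib.metadata import version
    try:
        pkg_version = version("wetlandchange")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "package_version": pkg_version,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "through": through,
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))


def _accuracy_tables(dres: dict, reg, ddir: Path) -> None:
    reports = dres["reports"]
    rows = [{"algorithm": a, "overall_accuracy": r.overall_accuracy,
             "kappa": r.kappa} for a, r in reports.items()]
    if "ensemble_reports" in dres:
        rows += [{"algorithm": n, "overall_accuracy": r.overall_accuracy,
                  "kappa": r.kappa}
                 for n, r in dres["ensemble_reports"].items()]
    pd.DataFrame(rows).to_csv(reg(ddir / "accuracy.csv"), index=False)
    cls_rows = []
    for a, r in reports.items():
        for cid in r.producers_accuracy:
            cls_rows.append({"algorithm": a, "class_id": cid,
                             "producers_accuracy": r.producers_accuracy[cid],
                             "users_accuracy": r.users_accuracy[cid]})
    pd.DataFrame(cls_rows).to_csv(reg(ddir / "class_accuracy.csv"), index=False)
    dres["pvals"].to_csv(reg(ddir / "mcnemar_pvalues.csv"))
    pd.DataFrame({"retained": dres["retained"]}).to_csv(
        reg(ddir / "retained_algorithms.csv"), index=False)
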