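"""End-to-end orchestration: simulate, detect, featurize, model, test.

``run_experiment`` drives every stage on a synthetic corpus and produces a
deterministic machine-readable report (plus a short human summary).  The
report is stamped with the seed and a hash of the canonical config, and
validates against the JSON schema shipped with the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import ioformats, synth
from .errors import (
    ConfigError,
    EventExtractionError,
    InputError,
    MissingKeypointError,
    SplitError,
)
from .events import EventParams, extract_events
from .features import build_feature_vector
from .model import (
    ForestParams,
    PerformanceRecord,
    evaluate,
    extract_rules,
    fit_single_feature_baseline,
    records_to_frame,
    select_features,
    sequential_split,
    train_forest,
)
from .stats import Condition, assign_groups, dunnett_test, mann_whitney_u

__all__ = [
    "ModelConfig",
    "StatsConfig",
    "PipelineConfig",
    "run_experiment",
    "validate_report",
    "load_config",
    "save_config",
]

logger = logging.getLogger("wheelvault")

REPORT_SCHEMA_VERSION = 1

#: Detector parameters matched to the synthetic generator's low-resolution
#: velocity scale (the reference defaults of 5.5-15 px/frame assume
#: full-resolution footage).
SYNTH_EVENT_PARAMS = EventParams(eps=0.5, mag_lo=0.6, mag_hi=4.0)


@dataclass(frozen=True)
class ModelConfig:
    forest: ForestParams = field(default_factory=ForestParams)
    importance_threshold: float = 0.1
    n_test_days: int = 2
    baseline_feature: str = "time_on_wheel"
    baseline_regressor: str = "ols"


@dataclass(frozen=True)
class StatsConfig:
    cond_a: str = "time_on_wheel<=4.935"
    cond_b: str = "knee_pikemount>162.5"
    control_group: str = "I"
    alpha: float = 0.05
    alternative: str = "two-sided"


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    events: EventParams = SYNTH_EVENT_PARAMS
    side: str = "left"
    model: ModelConfig = field(default_factory=ModelConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, synth=replace(self.synth, seed=seed))

    def as_dict(self) -> dict:
        return asdict(self)


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a nested-key/value YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    synth_kw = dict(raw.get("synth", {}))
    if "meta" in synth_kw:
        synth_kw["meta"] = synth.VideoMeta(**synth_kw["meta"])
    for key in ("ride_time_range", "knee_angle_range"):
        if key in synth_kw:
            synth_kw[key] = tuple(synth_kw[key])
    model_kw = dict(raw.get("model", {}))
    if "forest" in model_kw:
        model_kw["forest"] = ForestParams(**model_kw["forest"])
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        synth=synth.SynthConfig(**synth_kw),
        events=EventParams(**raw.get("events", asdict(SYNTH_EVENT_PARAMS))),
        side=raw.get("side", "left"),
        model=ModelConfig(**model_kw),
        stats=StatsConfig(**raw.get("stats", {})),
    )


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=False))


def validate_report(report: dict) -> None:
    """Check the report against the shipped JSON schema (subset validator)."""
    schema = json.loads(
        resources.files("wheelvault").joinpath("schema/report_schema.json").read_text()
    )
    _validate(report, schema, "report")


def _validate(value, schema: dict, path: str) -> None:
    kind = schema.get("type")
    if kind == "object":
        if not isinstance(value, dict):
            raise InputError(f"{path}: expected object")
        for key in schema.get("required", ()):
            if key not in value:
                raise InputError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate(value[key], sub, f"{path}.{key}")
    elif kind == "array":
        if not isinstance(value, list):
            raise InputError(f"{path}: expected array")
        items = schema.get("items")
        if items:
            for i, item in enumerate(value):
                _validate(item, items, f"{path}[{i}]")
    elif kind == "integer":
        if not isinstance(value, int) or isinstance(value, bool):
            raise InputError(f"{path}: expected integer")
    elif kind == "number":
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise InputError(f"{path}: expected number")
    elif kind == "string":
        if not isinstance(value, str):
            raise InputError(f"{path}: expected string")


def _jsonable(value):
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if np.isnan(v) else v
    if isinstance(value, (np.integer,)):
        return int(value)
    return value


def run_experiment(
    config: PipelineConfig, outdir: str | Path | None = None
) -> dict:
    """Run every stage end-to-end and return the report dictionary.

    Performances whose event extraction or featurization fails are recorded
    in ``discarded`` (with the failing stage) and excluded from modelling,
    mirroring the discard-don't-impute policy.  With a fixed config the
    report is byte-identical across reruns.
    """
    cfg = config.with_seed(config.seed)
    fps = cfg.synth.meta.fps
    records: list[PerformanceRecord] = []
    discarded: list[dict] = []
    event_errors: dict[str, list[int]] = {
        "takeoff": [], "pikemount": [], "contact_start": [], "thrust": []
    }
    n_total = 0
    n_recovered = 0

    logger.info("stage 1/4: simulate + detect + featurize")
    for idx, perf in enumerate(synth.iter_dataset(cfg.synth)):
        n_total += 1
        series, truth = perf.series, perf.truth
        try:
            detected = extract_events(series, cfg.events)
        except EventExtractionError as exc:
            logger.warning("performance %d: detection failed at %s", idx, exc.stage)
            discarded.append(
                {"index": idx, "day": perf.day, "stage": exc.stage or "events",
                 "reason": str(exc)}
            )
            series.clear_cache()
            continue
        gt = truth.event_frames
        diffs = np.abs(np.array(detected.as_tuple()) - np.array(gt.as_tuple()))
        if diffs.max() <= 1:
            n_recovered += 1
        for name, d in zip(event_errors, diffs):
            event_errors[name].append(int(d))
        try:
            kp_by_frame = {
                f: series.keypoint_set(f)
                for f in (detected.takeoff, detected.pikemount, detected.thrust)
            }
            fv = build_feature_vector(detected, kp_by_frame, fps)
        except MissingKeypointError as exc:
            discarded.append(
                {"index": idx, "day": perf.day, "stage": "features",
                 "reason": str(exc)}
            )
            series.clear_cache()
            continue
        records.append(
            PerformanceRecord(
                gymnast_id=perf.gymnast_id,
                day=perf.day,
                features=fv,
                judge_deductions=truth.judge_scores,
            )
        )
        series.clear_cache()

    if len(records) < 4:
        raise ConfigError("too few usable performances to model")

    logger.info("stage 2/4: split + train + evaluate (%d records)", len(records))
    train, test = sequential_split(records, cfg.model.n_test_days)
    model = train_forest(train, cfg.model.forest, seed=cfg.seed)
    metrics = evaluate(model, test)
    selected = select_features(model, cfg.model.importance_threshold)
    baseline = fit_single_feature_baseline(
        records, cfg.model.baseline_feature, (train, test),
        regressor=cfg.model.baseline_regressor, seed=cfg.seed,
    )

    logger.info("stage 3/4: rule extraction")
    first_tree = model.forest.estimators_[0]
    paths = extract_rules(first_tree)
    min_path = min(paths, key=lambda p: p.leaf_prediction)
    max_path = max(paths, key=lambda p: p.leaf_prediction)

    logger.info("stage 4/4: group hypothesis tests")
    table = records_to_frame(records)
    cond_a = Condition.parse(cfg.stats.cond_a)
    cond_b = Condition.parse(cfg.stats.cond_b)
    groups = assign_groups(table, cond_a, cond_b)
    by_group = groups.values_by_group(table["mean_deduction"].to_numpy())
    stats_out: dict = {
        "cond_a": str(cond_a),
        "cond_b": str(cond_b),
        "group_sizes": groups.sizes,
    }
    control_label = cfg.stats.control_group
    others = [g for g in ("I", "II", "III", "IV") if g != control_label]
    try:
        dunnett = dunnett_test(
            by_group[control_label],
            [by_group[g] for g in others],
            alpha=cfg.stats.alpha,
            alternative=cfg.stats.alternative,
            seed=cfg.seed,
        )
        stats_out["dunnett"] = {
            "control": control_label,
            "comparisons": {
                g: r.as_dict() for g, r in zip(others, dunnett)
            },
        }
    except InputError as exc:
        stats_out["dunnett"] = {"control": control_label, "error": str(exc)}
    for key, cond in (("mwu_cond_a", cond_a), ("mwu_cond_b", cond_b)):
        mask = cond.holds(table[cond.feature].to_numpy())
        met = table["mean_deduction"].to_numpy()[mask]
        unmet = table["mean_deduction"].to_numpy()[~mask]
        if met.size and unmet.size:
            stats_out[key] = mann_whitney_u(
                met, unmet, alternative=cfg.stats.alternative
            ).as_dict()
        else:
            stats_out[key] = {"error": "one side of the condition is empty"}

    per_event = {
        name: {
            "mean_abs_error": float(np.mean(d)) if d else None,
            "max_abs_error": int(np.max(d)) if d else None,
        }
        for name, d in event_errors.items()
    }
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "n_performances": n_total,
        "n_used": len(records),
        "discarded": discarded,
        "event_recovery": {
            "n_evaluated": n_total - sum(
                1 for d in discarded if d["stage"] != "features"
            ),
            "within_one_frame_rate": (
                n_recovered / max(n_total - len(discarded), 1)
            ),
            "per_event": per_event,
        },
        "model": {
            "train_days": sorted({r.day for r in train}),
            "test_days": sorted({r.day for r in test}),
            "n_train": len(train),
            "n_test": len(test),
            "metrics": metrics.as_dict(),
            "importances": model.importances,
            "selected_features": selected,
            "importance_threshold": cfg.model.importance_threshold,
        },
        "baseline": {
            "feature": cfg.model.baseline_feature,
            "regressor": cfg.model.baseline_regressor,
            "metrics": baseline.as_dict(),
        },
        "rules": {
            "n_paths_first_tree": len(paths),
            "min_deduction_path": min_path.as_dict(),
            "max_deduction_path": max_path.as_dict(),
        },
        "stats": stats_out,
    }
    report = _jsonable(report)
    validate_report(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        ioformats.write_feature_table(table, outdir / "features.csv")
        (outdir / "summary.txt").write_text(_summarize(report))
    return report


def _summarize(report: dict) -> str:
    m = report["model"]
    lines = [
        f"wheelvault experiment (seed {report['seed']}, "
        f"config {report['config_hash']})",
        f"performances: {report['n_performances']} simulated, "
        f"{report['n_used']} used, {len(report['discarded'])} discarded",
        f"event recovery within one frame: "
        f"{report['event_recovery']['within_one_frame_rate']:.1%}",
        f"train days {m['train_days']} ({m['n_train']}), "
        f"test days {m['test_days']} ({m['n_test']})",
        f"test RMSE {m['metrics']['rmse']:.3f}, R2 {m['metrics']['r2']:.3f}"
        if m["metrics"]["r2"] is not None
        else f"test RMSE {m['metrics']['rmse']:.3f}, R2 undefined",
        f"selected features (threshold {m['importance_threshold']}): "
        f"{', '.join(m['selected_features']) or 'none'}",
        f"baseline ({report['baseline']['feature']}): "
        f"RMSE {report['baseline']['metrics']['rmse']:.3f}, "
        f"R2 {report['baseline']['metrics']['r2']:.3f}",
        f"group sizes: {report['stats']['group_sizes']}",
    ]
    return "\n".join(lines) + "\n"
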