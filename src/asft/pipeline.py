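"""End-to-end pipeline: simulate → preprocess+extract → select → train → evaluate.

A single YAML config drives every stage; each artifact written to the output
directory is stamped with the config hash and global seed so reruns are
attributable. Stages can also be run individually through the CLI; running
them separately with a shared config produces the same artifacts as one
``run_pipeline`` call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from . import fttransformer as ftt
from .evaluate import EvalConfig, cross_clip_cv, cross_subject_cv
from .features import extract_study_features
from .io import write_feature_table, write_recording
from .preprocess import PreprocessConfig
from .select import SelectionConfig, fit_selection
from .synthetic import SimConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Merged per-stage settings plus global seed and output directory."""

    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ftt.FTTConfig = field(default_factory=ftt.FTTConfig)
    scheme: str = "cross_clip"
    n_folds: int = 4
    n_reps: int = 5
    paper_mode: bool = False
    seed: int = 0
    out_dir: str = "asft_out"
    write_recordings: bool = False

    def seeded(self) -> "PipelineConfig":
        """Push the global seed into every stage that takes one."""
        return replace(
            self,
            sim=replace(self.sim, seed=self.seed),
            selection=replace(self.selection, seed=self.seed),
            model=replace(self.model, seed=self.seed),
        )

    def to_dict(self) -> dict[str, Any]:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return clean(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _build_dataclass(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


_SECTION_TYPES = {"sim": SimConfig, "preprocess": PreprocessConfig,
                  "selection": SelectionConfig, "model": ftt.FTTConfig}


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus flat overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES and isinstance(value, dict):
            if "channels" in value:
                value["channels"] = tuple(value["channels"])
            if "effect_channels" in value:
                value["effect_channels"] = tuple(value["effect_channels"])
            kwargs[key] = _build_dataclass(_SECTION_TYPES[key], value)
        else:
            kwargs[key] = value
    return _build_dataclass(PipelineConfig, kwargs)


def _stamp(cfg: PipelineConfig) -> dict[str, Any]:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed}


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float))


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the five artifact types.

    Returns a map artifact-name → path: feature table CSV, selection report
    JSON, model checkpoint, evaluation report JSON, and the manifest.
    """
    cfg = cfg.seeded()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        recordings = simulate_study(cfg.sim)
        if cfg.write_recordings:
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for rec in recordings:
                write_recording(
                    rec, rec_dir / f"{rec.subject_id}_{rec.session}.csv")

        stage = "extract"
        table = extract_study_features(recordings, cfg.preprocess)
        artifacts["features"] = write_feature_table(table,
                                                    out / "features.csv")

        stage = "select"
        selection = fit_selection(table, cfg.selection)
        selected = selection.apply(table)
        logger.info("selection retained %d features × %s channels → %d columns",
                    len(selection.retained_features),
                    "all" if selection.retained_channels is None
                    else len(selection.retained_channels),
                    selected.n_columns)
        artifacts["selection"] = out / "selection.json"
        _write_json(artifacts["selection"],
                    {**_stamp(cfg), **selection.to_dict(),
                     "selected_columns": selected.n_columns})

        stage = "train"
        fitted = ftt.fit(selected, cfg=cfg.model)
        artifacts["model"] = fitted.save(out / "model.npz")

        stage = "evaluate"
        eval_cfg = EvalConfig(model=cfg.model, selection=cfg.selection,
                              n_folds=cfg.n_folds, n_reps=cfg.n_reps,
                              paper_mode=cfg.paper_mode, seed=cfg.seed)
        runner = {"cross_clip": cross_clip_cv,
                  "cross_subject": cross_subject_cv}[cfg.scheme]
        report = runner(table, eval_cfg)
        artifacts["evaluation"] = out / "evaluation.json"
        _write_json(artifacts["evaluation"], {**_stamp(cfg), **report.to_dict()})
        print(report.summary())
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    artifacts["manifest"] = out / "manifest.json"
    _write_json(artifacts["manifest"],
                {**_stamp(cfg), "config": cfg.to_dict(),
                 "artifacts": {k: str(v) for k, v in artifacts.items()}})
    return artifacts
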