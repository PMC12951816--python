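"""End-to-end orchestration: simulate -> prepare -> train -> evaluate -> fuse.

A single mapping (YAML/JSON) configures every stage, including all
hyperparameters that the protocol leaves open, so each choice is visible
in one place.  ``run_pipeline`` executes the enabled stages in canonical
order, logs seeds and durations, and writes a run manifest whose hash
covers the configuration and the produced outputs (not wall-clock data),
so identical configurations reproduce identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cnn import TrainConfig, score_grid
from .encoding import window_series
from .evaluation import (
    aggregate_repetitions,
    case_representative_scores,
    case_unit_reports,
    image_unit_reports,
)
from .fusion import clinical_frame, run_fusion
from .roi import RoiSpec, prepare_type
from .synthetic import SimulationConfig, generate_cohort, write_cohort

STAGE_ORDER = ("simulate", "prepare", "train", "evaluate", "fuse")

logger = logging.getLogger("uteroflow.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: Path
    stages: tuple[str, ...] = STAGE_ORDER
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    roi: RoiSpec = field(default_factory=RoiSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    folds: int = 6
    repetitions: int = 12
    image_types: tuple[str, ...] = ("P",)
    split_seed: int = 42
    case_windows: int = 10
    fusion_folds: int = 5
    rf_grid: dict | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        enabled = [s for s in STAGE_ORDER if s in self.stages]
        # later stages consume earlier in-memory products
        for i, stage in enumerate(STAGE_ORDER):
            if stage in enabled and any(
                prev not in enabled for prev in STAGE_ORDER[:i]
            ):
                raise ValueError(
                    f"stage {stage!r} requires all earlier stages to be enabled"
                )
        self.stages = tuple(enabled)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim = SimulationConfig(**data.pop("simulation", {}))
        roi_kwargs = dict(data.pop("roi", {}))
        if "output_size" in roi_kwargs:
            roi_kwargs["output_size"] = tuple(roi_kwargs["output_size"])
        roi = RoiSpec(**roi_kwargs)
        train_kwargs = dict(data.pop("train", {}))
        if "input_size" in train_kwargs:
            train_kwargs["input_size"] = tuple(train_kwargs["input_size"])
        train = TrainConfig(**train_kwargs)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "image_types" in data:
            data["image_types"] = tuple(data["image_types"])
        return cls(simulation=sim, roi=roi, train=train, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _hash_obj(obj: Any) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def _report_block(reports) -> dict:
    block = {"per_repetition": [r.as_dict() for r in reports]}
    if len(reports) >= 2:
        block["summary"] = aggregate_repetitions(reports)
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.canonical_dict(),
        "config_hash": _hash_obj(config.canonical_dict()),
        "seeds": {
            "simulation": config.simulation.seed,
            "train": config.train.seed,
            "split": config.split_seed,
        },
        "stages": {},
    }
    state: dict[str, Any] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s starting", name)
        try:
            outputs = fn()
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise PipelineError(name, exc) from exc
        dt = time.perf_counter() - t0
        logger.info("stage %s done in %.1fs", name, dt)
        manifest["stages"][name] = {"outputs": outputs, "duration_s": round(dt, 3)}

    # -- simulate -----------------------------------------------------------
    def _simulate():
        cases = generate_cohort(config.simulation)
        state["cases"] = cases
        paths = write_cohort(cases, out_dir / "cohort")
        return {
            "cohort_dir": str(out_dir / "cohort"),
            "n_cases": len(cases),
            "n_positive": int(sum(c.truth for c in cases)),
            "archive": str(paths["archive"]),
            "annotations": str(paths["annotations"]),
            "clinical": str(paths["clinical"]),
        }

    # -- prepare: ROI crop + motion encoding --------------------------------
    def _prepare():
        prepared: dict[str, dict[str, np.ndarray]] = {}
        for image_type in config.image_types:
            spec = RoiSpec(
                image_type=image_type,
                p_diameter_px=config.roi.p_diameter_px,
                fill_value=config.roi.fill_value,
                output_size=config.roi.output_size,
            )
            per_case: dict[str, np.ndarray] = {}
            for case in state["cases"]:
                seq = prepare_type(case.sequence, case.annotation, spec)
                combined = window_series(seq)
                per_case[case.case_id] = np.stack([c.channels for c in combined])
            prepared[image_type] = per_case
        state["prepared"] = prepared
        n_images = sum(
            arr.shape[0] for per in prepared.values() for arr in per.values()
        )
        return {"image_types": list(config.image_types), "n_combined_images": n_images}

    # -- train: grouped CV grid scoring --------------------------------------
    def _train():
        truth_map = {c.case_id: c.truth for c in state["cases"]}
        tables = []
        for image_type, per_case in state["prepared"].items():
            tables.append(
                score_grid(
                    per_case,
                    truth_map,
                    image_type,
                    config.train,
                    folds=config.folds,
                    repetitions=config.repetitions,
                )
            )
        scores = pd.concat(tables, ignore_index=True)
        state["scores"] = scores
        path = out_dir / "scores.csv"
        scores.to_csv(path, index=False)
        return {"scores": str(path), "n_records": len(scores)}

    # -- evaluate -------------------------------------------------------------
    def _evaluate():
        truth_map = {c.case_id: c.truth for c in state["cases"]}
        frames_per_case = config.simulation.frames_per_case
        metrics: dict[str, Any] = {}
        for image_type in config.image_types:
            sub = state["scores"][state["scores"]["image_type"] == image_type]
            block = {}
            for unit, fn, kwargs in (
                ("image_unit", image_unit_reports, {}),
                (
                    "case_unit",
                    case_unit_reports,
                    {
                        "frames_per_case": frames_per_case,
                        "n_windows": config.case_windows,
                    },
                ),
            ):
                for mode, ensemble in (("single", False), ("ensemble", True)):
                    if ensemble and config.repetitions < 2:
                        continue
                    reports = fn(sub, truth_map, ensemble=ensemble, **kwargs)
                    block[f"{unit}_{mode}"] = _report_block(reports)
            metrics[image_type] = block
        state["metrics"] = metrics
        path = out_dir / "metrics.json"
        path.write_text(json.dumps(metrics, indent=2))
        return {"metrics": str(path)}

    # -- fuse -----------------------------------------------------------------
    def _fuse():
        fusion_type = config.image_types[0]
        sub = state["scores"][state["scores"]["image_type"] == fusion_type]
        case_scores = case_representative_scores(
            sub,
            frames_per_case=config.simulation.frames_per_case,
            n_windows=config.case_windows,
        )
        clin = clinical_frame(c.clinical for c in state["cases"])
        clinical_only = run_fusion(
            clin, None, seed=config.split_seed,
            grid=config.rf_grid, grouped_k=config.fusion_folds,
        )
        fused = run_fusion(
            clin, case_scores, seed=config.split_seed,
            grid=config.rf_grid, grouped_k=config.fusion_folds,
        )
        result = {
            "image_type": fusion_type,
            "clinical_only": clinical_only["report"].as_dict(),
            "fused": fused["report"].as_dict(),
            "n_train": len(fused["train_ids"]),
            "n_validation": len(fused["validation_ids"]),
        }
        path = out_dir / "fusion.json"
        path.write_text(json.dumps(result, indent=2))
        case_scores.to_csv(out_dir / "case_scores.csv", index=False)
        return {"fusion": str(path), **{k: v for k, v in result.items()
                                        if k not in ("clinical_only", "fused")},
                "clinical_only": result["clinical_only"],
                "fused": result["fused"]}

    stage_fns = {
        "simulate": _simulate,
        "prepare": _prepare,
        "train": _train,
        "evaluate": _evaluate,
        "fuse": _fuse,
    }
    for stage in STAGE_ORDER:
        if stage in config.stages:
            run_stage(stage, stage_fns[stage])

    hashable = {
        "config_hash": manifest["config_hash"],
        "stages": {
            name: blk["outputs"] for name, blk in manifest["stages"].items()
        },
    }
    manifest["manifest_hash"] = _hash_obj(hashable)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
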