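"""End-to-end pipeline runner: synthesize -> train -> decompose -> score.

`run_pipeline` executes the configured stages in a fixed order, writes
every artifact under the output directory, and returns a manifest with
a SHA-256 hash per output file.  All randomness derives from the single
config seed, so identical configs reproduce identical manifests for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .classifier import TissueClassifier, evaluate, split_dataset
from .cohort import ACTIVATION_COLUMNS, CohortConfig, generate_cohort
from .decompose import region_activation
from .score import (ScoreModel, build_score_model, multivariable_cox,
                    per_stage_models, univariable_hr)
from .textures import TextureParams
from .tissue import CLASS_CODES

logger = logging.getLogger(__name__)

STAGE_ORDER = ("synthesize_patches", "train", "evaluate", "decompose",
               "synthesize_cohort", "build_score", "apply_score", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "out"
    seed: int = 0
    stages: tuple[str, ...] = ("synthesize_cohort", "build_score",
                               "apply_score", "report")
    patches: dict = field(default_factory=lambda: {"n_per_class": 30})
    training: dict = field(default_factory=dict)
    tiling: dict = field(default_factory=lambda: {"tile": 224, "stride": 112})
    cohort: dict = field(default_factory=lambda: {"n_patients": 120})
    scoring: dict = field(default_factory=lambda: {"endpoint": "OS"})
    synthesis: dict = field(default_factory=dict)
    decompose: dict = field(default_factory=lambda: {"n_regions": 6})
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return the artifact manifest."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    manifest: dict = {"seed": cfg.seed, "stages": {}}
    state: dict = {}

    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](cfg, out, state)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s done (%.1fs)", stage,
                    manifest["stages"][stage]["seconds"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations (each returns the list of files it wrote)


def _stage_synthesize_patches(cfg, out, state):
    params = TextureParams(seed=cfg.seed, **cfg.synthesis)
    root = out / "patches"
    dio.write_patch_dataset(root, cfg.patches.get("n_per_class", 30), params)
    state["patch_root"] = root
    return []


def _stage_train(cfg, out, state):
    root = Path(cfg.patches.get("root", state.get("patch_root", "")))
    patches, labels, _ = dio.read_patch_dataset(root)
    tr, va, _te = split_dataset(labels, seed=cfg.seed)
    clf = TissueClassifier(seed=cfg.seed, **cfg.training)
    clf.fit([patches[i] for i in tr], labels[tr],
            X_val=[patches[i] for i in va], y_val=labels[va])
    model_dir = out / "model"
    clf.save(model_dir)
    state["model"] = clf
    state["split"] = (tr, va, _te)
    state["patches"], state["labels"] = patches, labels
    return [model_dir / "model.json"]


def _stage_evaluate(cfg, out, state):
    clf = state.get("model") or TissueClassifier.load(
        cfg.training.get("model_dir", out / "model"))
    if "patches" not in state:
        patches, labels, _ = dio.read_patch_dataset(
            Path(cfg.patches.get("root", out / "patches")))
        tr, va, te = split_dataset(labels, seed=cfg.seed)
        state.update(patches=patches, labels=labels, split=(tr, va, te))
    _, _, te = state["split"]
    cm, acc = evaluate(clf, [state["patches"][i] for i in te],
                       state["labels"][te])
    path = out / "classifier_metrics.json"
    path.write_text(json.dumps({
        "accuracy": acc,
        "confusion_matrix": cm.tolist(),
        "class_order": list(CLASS_CODES),
    }, indent=1))
    return [path]


def _stage_decompose(cfg, out, state):
    model = state.get("model")
    if model is None:
        model_dir = Path(cfg.decompose.get("model_dir", out / "model"))
        if not (model_dir / "model.joblib").exists():
            raise FileNotFoundError(f"no trained model at {model_dir}")
        model = TissueClassifier.load(model_dir)
    from .cohort import region_compositions
    from .textures import generate_region
    n_regions = int(cfg.decompose.get("n_regions", 6))
    size = int(cfg.decompose.get("region_size", 1500))
    params = TextureParams(seed=cfg.seed, **cfg.synthesis)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for r in range(n_regions):
        frac = rng.dirichlet(np.ones(len(CLASS_CODES)))
        comp = dict(zip(CLASS_CODES, frac))
        region, _ = generate_region(comp, params, index=r, size=size)
        vec = region_activation(model, region, **cfg.tiling)
        rows.append({"patient_id": f"R-{r:03d}", "slide_id": "S0",
                     "region_id": r,
                     **dict(zip(ACTIVATION_COLUMNS, vec))})
    path = out / "activations.csv"
    dio.write_activation_table(path, pd.DataFrame(rows))
    return [path]


def _stage_synthesize_cohort(cfg, out, state):
    cc = CohortConfig(seed=cfg.seed, **cfg.cohort)
    cohort = generate_cohort(cc)
    path = out / "cohort.csv"
    cohort.to_csv(path, index=False, float_format="%.10g")
    state["cohort"] = cohort
    return [path]


def _load_cohort(cfg, out, state):
    if "cohort" in state:
        return state["cohort"]
    path = Path(cfg.scoring.get("cohort", out / "cohort.csv"))
    cohort, _ = dio.read_clinical_table(path)
    state["cohort"] = cohort
    return cohort


def _stage_build_score(cfg, out, state):
    cohort = _load_cohort(cfg, out, state)
    sm = build_score_model(cohort, endpoint=cfg.scoring.get("endpoint", "OS"))
    path = out / "score_model.json"
    sm.to_json(path)
    state["score_model"] = sm
    return [path]


def _stage_apply_score(cfg, out, state):
    cohort = _load_cohort(cfg, out, state)
    sm = state.get("score_model")
    if sm is None:
        sm = ScoreModel.from_json(Path(cfg.scoring.get("model", out / "score_model.json")))
        state["score_model"] = sm
    scores = sm.score(cohort[list(ACTIVATION_COLUMNS)].to_numpy(float))
    labels = sm.dichotomize(scores)
    tab = cohort[["patient_id"]].copy()
    tab["deep_stroma_score"] = scores
    tab["high_risk"] = labels
    path = out / "scores.csv"
    tab.to_csv(path, index=False, float_format="%.10g")
    state["scores"], state["labels"] = scores, labels
    return [path]


def _stage_report(cfg, out, state):
    cohort = _load_cohort(cfg, out, state)
    sm = state["score_model"]
    labels = state["labels"]
    endpoint = cfg.scoring.get("endpoint", "OS")
    uni = {}
    for code, col in zip(CLASS_CODES, ACTIVATION_COLUMNS):
        uni[code] = univariable_hr(cohort[col], cohort[f"time_{endpoint}"],
                                   cohort[f"event_{endpoint}"])
    multi = multivariable_cox(cohort, labels, endpoint)
    stages = per_stage_models(cohort, labels, endpoint)

    def _cox_json(res):
        if isinstance(res, str):
            return res
        return {k: dataclasses.asdict(v) for k, v in res.items()}

    report = {
        "endpoint": endpoint,
        "n": int(len(cohort)),
        "n_events": int(cohort[f"event_{endpoint}"].sum()),
        "univariable_hr": uni,
        "score_model": json.loads(sm.to_json()),
        "fraction_high": float(np.mean(labels)),
        "multivariable": _cox_json(multi),
        "per_stage": {str(k): _cox_json(v) for k, v in stages.items()},
    }
    path = out / "survival_report.json"
    path.write_text(json.dumps(report, indent=1))
    return [path]


_STAGE_FUNCS = {
    "synthesize_patches": _stage_synthesize_patches,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "decompose": _stage_decompose,
    "synthesize_cohort": _stage_synthesize_cohort,
    "build_score": _stage_build_score,
    "apply_score": _stage_apply_score,
    "report": _stage_report,
}


def demo_config(output_dir: str | Path = "demo_out", seed: int = 7) -> RunConfig:
    """The shipped demo: a 120-patient synthetic cohort scored end to end."""
    return RunConfig(
        output_dir=str(output_dir),
        seed=seed,
        stages=("synthesize_cohort", "build_score", "apply_score", "report"),
        cohort={
            "n_patients": 120,
            "beta": {"DEB": np.log(6.0), "MUS": np.log(4.0)},
            "baseline_hazard": 0.02,
            "censoring_horizon": 120.0,
        },
        scoring={"endpoint": "OS"},
    )
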