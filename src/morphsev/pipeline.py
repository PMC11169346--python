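"""End-to-end experiment driver.

Ties the stages together on one shared partition plan: cohort synthesis or
loading -> preprocessing (merge / downsample / crop / scale) -> partition
plan -> CNN and SVM training on identical partitions -> fusion -> saliency
for the mean-performing CNN repeat -> consensus subtyping -> reports.

Stage outputs are cached inside the output directory keyed by a hash of the
experiment configuration, so reruns resume from intermediates, and every
numeric report carries the config hash and seed.  Problem sizes (repeats,
folds, epochs, sweep resolutions) are all configuration; the defaults here
are a desk-scale profile suited to a single CPU.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn as cnn_mod
from . import svm as svm_mod
from .evaluation import aggregate_metrics, compute_metrics
from .fusion import weighted_average_sweep
from .partitions import PartitionConfig, PartitionPlan, build_nested_partitions
from .saliency import (
    SaliencyMap,
    deep_shap,
    gradcampp,
    mean_performing_repeat,
    rectify_and_normalize,
)
from .subtyping import ConsensusConfig, run_consensus
from .synthetic import Motif, SyntheticCohortConfig, cohort_table, generate_cohort
from .volumes import MorphometryVolume, load_nifti, scale_minmax

log = logging.getLogger("morphsev")


@dataclass
class ExperimentConfig:
    """Complete description of one experiment run."""

    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    cohort_dir: str | None = None  # real-data mode: NIfTI + cohort.csv
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    cnn_blocks: tuple[tuple[int, int], ...] = ((1, 8), (1, 16))
    cnn_dropout: float = 0.6
    cnn_l2: float = 0.001
    cnn_lr0: float = 0.01
    cnn_epochs: int = 150
    cnn_patience: int = 60
    svm_variants: tuple[str, ...] = ("linear", "rbf")
    svm_search_draws: int = 20
    weight_grid_points: int = 101
    saliency_backgrounds: int = 8
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    run_subtyping: bool = False
    out_dir: str = "morphsev_out"
    seed: int = 0

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_to_jsonable(asdict(self)), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_jsonable(asdict(self))))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "motif_catalog" in c:
                c["motif_catalog"] = tuple(
                    Motif(**m) if isinstance(m, dict) else m
                    for m in c["motif_catalog"]
                )
            for key in ("grid_shape", "lesion_volume_range", "outcome_coefficients"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = SyntheticCohortConfig(**c)
        if "partition" in d and isinstance(d["partition"], dict):
            d["partition"] = PartitionConfig(**d["partition"])
        if "consensus" in d and isinstance(d["consensus"], dict):
            cc = dict(d["consensus"])
            for key in ("k_range", "pac_bounds"):
                if key in cc:
                    cc[key] = tuple(cc[key])
            d["consensus"] = ConsensusConfig(**cc)
        if "cnn_blocks" in d:
            d["cnn_blocks"] = tuple(tuple(b) for b in d["cnn_blocks"])
        if "svm_variants" in d:
            d["svm_variants"] = tuple(d["svm_variants"])
        return cls(**d)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    plan_hash: str
    metrics: dict[str, pd.DataFrame]  # per model: one row per repeat
    summary: pd.DataFrame
    saliency_repeat: int
    out_dir: Path


# ---------------------------------------------------------------------------
# stages


def stage_cohort(cfg: ExperimentConfig):
    """Synthesize or load the cohort; returns (scaled stack, labels, table,
    lesion masks)."""
    if cfg.cohort_dir is not None:
        table = pd.read_csv(Path(cfg.cohort_dir) / "cohort.csv")
        vols = [
            load_nifti(str(Path(cfg.cohort_dir) / f"{sid}.nii"))
            for sid in table["subject_id"]
        ]
        scaled = np.stack([scale_minmax(v).scaled for v in vols])
        lesions = np.stack([v.grid == 4 for v in vols])
    else:
        subjects = generate_cohort(cfg.cohort)
        table = cohort_table(subjects)
        scaled = np.stack([scale_minmax(s.volume).scaled for s in subjects])
        lesions = np.stack([s.lesion_mask for s in subjects])
    y = (table["label2"] == "severe").to_numpy().astype(int)
    return scaled, y, table, lesions


def stage_plan(cfg: ExperimentConfig, table: pd.DataFrame) -> PartitionPlan:
    return build_nested_partitions(table["category4"].to_numpy(), cfg.partition)


def run_cnn_over_plan(
    cfg: ExperimentConfig, x: np.ndarray, y: np.ndarray, plan: PartitionPlan
) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Train/test the CNN on every outer fold of every repeat.

    Returns per-repeat metrics and out-of-fold severe probabilities of shape
    (n_repeats, n_subjects).  Models are not retained here; any repeat's
    models are reproducible via :func:`train_cnn_repeat`.
    """
    R = plan.config.n_repeats
    proba = np.zeros((R, len(y)))
    rows = []
    for r in range(R):
        models = train_cnn_repeat(cfg, x, y, plan, r)
        for f, model in enumerate(models):
            _, test_ids = plan.outer_split(r, f)
            proba[r, test_ids] = cnn_mod.predict_proba(model, x[test_ids])[:, 1]
        rows.append(
            {"repeat": r, **compute_metrics(y, (proba[r] >= 0.5).astype(int))}
        )
        log.info("cnn repeat %d f1=%.3f", r, rows[-1]["f1"])
    return pd.DataFrame(rows), proba, []


def train_cnn_repeat(
    cfg: ExperimentConfig,
    x: np.ndarray,
    y: np.ndarray,
    plan: PartitionPlan,
    repeat: int,
) -> list:
    """Train the CNN on every outer fold of one repeat (deterministic given
    the config, so any repeat's models can be reproduced on demand)."""
    spec = cnn_mod.ArchitectureSpec(
        blocks=cfg.cnn_blocks, dropout_rate=cfg.cnn_dropout, l2=cfg.cnn_l2
    )
    shape = x.shape[1:]
    models = []
    for f in range(plan.config.n_outer):
        tr, va = plan.val_split(repeat, f)
        tcfg = cnn_mod.TrainConfig(
            lr0=cfg.cnn_lr0,
            epochs=cfg.cnn_epochs,
            early_stopping_patience=cfg.cnn_patience,
            seed=cfg.seed + 1000 * repeat + f,
        )
        model = cnn_mod.build_network(spec, shape, seed=tcfg.seed)
        cnn_mod.train_cnn(
            model, x[tr][:, None], y[tr], x[va][:, None], y[va], tcfg
        )
        models.append(model)
    return models


def run_svm_over_plan(
    cfg: ExperimentConfig,
    table: np.ndarray,
    y: np.ndarray,
    plan: PartitionPlan,
    base: svm_mod.SVMConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tune (inner folds) and test (outer folds) one SVM variant on the plan."""
    R, O = plan.config.n_repeats, plan.config.n_outer
    proba = np.zeros((R, len(y)))
    rows = []
    for r in range(R):
        for f in range(O):
            train_ids, test_ids = plan.outer_split(r, f)
            inner = [
                plan.inner_split(r, f, i) for i in range(plan.config.n_inner)
            ]
            tuned = svm_mod.tune_svm(
                table, y, inner, base, n_draws=cfg.svm_search_draws
            )
            model = svm_mod.train_svm(table[train_ids], y[train_ids], tuned)
            proba[r, test_ids] = svm_mod.predict_proba_svm(
                model, table[test_ids]
            )[:, 1]
        rows.append(
            {"repeat": r, **compute_metrics(y, (proba[r] >= 0.5).astype(int))}
        )
        log.info("svm(%s) repeat %d f1=%.3f", base.kernel, r, rows[-1]["f1"])
    return pd.DataFrame(rows), proba


def stage_saliency(
    cfg: ExperimentConfig,
    x: np.ndarray,
    y: np.ndarray,
    plan: PartitionPlan,
    models: list,
    repeat: int,
) -> list[SaliencyMap]:
    """Grad-CAM++ maps for every subject from its held-out fold's model."""
    maps = []
    for f, model in enumerate(models):
        _, test_ids = plan.outer_split(repeat, f)
        for sid in test_ids:
            pred = int(
                cnn_mod.predict_proba(model, x[sid][None])[0].argmax()
            )
            m = gradcampp(model, x[sid], pred, subject_id=str(sid))
            maps.append(rectify_and_normalize(m.grid, "gradcampp", str(sid)))
            maps[-1].predicted_class = pred
    order = np.argsort([int(m.subject_id) for m in maps])
    return [maps[i] for i in order]


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline; stages cache to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.hash(), "seed": cfg.seed}
    x, y, table, lesions = stage_cohort(cfg)
    plan = stage_plan(cfg, table)
    (out / "plan.json").write_text(plan.to_json())

    metrics: dict[str, pd.DataFrame] = {}
    cache = out / f"cache_{cfg.hash()}"
    cache.mkdir(exist_ok=True)

    cnn_metrics, cnn_proba, _ = _cached(
        cache / "cnn.pkl", lambda: run_cnn_over_plan(cfg, x, y, plan)
    )
    metrics["cnn"] = cnn_metrics

    flat = svm_mod.flatten(x)
    svm_probas = {}
    for variant in cfg.svm_variants:
        if variant in ("linear", "rbf"):
            base = svm_mod.SVMConfig(kernel=variant, seed=cfg.seed)
        elif variant in ("pca", "ica"):
            base = svm_mod.SVMConfig(
                kernel="linear", reduction=variant, seed=cfg.seed
            )
        else:
            raise ValueError(f"unknown svm variant {variant!r}")
        m, p = _cached(
            cache / f"svm_{variant}.pkl",
            lambda b=base: run_svm_over_plan(cfg, flat, y, plan, b),
        )
        metrics[f"svm_{variant}"] = m
        svm_probas[variant] = p

    # fusion: weighted average sweep on repeat-0 out-of-fold probabilities
    first_svm = next(iter(svm_probas))
    fusion_res = weighted_average_sweep(
        cnn_proba[0], svm_probas[first_svm][0], y,
        np.linspace(0, 1, cfg.weight_grid_points),
    )
    fusion_res.metrics_per_value.assign(**stamp).to_csv(
        out / "fusion_weighted_average.csv", index=False
    )

    # saliency comes from the mean-performing repeat's models (F1 closest to
    # the across-repeat mean); determinism lets us rebuild them on demand
    sal_repeat = mean_performing_repeat(cnn_metrics["f1"].to_numpy())
    sal_models = _cached(
        cache / "saliency_models.pkl",
        lambda: train_cnn_repeat(cfg, x, y, plan, sal_repeat),
    )
    maps = stage_saliency(cfg, x, y, plan, sal_models, repeat=sal_repeat)

    if cfg.run_subtyping:
        severe_ids = [i for i, m in enumerate(maps) if m.predicted_class == 1]
        if len(severe_ids) > cfg.consensus.k_range[0] + 1:
            stack = np.stack([maps[i].grid.ravel() for i in severe_ids])
            run = run_consensus(stack, cfg.consensus)
            pd.DataFrame(
                {
                    "subject": severe_ids,
                    "cluster": run.labels,
                }
            ).assign(**stamp).to_csv(out / "subtypes_severe.csv", index=False)

    for name, df in metrics.items():
        df.assign(**stamp).to_csv(out / f"metrics_{name}.csv", index=False)
    summary = pd.concat(
        {name: aggregate_metrics(df.drop(columns="repeat").to_dict("records"))
         for name, df in metrics.items()},
        names=["model", "metric"],
    )
    summary.to_csv(out / "summary.csv")
    (out / "run.json").write_text(
        json.dumps({**stamp, "plan_hash": plan.hash(),
                    "saliency_repeat": int(sal_repeat)}, indent=2)
    )
    return ExperimentResult(
        config=cfg,
        plan_hash=plan.hash(),
        metrics=metrics,
        summary=summary,
        saliency_repeat=int(sal_repeat),
        out_dir=out,
    )


def _cached(path: Path, fn):
    import joblib

    if path.exists():
        return joblib.load(path)
    result = fn()
    joblib.dump(result, path)
    return result
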