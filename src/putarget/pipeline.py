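"""End-to-end orchestration: evidence -> features -> labels -> model -> reports.

The pipeline reads (or synthesises) the three inputs — evidence records, a
development-stage table and an external gene list — builds the five-feature
matrix, assigns PU labels, constructs the balanced working set and its
train/test split, optionally benchmarks the classifier families by nested
cross-validation, fits the selected bagged model (default: the
single-hidden-layer network), evaluates it on the held-out test set, ranks
the prediction-set genes by target probability, applies the stringent
probability cut-off (default 0.9) to nominate novel targets, computes
feature importance and the inspection tree, the stage-wise analysis, and
the literature-overlap enrichment with its permutation null.

A single global seed fans out to per-stage seeds through a seed sequence,
so every stage is independently reproducible; a manifest records the
configuration hash and all derived seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import evidence_features as ef
from . import labelling_splits as ls
from .enrichment_validation import PermutationConfig, overlap_enrichment, permutation_null
from .interpretation import feature_importance, fit_inspection_tree
from .metrics_eval import evaluate_on_test, stage_association
from .model_selection import (
    METRIC_COLUMNS,
    CVConfig,
    StabilityConfig,
    benchmark,
    monte_carlo_stability,
)
from .pu_bagging import BaggingConfig, BaseLearnerSpec, fit_bagged, predict_bagged, save_model
from .synthetic_data import SyntheticConfig, write_synthetic_inputs

logger = logging.getLogger(__name__)

_STAGE_NAMES = (
    "synthetic", "features", "split", "benchmark", "fit",
    "stability", "importance", "enrichment",
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; see module docstring for the flow."""

    output_dir: str = "putarget_run"
    seed: int = 0
    # inputs: either paths to the three files, or a synthetic spec
    evidence_path: str | None = None
    evidence_format: str = "jsonl"
    stages_path: str | None = None
    literature_path: str | None = None
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    # stages
    features: ef.FeatureConfig = field(default_factory=ef.FeatureConfig)
    split: ls.SplitConfig = field(default_factory=ls.SplitConfig)
    model: BaseLearnerSpec = field(
        default_factory=lambda: BaseLearnerSpec(
            "feedforward_nn_1hidden", {"size": 5, "decay": 0.01}
        )
    )
    bagging: BaggingConfig = field(default_factory=BaggingConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    probability_threshold: float = 0.9
    universe_size: int | None = None  # default: number of genes in the matrix
    run_benchmark: bool = False
    run_stability: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must lie in (0, 1)")
        have_files = all(
            p is not None
            for p in (self.evidence_path, self.stages_path, self.literature_path)
        )
        if not have_files and self.synthetic is None:
            raise ValueError("either the three input paths or a synthetic spec is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        plain = {
            "output_dir", "seed", "evidence_path", "evidence_format", "stages_path",
            "literature_path", "probability_threshold", "universe_size",
            "run_benchmark", "run_stability",
        }
        sub = {
            "synthetic": SyntheticConfig,
            "features": ef.FeatureConfig,
            "split": ls.SplitConfig,
            "bagging": BaggingConfig,
            "cv": CVConfig,
            "stability": StabilityConfig,
            "permutation": PermutationConfig,
        }
        for key, value in raw.items():
            if key in plain:
                kwargs[key] = value
            elif key in sub:
                if key == "synthetic" and value is None:
                    kwargs[key] = None
                else:
                    if key in ("synthetic", "features") and isinstance(value, dict):
                        for tup in ("signal_features", "score_shape_target",
                                    "score_shape_background", "used_data_types",
                                    "excluded_data_types"):
                            if tup in value and isinstance(value[tup], list):
                                value[tup] = tuple(value[tup])
                    kwargs[key] = sub[key](**value)
            elif key == "model":
                kwargs[key] = BaseLearnerSpec(
                    value["family"], value.get("hyperparameters", {})
                )
            else:
                raise ValueError(f"unknown pipeline config key: {key!r}")
        return cls(**kwargs)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(c.generate_state(1)[0] % 2**31)
        for name, c in zip(_STAGE_NAMES, children)
    }


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    payload = asdict(config)
    payload.pop("output_dir", None)  # the run's identity should not depend on where it lands
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write every artefact under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "timings_s": {},
    }

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["timings_s"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    # --- inputs -----------------------------------------------------------
    with stage("synthetic"):
        if config.evidence_path is not None:
            evidence_path = Path(config.evidence_path)
            stages_path = Path(config.stages_path)
            literature_path = Path(config.literature_path)
            evidence_format = config.evidence_format
        else:
            syn = config.synthetic
            syn_cfg = SyntheticConfig(**{**syn.__dict__, "seed": seeds["synthetic"]})
            paths = write_synthetic_inputs(out / "inputs", syn_cfg)
            evidence_path = paths["evidence_jsonl"]
            stages_path = paths["stages"]
            literature_path = paths["literature"]
            evidence_format = "jsonl"

    # --- features ---------------------------------------------------------
    with stage("features"):
        records, errors = ef.read_evidence(evidence_path, fmt=evidence_format)
        matrix = ef.build_feature_matrix(records, config.features)
        ef.write_feature_matrix(matrix, out / "features.tsv")
        manifest["n_genes"] = int(len(matrix))
        manifest["n_evidence_errors"] = len(errors)

    # --- labels and partitions -------------------------------------------
    with stage("split"):
        stage_records = pd.read_csv(stages_path, sep="\t", dtype=str)
        labels = ls.assign_labels(stage_records, matrix.index)
        split_cfg = ls.SplitConfig(
            train_fraction=config.split.train_fraction,
            balanced=config.split.balanced,
            seed=seeds["split"],
        )
        partition = ls.make_working_split(labels, split_cfg)
        pd.DataFrame(
            {"label": labels["label"], "best_stage": labels["best_stage"],
             "partition": partition}
        ).to_csv(out / "partitions.tsv", sep="\t")
        manifest["partition_counts"] = ls.partition_counts(partition)

        is_train = partition == "train"
        is_test = partition == "test"
        is_pred = partition == "prediction"
        X_train, y_train = matrix[is_train], labels.loc[is_train, "label"].to_numpy()
        X_test, y_test = matrix[is_test], labels.loc[is_test, "label"].to_numpy()
        X_pred = matrix[is_pred]

    # --- benchmark (optional) --------------------------------------------
    if config.run_benchmark:
        with stage("benchmark"):
            specs = [
                BaseLearnerSpec("random_forest"),
                BaseLearnerSpec("feedforward_nn_1hidden"),
                BaseLearnerSpec("svm_rbf"),
                BaseLearnerSpec("gbm_adaboost_exponential"),
            ]
            cv_cfg = CVConfig(
                k_outer=config.cv.k_outer, k_inner=config.cv.k_inner,
                tuning_grid=config.cv.tuning_grid,
                tuning_measure=config.cv.tuning_measure, seed=seeds["benchmark"],
            )
            table, results = benchmark(specs, X_train, y_train, cv_cfg, config.bagging)
            table.round(3).to_csv(out / "benchmark.tsv", sep="\t")
            with open(out / "benchmark_confusions.txt", "w") as fh:
                for family, res in results.items():
                    fh.write(f"# {family} (pooled over outer folds)\n")
                    fh.write(res.pooled_confusion.as_table().to_string() + "\n\n")

    # --- fit, test, predict ----------------------------------------------
    with stage("fit"):
        bag_cfg = BaggingConfig(
            n_bags=config.bagging.n_bags, aggregate=config.bagging.aggregate,
            seed=seeds["fit"],
        )
        model = fit_bagged(config.model, X_train, y_train, bag_cfg)
        save_model(model, out / "model.pkl")

        report, cm = evaluate_on_test(
            model, X_test, y_test, train_ids=X_train.index
        )
        with open(out / "test_metrics.json", "w") as fh:
            json.dump(report.rounded(3), fh, indent=2)
        with open(out / "test_confusion.txt", "w") as fh:
            fh.write(cm.as_table().to_string() + "\n")

        pred_class, pred_prob = predict_bagged(
            model, X_pred, threshold=config.probability_threshold
        )
        predictions = (
            pd.DataFrame(
                {
                    "gene": X_pred.index,
                    "predicted_class": pred_class,
                    "probability_target": pred_prob,
                    "probability_non_target": 1.0 - pred_prob,
                }
            )
            .sort_values("probability_target", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )
        predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
        novel = predictions.loc[predictions["predicted_class"] == 1, "gene"]
        manifest["n_novel_targets"] = int(len(novel))

        # stage-wise analysis over the labelled (working-set) genes
        working = is_train | is_test
        labelled = working & (labels["label"] == 1) & labels["best_stage"].notna()
        if labelled.sum() >= 2 and labels.loc[labelled, "best_stage"].nunique() >= 2:
            wc, wp = predict_bagged(model, matrix[labelled], threshold=0.5)
            assoc = stage_association(
                correct=(wc == 1), stages=labels.loc[labelled, "best_stage"]
            )
            assoc.to_csv(out / "stage_association.tsv", sep="\t")

    # --- stability (optional) --------------------------------------------
    if config.run_stability:
        with stage("stability"):
            stab_cfg = StabilityConfig(
                n_iterations=config.stability.n_iterations, seed=seeds["stability"]
            )
            working_X = pd.concat([X_train, X_test])
            working_y = np.concatenate([y_train, y_test])
            stab = monte_carlo_stability(
                config.model, working_X, working_y, X_pred, stab_cfg,
                config.split, config.bagging,
            )
            stab.to_csv(out / "stability.tsv", sep="\t")
            manifest["stability_summary"] = {
                "mean_accuracy": float(stab["accuracy"].mean()),
                "sd_accuracy": float(stab["accuracy"].std()),
                "mean_auc": float(stab["auc"].mean()),
                "sd_auc": float(stab["auc"].std()),
            }

    # --- interpretation ---------------------------------------------------
    with stage("importance"):
        working = is_train | is_test
        Xw, yw = matrix[working], labels.loc[working, "label"].to_numpy()
        imp = pd.DataFrame(
            {
                "chi_squared": feature_importance(Xw, yw, method="chisq")["value"],
                "information_gain_bits": feature_importance(Xw, yw, method="infogain")["value"],
            }
        )
        imp.to_csv(out / "importance.tsv", sep="\t")
        tree = fit_inspection_tree(X_train, y_train, seed=seeds["importance"])
        (out / "tree.txt").write_text(tree.render() + "\n")
        with open(out / "tree.json", "w") as fh:
            json.dump(tree.to_records(), fh, indent=2)

    # --- external validation ---------------------------------------------
    with stage("enrichment"):
        literature = set(
            pd.read_csv(literature_path, sep="\t", dtype=str)["gene"].dropna()
        )
        working_genes = set(matrix.index[is_train | is_test])
        universe = config.universe_size or len(matrix)
        enrich = overlap_enrichment(
            predicted=set(novel), reference=literature,
            exclusions=working_genes, universe_size=universe,
        )
        null = permutation_null(
            predicted_size=len(set(novel) - working_genes),
            reference_size=len(literature - working_genes),
            universe_size=universe,
            config=PermutationConfig(
                n_permutations=config.permutation.n_permutations,
                seed=seeds["enrichment"],
            ),
        )
        payload = {
            "observed": enrich.to_dict(),
            "permutation_null": {
                "n_permutations": int(len(null)),
                "mean_odds_ratio": float(null["odds_ratio"].mean()),
                "sd_odds_ratio": float(null["odds_ratio"].std()),
                "mean_p_value": float(null["p_value"].mean()),
                "sd_p_value": float(null["p_value"].std()),
            },
        }
        with open(out / "enrichment.json", "w") as fh:
            json.dump(payload, fh, indent=2)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
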