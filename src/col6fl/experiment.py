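"""End-to-end experiment: single-node vs federated vs pooled comparison.

One trial generates the synthetic two-site dataset, holds out whole
patients until the per-site test counts are met, augments the training
partitions only, extracts frozen features, then trains four arms under an
identical R x E epoch budget: one single-node baseline per site, the
FedAvg federation of all sites, and a pooled-centralized upper reference.
All arms are scored on the same held-out test set, both on the four-class
task and after collapsing to control-vs-pathogenic.  A comparison repeats
this over seeded trials and reports mean +/- sample-STD macro-F1 and
accuracy per arm.

The whole comparison is a pure function of (config, root seed): trial
seeds are derived through ``SeedSequence`` spawn keys.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, augment_training_set, resize_normalize
from .features import ModelParams, extract_feature_matrix, extract_features, predict
from .federated import FedAvgConfig, Node, run_federated, run_single_node
from .metrics import (
    ConfusionMatrix,
    EvaluationReport,
    binarize,
    evaluate_predictions,
    summarize_trials,
)
from .scenario import Scenario, default_scenario
from .simulate import generate_federated_dataset, split_patient_level

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "run_trial",
    "run_comparison",
    "write_report",
    "read_report",
]

log = logging.getLogger("col6fl")

FEDERATED_ARM = "federated"
POOLED_ARM = "pooled_centralized"


@dataclass
class ExperimentConfig:
    scenario: Scenario = field(default_factory=default_scenario)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    backend_id: str = "texture_descriptor"
    fedavg: FedAvgConfig = field(default_factory=FedAvgConfig)
    n_trials: int = 10
    seed: int = 0
    include_pooled: bool = True
    out_dir: str | None = None  # used by the CLI's compare subcommand

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.scenario.test_counts:
            raise ValueError("scenario must define per-site test_counts")

    @property
    def arm_names(self) -> list[str]:
        arms = [f"single_node_{s.site_id}" for s in self.scenario.sites]
        arms.append(FEDERATED_ARM)
        if self.include_pooled:
            arms.append(POOLED_ARM)
        return arms


@dataclass
class ComparisonReport:
    """Per-arm trial metrics (four-class and binary) plus summaries."""

    arms: list[str]
    n_trials: int
    seed: int
    reports: dict[str, list[EvaluationReport]]
    binary_reports: dict[str, list[EvaluationReport]]
    summary: dict[str, dict]
    binary_summary: dict[str, dict]

    def pooled_confusion(self, arm: str) -> ConfusionMatrix:
        """Element-wise sum of an arm's per-trial confusion matrices."""
        mats = [r.confusion for r in self.reports[arm]]
        return ConfusionMatrix(
            sum(m.counts for m in mats), mats[0].class_order
        )

    def to_dict(self) -> dict:
        return {
            "arms": self.arms,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "reports": {a: [r.to_dict() for r in rs] for a, rs in self.reports.items()},
            "binary_reports": {
                a: [r.to_dict() for r in rs] for a, rs in self.binary_reports.items()
            },
            "summary": self.summary,
            "binary_summary": self.binary_summary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            arms=list(d["arms"]),
            n_trials=int(d["n_trials"]),
            seed=int(d["seed"]),
            reports={
                a: [EvaluationReport.from_dict(r) for r in rs]
                for a, rs in d["reports"].items()
            },
            binary_reports={
                a: [EvaluationReport.from_dict(r) for r in rs]
                for a, rs in d["binary_reports"].items()
            },
            summary=d["summary"],
            binary_summary=d["binary_summary"],
        )


def _trial_seed(root: int, trial: int, slot: int) -> int:
    ss = np.random.SeedSequence(root, spawn_key=(trial, slot))
    return int(ss.generate_state(1)[0] % (2**31))


def run_trial(cfg: ExperimentConfig, trial: int) -> dict[str, dict[str, EvaluationReport]]:
    """One seeded trial; returns {arm: {"four_class": report, "binary": report}}."""
    gen_seed = _trial_seed(cfg.seed, trial, 0)
    split_seed = _trial_seed(cfg.seed, trial, 1)
    train_seed = _trial_seed(cfg.seed, trial, 2)

    log.info("trial %d: generating dataset (seed %d)", trial, gen_seed)
    dataset = generate_federated_dataset(cfg.scenario, gen_seed)
    train, test = split_patient_level(dataset, cfg.scenario.test_counts, split_seed)

    # per-site training nodes: resize/normalize -> augment -> features,
    # streamed image by image so augmented frames never accumulate
    nodes: list[Node] = []
    for site in cfg.scenario.sites:
        rows, y = [], []
        for im in train.images(site.site_id):
            base = type(im)(
                pixels=resize_normalize(im.pixels, cfg.augmentation.target_size),
                label=im.label, patient_id=im.patient_id,
                site_id=im.site_id, partition=im.partition,
            )
            for variant in augment_training_set([base], cfg.augmentation):
                rows.append(extract_features(variant.pixels, cfg.backend_id).values)
                y.append(variant.label.index - 1)
        nodes.append(Node(site.site_id, np.stack(rows), np.array(y)))

    # shared test set: resize/normalize only (no augmentation)
    test_imgs = test.images()
    X_test = extract_feature_matrix(
        [resize_normalize(im.pixels, cfg.augmentation.target_size) for im in test_imgs],
        cfg.backend_id,
    )
    y_test = np.array([im.label.index for im in test_imgs])  # 1-based

    d = nodes[0].features.shape[1]
    params0 = ModelParams.zeros(d, 4)
    fed_cfg = FedAvgConfig(
        rounds=cfg.fedavg.rounds,
        local_epochs=cfg.fedavg.local_epochs,
        batch_size=cfg.fedavg.batch_size,
        learning_rate=cfg.fedavg.learning_rate,
        l2=cfg.fedavg.l2,
        weighting=cfg.fedavg.weighting,
        seed=train_seed,
    )

    trained: dict[str, ModelParams] = {}
    for node in nodes:
        trained[f"single_node_{node.site_id}"], _ = run_single_node(
            node, fed_cfg, params0
        )
    trained[FEDERATED_ARM], _ = run_federated(nodes, fed_cfg, params0)
    if cfg.include_pooled:
        pooled = Node(
            "pooled",
            np.vstack([n.features for n in nodes]),
            np.concatenate([n.labels for n in nodes]),
        )
        trained[POOLED_ARM], _ = run_single_node(pooled, fed_cfg, params0)

    out: dict[str, dict[str, EvaluationReport]] = {}
    class_order = ["control", "glycine_substitution",
                   "pseudoexon_insertion", "exon_skipping"]
    for arm, params in trained.items():
        probs = predict(params, X_test)
        y_pred = probs.argmax(axis=1) + 1  # back to 1-based
        four = evaluate_predictions(y_test, y_pred, k=4, class_order=class_order)
        binary = evaluate_predictions(
            binarize(y_test) + 1, binarize(y_pred) + 1, k=2,
            class_order=["control", "pathogenic"],
        )
        out[arm] = {"four_class": four, "binary": binary}
    return out


def run_comparison(cfg: ExperimentConfig | None = None) -> ComparisonReport:
    """Run all arms over ``cfg.n_trials`` seeded trials and summarize."""
    cfg = cfg or ExperimentConfig()
    reports: dict[str, list[EvaluationReport]] = {a: [] for a in cfg.arm_names}
    binary_reports: dict[str, list[EvaluationReport]] = {a: [] for a in cfg.arm_names}
    for t in range(cfg.n_trials):
        try:
            trial_out = run_trial(cfg, t)
        except Exception as exc:
            raise RuntimeError(f"trial {t} failed: {exc}") from exc
        for arm in cfg.arm_names:
            reports[arm].append(trial_out[arm]["four_class"])
            binary_reports[arm].append(trial_out[arm]["binary"])
        log.info(
            "trial %d macro-F1: %s", t,
            {a: round(reports[a][-1].macro_f1, 3) for a in cfg.arm_names},
        )
    with_std = cfg.n_trials >= 2
    summary = {a: summarize_trials(reports[a], with_std) for a in cfg.arm_names}
    binary_summary = {
        a: summarize_trials(binary_reports[a], with_std) for a in cfg.arm_names
    }
    return ComparisonReport(
        arms=cfg.arm_names,
        n_trials=cfg.n_trials,
        seed=cfg.seed,
        reports=reports,
        binary_reports=binary_reports,
        summary=summary,
        binary_summary=binary_summary,
    )


def write_report(report: ComparisonReport, out_dir: str | Path) -> dict[str, Path]:
    """Write comparison.json (full precision), comparison.csv (rounded to
    three decimals), per-arm summed confusion CSVs, and a short run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["json"] = out / "comparison.json"
    paths["json"].write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))

    rows = []
    for arm in report.arms:
        s = report.summary[arm]
        rows.append(
            {
                "arm": arm,
                "mean_f1": round(s["macro_f1_mean"], 3),
                "std_f1": round(s.get("macro_f1_std", 0.0), 3),
                "mean_accuracy": round(s["accuracy_mean"], 3),
                "std_accuracy": round(s.get("accuracy_std", 0.0), 3),
            }
        )
    paths["csv"] = out / "comparison.csv"
    pd.DataFrame(rows).to_csv(paths["csv"], index=False)

    for arm in report.arms:
        cm = report.pooled_confusion(arm)
        p = out / f"confusion_{arm}.csv"
        pd.DataFrame(cm.counts, index=cm.class_order, columns=cm.class_order).to_csv(p)
        paths[f"confusion_{arm}"] = p

    lines = [f"trials={report.n_trials} seed={report.seed}"]
    for arm in report.arms:
        s = report.summary[arm]
        lines.append(
            f"{arm}: macro_f1 {s['macro_f1_mean']:.3f} "
            f"accuracy {s['accuracy_mean']:.3f}"
        )
    paths["log"] = out / "run.log"
    paths["log"].write_text("\n".join(lines) + "\n")
    return paths


def read_report(out_dir: str | Path) -> ComparisonReport:
    """Reload the full-precision JSON report written by :func:`write_report`."""
    return ComparisonReport.from_dict(
        json.loads((Path(out_dir) / "comparison.json").read_text())
    )
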