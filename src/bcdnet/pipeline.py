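"""End-to-end orchestration: data -> features -> phase 1 -> phase 2 -> report.

A run proceeds through five seeded stages:

1. **data** — generate phantoms (or load a class-per-folder image tree)
   and split train/test stratified;
2. **features** — preprocess images and export backbone features;
3. **phase 1** — metaheuristic search over the feature-gain vector;
4. **phase 2** — metaheuristic search over the four classifier
   hyperparameters, then final training of both branches on the full
   training set;
5. **evaluate** — averaged-branch predictions on the held-out test set,
   the full metric report (macro and per-class), ROC for the malignant
   class, and persisted artifacts (JSON report, CSVs, PNG plots).

Every stage derives its seed from the run seed, so a run is reproducible
end to end; the written report is checked for self-consistency against
the persisted predictions at write time.

Two profiles bundle defaults: ``paper`` (population 10, 50 iterations,
224x224 full backbone) and ``desk`` (population 4, 5 iterations, 64x64
tiny backbone) — the scale used by the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from bcdnet import classifier, features, metrics, optimizers, synthetic_data

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunReport",
    "desk_config",
    "paper_config",
    "run_bcdnet",
    "compare_optimizers",
    "sphere",
]

#: headline positive class for binary metrics
POSITIVE_CLASS = "malignant"


def sphere(x: np.ndarray) -> float:
    """The 6-D benchmark objective used by the comparison harness."""
    return float(np.sum(np.square(x)))


@dataclass
class RunConfig:
    phantoms: synthetic_data.PhantomSpec | None = None
    data_dir: str | None = None
    backbone: features.BackboneConfig = field(default_factory=features.BackboneConfig)
    phase1_optimizer: optimizers.OptimizerConfig = field(
        default_factory=optimizers.OptimizerConfig
    )
    phase2_optimizer: optimizers.OptimizerConfig = field(
        default_factory=optimizers.OptimizerConfig
    )
    classifier_base: classifier.AHDNAMConfig = field(
        default_factory=classifier.AHDNAMConfig
    )
    n_gain_groups: int = 6
    test_fraction: float = 0.25
    out_dir: str = "bcdnet_run"
    seed: int = 0
    method: str = "rpaosm-eso"
    write_plots: bool = True

    def reseed(self, seed: int) -> "RunConfig":
        """Propagate one run seed into every nested seeded config."""
        return dataclasses.replace(
            self,
            seed=seed,
            phantoms=(
                dataclasses.replace(self.phantoms, seed=seed)
                if self.phantoms is not None else None
            ),
            backbone=dataclasses.replace(self.backbone, seed=seed),
            phase1_optimizer=dataclasses.replace(self.phase1_optimizer, seed=seed),
            phase2_optimizer=dataclasses.replace(self.phase2_optimizer, seed=seed + 1),
            classifier_base=dataclasses.replace(self.classifier_base, seed=seed),
        )


def desk_config(seed: int = 0, out_dir: str = "bcdnet_run") -> RunConfig:
    """Desk-scale profile: 64x64 phantoms, tiny backbone, budget 4x5."""
    cfg = RunConfig(
        phantoms=synthetic_data.PhantomSpec(n_per_class=(27, 27, 26), image_size=64),
        backbone=features.BackboneConfig(tiny_mode=True),
        phase1_optimizer=optimizers.OptimizerConfig(pop_size=4, max_iter=5),
        phase2_optimizer=optimizers.OptimizerConfig(pop_size=4, max_iter=5),
        out_dir=out_dir,
    )
    return cfg.reseed(seed)


def paper_config(seed: int = 0, out_dir: str = "bcdnet_run") -> RunConfig:
    """Full-scale profile: 224x224, full backbone, population 10, 50 iters."""
    cfg = RunConfig(
        phantoms=synthetic_data.PhantomSpec(n_per_class=(50, 50, 50), image_size=224),
        backbone=features.BackboneConfig(tiny_mode=False),
        phase1_optimizer=optimizers.OptimizerConfig(pop_size=10, max_iter=50),
        phase2_optimizer=optimizers.OptimizerConfig(pop_size=10, max_iter=50),
        out_dir=out_dir,
    )
    return cfg.reseed(seed)


@dataclass
class RunReport:
    config: RunConfig
    class_names: tuple[str, ...]
    test_accuracy: float
    macro: metrics.MetricReport
    headline: metrics.MetricReport
    per_class: dict
    confusion_matrix: np.ndarray
    roc_auc: float
    gains: np.ndarray
    best_classifier: classifier.AHDNAMConfig
    trace_phase1: np.ndarray
    trace_phase2: np.ndarray
    phase2_initial_median: float
    phase2_final: float
    wall_clock_s: float
    seed: int

    def headline_dict(self) -> dict:
        return {
            "test_accuracy": self.test_accuracy,
            "macro_accuracy": self.macro.accuracy,
            "mcc": self.headline.mcc,
            "sensitivity": self.headline.sensitivity,
            "fnr": self.headline.fnr,
            "roc_auc": self.roc_auc,
            "phase2_objective": self.phase2_final,
        }


def _confusion_matrix(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        m[t, p] += 1
    return m


def _write_csv(path: Path, header: list[str], rows) -> None:
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _save_plots(out: Path, report: RunReport, roc_pts: np.ndarray) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_pts[:, 0], roc_pts[:, 1], marker=".", label=f"AUC={report.roc_auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate"); ax.set_ylabel("true positive rate")
    ax.set_title(f"ROC ({POSITIVE_CLASS} vs rest)"); ax.legend()
    fig.tight_layout(); fig.savefig(out / "roc.png", dpi=100); plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(report.confusion_matrix, cmap="Blues")
    for i in range(report.confusion_matrix.shape[0]):
        for j in range(report.confusion_matrix.shape[1]):
            ax.text(j, i, str(report.confusion_matrix[i, j]), ha="center", va="center")
    ax.set_xticks(range(len(report.class_names)), report.class_names, rotation=45)
    ax.set_yticks(range(len(report.class_names)), report.class_names)
    ax.set_xlabel("predicted"); ax.set_ylabel("true")
    fig.tight_layout(); fig.savefig(out / "confusion.png", dpi=100); plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(np.arange(1, report.trace_phase1.size + 1), report.trace_phase1,
            label="phase 1 (gains)")
    ax.plot(np.arange(1, report.trace_phase2.size + 1), report.trace_phase2,
            label="phase 2 (hyperparameters)")
    ax.set_xlabel("iteration"); ax.set_ylabel("best objective"); ax.legend()
    fig.tight_layout(); fig.savefig(out / "convergence.png", dpi=100); plt.close(fig)


def run_bcdnet(config: RunConfig) -> RunReport:
    """Execute the full two-phase pipeline and persist a report."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "data"
    try:
        if config.data_dir is not None:
            dataset = synthetic_data.load_busi_folder(config.data_dir)
        elif config.phantoms is not None:
            dataset = synthetic_data.generate_phantoms(config.phantoms)
        else:
            raise ValueError("config needs either phantoms or data_dir")
        train_set, test_set = synthetic_data.split_train_test(
            dataset, config.test_fraction, config.seed
        )
        if len(test_set) == 0:
            raise ValueError("empty test split")
        logger.info("stage data: %d train / %d test", len(train_set), len(test_set))

        stage = "features"
        size = config.backbone.effective_input_size
        backbone = features.VGGBackbone(config.backbone)
        f_train = features.extract_deep_features(
            features.preprocess_images(list(train_set.images), size, train_set.labels),
            backbone=backbone,
        )
        f_test = features.extract_deep_features(
            features.preprocess_images(list(test_set.images), size, test_set.labels),
            backbone=backbone,
        )
        features.save_features(f_train, out / "features_train", backbone)
        features.save_features(f_test, out / "features_test", backbone)

        stage = "phase1"
        gains, res1 = features.optimize_feature_gains(
            f_train,
            optimizer_config=config.phase1_optimizer,
            n_groups=config.n_gain_groups,
            method=config.method,
        )
        logger.info("stage phase1: best objective %.4f gains %s",
                    res1.best_fitness, np.round(gains.gains, 3))
        g_train = features.apply_feature_gains(f_train, gains)
        g_test = features.apply_feature_gains(
            features.FeatureMatrix(f_test.values, f_test.labels),
            features.FeatureGainVector(gains.gains, f_test.width),
        )

        stage = "phase2"
        best_cfg, res2 = classifier.optimize_hyperparams(
            g_train.values, g_train.labels,
            config.phase2_optimizer, config.classifier_base, method=config.method,
        )
        # median objective of the initial population, for the improvement check
        init_state = optimizers.init_population(
            lambda p: classifier.phase2_objective(
                p, g_train.values, g_train.labels,
                base_config=config.classifier_base,
                split_seed=config.phase2_optimizer.seed,
            ),
            classifier.hyperparam_search_space(),
            config.phase2_optimizer,
        )
        phase2_initial_median = float(
            np.median([c.fitness for c in init_state.population])
        )
        logger.info("stage phase2: best objective %.4f config %s",
                    res2.best_fitness, best_cfg)

        stage = "train"
        dtcn = classifier.train_branch(g_train.values, g_train.labels, "dtcn", best_cfg)
        cnn = classifier.train_branch(g_train.values, g_train.labels, "cnn", best_cfg)
        dtcn.save(out / "branch_dtcn")
        cnn.save(out / "branch_cnn")

        stage = "evaluate"
        scores = classifier.predict_ahdnam(g_test.values, dtcn, cnn)
        true = np.asarray(test_set.labels)
        pred = scores.labels
        class_names = test_set.class_names
        n_classes = len(class_names)
        test_accuracy = metrics.multiclass_accuracy(true, pred)
        macro = metrics.macro_metrics(true, pred, classes=range(n_classes))
        pos_id = (
            class_names.index(POSITIVE_CLASS) if POSITIVE_CLASS in class_names else 1
        )
        headline = metrics.classification_metrics(
            metrics.confusion_from_labels(true, pred, pos_id)
        )
        per_class = {
            name: metrics.classification_metrics(
                metrics.confusion_from_labels(true, pred, cid)
            )
            for cid, name in enumerate(class_names)
        }
        conf = _confusion_matrix(true, pred, n_classes)
        roc_pts, auc = metrics.roc_points(
            scores.averaged[:, pos_id], true, positive_class=pos_id
        )

        report = RunReport(
            config=config,
            class_names=class_names,
            test_accuracy=test_accuracy,
            macro=macro,
            headline=headline,
            per_class=per_class,
            confusion_matrix=conf,
            roc_auc=auc,
            gains=gains.gains,
            best_classifier=best_cfg,
            trace_phase1=res1.trace,
            trace_phase2=res2.trace,
            phase2_initial_median=phase2_initial_median,
            phase2_final=res2.best_fitness,
            wall_clock_s=time.time() - t_start,
            seed=config.seed,
        )

        stage = "persist"
        np.save(out / "predictions.npy", scores.averaged)
        _write_csv(
            out / "predictions.csv",
            ["true"] + [f"p_{c}" for c in class_names] + ["pred"],
            [[t] + list(row) + [p] for t, row, p in zip(true, scores.averaged, pred)],
        )
        # self-consistency: the report's metrics must be recomputable from
        # the persisted predictions
        re_pred = np.argmax(np.load(out / "predictions.npy"), axis=1)
        if not np.array_equal(re_pred, pred):
            raise RuntimeError("report inconsistent with persisted predictions")
        assert abs(metrics.multiclass_accuracy(true, re_pred) - test_accuracy) < 1e-12

        _write_csv(out / "metrics.csv",
                   ["metric", "macro", POSITIVE_CLASS],
                   [[k, getattr(macro, k), getattr(headline, k)]
                    for k in ("accuracy", "sensitivity", "specificity", "precision",
                              "npv", "f1", "mcc", "fnr", "fpr", "fdr", "forate")])
        _write_csv(out / "confusion.csv", ["true\\pred"] + list(class_names),
                   [[class_names[i]] + list(conf[i]) for i in range(n_classes)])
        _write_csv(out / "roc.csv", ["fpr", "tpr"], roc_pts)
        _write_csv(out / "trace_phase1.csv", ["iteration", "best_objective"],
                   enumerate(res1.trace, start=1))
        _write_csv(out / "trace_phase2.csv", ["iteration", "best_objective"],
                   enumerate(res2.trace, start=1))
        (out / "report.json").write_text(json.dumps({
            "seed": config.seed,
            "class_names": list(class_names),
            "test_accuracy": test_accuracy,
            "headline": report.headline.as_dict(),
            "macro": macro.as_dict(),
            "roc_auc": auc,
            "gains": gains.gains.tolist(),
            "best_classifier": {
                "dtcn_hidden": best_cfg.dtcn_hidden,
                "dtcn_steps_per_epoch": best_cfg.dtcn_steps_per_epoch,
                "cnn_hidden": best_cfg.cnn_hidden,
                "cnn_steps_per_epoch": best_cfg.cnn_steps_per_epoch,
            },
            "phase1_trace": res1.trace.tolist(),
            "phase2_trace": res2.trace.tolist(),
            "phase2_initial_median": phase2_initial_median,
            "wall_clock_s": report.wall_clock_s,
        }, indent=2))
        if config.write_plots:
            _save_plots(out, report, roc_pts)
        return report
    except Exception:
        logger.exception("pipeline aborted in stage %r (partial artifacts in %s)",
                         stage, out)
        raise


def compare_optimizers(
    optimizer_config: optimizers.OptimizerConfig,
    methods: tuple[str, ...] = ("aosma", "esoa", "rpaosm-eso"),
    n_runs: int = 5,
    objective=sphere,
    space: optimizers.SearchSpace | None = None,
    out_path: str | Path | None = None,
) -> dict[str, optimizers.RunStats]:
    """Best/worst/mean/median/std of final fitness per optimizer.

    Every optimizer sees the same objective and the same seed list, so
    differences are attributable to the update rules alone.
    """
    for m in methods:
        if m not in optimizers.METHODS:
            raise ValueError(f"unknown optimizer {m!r}")
    space = space or optimizers.SearchSpace(
        lower=-5.0 * np.ones(6), upper=5.0 * np.ones(6)
    )
    seeds = [optimizer_config.seed + k for k in range(n_runs)]
    table = {
        m: optimizers.multi_run_stats(
            objective, space, optimizer_config, n_runs, method=m, seeds=seeds
        )
        for m in methods
    }
    if out_path is not None:
        rows = [[m, s.best, s.worst, s.mean, s.median, s.std]
                for m, s in table.items()]
        _write_csv(Path(out_path), ["optimizer", "best", "worst", "mean", "median", "std"],
                   rows)
    return table
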