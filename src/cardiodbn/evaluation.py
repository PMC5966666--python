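"""Repeated-run evaluation protocol and depth sweeps.

One evaluation run is the full pipeline: stratified 70/30 split, fit
the preprocessor on the training partition, grow and pretrain the DBN,
fine-tune with the training labels, and score accuracy on the held-out
partition.  The repeated protocol performs ``n_runs`` independent runs
-- fresh split and fresh weight initialization each time, seeded from a
single master seed -- and reports the per-run accuracies with their
mean and population variance, mirroring how stability of stochastic
training is conventionally summarized for this task (30 independent
experiments).

The depth sweep disables the autonomous stopping rule and forces a
range of depths, reporting the top layer's reconstruction error, the
test accuracy and the wall-clock time per depth.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import RawRecord, split_train_test
from .dbn import DBNModel, GrowthConfig, finetune, grow_pretrain, predict_label
from .preprocessing import FeatureSchema, Preprocessor

logger = logging.getLogger(__name__)


def accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Percent agreement between binary prediction and truth."""
    predicted = np.asarray(predicted).ravel()
    actual = np.asarray(actual).ravel()
    if predicted.size == 0 or predicted.size != actual.size:
        raise ValueError("prediction and truth must be non-empty, equal length")
    return float(100.0 * np.mean(predicted == actual))


@dataclass
class RunReport:
    """Outcome of the repeated-run protocol.

    Mean and variance are derivable from ``accuracies``; the variance
    convention is the population variance (divide by n_runs).
    """

    accuracies: list[float]
    depths: list[int]
    architectures: list[str]
    master_seed: int

    @property
    def n_runs(self) -> int:
        return len(self.accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def variance(self) -> float:
        return float(np.var(self.accuracies))  # population convention

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "mean_accuracy": self.mean_accuracy,
            "variance": self.variance,
            "accuracies": self.accuracies,
            "depths": self.depths,
            "architectures": self.architectures,
            "master_seed": self.master_seed,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_once(
    records: list[RawRecord],
    config: GrowthConfig,
    split_seed: int,
    init_seed: int,
    schema: list[FeatureSchema] | None = None,
    train_fraction: float = 0.7,
) -> tuple[float, DBNModel]:
    """One full pipeline execution; returns test accuracy and the model."""
    train, test = split_train_test(records, train_fraction, seed=split_seed)
    prep = Preprocessor(schema)
    X_train, y_train = prep.fit_transform(train)
    X_test, y_test = prep.transform(test)

    cfg = replace(config, rbm_config=replace(config.rbm_config, seed=init_seed))
    model, _ = grow_pretrain(X_train, cfg)
    model = finetune(model, X_train, y_train, cfg)
    acc = accuracy(predict_label(model, X_test), y_test)
    return acc, model


def repeated_runs(
    records: list[RawRecord],
    config: GrowthConfig,
    n_runs: int = 30,
    master_seed: int = 0,
    schema: list[FeatureSchema] | None = None,
    train_fraction: float = 0.7,
) -> RunReport:
    """Independent repetitions of the full pipeline.

    Each run draws its own split seed and weight-initialization seed
    from the master seed, so both the 70/30 partition and the network
    initialization are re-randomized per run.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    children = np.random.SeedSequence(master_seed).spawn(n_runs)
    accs: list[float] = []
    depths: list[int] = []
    archs: list[str] = []
    for i, child in enumerate(children):
        split_seed, init_seed = (
            int(s % (2 ** 31)) for s in child.generate_state(2)
        )
        logger.info("run %d/%d: split_seed=%d init_seed=%d",
                    i + 1, n_runs, split_seed, init_seed)
        acc, model = run_once(
            records, config, split_seed, init_seed, schema, train_fraction
        )
        logger.info("run %d/%d: depth=%d arch=%s accuracy=%.2f%%",
                    i + 1, n_runs, model.depth, model.architecture, acc)
        accs.append(acc)
        depths.append(model.depth)
        archs.append(model.architecture)
    return RunReport(accuracies=accs, depths=depths, architectures=archs,
                     master_seed=master_seed)


def depth_sweep(
    records: list[RawRecord],
    depths: list[int],
    config: GrowthConfig,
    seed: int = 0,
    schema: list[FeatureSchema] | None = None,
    train_fraction: float = 0.7,
) -> list[dict]:
    """Fixed-depth comparison table.

    For each requested depth (feature layers including the input) the
    stack is grown to exactly depth-1 RBMs with the epsilon rule
    disabled, fine-tuned, and scored.  Rows report the final layer's
    reconstruction error, test accuracy in percent, the architecture
    string, and the wall-clock runtime (informational only --
    hardware-dependent).
    """
    if any(d < 2 for d in depths):
        raise ValueError("depths must be >= 2 (at least one RBM layer)")
    train, test = split_train_test(records, train_fraction, seed=seed)
    prep = Preprocessor(schema)
    X_train, y_train = prep.fit_transform(train)
    X_test, y_test = prep.transform(test)

    rows = []
    for depth in depths:
        t0 = time.perf_counter()
        cfg = replace(config, rbm_config=replace(config.rbm_config, seed=seed))
        model, trace = grow_pretrain(X_train, cfg, forced_layers=depth - 1)
        model = finetune(model, X_train, y_train, cfg)
        acc = accuracy(predict_label(model, X_test), y_test)
        rows.append({
            "depth": depth,
            "r_error": trace.r_errors[-1],
            "accuracy": acc,
            "architecture": model.architecture,
            "runtime_s": time.perf_counter() - t0,
        })
    return rows
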