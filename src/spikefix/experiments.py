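"""Experiment protocols: training/evaluation runs, confusion matrices,
and the precision sweep.

Two dataset backends are supported: ``synthetic`` (self-contained 12×12
digit fixtures, see :mod:`spikefix.encoding`) and ``mnist`` (IDX files on
disk, 28×28 images downscaled to 12×12 with nearest-neighbour sampling).
Every experiment trains with the teacher signal, then evaluates twice —
once on a held-out subset of the training patterns and once on unseen test
patterns — and reports a confusion matrix, overall and per-class accuracy,
and the count of silent (no-response) presentations.

The reference protocols at full scale are 5-class (classes 0–4, groups of
20 excitatory neurons, 15,000 patterns over 2 epochs, 5,000 + 5,000
evaluation) and 10-class (groups of 10, 15,000 patterns over 4 epochs,
10,000 + 10,000 evaluation); both need the MNIST IDX files and hours of
simulated time, so the desk-scale protocol used throughout the test suite
is a 3-class synthetic task (30 excitatory + 30 inhibitory neurons, 600
training presentations, 150 test samples).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .encoding import (ImageSample, read_idx, resize_nearest, synth_digits)
from .engine import CompiledNetwork, SimConfig, evaluate, train
from .network import WeightDefaults, build_digit_network

FIVE_CLASS_DIGITS = (0, 1, 2, 3, 4)   # most mutually dissimilar digits


@dataclass
class ExperimentResult:
    """Confusion matrix, accuracies and provenance of one evaluation."""

    confusion: np.ndarray
    n_no_response: int
    config_echo: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        if self.n_total == 0:
            return float("nan")     # undefined on an empty evaluation
        return float(np.trace(self.confusion)) / self.n_total

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.confusion) / row,
                            np.nan)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_accuracy": [None if np.isnan(x) else float(x)
                                   for x in self.per_class_accuracy],
            "n_no_response": self.n_no_response,
            "n_total": self.n_total,
            "config": self.config_echo,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_matrix(predictions: Sequence[int], labels: Sequence[int],
                     n_classes: int) -> np.ndarray:
    """Counts[i, j] = samples of true class i predicted as class j."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (labels, predictions), 1)
    return mat


def accuracy(matrix: np.ndarray) -> float:
    total = matrix.sum()
    if total == 0:
        return float("nan")
    return float(np.trace(matrix)) / float(total)


# ---------------------------------------------------------------------------
# Dataset loading
# ---------------------------------------------------------------------------


def load_mnist(data_dir, train: bool = True,
               classes: Optional[Sequence[int]] = None) -> list:
    """Load MNIST IDX files and downscale to 12×12 samples.

    Expects ``train-images-idx3-ubyte``/``train-labels-idx1-ubyte`` (or the
    ``t10k-`` pair) inside ``data_dir``.
    """
    stem = "train" if train else "t10k"
    imgs_path = os.path.join(data_dir, f"{stem}-images-idx3-ubyte")
    lbls_path = os.path.join(data_dir, f"{stem}-labels-idx1-ubyte")
    for p in (imgs_path, lbls_path):
        if not os.path.exists(p):
            raise FileNotFoundError(
                f"MNIST file not found: {p} — download the IDX files and "
                f"place them (uncompressed) in {data_dir}")
    images, labels = read_idx(imgs_path, lbls_path)
    keep = np.ones(len(labels), dtype=bool)
    remap = {c: c for c in range(10)}
    if classes is not None:
        keep = np.isin(labels, list(classes))
        remap = {c: i for i, c in enumerate(classes)}
    return [ImageSample(resize_nearest(img), remap[int(lab)])
            for img, lab in zip(images[keep], labels[keep])]


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


def run_experiment(dataset: str, n_classes: int, group_size: int,
                   n_train: int, epochs: int, n_eval_train: int,
                   n_eval_test: int, cfg: SimConfig,
                   noise_sd: float = 25.0,
                   data_dir: Optional[str] = None
                   ) -> tuple[ExperimentResult, ExperimentResult]:
    """Train the digit network and evaluate on train- and test-subsets.

    Returns ``(train_subset_result, test_subset_result)``.  For the
    synthetic backend the train/test pools are freshly generated with
    derived seeds; for MNIST the official train/test split is used and
    evaluation subsets are drawn with a seeded sampler.
    """
    rng = np.random.default_rng(cfg.seed)
    if dataset == "synthetic":
        per = -(-n_train // n_classes)      # ceil
        pool = synth_digits(n_classes, per, noise_sd,
                            seed=int(rng.integers(2 ** 31)))
        train_samples = pool[:n_train]
        eval_train = synth_digits(
            n_classes, max(1, -(-n_eval_train // n_classes)), noise_sd,
            seed=int(rng.integers(2 ** 31)))[:n_eval_train] \
            if n_eval_train else []
        eval_test = synth_digits(
            n_classes, max(1, -(-n_eval_test // n_classes)), noise_sd,
            seed=int(rng.integers(2 ** 31)))[:n_eval_test] \
            if n_eval_test else []
    elif dataset == "mnist":
        classes = list(FIVE_CLASS_DIGITS)[:n_classes] \
            if n_classes < 10 else None
        full_train = load_mnist(data_dir, train=True, classes=classes)
        full_test = load_mnist(data_dir, train=False, classes=classes)
        idx = rng.permutation(len(full_train))
        train_samples = [full_train[i] for i in idx[:n_train]]
        idx2 = rng.permutation(len(full_train))
        eval_train = [full_train[i] for i in idx2[:n_eval_train]]
        idx3 = rng.permutation(len(full_test))
        eval_test = [full_test[i] for i in idx3[:n_eval_test]]
    else:
        raise ValueError("dataset must be 'synthetic' or 'mnist'")

    layers, netlist = build_digit_network(
        n_classes, group_size, seed=int(rng.integers(2 ** 31)),
        weights=cfg.run.weights)
    cnet = CompiledNetwork(layers, netlist)
    state = train(cnet, train_samples, epochs, cfg)

    echo = {"dataset": dataset, "n_classes": n_classes,
            "group_size": group_size, "n_train": len(train_samples),
            "epochs": epochs, "seed": cfg.seed, "noise_sd": noise_sd,
            **cfg.run.echo()}
    results = []
    for samples in (eval_train, eval_test):
        if samples:
            preds, labels, silent = evaluate(cnet, samples, cfg, state)
            mat = confusion_matrix(preds, labels, n_classes)
        else:
            mat, silent = np.zeros((n_classes, n_classes), dtype=int), 0
        results.append(ExperimentResult(mat, silent, echo))
    return results[0], results[1]


def desk_task(seed: int, precision: str = "fixed16",
              n_train: int = 600, n_eval_test: int = 150,
              n_eval_train: int = 150, noise_sd: float = 25.0
              ) -> tuple[ExperimentResult, ExperimentResult]:
    """The desk-scale 3-class synthetic task (30 exc + 30 inh neurons)."""
    run = RunConfig.from_dict({"precision": precision})
    cfg = SimConfig(run=run, mode="train", seed=seed)
    return run_experiment("synthetic", n_classes=3, group_size=10,
                          n_train=n_train, epochs=1,
                          n_eval_train=n_eval_train,
                          n_eval_test=n_eval_test, cfg=cfg,
                          noise_sd=noise_sd)


def sweep_precision(modes: Sequence[str], train_sizes: Sequence[int],
                    seeds: Sequence[int], n_eval_test: int = 150,
                    noise_sd: float = 25.0) -> pd.DataFrame:
    """Accuracy of the desk task per (precision mode, training size, seed).

    Returns a tidy DataFrame with columns mode, n_train, seed, accuracy,
    no_response — the software analogue of the hardware study comparing
    8/16/32-bit arithmetic as training data grows.
    """
    rows = []
    for mode in modes:
        for n_train in train_sizes:
            for seed in seeds:
                _, test = desk_task(seed, precision=mode, n_train=n_train,
                                    n_eval_train=0,
                                    n_eval_test=n_eval_test,
                                    noise_sd=noise_sd)
                rows.append({"mode": mode, "n_train": n_train,
                             "seed": seed, "accuracy": test.accuracy,
                             "no_response": test.n_no_response})
    return pd.DataFrame(rows)
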