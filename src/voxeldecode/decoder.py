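"""Per-band 1D-CNN decoding of two continuous task states.

One classifier is trained per (voxel, frequency band): the input is a single
band's CWT coefficient row (or the raw series), length T, one channel.  The
architecture is three conv blocks (32, 64, 128 filters; kernel 3; batch norm;
LeakyReLU alpha 0.3; max-pool 2) followed by flatten, a 128-unit dense layer
with LeakyReLU and dropout 0.5, and a sigmoid output unit, trained with Adam
on binary cross-entropy with an L1 weight penalty.  Training runs a fixed
number of epochs at batch size 2; after each epoch the model is scored on a
monitor set and the best monitor AUC is kept.  The whole procedure repeats
``n_repetitions`` times from different random initializations and the mean
AUC over repetitions is the reported decoding performance.

Note on the monitor: by default the *test* set is the monitor, mirroring the
reference protocol ("best model on the test set"); this optimistically biases
the reported AUC.  An honest mode (``monitor='validation'``) carves a
validation set out of the training data, selects the epoch on it, and reports
the test AUC at that epoch; results carry the monitor mode used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .bold_io import LabeledDataset
from .evaluation import auc

__all__ = [
    "CnnHyper",
    "TrainTestSplit",
    "DecodingResult",
    "make_split",
    "build_model",
    "train_once",
    "train_repeated",
]

POSITIVE_LABEL = "SI"


@dataclass(frozen=True)
class CnnHyper:
    """Hyperparameters of the per-band decoder.

    Defaults are the reference configuration.  ``learning_rate`` defaults to
    5e-5; the reference configuration files also carry 1e-3 — both are valid
    settings of the same architecture.
    """

    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 3
    leaky_alpha: float = 0.3
    pool_size: int = 2
    dense_units: int = 128
    dropout_rate: float = 0.5
    l1_weight: float = 1e-5
    learning_rate: float = 5e-5
    batch_size: int = 2
    epochs: int = 200
    n_repetitions: int = 10
    standardize: bool = True
    monitor: str = "test"  # "test" (reference protocol) or "validation" (honest)
    validation_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("conv_filters must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be >= 0")
        if min(self.kernel_size, self.pool_size, self.dense_units, self.batch_size,
               self.epochs, self.n_repetitions) < 1:
            raise ValueError("all counts must be positive")
        if self.monitor not in ("test", "validation"):
            raise ValueError("monitor must be 'test' or 'validation'")


@dataclass
class TrainTestSplit:
    """Disjoint train/test index sets covering a dataset."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    split_seed: int
    stratified_by: str  # "sample" or "subject"

    def __post_init__(self) -> None:
        tr = set(self.train_indices.tolist())
        te = set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


@dataclass
class DecodingResult:
    """Averaged decoding performance of one (voxel, band, method) model."""

    voxel_id: str
    band_label: str  # a band label or "original"
    method: str  # "cnn" or "alff"
    auc_mean: float
    auc_per_repetition: np.ndarray
    split_seed: int
    n_repetitions: int
    monitor: str = "test"

    def __post_init__(self) -> None:
        self.auc_per_repetition = np.asarray(self.auc_per_repetition, dtype=float)
        if np.any((self.auc_per_repetition < 0) | (self.auc_per_repetition > 1)):
            raise ValueError("AUC values must lie in [0, 1]")
        if abs(self.auc_mean - self.auc_per_repetition.mean()) > 1e-9:
            raise ValueError("auc_mean must be the mean of auc_per_repetition")


def _stratified_counts(class_sizes: list[int], fraction: float) -> list[int]:
    """Per-class test counts by largest-remainder apportionment of round(f*N)."""
    total = int(round(fraction * sum(class_sizes)))
    raw = [fraction * n for n in class_sizes]
    counts = [int(np.floor(r)) for r in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in remainders[: total - sum(counts)]:
        counts[i] += 1
    return counts


def make_split(
    labels,
    subjects=None,
    test_fraction: float = 0.25,
    mode: str = "sample",
    seed: int = 0,
) -> TrainTestSplit:
    """Draw a class-stratified train/test split.

    In ``"sample"`` mode individual series are assigned to sides (a subject's
    SI and VG runs may straddle the split — fast but leaks subject identity).
    In ``"subject"`` mode whole subjects are assigned, so both states of a
    test subject stay on the test side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if isinstance(labels, LabeledDataset):
        ds = labels
        labels, subjects = np.asarray(ds.labels), np.asarray(ds.subjects)
    else:
        labels = np.asarray(labels)
        subjects = None if subjects is None else np.asarray(subjects)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    test_idx: list[int] = []
    if mode == "sample":
        class_indices = [np.flatnonzero(labels == c) for c in classes]
        counts = _stratified_counts([len(ci) for ci in class_indices], test_fraction)
        for ci, n_test in zip(class_indices, counts):
            if n_test < 1 or len(ci) - n_test < 1:
                raise ValueError(
                    "split would leave a class empty on one side; adjust test_fraction"
                )
            test_idx.extend(rng.permutation(ci)[:n_test].tolist())
    elif mode == "subject":
        if subjects is None:
            raise ValueError("subject mode requires per-series subject ids")
        uniq = sorted(set(subjects.tolist()))
        n_test_subj = int(round(test_fraction * len(uniq)))
        n_test_subj = min(max(n_test_subj, 1), len(uniq) - 1)
        chosen = set(np.asarray(uniq, dtype=object)[rng.permutation(len(uniq))[:n_test_subj]])
        test_idx = np.flatnonzero(np.isin(subjects, list(chosen))).tolist()
    else:
        raise ValueError("mode must be 'sample' or 'subject'")
    test = np.array(sorted(test_idx), dtype=int)
    train = np.setdiff1d(np.arange(labels.size), test)
    for side, name in ((train, "train"), (test, "test")):
        present = set(labels[side].tolist())
        if len(present) < 2:
            raise ValueError(f"{name} side is missing a class; adjust the split")
    return TrainTestSplit(train, test, split_seed=seed, stratified_by=mode)


def build_model(input_length: int, n_channels: int = 1, hyper: CnnHyper = CnnHyper(),
                rng: np.random.Generator | None = None) -> nn.Sequential:
    """Assemble the three-block conv net for one band's coefficient row.

    The trainable-parameter count is a pure function of (input_length, hyper).
    Raises if three pooling halvings would exhaust the input.
    """
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    length = input_length
    layers: list[nn.Layer] = []
    c_in = n_channels
    for filters in hyper.conv_filters:
        next_length = length // hyper.pool_size
        if next_length < 1:
            raise ValueError(
                f"input_length {input_length} too short for {len(hyper.conv_filters)} "
                f"pooling halvings (fails at length {length})"
            )
        layers += [
            nn.Conv1D(c_in, filters, hyper.kernel_size, hyper.l1_weight, rng),
            nn.BatchNorm1D(filters),
            nn.LeakyReLU(hyper.leaky_alpha),
            nn.MaxPool1D(hyper.pool_size),
        ]
        c_in, length = filters, next_length
    layers += [
        nn.Flatten(),
        nn.Dense(length * c_in, hyper.dense_units, hyper.l1_weight, rng),
        nn.LeakyReLU(hyper.leaky_alpha),
        nn.Dropout(hyper.dropout_rate, rng),
        nn.Dense(hyper.dense_units, 1, hyper.l1_weight, rng),
    ]
    return nn.Sequential(layers)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return (x - mean) / sd


def train_once(
    split: TrainTestSplit,
    features: np.ndarray,
    labels,
    hyper: CnnHyper,
    repetition_seed: int | np.random.SeedSequence,
) -> tuple[float, int]:
    """Train one model and return ``(auc, best_epoch)``.

    Trains for ``hyper.epochs`` epochs; after each epoch the model is scored
    on the monitor set and the epoch with the highest monitor AUC wins.  In
    the default ``monitor='test'`` mode the returned AUC is that maximum test
    AUC (the reference protocol); in ``'validation'`` mode the epoch is chosen
    on a held-out slice of the training data and the returned AUC is the test
    AUC at that epoch.  Fully deterministic given the seed.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if hyper.standardize:
        features = _standardize_rows(features)
    y = (labels == POSITIVE_LABEL).astype(float)
    if isinstance(repetition_seed, np.random.SeedSequence):
        rng = np.random.default_rng(repetition_seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(repetition_seed)]))

    train_idx = split.train_indices
    if hyper.monitor == "validation":
        # carve a stratified validation slice out of the training side
        inner = make_split(
            labels[train_idx],
            test_fraction=hyper.validation_fraction,
            mode="sample",
            seed=int(rng.integers(2**31)),
        )
        monitor_idx = train_idx[inner.test_indices]
        train_idx = train_idx[inner.train_indices]
    else:
        monitor_idx = split.test_indices

    x_train, y_train = features[train_idx][:, :, None], y[train_idx]
    x_monitor, y_monitor = features[monitor_idx][:, :, None], y[monitor_idx]
    x_test, y_test = features[split.test_indices][:, :, None], y[split.test_indices]

    model = build_model(features.shape[1], 1, hyper, rng)
    optimizer = nn.Adam(hyper.learning_rate)
    n = x_train.shape[0]
    best_monitor, best_epoch, best_test = -np.inf, 0, 0.5
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hyper.batch_size):
            batch = order[start : start + hyper.batch_size]
            model.train_step(x_train[batch], y_train[batch], optimizer)
        monitor_auc = auc(model.predict_proba(x_monitor), y_monitor, positive_label=1.0)
        if monitor_auc > best_monitor:
            best_monitor, best_epoch = monitor_auc, epoch
            if hyper.monitor == "validation":
                best_test = auc(model.predict_proba(x_test), y_test, positive_label=1.0)
    return (best_monitor if hyper.monitor == "test" else best_test), best_epoch


def train_repeated(
    split: TrainTestSplit,
    features: np.ndarray,
    labels,
    hyper: CnnHyper,
    voxel_id: str = "",
    band_label: str = "",
) -> DecodingResult:
    """Repeat :func:`train_once` from fresh initializations and average.

    Repetition seeds derive from ``hyper.seed`` so the whole result is a pure
    function of (split, features, labels, hyper).
    """
    aucs = []
    for rep in range(hyper.n_repetitions):
        ss = np.random.SeedSequence([hyper.seed, rep])
        rep_auc, _ = train_once(split, features, labels, hyper, ss)
        aucs.append(rep_auc)
    aucs = np.asarray(aucs)
    return DecodingResult(
        voxel_id=voxel_id,
        band_label=band_label,
        method="cnn",
        auc_mean=float(aucs.mean()),
        auc_per_repetition=aucs,
        split_seed=split.split_seed,
        n_repetitions=hyper.n_repetitions,
        monitor=hyper.monitor,
    )
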