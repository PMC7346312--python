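"""Four-stage diagnostic pipeline: features -> SOM clustering -> per-cluster
backpropagation networks -> decision, plus the parameter-grid evaluator.

The training set is partitioned into learning subsets by a self-organizing
map; one network is trained per non-empty subset.  Two rules combine the
per-network classifications of a new sample: majority vote across all
networks (ties broken by the network with the best validation accuracy), or
adopting wholesale the network whose learning subset achieved the best
validation accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mlp as _mlp
from . import som as _som
from .exceptions import ParameterError
from .qrs import QRSConfig, detect_r_peaks
from .rbp import RBPConfig, rbp_feature
from .signal_io import ECGRecord, FilterSpec, LABEL_SMOKER, apply_filter
from .wavelet import WaveletConfig, record_wavelet_features

logger = logging.getLogger(__name__)


@dataclass
class MLPParams:
    hidden: list[int] | None = None  # None -> max(8, round(sqrt(d)))
    lr: float = 0.5
    epochs: int = 400


@dataclass
class DiagnosticConfig:
    feature: str = "wavelet"  # "rbp" or "wavelet"
    rbp: RBPConfig = field(default_factory=RBPConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    c: int = 2
    decision: str = "best_subset"  # or "majority"
    nn: MLPParams = field(default_factory=MLPParams)
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    filter_spec: FilterSpec = field(default_factory=lambda: FilterSpec(kind="none"))
    qrs: QRSConfig = field(default_factory=QRSConfig)
    som_epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in ("rbp", "wavelet"):
            raise ParameterError(f"unknown feature kind {self.feature!r}")
        if self.decision not in ("majority", "best_subset"):
            raise ParameterError(f"unknown decision rule {self.decision!r}")
        if self.c < 1:
            raise ParameterError("c must be >= 1")
        fr = self.split
        if len(fr) != 3 or min(fr) <= 0 or abs(sum(fr) - 1.0) > 1e-9:
            raise ParameterError("split fractions must be positive and sum to 1")


@dataclass
class Standardizer:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=mean, std=std)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) / self.std


@dataclass
class Splits:
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class DiagnosticModel:
    som: _som.SOMModel
    nets: list[_mlp.MLPModel]  # one per non-empty cluster
    cluster_ids: list[int]  # SOM unit index behind each net
    val_accuracy: list[float]
    decision: str
    scaler: Standardizer
    config: DiagnosticConfig
    splits: Splits | None = None


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def extract_features(
    records: list[ECGRecord], config: DiagnosticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """One feature vector and one 0/1 label (1 = smoker) per record.

    RBP features are computed over the full pre-filtered trace; wavelet
    features are the mean of the record's per-group coefficient vectors, so
    each subject contributes exactly one vector.
    """
    feats: list[np.ndarray] = []
    labels: list[int] = []
    for rec in records:
        pre = apply_filter(rec, config.filter_spec)
        if config.feature == "rbp":
            vec = rbp_feature(pre.samples, config.rbp).values
        else:
            peaks = detect_r_peaks(pre, config.qrs)
            groups = record_wavelet_features(pre, peaks, config.wavelet)
            vec = np.mean([g.values for g in groups], axis=0)
        feats.append(vec)
        labels.append(1 if rec.label == LABEL_SMOKER else 0)
    X = np.vstack(feats)
    return X, np.array(labels, dtype=int)


def stratified_split(
    y: np.ndarray, fractions: tuple[float, float, float], seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded per-class shuffle into train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = idx.size
        n_train = max(int(round(fractions[0] * n)), 1)
        n_val = max(int(round(fractions[1] * n)), 1)
        n_train = min(n_train, n - 2) if n >= 3 else n_train
        train.extend(idx[:n_train])
        val.extend(idx[n_train : n_train + n_val])
        test.extend(idx[n_train + n_val :])
    return (np.sort(train).astype(int), np.sort(val).astype(int), np.sort(test).astype(int))


# ---------------------------------------------------------------------------
# fit / decide
# ---------------------------------------------------------------------------


def fit_diagnostic(
    records: list[ECGRecord], config: DiagnosticConfig
) -> DiagnosticModel:
    """Fit the full four-stage system on a labeled record cohort.

    Records are split (stratified, seeded) into train/validation/test;
    features are standardized with training-split statistics; a 1 x c SOM
    partitions the training features; one MLP is trained per non-empty
    cluster and scored on the shared validation split.
    """
    X, y = extract_features(records, config)
    i_train, i_val, i_test = stratified_split(y, config.split, config.seed)
    scaler = Standardizer.fit(X[i_train])
    splits = Splits(
        X_train=scaler(X[i_train]),
        y_train=y[i_train],
        X_val=scaler(X[i_val]),
        y_val=y[i_val],
        X_test=scaler(X[i_test]),
        y_test=y[i_test],
    )
    model = fit_on_features(splits, config, scaler=scaler)
    model.splits = splits
    return model


def fit_on_features(
    splits: Splits, config: DiagnosticConfig, scaler: Standardizer | None = None
) -> DiagnosticModel:
    """Clustering + per-cluster network training on already-split features."""
    Xtr, ytr = splits.X_train, splits.y_train
    if min(np.bincount(ytr, minlength=2)) < 2:
        raise ParameterError("need >= 2 training records per class")
    c = min(config.c, Xtr.shape[0])
    som = _som.train_som(Xtr, c=c, epochs=config.som_epochs, seed=config.seed)
    assignment = _som.assign_clusters(som, Xtr)

    nets: list[_mlp.MLPModel] = []
    cluster_ids: list[int] = []
    val_accuracy: list[float] = []
    for k in range(c):
        members = assignment.members(k)
        if members.size == 0:
            logger.info("cluster %d is empty; no network trained for it", k)
            continue
        net = _mlp.train_mlp(
            Xtr[members],
            ytr[members],
            hidden=config.nn.hidden,
            lr=config.nn.lr,
            epochs=config.nn.epochs,
            seed=config.seed + 17 * (k + 1),
        )
        _, val_pred = _mlp.predict(net, splits.X_val)
        acc = float(np.mean(val_pred == splits.y_val)) if splits.y_val.size else 0.0
        nets.append(net)
        cluster_ids.append(k)
        val_accuracy.append(acc)
        logger.info(
            "cluster %d: %d samples (class counts %s), val accuracy %.3f",
            k,
            members.size,
            np.bincount(ytr[members], minlength=2).tolist(),
            acc,
        )
    if not nets:
        raise ParameterError("no non-empty cluster; cannot fit any network")

    if scaler is None:
        scaler = Standardizer(
            mean=np.zeros(Xtr.shape[1]), std=np.ones(Xtr.shape[1])
        )
    return DiagnosticModel(
        som=som,
        nets=nets,
        cluster_ids=cluster_ids,
        val_accuracy=val_accuracy,
        decision=config.decision,
        scaler=scaler,
        config=config,
    )


def decide(
    model: DiagnosticModel, X: np.ndarray, rule: str | None = None
) -> np.ndarray:
    """Final 0/1 labels for standardized-or-raw feature rows ``X``.

    ``X`` is taken to be on the raw feature scale and is standardized with
    the model's training statistics.  majority: per-sample vote across all
    networks, ties going to the network with the best validation accuracy;
    best_subset: the single network with the best validation accuracy
    decides alone (ties to the lowest network index).
    """
    rule = rule or model.decision
    Xs = model.scaler(X) if model.scaler is not None else np.atleast_2d(X)
    votes = np.stack([_mlp.predict(net, Xs)[1] for net in model.nets])  # (nets, n)
    best = int(np.argmax(model.val_accuracy))
    if rule == "best_subset":
        return votes[best]
    if rule != "majority":
        raise ParameterError(f"unknown decision rule {rule!r}")
    ones = votes.sum(axis=0)
    n_nets = votes.shape[0]
    out = np.where(2 * ones > n_nets, 1, 0)
    tied = 2 * ones == n_nets
    out[tied] = votes[best, tied]
    return out


def _decide_standardized(model: DiagnosticModel, Xs: np.ndarray, rule: str) -> np.ndarray:
    votes = np.stack([_mlp.predict(net, Xs)[1] for net in model.nets])
    best = int(np.argmax(model.val_accuracy))
    if rule == "best_subset":
        return votes[best]
    ones = votes.sum(axis=0)
    out = np.where(2 * ones > votes.shape[0], 1, 0)
    tied = 2 * ones == votes.shape[0]
    out[tied] = votes[best, tied]
    return out


def held_out_accuracy(model: DiagnosticModel, rule: str | None = None) -> float:
    """Held-out test accuracy of a model fitted by :func:`fit_diagnostic`."""
    if model.splits is None:
        raise ParameterError("model carries no held-out split")
    pred = _decide_standardized(model, model.splits.X_test, rule or model.decision)
    return float(np.mean(pred == model.splits.y_test))


# ---------------------------------------------------------------------------
# parameter-grid evaluation
# ---------------------------------------------------------------------------


@dataclass
class AccuracyGrid:
    row_name: str
    row_values: list
    col_name: str
    col_values: list
    cells: np.ndarray  # (rows, cols) mean held-out accuracy; NaN = invalid combo
    seeds: np.ndarray  # (rows, cols, repeats) seeds actually used

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, index=self.row_values, columns=self.col_values)
        df.index.name = self.row_name
        df.columns.name = self.col_name
        return df


def _with_param(config: DiagnosticConfig, name: str, value) -> DiagnosticConfig:
    if name == "m":
        return replace(config, rbp=replace(config.rbp, m=int(value)))
    if name == "alpha":
        return replace(config, rbp=replace(config.rbp, alpha=int(value)))
    if name == "n":
        return replace(config, wavelet=replace(config.wavelet, n=int(value)))
    if name == "c":
        return replace(config, c=int(value))
    raise ParameterError(f"unknown grid parameter {name!r}")


def evaluate_grid(
    records: list[ECGRecord],
    base_config: DiagnosticConfig,
    rows: tuple[str, list],
    cols: tuple[str, list],
    repeats: int = 1,
) -> AccuracyGrid:
    """Mean held-out accuracy for every (row, col) parameter combination.

    Each cell refits the whole pipeline ``repeats`` times with derived
    seeds and averages the test accuracy; an invalid combination (e.g. a
    DWT level past the admissible bound) leaves a NaN cell and the sweep
    continues.
    """
    row_name, row_values = rows
    col_name, col_values = cols
    cells = np.full((len(row_values), len(col_values)), np.nan)
    seeds = np.zeros((len(row_values), len(col_values), repeats), dtype=np.int64)
    for i, rv in enumerate(row_values):
        for j, cv in enumerate(col_values):
            accs = []
            for rep in range(repeats):
                seed = int(
                    np.random.SeedSequence(
                        entropy=base_config.seed, spawn_key=(i, j, rep)
                    ).generate_state(1)[0]
                    % (2**31)
                )
                seeds[i, j, rep] = seed
                try:
                    cfg = _with_param(base_config, row_name, rv)
                    cfg = _with_param(cfg, col_name, cv)
                    cfg = replace(cfg, seed=seed)
                    model = fit_diagnostic(records, cfg)
                    accs.append(held_out_accuracy(model))
                except ParameterError as exc:
                    logger.warning(
                        "cell (%s=%s, %s=%s) invalid: %s",
                        row_name, rv, col_name, cv, exc,
                    )
                    accs = []
                    break
            if accs:
                cells[i, j] = float(np.mean(accs))
    return AccuracyGrid(
        row_name=row_name,
        row_values=list(row_values),
        col_name=col_name,
        col_values=list(col_values),
        cells=cells,
        seeds=seeds,
    )
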