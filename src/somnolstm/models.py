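"""Classifier families: logistic regression, random forest and the
local-global LSTM, with balanced class weighting, grid search and grouped
k-fold cross-validation.

The API follows the fitted-model convention: :func:`train_model` builds and
fits the family named in a :class:`ModelConfig` and returns a
:class:`TrainedModel` results object exposing ``predict`` and ``summary``;
:func:`cross_validate` returns a :class:`CVResult` carrying out-of-fold
predictions for every valid epoch.

Class weights follow the balanced scheme w_c = n_samples / (n_classes * n_c),
so underrepresented classes (wake, deep, REM) contribute equally to the loss.
All feature normalisation and imputation statistics are computed on the
training fold only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score

from .exceptions import InferenceError, TrainingError, ValidationError
from .features import FeatureDataset, LstmInput, SequenceDataset
from .metrics import BINARY_CLASSES, STAGE4_CLASSES, collapse_stages
from .nn import LocalGlobalLSTM

logger = logging.getLogger(__name__)

FAMILIES = ("logistic", "random_forest", "lstm")
TASKS = ("binary", "stage4")

#: Hyperparameter grids explored by 3-fold grid search.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logistic": [
        {"C": c, "penalty": p}
        for c in (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
        for p in ("l1", "l2")
    ],
    "random_forest": [{"max_depth": d} for d in (10, 50, 100)],
    "lstm": [
        {"hidden": h, "lr": lr, "dropout": d}
        for h in (64, 128, 256)
        for lr in (1e-4, 1e-3, 1e-2)
        for d in (0.0, 0.1, 0.3)
    ],
}

#: Shipped default hyperparameters per family (the LSTM configuration is the
#: selected point of its grid: hidden 128, learning rate 1e-4, dropout 0.1).
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "logistic": {"C": 1.0, "penalty": "l2"},
    "random_forest": {"max_depth": 50},
    "lstm": {"hidden": 128, "lr": 1e-4, "dropout": 0.1},
}

#: Architecture constants of the LSTM not subject to the grid.
LSTM_FIXED = {
    "local_hidden": 32,
    "chunk_len": 120,
    "batch_chunks": 2,
    "max_passes": 50,
    "patience": 5,
    "val_fraction": 0.1,
}


@dataclass(frozen=True)
class ClassWeights:
    """Balanced class weights w_c = n_samples / (n_classes * n_c)."""

    weights: dict[str, float]
    n_samples: int
    n_classes: int
    counts: dict[str, int]

    def as_array(self, class_order: tuple[str, ...]) -> np.ndarray:
        return np.array([self.weights[c] for c in class_order])


def compute_class_weights(labels, classes: tuple[str, ...] | None = None) -> ClassWeights:
    """Balanced weights of a label sequence; every declared class must occur."""
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        classes = tuple(sorted(set(labels)))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    for c, n_c in counts.items():
        if n_c == 0:
            raise TrainingError(f"training fold has no samples of class {c!r}")
    n = len(labels)
    k = len(classes)
    weights = {c: n / (k * n_c) for c, n_c in counts.items()}
    return ClassWeights(weights=weights, n_samples=n, n_classes=k, counts=counts)


@dataclass(frozen=True)
class ModelConfig:
    """Family, task, HR usage, hyperparameters and seed of one model."""

    family: str = "lstm"
    task: str = "binary"
    include_hr: bool = True
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if not self.hyperparameters:
            object.__setattr__(
                self, "hyperparameters", dict(DEFAULT_HYPERPARAMETERS[self.family])
            )

    @property
    def class_order(self) -> tuple[str, ...]:
        return BINARY_CLASSES if self.task == "binary" else STAGE4_CLASSES


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

@dataclass
class TableNormalizer:
    """Training-fold median imputation + standardisation for feature tables."""

    medians: pd.Series
    means: pd.Series
    stds: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "TableNormalizer":
        medians = X.median()
        medians = medians.fillna(0.0)  # all-NaN columns impute to 0
        Xi = X.fillna(medians)
        means = Xi.mean()
        stds = Xi.std(ddof=0).replace(0.0, 1.0)
        return cls(medians=medians, means=means, stds=stds)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Xi = X.fillna(self.medians)
        out = (Xi - self.means) / self.stds
        return out.to_numpy(dtype=float)


@dataclass
class SequenceNormalizer:
    """log1p + per-(component, channel) standardisation of spectral blocks."""

    mean: np.ndarray  # (K, C)
    std: np.ndarray

    @classmethod
    def fit(cls, seqs: list[np.ndarray]) -> "SequenceNormalizer":
        stacked = np.log1p(np.concatenate(seqs, axis=0))  # (N, K, C)
        mean = stacked.mean(axis=0)
        std = stacked.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=mean, std=std)

    def transform(self, seq: np.ndarray) -> np.ndarray:
        return (np.log1p(seq) - self.mean) / self.std


def _to_step_sequences(ds: SequenceDataset, include_hr: bool) -> list[np.ndarray]:
    """LstmInput blocks (n, 5, K) -> per-night step arrays (n, K, 5)."""
    out = []
    for night in ds.nights:
        X = night.X
        if not include_hr:
            X = X.copy()
            X[:, 4, :] = 0.0
        out.append(np.transpose(X, (0, 2, 1)))
    return out


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Fitted classifier plus everything needed to apply it."""

    config: ModelConfig
    class_order: tuple[str, ...]
    estimator: object
    table_norm: TableNormalizer | None = None
    seq_norm: SequenceNormalizer | None = None
    feature_cols: list[str] | None = None
    class_weights: ClassWeights | None = None

    def predict(self, data) -> pd.DataFrame:
        """Per-epoch labels and class probabilities.

        ``data`` is a FeatureDataset / feature DataFrame for logistic and
        random-forest models, or a SequenceDataset / LstmInput for the LSTM.
        Ties in the probability row break toward the class earlier in the
        fixed order (wake first).
        """
        if self.config.family == "lstm":
            return self._predict_sequences(data)
        return self._predict_table(data)

    def _finish(self, meta: pd.DataFrame, probs: np.ndarray) -> pd.DataFrame:
        if probs.shape[1] != len(self.class_order):  # pragma: no cover
            raise InferenceError("probability width mismatch")
        pred = np.asarray(self.class_order, dtype=object)[np.argmax(probs, axis=1)]
        out = meta.copy()
        out["pred"] = pred
        for j, c in enumerate(self.class_order):
            out[f"p_{c}"] = probs[:, j]
        return out

    def _predict_table(self, data) -> pd.DataFrame:
        df = data.df if isinstance(data, FeatureDataset) else data
        if self.feature_cols is None or any(
            c not in df.columns for c in self.feature_cols
        ):
            raise InferenceError("input table lacks the model's feature columns")
        X = self.table_norm.transform(df[self.feature_cols])
        raw = self.estimator.predict_proba(X)
        cls = list(self.estimator.classes_)
        probs = np.zeros((len(df), len(self.class_order)))
        for j, c in enumerate(self.class_order):
            if c in cls:
                probs[:, j] = raw[:, cls.index(c)]
        meta = df[["participant_id", "epoch_index"]].reset_index(drop=True)
        meta["true"] = collapse_stages(df["label"].to_numpy(), self.config.task)
        return self._finish(meta, probs)

    def _predict_sequences(self, data) -> pd.DataFrame:
        if isinstance(data, LstmInput):
            data = SequenceDataset([data])
        frames = []
        for night, seq in zip(
            data.nights, _to_step_sequences(data, self.config.include_hr)
        ):
            Xn = self.seq_norm.transform(seq)
            probs = self.estimator.predict_proba_night(Xn)
            meta = pd.DataFrame(
                {
                    "participant_id": night.participant_id,
                    "epoch_index": night.epoch_index,
                    "true": collapse_stages(night.labels, self.config.task),
                }
            )
            frames.append(self._finish(meta, probs))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = [
            "TrainedModel",
            f"  family        : {self.config.family}",
            f"  task          : {self.config.task} {self.class_order}",
            f"  include_hr    : {self.config.include_hr}",
            f"  hyperparams   : {self.config.hyperparameters}",
            f"  seed          : {self.config.seed}",
        ]
        if self.class_weights is not None:
            lines.append(f"  class weights : { {k: round(v, 4) for k, v in self.class_weights.weights.items()} }")
        return "\n".join(lines)


def train_model(config: ModelConfig, data) -> TrainedModel:
    """Fit one model family on a training dataset.

    ``data`` is a :class:`FeatureDataset` (logistic / random forest) or a
    :class:`SequenceDataset` (LSTM). Labels are collapsed to the config's
    task in here; every task class must be present in the training fold.
    """
    if config.family == "lstm":
        if not isinstance(data, SequenceDataset):
            raise ValidationError("LSTM training requires a SequenceDataset")
        return _train_lstm(config, data)
    if not isinstance(data, FeatureDataset):
        raise ValidationError("logistic/random-forest training requires a FeatureDataset")
    return _train_table_model(config, data)


def _train_table_model(config: ModelConfig, data: FeatureDataset) -> TrainedModel:
    df = data.df
    y = collapse_stages(df["label"].to_numpy(), config.task)
    cw = compute_class_weights(y, classes=config.class_order)
    feature_cols = list(data.feature_cols)
    if not config.include_hr:
        hr_cols = [c for c in feature_cols if c.startswith("hr_")]
        df = df.copy()
        df[hr_cols] = 0.0
    norm = TableNormalizer.fit(df[feature_cols])
    X = norm.transform(df[feature_cols])
    hp = config.hyperparameters
    if config.family == "logistic":
        est = LogisticRegression(
            C=float(hp.get("C", 1.0)),
            l1_ratio=1.0 if hp.get("penalty", "l2") == "l1" else 0.0,
            solver="liblinear",
            class_weight=cw.weights,
            max_iter=2000,
            random_state=config.seed,
        )
    else:
        est = RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            max_depth=hp.get("max_depth", 50),
            class_weight=cw.weights,
            random_state=config.seed,
            n_jobs=1,
        )
    est.fit(X, y.astype(str))
    return TrainedModel(
        config=config,
        class_order=config.class_order,
        estimator=est,
        table_norm=norm,
        feature_cols=feature_cols,
        class_weights=cw,
    )


def _train_lstm(config: ModelConfig, data: SequenceDataset) -> TrainedModel:
    hp = dict(LSTM_FIXED)
    hp.update(config.hyperparameters)
    seqs = _to_step_sequences(data, config.include_hr)
    labels_str = [collapse_stages(n.labels, config.task) for n in data.nights]
    all_labels = np.concatenate(labels_str)
    cw = compute_class_weights(all_labels, classes=config.class_order)
    cls_index = {c: i for i, c in enumerate(config.class_order)}
    labels = [np.array([cls_index[l] for l in ls]) for ls in labels_str]

    # hold out ~10% of training subjects for early stopping
    rng = np.random.default_rng(config.seed)
    n = len(seqs)
    # at least two validation nights when affordable: a single night makes
    # the early-stopping signal too noisy
    if n >= 8:
        n_val = max(2, int(round(hp["val_fraction"] * n)))
    elif n >= 3:
        n_val = 1
    else:
        n_val = 0
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    tr = [i for i in range(n) if i not in val_idx]
    va = [i for i in range(n) if i in val_idx]

    norm = SequenceNormalizer.fit([seqs[i] for i in tr] or seqs)
    seqs_n = [norm.transform(s).astype(np.float32) for s in seqs]

    net = LocalGlobalLSTM(
        n_classes=len(config.class_order),
        n_components=data.nights[0].K,
        n_channels=seqs[0].shape[2],
        local_hidden=int(hp["local_hidden"]),
        hidden=int(hp.get("hidden", 128)),
        dropout=float(hp.get("dropout", 0.1)),
        lr=float(hp.get("lr", 1e-4)),
        seed=config.seed,
        max_passes=int(hp["max_passes"]),
        patience=int(hp["patience"]),
        chunk_len=int(hp["chunk_len"]),
        batch_chunks=int(hp["batch_chunks"]),
    )
    net.fit(
        [seqs_n[i] for i in tr],
        [labels[i] for i in tr],
        cw.as_array(config.class_order),
        val_sequences=[seqs_n[i] for i in va] or None,
        val_labels=[labels[i] for i in va] or None,
    )
    return TrainedModel(
        config=config,
        class_order=config.class_order,
        estimator=net,
        seq_norm=norm,
        class_weights=cw,
    )


def predict(model: TrainedModel, night_data) -> pd.DataFrame:
    """Apply a fitted model to one night (or a whole dataset)."""
    return model.predict(night_data)


# ---------------------------------------------------------------------------
# grid search and cross-validation
# ---------------------------------------------------------------------------

def _grouped_folds(participants: list[str], k: int, seed: int) -> list[list[str]]:
    ids = sorted(participants)
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds the {len(ids)} participants")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return [list(f) for f in np.array_split(np.array(perm, dtype=object), k)]


def grid_search(
    config: ModelConfig, data, grid: list[dict], inner_k: int = 3, seed: int | None = None
) -> dict:
    """Exhaustive grid search by mean inner-fold balanced accuracy.

    Inner folds are grouped by participant. A candidate whose inner fold is
    degenerate (fails to train or predict) is scored as failed and logged.
    Ties break toward the candidate declared first.
    """
    if not grid:
        raise ValidationError("grid must be non-empty")
    if len(grid) == 1:
        return dict(grid[0])
    seed = config.seed if seed is None else seed
    folds = _grouped_folds(data.participants, inner_k, seed + 17)
    scores = []
    for ci, hp in enumerate(grid):
        cand = replace(config, hyperparameters=dict(hp))
        fold_scores = []
        for f in folds:
            test_ids = set(f)
            train_ids = [p for p in data.participants if p not in test_ids]
            try:
                model = train_model(cand, data.subset(train_ids))
                pred = model.predict(data.subset(sorted(test_ids)))
                fold_scores.append(
                    balanced_accuracy_score(pred["true"], pred["pred"])
                )
            except TrainingError as exc:
                logger.warning("grid candidate %r failed: %s", hp, exc)
                fold_scores = None
                break
        scores.append(-np.inf if fold_scores is None else float(np.mean(fold_scores)))
    best = int(np.argmax(scores))  # argmax keeps the earliest on ties
    return dict(grid[best])


@dataclass
class CVResult:
    """Out-of-fold predictions of a grouped k-fold cross-validation."""

    predictions: pd.DataFrame  # participant_id, epoch_index, fold, true, pred, p_*
    fold_map: dict[str, int]
    chosen_params: dict[int, dict]
    config: ModelConfig

    def accuracy(self) -> float:
        return float(np.mean(self.predictions["true"] == self.predictions["pred"]))

    def summary(self) -> str:
        lines = [
            "CVResult",
            f"  family={self.config.family} task={self.config.task} "
            f"include_hr={self.config.include_hr}",
            f"  folds={len(set(self.fold_map.values()))} "
            f"participants={len(self.fold_map)} epochs={len(self.predictions)}",
            f"  out-of-fold accuracy={self.accuracy():.4f}",
        ]
        return "\n".join(lines)


def cross_validate(
    data,
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    grid: list[dict] | None = None,
    epoch_level: bool = False,
) -> CVResult:
    """Grouped k-fold cross-validation (no subject in both train and test).

    With ``grid`` given, hyperparameters are re-chosen per fold by
    :func:`grid_search` on the training subjects. ``epoch_level=True``
    switches logistic/random-forest models to epoch-level splitting for
    comparability studies (the LSTM always splits by subject because it
    consumes whole nights).
    """
    if epoch_level and config.family != "lstm":
        return _cross_validate_epoch_level(data, config, k, seed, grid)
    folds = _grouped_folds(data.participants, k, seed)
    fold_map = {p: i for i, f in enumerate(folds) for p in f}
    frames = []
    chosen: dict[int, dict] = {}
    for i, f in enumerate(folds):
        test_ids = set(f)
        train_ids = [p for p in data.participants if p not in test_ids]
        train = data.subset(train_ids)
        cfg = replace(config, seed=config.seed + i)
        if grid is not None and len(grid) > 1:
            cfg = replace(cfg, hyperparameters=grid_search(cfg, train, grid))
        chosen[i] = dict(cfg.hyperparameters)
        model = train_model(cfg, train)
        pred = model.predict(data.subset(sorted(test_ids)))
        pred.insert(2, "fold", i)
        frames.append(pred)
    predictions = pd.concat(frames, ignore_index=True)
    return CVResult(
        predictions=predictions, fold_map=fold_map, chosen_params=chosen, config=config
    )


def _cross_validate_epoch_level(data, config, k, seed, grid) -> CVResult:
    df = data.df.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    folds = np.array_split(perm, k)
    frames = []
    chosen: dict[int, dict] = {}
    for i, idx in enumerate(folds):
        mask = np.zeros(len(df), dtype=bool)
        mask[idx] = True
        train = FeatureDataset(df[~mask].reset_index(drop=True))
        test = FeatureDataset(df[mask].reset_index(drop=True))
        cfg = replace(config, seed=config.seed + i)
        if grid is not None and len(grid) > 1:
            cfg = replace(cfg, hyperparameters=grid_search(cfg, train, grid))
        chosen[i] = dict(cfg.hyperparameters)
        model = train_model(cfg, train)
        pred = model.predict(test)
        pred.insert(2, "fold", i)
        frames.append(pred)
    predictions = pd.concat(frames, ignore_index=True)
    return CVResult(
        predictions=predictions,
        fold_map={},
        chosen_params=chosen,
        config=config,
    )
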