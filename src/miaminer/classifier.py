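"""Feed-forward MIA / non-MIA transcript classifier on expression profiles.

The published protocol is followed: per-transcript standardized log2(TPM+1)
expression profiles feed a two-hidden-layer network (40 and 20 units) with
input dropout 0.1 and hidden dropout 0.5, trained with binary cross-entropy
(softmax over two outputs) for a fixed number of epochs on a stratified
70/30 split seeded with 666, evaluated with AUC and 5-fold cross-validation
and a per-epoch logloss trajectory.  Positives are known pathway orthologs;
negatives are conserved single-copy genes, which are not expected to belong
to the pathway.  The trained model then scores the unlabeled transcripts,
and those with P(MIA) above 0.5 are reported as predicted pathway members.

The network itself is implemented here in numpy (Adam optimizer, inverted
dropout, optional inverse-frequency class weights); all randomness — weight
initialization, dropout masks, minibatch order, splits — derives from the
single configured seed, so a run is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .atlas import ExpressionAtlas


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class LabelSet:
    """Pairwise-disjoint positive / negative / unlabeled transcript id sets."""

    positives: frozenset[str]
    negatives: frozenset[str]
    unlabeled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (
            self.positives & self.negatives
            or self.positives & self.unlabeled
            or self.negatives & self.unlabeled
        ):
            raise TrainingError("label sets must be pairwise disjoint")

    @staticmethod
    def from_lists(positives, negatives, unlabeled=()) -> "LabelSet":
        return LabelSet(frozenset(positives), frozenset(negatives), frozenset(unlabeled))


@dataclass
class ClassifierConfig:
    """Architecture and training protocol (defaults follow the published run)."""

    hidden_sizes: tuple[int, ...] = (40, 20)
    dropout_input: float = 0.1
    dropout_hidden: float = 0.5
    epochs: int = 1500
    split: float = 0.7
    cv_folds: int = 5
    seed: int = 666
    learning_rate: float = 1e-3
    batch_size: int = 32
    class_weights: bool = True
    threshold: float = 0.5
    patience: int = 50

    def validate(self) -> None:
        if not 0 < self.split < 1:
            raise TrainingError("split must be in (0, 1)")
        if not self.hidden_sizes:
            raise TrainingError("hidden_sizes must be nonempty")
        for d in (self.dropout_input, self.dropout_hidden):
            if not 0 <= d < 1:
                raise TrainingError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise TrainingError("epochs must be >= 1")


@dataclass
class ClassifierReport:
    confusion_train: np.ndarray
    confusion_val: np.ndarray
    auc_train: float
    auc_val: float
    auc_cv: list[float] = field(default_factory=list)
    logloss_train: list[float] = field(default_factory=list)
    logloss_val: list[float] = field(default_factory=list)
    divergence_epoch: int | None = None
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)
    predicted_mia: set[str] = field(default_factory=set)
    scores: pd.Series | None = None

    @property
    def auc_cv_mean(self) -> float:
        return float(np.mean(self.auc_cv)) if self.auc_cv else float("nan")


def make_features(
    atlas: ExpressionAtlas, collapse_replicates: bool = False
) -> pd.DataFrame:
    """Per-transcript standardized log2(TPM+1) profiles.

    Feature columns are the samples, or per-tissue means when
    ``collapse_replicates`` is set.  Rows are z-scored with the population
    standard deviation; zero-variance transcripts are dropped with a warning.
    """
    log = np.log2(atlas.matrix + 1.0)
    if collapse_replicates:
        tissues = atlas.sample_meta.loc[log.columns, "tissue_type"]
        log = log.T.groupby(tissues.values).mean().T
        log.columns = list(log.columns)
    sd = log.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance transcripts dropped from features"
        )
    log = log.loc[keep]
    vals = log.values
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    return pd.DataFrame(vals, index=log.index, columns=log.columns)


class FeedForwardNet:
    """Minimal two-class MLP: ReLU hiddens, softmax output, Adam, inverted dropout."""

    def __init__(self, config: ClassifierConfig, n_features: int, rng: np.random.Generator):
        self.config = config
        sizes = [n_features, *config.hidden_sizes, 2]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(s) for s in sizes[1:]]
        self._rng = rng
        self._adam_m = [np.zeros_like(w) for w in self.weights] + [
            np.zeros_like(b) for b in self.biases
        ]
        self._adam_v = [np.zeros_like(p) for p in self._adam_m]
        self._adam_t = 0

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool):
        cfg = self.config
        acts, masks = [x], []
        h = x
        if train and cfg.dropout_input > 0:
            mask = (
                self._rng.random(h.shape) >= cfg.dropout_input
            ) / (1.0 - cfg.dropout_input)
            h = h * mask
            acts[0] = h
            masks.append(mask)
        else:
            masks.append(None)
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if layer < len(self.weights) - 1:
                h = np.maximum(z, 0.0)
                if train and cfg.dropout_hidden > 0:
                    mask = (
                        self._rng.random(h.shape) >= cfg.dropout_hidden
                    ) / (1.0 - cfg.dropout_hidden)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                p = e / e.sum(axis=1, keepdims=True)
        return p, acts, masks

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p, _, _ = self._forward(np.asarray(x, dtype=float), train=False)
        return p

    # -- training ----------------------------------------------------------
    def _adam_step(self, grads: list[np.ndarray]) -> None:
        cfg = self.config
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        params = self.weights + self.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
            mhat = self._adam_m[i] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[i] / (1 - b2 ** self._adam_t)
            p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def _batch_update(self, x, y, w) -> None:
        p, acts, masks = self._forward(x, train=True)
        n = x.shape[0]
        onehot = np.zeros_like(p)
        onehot[np.arange(n), y] = 1.0
        delta = (p - onehot) * w[:, None] / w.sum()
        grads_w, grads_b = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            a = acts[layer]
            grads_w.append(a.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = delta @ self.weights[layer].T
                delta = delta * (acts[layer] > 0)
                if masks[layer] is not None:
                    delta = delta * masks[layer]
        self._adam_step(list(reversed(grads_w)) + list(reversed(grads_b)))

    def fit(self, x, y, x_val=None, y_val=None):
        """Train for the configured fixed number of epochs, recording the
        logloss trajectory; returns (logloss_train, logloss_val, divergence_epoch).
        Validation logloss rising for ``patience`` consecutive epochs is
        logged as divergence but training still runs to the fixed epoch count.
        """
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        n = x.shape[0]
        if cfg.class_weights:
            freq = np.bincount(y, minlength=2)
            cw = n / (2.0 * np.maximum(freq, 1))
        else:
            cw = np.ones(2)
        sample_w = cw[y]
        ll_train, ll_val = [], []
        divergence_epoch = None
        rising = 0
        prev_val = np.inf
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            for s in range(0, n, cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                self._batch_update(x[idx], y[idx], sample_w[idx])
            p = self.predict_proba(x)[:, 1]
            ll_train.append(log_loss(y, p, labels=[0, 1]))
            if x_val is not None and len(x_val):
                pv = self.predict_proba(x_val)[:, 1]
                cur = log_loss(y_val, pv, labels=[0, 1])
                ll_val.append(cur)
                rising = rising + 1 if cur > prev_val else 0
                prev_val = cur
                if rising >= cfg.patience and divergence_epoch is None:
                    divergence_epoch = epoch + 1
        if divergence_epoch is not None:
            warnings.warn(
                f"validation logloss rose for {cfg.patience} consecutive epochs "
                f"(first at epoch {divergence_epoch}); training continued to "
                f"{cfg.epochs} epochs per the fixed-epoch protocol"
            )
        return ll_train, ll_val, divergence_epoch


def _subset(features: pd.DataFrame, ids: list[str]):
    return features.loc[ids].values


def train_classifier(
    features: pd.DataFrame,
    labels: LabelSet,
    config: ClassifierConfig | None = None,
    run_cv: bool = True,
):
    """Train on the labelled transcripts with a stratified split; returns
    ``(model, report)``.

    Labelled ids absent from the feature matrix (e.g. dropped by the
    expression filter) are ignored with a warning.  Requires both classes in
    the training partition.
    """
    config = config or ClassifierConfig()
    config.validate()
    pos = sorted(labels.positives & set(features.index))
    neg = sorted(labels.negatives & set(features.index))
    lost = (len(labels.positives) - len(pos)) + (len(labels.negatives) - len(neg))
    if lost:
        warnings.warn(f"{lost} labelled transcripts absent from the feature matrix")
    if not pos:
        raise TrainingError("no positive examples available for training")
    if not neg:
        raise TrainingError("no negative examples available for training")
    ids = pos + neg
    y = np.array([1] * len(pos) + [0] * len(neg))
    train_ids, val_ids, y_train, y_val = train_test_split(
        ids,
        y,
        train_size=config.split,
        random_state=config.seed,
        stratify=y,
        shuffle=True,
    )
    if len(set(y_train)) < 2:
        raise TrainingError("training partition lost a class")

    x_train = _subset(features, train_ids)
    x_val = _subset(features, val_ids)
    rng = np.random.default_rng(config.seed)
    model = FeedForwardNet(config, x_train.shape[1], rng)
    ll_train, ll_val, div = model.fit(x_train, y_train, x_val, y_val)

    p_train = model.predict_proba(x_train)[:, 1]
    p_val = model.predict_proba(x_val)[:, 1]
    thr = config.threshold
    report = ClassifierReport(
        confusion_train=confusion_matrix(y_train, p_train > thr, labels=[0, 1]),
        confusion_val=confusion_matrix(y_val, p_val > thr, labels=[0, 1]),
        auc_train=float(roc_auc_score(y_train, p_train)),
        auc_val=float(roc_auc_score(y_val, p_val)),
        logloss_train=ll_train,
        logloss_val=ll_val,
        divergence_epoch=div,
        train_ids=list(train_ids),
        val_ids=list(val_ids),
    )

    if run_cv and config.cv_folds > 1:
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        x_all = _subset(features, ids)
        for fold, (tr, te) in enumerate(skf.split(x_all, y)):
            fold_rng = np.random.default_rng(config.seed + 1000 + fold)
            m = FeedForwardNet(config, x_all.shape[1], fold_rng)
            m.fit(x_all[tr], y[tr])
            p = m.predict_proba(x_all[te])[:, 1]
            report.auc_cv.append(float(roc_auc_score(y[te], p)))
    return model, report


def predict_unlabeled(
    model: FeedForwardNet,
    features: pd.DataFrame,
    labels: LabelSet,
    threshold: float = 0.5,
) -> tuple[set[str], pd.Series]:
    """Score every unlabeled transcript present in the feature matrix and
    return the ids with P(MIA) above the threshold plus all scores."""
    unl = sorted(labels.unlabeled & set(features.index))
    if not unl:
        return set(), pd.Series(dtype=float)
    p = model.predict_proba(features.loc[unl].values)[:, 1]
    scores = pd.Series(p, index=unl, name="p_mia")
    return set(scores.index[scores > threshold]), scores
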