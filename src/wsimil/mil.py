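"""Attention-based multiple instance learning for 2-/5-year relapse.

Each patient is a bag of patch feature vectors. A shared multilayer
perceptron scores every instance (z_i); a parallel attention branch produces
normalized weights (a_i, sum 1); the bag logit is the attention-weighted sum
of instance scores, squashed through a sigmoid into the relapse probability.
The objective is the Bernoulli negative log-likelihood; the minority
(relapse) class is balanced by resampling before training.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._autodiff import Tensor
from ._nn import (
    Adam,
    Dense,
    bce_with_logits,
    restore,
    segment_softmax,
    segment_sum,
    snapshot,
)
from .bags import InstanceBag, stack_bags

logger = logging.getLogger(__name__)


def label_bags(bags: list[InstanceBag], horizon_days: float) -> list[InstanceBag]:
    """Binary relapse-within-horizon labels.

    Label 1: event observed at or before the horizon. Label 0: followed up
    beyond the horizon. Patients censored before the horizon without an
    event are excluded (their status at the horizon is unknown).
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    labeled = []
    for bag in bags:
        if bag.survival is None:
            raise ValueError(f"bag {bag.patient_id} has no survival data")
        t, e = bag.survival
        if e == 1 and t <= horizon_days:
            label = 1
        elif t > horizon_days:
            label = 0
        else:
            continue  # censored before horizon: outcome unknown
        labeled.append(
            InstanceBag(
                patient_id=bag.patient_id, instances=bag.instances,
                cluster_labels=bag.cluster_labels, label=label,
                time_days=bag.time_days, event=bag.event,
            )
        )
    return labeled


def oversample_minority(
    bags: list[InstanceBag], seed: int = 0
) -> list[InstanceBag]:
    """Balance classes by re-drawing random minority bags (by reference)."""
    labels = np.array([b.label for b in bags])
    if set(labels.tolist()) != {0, 1}:
        raise ValueError("both classes must be present to oversample")
    n0, n1 = int((labels == 0).sum()), int((labels == 1).sum())
    if n0 == n1:
        return list(bags)
    minority = 1 if n1 < n0 else 0
    pool = [b for b in bags if b.label == minority]
    rng = np.random.default_rng(seed)
    extra = [pool[i] for i in rng.integers(len(pool), size=abs(n0 - n1))]
    return list(bags) + extra


class AttentionMILClassifier(BaseEstimator, ClassifierMixin):
    """Attention-pooled MIL binary classifier over instance bags.

    ``fit(bags)`` takes :class:`InstanceBag` objects with binary ``label``
    set (or an explicit ``y``). Per-instance scores come from an MLP with
    ``hidden`` layers; attention is the (optionally gated) tanh bottleneck
    form of width ``attention_dim``. Early stopping monitors the Bernoulli
    loss on a stratified inner validation split with ``patience`` epochs of
    tolerance ``tol`` and restores the best weights.
    """

    def __init__(self, hidden: tuple[int, ...] = (64, 32),
                 attention_dim: int = 32, gated: bool = False,
                 lr: float = 5e-3, max_epochs: int = 500, patience: int = 200,
                 tol: float = 1e-5, val_fraction: float = 0.2,
                 oversample: bool = True, random_state: int = 0):
        self.hidden = hidden
        self.attention_dim = attention_dim
        self.gated = gated
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.val_fraction = val_fraction
        self.oversample = oversample
        self.random_state = random_state

    # -- architecture ---------------------------------------------------
    def _init_params(self, m: int, rng: np.random.Generator) -> None:
        sizes = (m, *self.hidden)
        self.mlp_ = [Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        h_last = sizes[-1]
        self.score_ = Dense(h_last, 1, rng)
        self.attV_ = Dense(h_last, self.attention_dim, rng)
        self.attU_ = Dense(h_last, self.attention_dim, rng) if self.gated else None
        self.attw_ = Dense(self.attention_dim, 1, rng)
        self.params_ = [p for layer in self.mlp_ for p in layer.parameters()]
        self.params_ += self.score_.parameters() + self.attV_.parameters()
        self.params_ += self.attw_.parameters()
        if self.attU_ is not None:
            self.params_ += self.attU_.parameters()

    def _forward_stacked(
        self, X: np.ndarray, bag_ids: np.ndarray, n_bags: int
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Vectorized forward over stacked instances -> (logits, a, z)."""
        h = Tensor(X)
        for layer in self.mlp_:
            h = layer(h).relu()
        z = self.score_(h)
        gate = self.attV_(h).tanh()
        if self.attU_ is not None:
            gate = gate * self.attU_(h).sigmoid()
        e = self.attw_(gate)
        a = segment_softmax(e, bag_ids, n_bags)
        logits = segment_sum(a * z, bag_ids, n_bags).reshape(-1)
        return logits, a, z

    def forward_bag(self, bag: InstanceBag) -> tuple[float, np.ndarray, np.ndarray]:
        """(p, attention weights, instance scores) for one bag."""
        X = bag.instances
        logits, a, z = self._forward_stacked(
            X, np.zeros(len(X), dtype=np.int64), 1
        )
        p = float(Tensor(logits.data).sigmoid().data[0])
        return p, a.data[:, 0].copy(), z.data[:, 0].copy()

    # -- training ---------------------------------------------------------
    def fit(self, bags: list[InstanceBag], y=None) -> "AttentionMILClassifier":
        if y is not None:
            bags = [
                InstanceBag(b.patient_id, b.instances, b.cluster_labels,
                            label=int(lbl), time_days=b.time_days, event=b.event)
                for b, lbl in zip(bags, y)
            ]
        labels = np.array([b.label for b in bags])
        if any(l is None for l in labels):
            raise ValueError("bags must carry binary labels")
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.random_state)
        m = bags[0].n_features
        self._init_params(m, rng)

        idx = np.arange(len(bags))
        use_val = (0.0 < self.val_fraction < 1.0 and len(bags) >= 10
                   and labels.sum() >= 2 and (1 - labels).sum() >= 2)
        if use_val:
            tr_idx, va_idx = train_test_split(
                idx, test_size=self.val_fraction, stratify=labels,
                random_state=int(rng.integers(2**31 - 1)),
            )
        else:
            tr_idx, va_idx = idx, idx
        tr_bags = [bags[i] for i in tr_idx]
        if self.oversample and len(set(labels[tr_idx].tolist())) == 2:
            tr_bags = oversample_minority(tr_bags, seed=int(rng.integers(2**31 - 1)))
        Xtr, ids_tr = stack_bags(tr_bags)
        ytr = np.array([b.label for b in tr_bags], dtype=np.float64)
        Xva, ids_va = stack_bags([bags[i] for i in va_idx])
        yva = labels[va_idx].astype(np.float64)

        opt = Adam(self.params_, lr=self.lr)
        best_loss, best_epoch = np.inf, -1
        best_weights = snapshot(self.params_)
        self.history_ = []
        for epoch in range(self.max_epochs):
            opt.zero_grad()
            logits, _, _ = self._forward_stacked(Xtr, ids_tr, len(tr_bags))
            loss = bce_with_logits(logits, ytr)
            loss.backward()
            opt.step()
            vlogits, _, _ = self._forward_stacked(Xva, ids_va, len(yva))
            val_loss = float(bce_with_logits(Tensor(vlogits.data), yva).data)
            self.history_.append({"epoch": epoch, "train_loss": float(loss.data),
                                  "val_loss": val_loss})
            if val_loss < best_loss - self.tol:
                best_loss, best_epoch = val_loss, epoch
                best_weights = snapshot(self.params_)
            elif epoch - best_epoch >= self.patience:
                break
        restore(self.params_, best_weights)
        self.stopped_epoch_ = self.history_[-1]["epoch"]
        self.best_epoch_ = best_epoch
        self.n_features_in_ = m
        return self

    def predict_proba(self, bags: list[InstanceBag]) -> np.ndarray:
        X, ids = stack_bags(bags)
        logits, _, _ = self._forward_stacked(X, ids, len(bags))
        p = 1.0 / (1.0 + np.exp(-logits.data))
        return np.column_stack([1.0 - p, p])

    def predict(self, bags: list[InstanceBag]) -> np.ndarray:
        return (self.predict_proba(bags)[:, 1] >= 0.5).astype(int)

    def attention_frame(self, bags: list[InstanceBag]) -> pd.DataFrame:
        """Per-patch attention export (patient_id, instance index, a, z)."""
        rows = []
        for bag in bags:
            _, a, z = self.forward_bag(bag)
            for i, (ai, zi) in enumerate(zip(a, z)):
                rows.append({"patient_id": bag.patient_id, "instance": i,
                             "attention": ai, "score": zi})
        return pd.DataFrame(rows)


def train_mil(
    bags: list[InstanceBag], horizon_days: float, k: int = 5, seed: int = 0,
    **model_params,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k-fold cross-validated MIL for one horizon.

    Bags are labeled against ``horizon_days`` (censored-before-horizon
    patients excluded), folds stratified by label. Returns (out-of-fold
    prediction table, per-fold metrics).
    """
    labeled = label_bags(bags, horizon_days)
    labels = np.array([b.label for b in labeled])
    if len(labeled) < k:
        raise ValueError(f"need at least {k} labeled bags for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, fold_rows = [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labeled)), labels)):
        if len(set(labels[tr].tolist())) < 2:
            logger.warning("fold %d has a single-class training set; skipped", fold)
            continue
        model = AttentionMILClassifier(random_state=seed * 1000 + fold, **model_params)
        model.fit([labeled[i] for i in tr])
        p = model.predict_proba([labeled[i] for i in te])[:, 1]
        yhat = (p >= 0.5).astype(int)
        fold_rows.append({
            "fold": fold,
            "accuracy": accuracy_score(labels[te], yhat),
            "f1": f1_score(labels[te], yhat, zero_division=0.0),
            "stopped_epoch": model.stopped_epoch_,
        })
        for i, pi in zip(te, p):
            rows.append({"patient_id": labeled[i].patient_id, "fold": fold,
                         "horizon_days": horizon_days, "p": float(pi),
                         "label": int(labels[i])})
    return pd.DataFrame(rows), pd.DataFrame(fold_rows)


def evaluate_classification(p, labels, threshold: float = 0.5) -> dict:
    """F1 (positive class) and accuracy of thresholded probabilities."""
    p = np.asarray(p, dtype=np.float64)
    labels = np.asarray(labels)
    yhat = (p >= threshold).astype(int)
    out = {"accuracy": float(accuracy_score(labels, yhat))}
    if len(set(labels.tolist())) < 2 and labels.sum() == 0:
        out["f1"] = float("nan")  # no positive ground truth: F1 undefined
    else:
        out["f1"] = float(f1_score(labels, yhat, zero_division=0.0))
    return out
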