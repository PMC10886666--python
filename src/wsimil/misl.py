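"""Multiple instance survival learning (MISL) with a Cox partial-likelihood loss.

The model aggregates a patient's patch feature vectors within each
stroma/epithelium composition cluster (C1/C2/C3) by learned attention into
one vector per cluster, scores each cluster vector, and combines the cluster
scores through a second attention layer into a single unbounded log-risk per
patient. Training minimizes the Breslow negative partial log-likelihood over
a survival-matrix-oversampled replicate stream: the cohort's follow-up axis
is discretized into ``tstep``-day columns and every (patient, timestep) cell
contributes one training replicate, so patients with short survival are seen
as often as fully followed-up ones.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _ll_concordance
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._autodiff import Tensor
from ._nn import Adam, Dense, restore, segment_softmax, segment_sum, snapshot
from .bags import CLUSTERS, InstanceBag

logger = logging.getLogger(__name__)

# Survival-matrix cell statuses.
STATUS_LEFT_CENSORED = 0  # under observation, event not yet occurred
STATUS_EVENT = 1
STATUS_RIGHT_CENSORED = 2


@dataclass
class SurvivalMatrix:
    """m x n patient-by-timestep status grid used for MISL oversampling."""

    statuses: np.ndarray  # (m, n) of STATUS_* values
    tmax: float
    tstep: float
    patient_order: list[str]

    @property
    def timesteps(self) -> np.ndarray:
        """Day value of each column: tstep, 2*tstep, ..., n*tstep."""
        return (np.arange(self.statuses.shape[1]) + 1) * self.tstep


def build_survival_matrix(
    times, events, patient_ids=None, tstep: float = 30.0
) -> SurvivalMatrix:
    """Discretize follow-up into ``tstep``-day columns of survival statuses.

    Follow-up is artificially extended to the cohort's longest time (tmax):
    columns strictly before a patient's observed time are "left-censored"
    (still event-free); columns at or after it carry the terminal status
    (event or right-censored).
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if times.size == 0:
        raise ValueError("cohort is empty")
    if np.any(times <= 0):
        raise ValueError("all survival times must be positive")
    if patient_ids is None:
        patient_ids = [f"P{i}" for i in range(times.size)]
    tmax = float(times.max())
    n_cols = int(math.ceil(tmax / tstep))
    col_times = (np.arange(n_cols) + 1) * tstep
    statuses = np.empty((times.size, n_cols), dtype=np.int8)
    for i, (t, e) in enumerate(zip(times, events)):
        pre = col_times < t
        statuses[i, pre] = STATUS_LEFT_CENSORED
        statuses[i, ~pre] = STATUS_EVENT if e == 1 else STATUS_RIGHT_CENSORED
    return SurvivalMatrix(statuses=statuses, tmax=tmax, tstep=float(tstep),
                          patient_order=list(patient_ids))


def matrix_to_training_samples(
    matrix: SurvivalMatrix, bags: list[InstanceBag] | None = None
) -> pd.DataFrame:
    """One training replicate per (patient, timestep) cell.

    Each replicate carries the cell's timestep day as its working time and
    the cell's status collapsed to an event indicator (only ``event`` cells
    count as events; both censoring flavors are non-events at that time).
    """
    if bags is not None:
        bag_ids = [b.patient_id for b in bags]
        if bag_ids != list(matrix.patient_order):
            raise RuntimeError("bags and survival matrix list different patients")
    m, n = matrix.statuses.shape
    col_times = matrix.timesteps
    rows = {
        "patient_index": np.repeat(np.arange(m), n),
        "patient_id": np.repeat(np.asarray(matrix.patient_order, dtype=object), n),
        "time_days": np.tile(col_times, m),
        "status": matrix.statuses.ravel(),
    }
    frame = pd.DataFrame(rows)
    frame["event"] = (frame["status"] == STATUS_EVENT).astype(np.int64)
    return frame


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties) and concordance
# ---------------------------------------------------------------------------

def _cox_loss_tensor(risks: Tensor, times: np.ndarray, events: np.ndarray) -> Tensor:
    """Breslow negative partial log-likelihood as an autodiff Tensor.

    loss = -sum_{i: event} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.float64)
    if events.sum() == 0:
        raise ValueError("Cox partial likelihood requires at least one event")
    order = np.argsort(-times, kind="stable")
    t_s = times[order]
    ev_s = events[order]
    # risk set of i = everything up to the end of i's tie group (descending order)
    tie_end = np.searchsorted(-t_s, -t_s, side="right") - 1
    shift = float(np.max(risks.data))
    r_s = risks.reshape(-1).take(order)
    csum = (r_s - shift).exp().cumsum(axis=0)
    log_denom = csum.take(tie_end).log() + shift
    return -((r_s - log_denom) * Tensor(ev_s)).sum()


def cox_loss(risks, times, events) -> float:
    """Breslow negative partial log-likelihood of ``risks`` (numpy scalar)."""
    t = Tensor(np.asarray(risks, dtype=np.float64).reshape(-1))
    return float(_cox_loss_tensor(t, np.asarray(times), np.asarray(events)).data)


def concordance_index(risks, times, events) -> float:
    """Fraction of comparable pairs ordered consistently: higher risk, shorter
    survival. Ties in risk count 0.5. Returns NaN if no pair is comparable."""
    risks = np.asarray(risks, dtype=np.float64)
    try:
        return float(_ll_concordance(np.asarray(times), -risks, np.asarray(events)))
    except ZeroDivisionError:
        warnings.warn("no comparable pairs; concordance index undefined")
        return float("nan")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _BagBatch:
    """Pre-stacked arrays for a vectorized forward over a set of bags."""

    def __init__(self, bags: list[InstanceBag]):
        segs = {}  # (bag_idx, cluster) -> segment index
        inst_seg = []
        X_rows = []
        for bi, bag in enumerate(bags):
            labels = bag.cluster_labels or ["C2"] * bag.n_instances
            for x, cl in zip(bag.instances, labels):
                key = (bi, cl)
                if key not in segs:
                    segs[key] = len(segs)
                inst_seg.append(segs[key])
                X_rows.append(x)
        self.X = Tensor(np.asarray(X_rows))
        self.inst_seg = np.asarray(inst_seg, dtype=np.int64)
        self.n_seg = len(segs)
        self.seg_bag = np.empty(self.n_seg, dtype=np.int64)
        for (bi, _), si in segs.items():
            self.seg_bag[si] = bi
        self.n_bags = len(bags)


class MISLRiskRegressor(BaseEstimator):
    """Cluster-attention multiple instance survival learner.

    Parameters
    ----------
    hidden : width of the cluster scorer's hidden layer.
    attention_dim : width of both attention layers' tanh bottleneck.
    tstep : survival-matrix column width in days.
    batch_cells : survival-matrix replicates per gradient step.
    patience : epochs without validation-loss improvement (> tol) before
        stopping; best weights are restored.
    val_fraction : fraction of training patients held out (stratified by
        event) for early stopping.

    Attributes
    ----------
    history_ : per-epoch training log (loss, validation loss, validation
        concordance index).
    """

    def __init__(self, hidden: int = 32, attention_dim: int = 16,
                 lr: float = 5e-3, max_epochs: int = 300, patience: int = 50,
                 tol: float = 1e-5, val_fraction: float = 0.2,
                 tstep: float = 30.0, batch_cells: int = 2048,
                 random_state: int = 0):
        self.hidden = hidden
        self.attention_dim = attention_dim
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.val_fraction = val_fraction
        self.tstep = tstep
        self.batch_cells = batch_cells
        self.random_state = random_state

    # -- forward -------------------------------------------------------
    def _forward(self, batch: _BagBatch) -> Tensor:
        e_i = (batch.X @ self.Vi_.weight + self.Vi_.bias).tanh() @ self.wi_.weight + self.wi_.bias
        a_i = segment_softmax(e_i, batch.inst_seg, batch.n_seg)
        cluster_vecs = segment_sum(a_i * batch.X, batch.inst_seg, batch.n_seg)
        s_c = self.score2_((self.score1_(cluster_vecs)).relu())
        e_c = (cluster_vecs @ self.Vc_.weight + self.Vc_.bias).tanh() @ self.wc_.weight + self.wc_.bias
        a_c = segment_softmax(e_c, batch.seg_bag, batch.n_bags)
        risks = segment_sum(a_c * s_c, batch.seg_bag, batch.n_bags)
        return risks.reshape(-1)

    def _init_params(self, m: int, rng: np.random.Generator) -> None:
        a, h = self.attention_dim, self.hidden
        self.Vi_ = Dense(m, a, rng)
        self.wi_ = Dense(a, 1, rng)
        self.score1_ = Dense(m, h, rng)
        self.score2_ = Dense(h, 1, rng)
        self.Vc_ = Dense(m, a, rng)
        self.wc_ = Dense(a, 1, rng)
        self.params_ = (self.Vi_.parameters() + self.wi_.parameters()
                        + self.score1_.parameters() + self.score2_.parameters()
                        + self.Vc_.parameters() + self.wc_.parameters())

    def _eval_loss(self, batch: _BagBatch, times, events) -> tuple[float, float]:
        risks = self._forward(batch)
        c = concordance_index(risks.data, times, events)
        if np.sum(events) == 0:
            return float("nan"), c
        loss = _cox_loss_tensor(risks, times, events).data / max(np.sum(events), 1)
        return float(loss), c

    # -- fit -----------------------------------------------------------
    def fit(self, bags: list[InstanceBag], y=None) -> "MISLRiskRegressor":
        if any(b.survival is None for b in bags):
            raise ValueError("every bag needs (time_days, event) survival data")
        rng = np.random.default_rng(self.random_state)
        m = bags[0].n_features
        self._init_params(m, rng)

        times = np.array([b.time_days for b in bags], dtype=np.float64)
        events = np.array([b.event for b in bags], dtype=np.int64)

        idx = np.arange(len(bags))
        use_val = 0.0 < self.val_fraction < 1.0 and len(bags) >= 10 and events.sum() >= 2
        if use_val:
            tr_idx, va_idx = train_test_split(
                idx, test_size=self.val_fraction, stratify=events,
                random_state=int(rng.integers(2**31 - 1)),
            )
            if events[va_idx].sum() == 0:  # pragma: no cover - stratify prevents
                use_val = False
        if not use_val:
            tr_idx, va_idx = idx, idx

        tr_bags = [bags[i] for i in tr_idx]
        tr_batch = _BagBatch(tr_bags)
        va_batch = _BagBatch([bags[i] for i in va_idx])
        va_times, va_events = times[va_idx], events[va_idx]

        matrix = build_survival_matrix(
            times[tr_idx], events[tr_idx],
            [b.patient_id for b in tr_bags], tstep=self.tstep,
        )
        reps = matrix_to_training_samples(matrix, tr_bags)
        rep_patient = reps["patient_index"].to_numpy()
        rep_time = reps["time_days"].to_numpy()
        rep_event = reps["event"].to_numpy()
        n_reps = len(reps)

        opt = Adam(self.params_, lr=self.lr)
        # model selection on the validation concordance index (the training
        # metric of the survival learner); validation loss is logged as well
        best_c, best_epoch = -np.inf, -1
        best_weights = snapshot(self.params_)
        self.history_ = []
        for epoch in range(self.max_epochs):
            perm = rng.permutation(n_reps)
            epoch_losses = []
            for start in range(0, n_reps, self.batch_cells):
                sel = perm[start : start + self.batch_cells]
                if rep_event[sel].sum() == 0:
                    logger.warning("skipping batch with no events (epoch %d)", epoch)
                    continue
                opt.zero_grad()
                risks = self._forward(tr_batch)
                r_sel = risks.take(rep_patient[sel])
                loss = _cox_loss_tensor(r_sel, rep_time[sel], rep_event[sel])
                loss = loss / float(rep_event[sel].sum())
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            val_loss, val_c = self._eval_loss(va_batch, va_times, va_events)
            self.history_.append(
                {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan,
                 "val_loss": val_loss, "val_c_index": val_c}
            )
            if val_c > best_c + self.tol:
                best_c, best_epoch = val_c, epoch
                best_weights = snapshot(self.params_)
            elif epoch - best_epoch >= self.patience:
                break
        restore(self.params_, best_weights)
        self.stopped_epoch_ = self.history_[-1]["epoch"]
        self.best_epoch_ = best_epoch
        self.n_features_in_ = m
        # reference level so out-of-fold risks from different folds share a scale
        self.train_risk_mean_ = float(np.mean(self._forward(tr_batch).data))
        return self

    def predict(self, bags: list[InstanceBag]) -> np.ndarray:
        """Centered log-risk per patient (higher = earlier expected relapse)."""
        risks = self._forward(_BagBatch(bags)).data
        return risks - self.train_risk_mean_

    def score(self, bags: list[InstanceBag], y=None) -> float:
        times = np.array([b.time_days for b in bags])
        events = np.array([b.event for b in bags])
        return concordance_index(self.predict(bags), times, events)


def train_misl(
    bags: list[InstanceBag], k: int = 3, seed: int = 0, **model_params
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k-fold cross-validated MISL; every patient gets one out-of-fold risk.

    Returns (risk table, per-fold metrics). Folds are stratified by the event
    indicator; a fold without events is rejected and the split is redrawn
    with a shifted seed.
    """
    events = np.array([b.event for b in bags], dtype=np.int64)
    if len(bags) < k:
        raise ValueError(f"need at least {k} bags for {k}-fold CV")
    if events.sum() == 0:
        raise ValueError("cohort has no events; survival learning is impossible")
    for attempt in range(20):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(bags)), events))
        if all(events[tr].sum() > 0 for tr, te in splits):
            if attempt:
                logger.warning("fold without training events; resampled split "
                               "(attempt %d)", attempt)
            break
    else:  # pragma: no cover
        raise RuntimeError("could not build folds with training events")

    rows, fold_rows = [], []
    for fold, (tr, te) in enumerate(splits):
        model = MISLRiskRegressor(random_state=seed * 1000 + fold, **model_params)
        model.fit([bags[i] for i in tr])
        risks = model.predict([bags[i] for i in te])
        c = concordance_index(
            risks, [bags[i].time_days for i in te], [bags[i].event for i in te]
        )
        fold_rows.append({"fold": fold, "c_index": c,
                          "stopped_epoch": model.stopped_epoch_,
                          "best_epoch": model.best_epoch_})
        for i, r in zip(te, risks):
            rows.append({"patient_id": bags[i].patient_id, "fold": fold,
                         "risk": float(r), "time_days": bags[i].time_days,
                         "event": bags[i].event})
    risk_df = pd.DataFrame(rows)
    return risk_df, pd.DataFrame(fold_rows)
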