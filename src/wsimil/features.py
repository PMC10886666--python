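"""Self-supervised patch-identity feature learning.

The pretext task: a small CNN must assign every 256-px patch to the slide
(patient) it was sampled from. Training data are edge-adjacent patch pairs;
one member of each pair trains the network, the other only validates it, so
the train and validation patch sets are disjoint and equally sized. The
activations of the compression layer — the last layer before the decision
layer, realized either as a 1x1 convolution with ``width`` output channels
followed by global average pooling (``conv2d``) or as a fully connected
layer of ``width`` units (``dense``) — are the patch feature vectors used by
all downstream models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._autodiff import Tensor, precision
from ._nn import Adam, Conv2d, Dense, global_avg_pool, restore, snapshot, softmax_cross_entropy

logger = logging.getLogger(__name__)

#: compression widths explored by the sweep
ALLOWED_WIDTHS = (1536, 1024, 512, 256, 128, 64, 32, 16, 8, 4, 2)

#: cap on pairs per slide when "all available" pairs are requested
ALL_PAIRS_CAP = 100


@dataclass
class PatchPair:
    wsi_id: str
    train_patch_id: str
    val_patch_id: str


@dataclass
class EncoderConfig:
    """Configuration of the identity encoder.

    ``n_pairs_per_wsi`` is 3, 10, or "all" (all available adjacent pairs,
    capped at 100). ``input_px`` is the side length patches are
    block-averaged to before entering the CNN — the desk-scale stand-in for
    a full-resolution backbone.
    """

    compression_mode: str = "conv2d"  # "conv2d" | "dense"
    width: int = 64
    n_pairs_per_wsi: int | str = "all"
    input_px: int = 64
    channels: tuple[int, ...] = (16, 32, 64, 96)
    strides: tuple[int, ...] = (2, 2, 2, 1)
    epochs: int = 40
    lr: float = 2e-3
    batch_size: int = 64
    augment: bool = True  # random dihedral flips of training patches
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width not in ALLOWED_WIDTHS:
            raise ValueError(f"width must be one of {ALLOWED_WIDTHS}")
        if self.compression_mode not in ("conv2d", "dense"):
            raise ValueError("compression_mode must be 'conv2d' or 'dense'")
        if self.n_pairs_per_wsi != "all" and int(self.n_pairs_per_wsi) < 1:
            raise ValueError("n_pairs_per_wsi must be positive or 'all'")


def sample_pairs(
    manifest: pd.DataFrame, n_pairs_per_wsi: int | str = "all", seed: int = 0
) -> list[PatchPair]:
    """Sample edge-adjacent 256-px patch pairs per slide.

    Adjacency is the 4-neighborhood on the 256-px grid. Pairs are a seeded
    maximal matching (no patch appears in two pairs), so assigning one
    member of each pair to the training split and the other to validation
    keeps the splits disjoint with a 1:1 size ratio. Requests beyond the
    available pairs fall back to all available; slides with no adjacent
    retained patches are logged and skipped.
    """
    rng = np.random.default_rng(seed)
    want = ALL_PAIRS_CAP if n_pairs_per_wsi == "all" else int(n_pairs_per_wsi)
    leaves = manifest[manifest["level_px"] == 256]
    pairs: list[PatchPair] = []
    for wsi_id, group in leaves.groupby("wsi_id", sort=True):
        coords = {}
        for row in group.itertuples(index=False):
            coords[(int(row.row), int(row.col))] = row.patch_id
        edges = []
        for (r, c), pid in coords.items():
            for dr, dc in ((0, 256), (256, 0)):
                other = coords.get((r + dr, c + dc))
                if other is not None:
                    edges.append((pid, other))
        if not edges:
            logger.warning("slide %s has no adjacent retained patches; skipped", wsi_id)
            continue
        rng.shuffle(edges)
        used: set[str] = set()
        taken = 0
        for a, b in edges:
            if taken >= want:
                break
            if a in used or b in used:
                continue
            used.update((a, b))
            if rng.uniform() < 0.5:
                a, b = b, a
            pairs.append(PatchPair(wsi_id=wsi_id, train_patch_id=a, val_patch_id=b))
            taken += 1
    return pairs


def _block_average(images: np.ndarray, out_px: int) -> np.ndarray:
    """(n, s, s, 3) uint8 -> (n, 3, out_px, out_px) float in [-1, 1]."""
    n, s, _, c = images.shape
    if s % out_px:
        raise ValueError(f"patch side {s} not divisible by {out_px}")
    f = s // out_px
    x = images.reshape(n, out_px, f, out_px, f, c).mean(axis=(2, 4))
    return (x.transpose(0, 3, 1, 2).astype(np.float64) - 127.5) / 127.5


class IdentityEncoder(BaseEstimator, TransformerMixin):
    """CNN trained on the slide-identity pretext task; ``transform`` emits
    the compression-layer activations as patch features.

    ``fit(X, y)`` takes patch images (n, s, s, 3) uint8 with integer slide
    identities ``y``; ``transform(X)`` returns (n, width) features.
    """

    def __init__(self, config: EncoderConfig | None = None):
        self.config = config

    # -- internals -----------------------------------------------------
    def _build(self, n_identities: int, rng: np.random.Generator) -> None:
        cfg = self.config_
        chans = (3, *cfg.channels)
        strides = cfg.strides
        self.convs_ = [
            Conv2d(chans[i], chans[i + 1], kernel=3, stride=strides[i], rng=rng)
            for i in range(4)
        ]
        px = cfg.input_px
        for s in strides:
            px = (px - 3) // s + 1
        self._map_px = px
        if cfg.compression_mode == "conv2d":
            self.compress_ = Conv2d(cfg.channels[-1], cfg.width, kernel=1, stride=1, rng=rng)
        else:
            self.compress_ = Dense(cfg.channels[-1] * px * px, cfg.width, rng)
        self.head_ = Dense(cfg.width, n_identities, rng)
        self.params_ = [p for c in self.convs_ for p in c.parameters()]
        self.params_ += self.compress_.parameters() + self.head_.parameters()

    def _features_tensor(self, x: np.ndarray) -> Tensor:
        h = Tensor(x)
        for conv in self.convs_:
            h = conv(h).relu()
        if self.config_.compression_mode == "conv2d":
            return global_avg_pool(self.compress_(h))
        n = h.shape[0]
        flat = h.reshape(n, -1)
        return self.compress_(flat)

    # -- sklearn surface -----------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "IdentityEncoder":
        self.config_ = self.config if self.config is not None else EncoderConfig()
        y = np.asarray(y, dtype=np.int64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("the identity task needs at least two slides")
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)
        rng = np.random.default_rng(self.config_.seed)
        with precision("float32"):  # single precision: ample for this task
            self._fit_impl(X, y_idx, classes, rng)
        self.n_identities_ = int(classes.size)
        return self

    def _fit_impl(self, X, y_idx, classes, rng) -> None:
        self._build(classes.size, rng)
        x = _block_average(np.asarray(X), self.config_.input_px)
        n = x.shape[0]
        opt = Adam(self.params_, lr=self.config_.lr)
        self.history_ = []
        for epoch in range(self.config_.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.config_.batch_size):
                sel = perm[start : start + self.config_.batch_size]
                xb = x[sel]
                if self.config_.augment:
                    if rng.uniform() < 0.5:
                        xb = xb[:, :, ::-1, :]
                    if rng.uniform() < 0.5:
                        xb = xb[:, :, :, ::-1]
                    if rng.uniform() < 0.5:
                        xb = xb.transpose(0, 1, 3, 2)
                    xb = np.ascontiguousarray(xb)
                opt.zero_grad()
                feats = self._features_tensor(xb)
                logits = self.head_(feats)
                loss = softmax_cross_entropy(logits, y_idx[sel])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.history_.append({"epoch": epoch, "train_loss": float(np.mean(losses))})

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Deterministic feature vectors (n, width) for patch images."""
        with precision("float32"):
            x = _block_average(np.asarray(X), self.config_.input_px)
            out = np.empty((x.shape[0], self.config_.width))
            for start in range(0, x.shape[0], 256):
                out[start : start + 256] = self._features_tensor(x[start : start + 256]).data
        return out

    def predict_identity(self, X: np.ndarray) -> np.ndarray:
        """Predicted slide identity labels (values from ``classes_``)."""
        with precision("float32"):
            x = _block_average(np.asarray(X), self.config_.input_px)
            preds = np.empty(x.shape[0], dtype=np.int64)
            for start in range(0, x.shape[0], 256):
                logits = self.head_(self._features_tensor(x[start : start + 256])).data
                preds[start : start + 256] = np.argmax(logits, axis=1)
        return self.classes_[preds]


def pairing_accuracy(encoder: IdentityEncoder, X_val: np.ndarray, y_val: np.ndarray) -> float:
    """Top-1 identity accuracy on held-out pair members."""
    y_val = np.asarray(y_val)
    if y_val.size == 0:
        raise ValueError("validation set is empty")
    return float(np.mean(encoder.predict_identity(X_val) == y_val))


def extract_features(encoder: IdentityEncoder, patches: np.ndarray) -> np.ndarray:
    """Feature vectors for an array of (resized-to-256) patch images."""
    return encoder.transform(patches)


# ---------------------------------------------------------------------------
# Feature store
# ---------------------------------------------------------------------------

def save_feature_store(
    path: str | Path, features: dict[str, np.ndarray]
) -> None:
    """Persist patch features: one .npz of arrays plus a patch-id manifest CSV.

    Round-trips bit-exactly (float64, uncompressed container).
    """
    path = Path(path)
    ids = sorted(features)
    arr = np.asarray([features[i] for i in ids], dtype=np.float64)
    np.savez(path.with_suffix(".npz"), features=arr)
    pd.DataFrame({"patch_id": ids}).to_csv(path.with_suffix(".csv"), index=False)


def load_feature_store(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    arr = np.load(path.with_suffix(".npz"))["features"]
    ids = pd.read_csv(path.with_suffix(".csv"))["patch_id"].astype(str).tolist()
    return {pid: arr[i] for i, pid in enumerate(ids)}
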