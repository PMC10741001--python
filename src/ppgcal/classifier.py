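"""Two-class image classifier for scalograms.

Two families of backbone sit behind one interface:

* ``tiny-test-cnn`` — a scratch convolutional network implemented here in
  numpy (8x average-pool to 28x28, one 3x3 conv with 8 filters, ReLU,
  2x2 max-pool, one hidden fully connected layer, softmax head), trained
  with Adam, mini-batches and early stopping on validation loss with
  best-weights restoration.  It is small enough to train on a CPU in
  seconds and is the backbone the test suite and desk-scale experiments
  use.
* ``googlenet`` / ``resnet18`` / ``resnet50`` — torchvision backbones with
  the final classification stage replaced by a fresh 2-class head, for
  paper-scale runs.  They require the optional ``torch``/``torchvision``
  dependency and raise an informative error when it is absent.

Labels: HTS is the positive class (index 1); argmax ties break toward NTS.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import NTS, HTS

logger = logging.getLogger(__name__)

LABELS = (NTS, HTS)  # class index 0, 1
TORCH_BACKBONES = ("googlenet", "resnet18", "resnet50")


@dataclass
class TrainConfig:
    backbone: str = "tiny-test-cnn"
    n_classes: int = 2
    initial_lr: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 20
    #: early stopping patience, counted in validation checks (one per epoch)
    patience: int = 3
    seed: int = 0
    #: fine-tune all layers (torch backbones); freeze_features=True trains
    #: only the replaced head
    freeze_features: bool = False

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


def desk_scale_config(seed: int = 0) -> TrainConfig:
    """Desk-scale settings for the scratch tiny CNN: smaller batches and a
    learning rate appropriate for training from scratch (1e-3; the 1e-4
    default targets fine-tuning of pretrained weights)."""
    return TrainConfig(backbone="tiny-test-cnn", initial_lr=1e-3,
                       batch_size=32, seed=seed)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    epochs_completed: int = 0
    stop_reason: str = ""
    best_epoch: int = 0


# ---------------------------------------------------------------------------
# tiny-test-cnn (numpy)

_POOL_IN = 224
_POOL_FACTOR = 8
_SIDE = _POOL_IN // _POOL_FACTOR  # 28
_N_FILT = 8
_CONV_OUT = _SIDE - 2  # valid 3x3 conv -> 26
_POOLED = _CONV_OUT // 2  # 13
_FLAT = _POOLED * _POOLED * _N_FILT
_HIDDEN = 32


class TinyCNN:
    """Scratch numpy CNN accepting uint8 images of shape (N, 224, 224, 3)."""

    input_shape = (_POOL_IN, _POOL_IN, 3)

    def __init__(self, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        he = lambda fan_in, *shape: rng.normal(0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "Wc": he(27, _N_FILT, 27),  # 3x3x3 patches -> 8 filters
            "bc": np.zeros(_N_FILT),
            "W1": he(_FLAT, _FLAT, _HIDDEN),
            "b1": np.zeros(_HIDDEN),
            "W2": he(_HIDDEN, _HIDDEN, n_classes),
            "b2": np.zeros(n_classes),
        }
        self.n_classes = n_classes
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward pieces ----------------------------------------------------
    @staticmethod
    def _prepare(images: np.ndarray) -> np.ndarray:
        """uint8 (N,224,224,3) -> standardized float (N,28,28,3)."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (_POOL_IN, _POOL_IN, 3):
            raise ValueError(
                f"expected images of shape (N, {_POOL_IN}, {_POOL_IN}, 3), "
                f"got {x.shape}"
            )
        x = x.astype(np.float64) / 255.0
        n = x.shape[0]
        x = x.reshape(n, _SIDE, _POOL_FACTOR, _SIDE, _POOL_FACTOR, 3)
        x = x.mean(axis=(2, 4))
        # per-batch, per-channel standardization (scratch backbone)
        mu = x.mean(axis=(0, 1, 2), keepdims=True)
        sd = x.std(axis=(0, 1, 2), keepdims=True) + 1e-8
        return (x - mu) / sd

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        """(N,28,28,3) -> (N, 26, 26, 27) of 3x3x3 patches."""
        n = x.shape[0]
        s0, s1, s2, s3 = x.strides
        patches = np.lib.stride_tricks.as_strided(
            x, shape=(n, _CONV_OUT, _CONV_OUT, 3, 3, 3),
            strides=(s0, s1, s2, s1, s2, s3), writeable=False,
        )
        return patches.reshape(n, _CONV_OUT, _CONV_OUT, 27)

    def _forward(self, images: np.ndarray, want_cache: bool = False):
        x = self._prepare(images)
        n = x.shape[0]
        cols = self._im2col(x)  # (N,26,26,27)
        conv = cols @ self.params["Wc"].T + self.params["bc"]  # (N,26,26,8)
        relu1 = np.maximum(conv, 0.0)
        # 2x2 max pool
        r = relu1.reshape(n, _POOLED, 2, _POOLED, 2, _N_FILT)
        pooled = r.max(axis=(2, 4))  # (N,13,13,8)
        flat = pooled.reshape(n, _FLAT)
        h = flat @ self.params["W1"] + self.params["b1"]
        relu2 = np.maximum(h, 0.0)
        logits = relu2 @ self.params["W2"] + self.params["b2"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if not want_cache:
            return probs
        cache = dict(cols=cols, conv=conv, r=r, pooled=pooled, flat=flat,
                     h=h, relu2=relu2, probs=probs, n=n)
        return probs, cache

    def predict_proba(self, images: np.ndarray,
                      chunk: int = 256) -> np.ndarray:
        """Probabilities in chunks to bound the float64 working set."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        return np.concatenate(
            [self._forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
        )

    # -- backward / optimizer ---------------------------------------------
    def _backward(self, cache: dict, y: np.ndarray) -> dict:
        n = cache["n"]
        dlogits = cache["probs"].copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {}
        grads["W2"] = cache["relu2"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        drelu2 = dlogits @ self.params["W2"].T
        dh = drelu2 * (cache["h"] > 0)
        grads["W1"] = cache["flat"].T @ dh
        grads["b1"] = dh.sum(axis=0)
        dflat = dh @ self.params["W1"].T
        dpooled = dflat.reshape(n, _POOLED, _POOLED, _N_FILT)
        # route gradient through the max locations
        r = cache["r"]  # (N,13,2,13,2,8)
        maxes = dpooled[:, :, None, :, None, :]
        mask = (r == r.max(axis=(2, 4), keepdims=True))
        # split ties evenly so the gradient stays well-defined
        mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        drelu1 = (mask * maxes).reshape(n, _CONV_OUT, _CONV_OUT, _N_FILT)
        dconv = drelu1 * (cache["conv"] > 0)
        dconv2 = dconv.reshape(-1, _N_FILT)
        cols2 = cache["cols"].reshape(-1, 27)
        grads["Wc"] = dconv2.T @ cols2
        grads["bc"] = dconv2.sum(axis=0)
        return grads

    def adam_step(self, grads: dict, lr: float,
                  beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_step(self, images: np.ndarray, y: np.ndarray, lr: float) -> float:
        probs, cache = self._forward(images, want_cache=True)
        n = len(y)
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        self.adam_step(self._backward(cache, y), lr)
        return float(loss)

    def get_weights(self) -> dict:
        return copy.deepcopy(self.params)

    def set_weights(self, weights: dict) -> None:
        self.params = copy.deepcopy(weights)


class _TorchBackbone:
    """Thin adapter for torchvision backbones with a replaced 2-class head."""

    def __init__(self, name: str, n_classes: int, seed: int,
                 pretrained: bool = False, freeze_features: bool = False):
        try:
            import torch
            import torchvision.models as tvm
        except ImportError as exc:  # pragma: no cover - torch optional
            raise ImportError(
                f"backbone {name!r} requires the optional 'cnn' extra "
                "(torch + torchvision); install ppgcal[cnn] or use the "
                "'tiny-test-cnn' backbone"
            ) from exc
        torch.manual_seed(seed)
        weights = "DEFAULT" if pretrained else None
        model = getattr(tvm, name)(weights=weights)
        import torch.nn as nn
        if freeze_features:
            for p in model.parameters():
                p.requires_grad = False
        # replace the classification head with a fresh 2-class stage
        if hasattr(model, "fc"):
            model.fc = nn.Linear(model.fc.in_features, n_classes)
        else:  # pragma: no cover
            raise ValueError(f"do not know where the head of {name} lives")
        self.model = model
        self.n_classes = n_classes

    def predict_proba(self, images: np.ndarray) -> np.ndarray:  # pragma: no cover
        import torch
        x = torch.from_numpy(
            np.asarray(images).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
        )
        with torch.no_grad():
            logits = self.model(x)
        return torch.softmax(logits, dim=1).numpy()


def build_model(cfg: TrainConfig):
    """Instantiate the configured backbone with a 2-class softmax head."""
    if cfg.backbone == "tiny-test-cnn":
        return TinyCNN(n_classes=cfg.n_classes, seed=cfg.seed)
    if cfg.backbone in TORCH_BACKBONES:
        return _TorchBackbone(cfg.backbone, cfg.n_classes, cfg.seed,
                              freeze_features=cfg.freeze_features)
    raise ValueError(f"unknown backbone {cfg.backbone!r}; choose one of "
                     f"{('tiny-test-cnn',) + TORCH_BACKBONES}")


def _labels_to_int(labels) -> np.ndarray:
    out = np.asarray([LABELS.index(l) for l in labels], dtype=int)
    return out


def predict(model, images: np.ndarray):
    """Class labels and probability scores for a batch of images.

    Ties in the probability vector break toward NTS (class 0).
    """
    probs = model.predict_proba(images)
    # argmax with ties toward the lower index (NTS): numpy argmax already
    # returns the first maximal index
    idx = np.argmax(probs, axis=1)
    labels = [LABELS[i] for i in idx]
    return labels, probs


def train_model(model, split, cfg: TrainConfig, images: dict[str, np.ndarray]
                ) -> tuple[object, TrainHistory]:
    """Train on a CalibrationSplit's manifests with early stopping.

    ``images`` maps segment_id -> uint8 pixel array.  Validation runs once
    per epoch (i.e. every floor(n_train / batch_size) iterations); early
    stopping triggers after ``cfg.patience`` checks without a new best
    validation loss, and the best-epoch weights are restored.
    """
    if not isinstance(model, TinyCNN):
        raise NotImplementedError(
            "the training loop is implemented for the scratch tiny-test-cnn; "
            "torch backbones are inference adapters here"
        )
    train_man, val_man = split.train_images, split.val_images
    if len(train_man) == 0:
        raise ValueError("empty training set")
    has_val = len(val_man) > 0
    if not has_val:
        logger.warning("empty validation set: training without early stopping")

    X_train = np.stack([images[s] for s in train_man["segment_id"]])
    y_train = _labels_to_int(train_man["label"])
    if has_val:
        X_val = np.stack([images[s] for s in val_man["segment_id"]])
        y_val = _labels_to_int(val_man["label"])

    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    since_best = 0

    n = len(y_train)
    batches = max(n // cfg.batch_size, 1)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for b in range(batches):
            sel = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            if len(sel) == 0:
                continue
            losses.append(model.train_step(X_train[sel], y_train[sel],
                                           cfg.initial_lr))
        tr_probs = model.predict_proba(X_train)
        tr_loss = float(-np.log(tr_probs[np.arange(n), y_train] + 1e-12).mean())
        tr_acc = float((np.argmax(tr_probs, axis=1) == y_train).mean())
        hist.train_loss.append(tr_loss)
        hist.train_acc.append(tr_acc)
        hist.epochs_completed = epoch

        if has_val:
            va_probs = model.predict_proba(X_val)
            va_loss = float(-np.log(
                va_probs[np.arange(len(y_val)), y_val] + 1e-12).mean())
            va_acc = float((np.argmax(va_probs, axis=1) == y_val).mean())
            hist.val_loss.append(va_loss)
            hist.val_acc.append(va_acc)
            if va_loss < best_loss:
                best_loss = va_loss
                best_weights = model.get_weights()
                hist.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    hist.stop_reason = "early_stop"
                    break
    if not hist.stop_reason:
        hist.stop_reason = "max_epochs"
    if has_val:
        model.set_weights(best_weights)
    return model, hist


__all__ = [
    "LABELS", "TORCH_BACKBONES", "TrainConfig", "TrainHistory", "TinyCNN",
    "desk_scale_config", "build_model", "predict", "train_model",
]
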