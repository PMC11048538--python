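"""ResNet-10 / ResNet-18 evaluation classifiers for 32x32 spectrogram images.

Stage layouts follow the tabulated architectures: a 3x3 stem
convolution, residual blocks of two 3x3 convolutions with identity or
stride-2 projection (1x1) shortcuts, global average pooling and a 2-way
softmax head.  ResNet-10 additionally max-pools after the stem and halves
the spatial size at every block; ResNet-18 keeps pairs of blocks per
width.

Accuracy on a held-out set of *real* images is the evaluation metric;
generated images are firewalled out of evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, grad, no_grad
from .preprocess import ImageSet

#: (name, out_channels, stride) per residual block, after the stem
_BLOCKS = {
    "resnet10": [("ResBlock 1", 64, 1), ("ResBlock 2", 128, 2),
                 ("ResBlock 3", 256, 2), ("ResBlock 4", 512, 2)],
    "resnet18": [("ResBlock 1", 64, 1), ("ResBlock 2", 64, 1),
                 ("ResBlock 3", 128, 2), ("ResBlock 4", 128, 1),
                 ("ResBlock 5", 256, 2), ("ResBlock 6", 256, 1),
                 ("ResBlock 7", 512, 2), ("ResBlock 8", 512, 1)],
}


@dataclass(frozen=True)
class ResNetSpec:
    variant: str = "resnet10"
    num_classes: int = 2
    stem_channels: int = 64
    input_shape: tuple = (32, 32)

    def __post_init__(self):
        if self.variant not in _BLOCKS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(_BLOCKS)}")

    @property
    def has_stem_pool(self) -> bool:
        return self.variant == "resnet10"

    @property
    def blocks(self):
        return _BLOCKS[self.variant]


@dataclass(frozen=True)
class ClassifierTrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class AccuracyReport:
    accuracy: float
    n_test: int
    per_class: dict
    confusion: np.ndarray  # rows: true, cols: predicted

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "n_test": self.n_test,
                "per_class": self.per_class,
                "confusion": self.confusion.tolist()}


def _he_conv(c_in, c_out, k, stride, pad, rng):
    """3x3/1x1 convolution with He (fan-in) initialisation.

    Without normalisation layers the GAN-style N(0, 0.02) init collapses
    activations through a deep ReLU stack; He scaling keeps per-stage
    variance near 1.
    """
    return nn.Conv2d(c_in, c_out, k, stride, pad, rng,
                     std=float(np.sqrt(2.0 / (c_in * k * k))))


class ResBlock(nn.Module):
    def __init__(self, c_in, c_out, stride, rng):
        self.conv1 = _he_conv(c_in, c_out, 3, stride, 1, rng)
        self.conv2 = _he_conv(c_out, c_out, 3, 1, 1, rng)
        self.proj = None
        if stride != 1 or c_in != c_out:
            self.proj = _he_conv(c_in, c_out, 1, stride, 0, rng)

    def __call__(self, x):
        h = ad.relu(self.conv1(x))
        h = self.conv2(h)
        sc = x if self.proj is None else self.proj(x)
        return ad.relu(h + sc)


class ResNet(nn.Module):
    def __init__(self, spec: ResNetSpec, rng: np.random.Generator):
        self.spec = spec
        self.stem = _he_conv(1, spec.stem_channels, 3, 1, 1, rng)
        blocks = []
        c_in = spec.stem_channels
        for _, c_out, stride in spec.blocks:
            blocks.append(ResBlock(c_in, c_out, stride, rng))
            c_in = c_out
        self.blocks = blocks
        self.head = nn.Linear(c_in, spec.num_classes, rng,
                              std=float(np.sqrt(1.0 / c_in)))

    def logits(self, x):
        x = ad.as_tensor(x)
        if x.ndim == 3:
            x = x.reshape((x.shape[0], 1) + tuple(x.shape[1:]))
        h = ad.relu(self.stem(x))
        if self.spec.has_stem_pool:
            h = ad.maxpool2d(h, 2)
        for blk in self.blocks:
            h = blk(h)
        h = h.mean(axis=(2, 3))  # global average pool
        return self.head(h)

    def __call__(self, x):
        return nn.softmax(self.logits(x))

    def shape_trace(self, input_hw=None):
        """(stage name, output (H, W, C)) pairs for one dummy input."""
        hw = input_hw or self.spec.input_shape
        x = Tensor(np.zeros((1, 1) + tuple(hw), dtype=np.float32))
        rows = [("Input", (hw[0], hw[1], 1))]
        with no_grad():
            h = ad.relu(self.stem(x))
            rows.append(("Convolution", (h.shape[2], h.shape[3], h.shape[1])))
            if self.spec.has_stem_pool:
                h = ad.maxpool2d(h, 2)
                rows.append(("Maxpool", (h.shape[2], h.shape[3], h.shape[1])))
            for (name, _, _), blk in zip(self.spec.blocks, self.blocks):
                h = blk(h)
                rows.append((name, (h.shape[2], h.shape[3], h.shape[1])))
            h = h.mean(axis=(2, 3))
            rows.append(("Avgpool", (1, 1, h.shape[1])))
            rows.append(("Output(Dense)", (self.spec.num_classes,)))
        return rows


def build_resnet(variant: str, seed: int = 0) -> ResNet:
    spec = ResNetSpec(variant=variant)
    return ResNet(spec, np.random.default_rng(np.random.SeedSequence(seed)))


def _to_clf_input(images: ImageSet) -> tuple:
    x = images.pixel_array().astype(np.float32)
    return (2.0 * x - 1.0)[:, None], images.label_array()


def train_classifier(images: ImageSet, cfg: ClassifierTrainConfig = ClassifierTrainConfig(),
                     variant: str = "resnet10", model: ResNet | None = None,
                     log: list | None = None) -> ResNet:
    """Cross-entropy training with a validation split and best-epoch selection.

    The best-validation-accuracy epoch's parameters are restored before
    returning (ties keep the earlier epoch).
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    x, y = _to_clf_input(images)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")

    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_loop = ss.spawn(2)
    if model is None:
        model = ResNet(ResNetSpec(variant=variant), np.random.default_rng(s_init))
    rng = np.random.default_rng(s_loop)

    n = x.shape[0]
    n_val = max(1, int(round(cfg.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(set(y[tr_idx].tolist())) < 2:  # tiny sets: fall back to train=val
        tr_idx = perm
    params = model.param_tensors()
    opt = nn.Adam(params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)

    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            bi = order[start:start + cfg.batch_size]
            loss = nn.cross_entropy(model.logits(x[bi]), y[bi])
            opt.step(grad(loss, params))
            ep_loss += loss.item() * bi.size
        val_acc = _accuracy(model, x[val_idx], y[val_idx])
        if log is not None:
            log.append({"epoch": epoch, "train_loss": ep_loss / order.size,
                        "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc, best_state = val_acc, model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


def _accuracy(model: ResNet, x: np.ndarray, y: np.ndarray, batch: int = 128) -> float:
    return float((_predict(model, x, batch) == y).mean())


def _predict(model: ResNet, x: np.ndarray, batch: int = 128) -> np.ndarray:
    preds = []
    with no_grad():
        for start in range(0, x.shape[0], batch):
            logits = model.logits(x[start:start + batch]).data
            preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def evaluate(model: ResNet, test: ImageSet) -> AccuracyReport:
    """Accuracy report on real images; generated images are rejected."""
    if len(test) == 0:
        raise ValueError("empty test set")
    kinds = {im.kind for im in test}
    if "generated" in kinds:
        raise ValueError("evaluation sets must contain real images only "
                         "(found kind='generated')")
    x, y = _to_clf_input(test)
    pred = _predict(model, x)
    k = model.spec.num_classes
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    per_class = {}
    from .synth import LABELS
    for ci, lab in enumerate(LABELS):
        total = confusion[ci].sum()
        per_class[lab] = float(confusion[ci, ci] / total) if total else float("nan")
    acc = float(np.trace(confusion) / len(test))
    return AccuracyReport(accuracy=acc, n_test=len(test), per_class=per_class,
                          confusion=confusion)
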