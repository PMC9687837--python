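"""The InRes hybrid architecture: configurable build, counting, training.

The network stacks four blocks. Block-1 is a plain convolutional stem
(3 conv, pool, 2 conv, pool). Blocks 2-4 are stacks of residual units, each
unit combining an inception-style branch (several convolutions plus a
pooling layer) with a three-convolution residual branch as
``y = act(r(x) + alpha * i(x))``, where ``alpha`` is a learnable residual
scaling factor initialized at 0.1 (fixed at 1 when disabled). Unit counts
are 3/5/3 and the inception branches hold 6/5/4 convolutions respectively,
giving per-block conv+pool layer counts of 7, 30, 45 and 24 — 106 in total,
the figure the architecture is named after.

Stride-2 pooling inside every stacked unit would both collapse a 224 px
input long before the last block and break the shape equality the residual
sum requires, so unit-internal pooling layers are size-preserving
(2x2, stride 1) and downsampling happens in the stem and in one stride-2
transition pool after each residual block; transitions and the classifier
head are reported separately from the per-block counts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .errors import ConfigurationError, InputError
from .synthio import CLASSES

#: (inception branch convolutions, default stack count) for Blocks 2-4.
BLOCK_UNITS = {2: (6, 3), 3: (5, 5), 4: (4, 3)}


@dataclass(frozen=True)
class ActivationSpec:
    kind: str = "prelu"
    prelu_init: float = 0.1

    def __post_init__(self) -> None:
        if self.kind.lower() not in ("relu", "prelu", "leakyrelu", "elu", "tanh"):
            raise ConfigurationError(f"unknown activation {self.kind!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training knobs; defaults are the tuned configuration
    selected by the ablation protocol (224x224 input, 3x3 kernels, 64
    filters, max pooling, PReLU, flatten head, categorical cross-entropy,
    Adam at 0.0007, batch 32, 160 epochs)."""

    input_size: int = 224
    filter_size: int = 3
    n_filters: int = 64
    pool_type: str = "max"
    activation: ActivationSpec = ActivationSpec()
    head_type: str = "flatten"
    loss: str = "categorical_crossentropy"
    optimizer: str = "adam"
    learning_rate: float = 0.0007
    batch_size: int = 32
    epochs: int = 160
    n_classes: int = 5
    rsf_enabled: bool = True
    rsf_init: float = 0.1
    stack_counts: tuple[int, int, int] = (3, 5, 3)
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.pool_type not in ("max", "average"):
            raise ConfigurationError(f"unknown pool type {self.pool_type!r}")
        if self.head_type not in ("flatten", "global-average-pool", "global-max-pool"):
            raise ConfigurationError(f"unknown head type {self.head_type!r}")
        if self.loss not in nn.LOSSES:
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        if self.optimizer.lower() not in nn.OPTIMIZERS:
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if not (0.1 <= self.rsf_init <= 0.3) and self.rsf_enabled:
            raise ConfigurationError("rsf_init must lie in [0.1, 0.3]")

    @staticmethod
    def reduced(**overrides) -> "ModelConfig":
        """Desk-scale preset: 64x64 input, 8 filters, one unit per block."""
        cfg = ModelConfig(
            input_size=64, n_filters=8, stack_counts=(1, 1, 1), epochs=25,
        )
        return replace(cfg, **overrides)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    best_epoch: int = -1


class InResModel:
    """A built computation graph plus its block structure for reporting."""

    def __init__(self, cfg: ModelConfig, blocks, transitions, head):
        self.cfg = cfg
        self.blocks = blocks              # name -> list of top-level layers
        self.transitions = transitions    # list of Pool2D
        self.head = head                  # list of layers ending in Dense
        layers: list[nn.Layer] = []
        for name in ("block1", "block2", "block3", "block4"):
            layers.extend(blocks[name])
            idx = int(name[-1]) - 2
            if 0 <= idx < len(transitions):
                layers.append(transitions[idx])
        layers.extend(head)
        self.network = nn.Sequential(layers)

    def params(self) -> list[nn.Param]:
        return self.network.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.network.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.network.backward(dout)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(nn.softmax(self.forward(x[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


def _conv_stack(n: int, in_ch: int, out_ch: int, k: int,
                rng: np.random.Generator, name: str) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    ch = in_ch
    for i in range(n):
        layers.append(nn.Conv2D(ch, out_ch, k, rng, name=f"{name}.conv{i}"))
        ch = out_ch
    return layers


def build_model(cfg: ModelConfig, seed: int = 0) -> InResModel:
    """Assemble the network described by ``cfg``.

    Both branches of every residual unit map to ``n_filters`` channels, so
    the residual sum needs no extra projection; with ``rsf_enabled=False``
    the scaling factor is fixed at 1 and not trainable, which is the base
    (unscaled) variant of the architecture.
    """
    min_size = 2 ** (2 + len(cfg.stack_counts))
    if cfg.input_size < min_size:
        raise ConfigurationError(
            f"input_size {cfg.input_size} too small for the pooling depth"
        )
    rng = np.random.default_rng(seed)
    F, k = cfg.n_filters, cfg.filter_size
    act = cfg.activation

    def activation() -> nn.Layer:
        return nn.make_activation(act.kind, F, act.prelu_init)

    block1: list[nn.Layer] = []
    block1 += _conv_stack(3, cfg.in_channels, F, k, rng, "b1a")
    block1 += [activation(), nn.Pool2D(cfg.pool_type, stride=2)]
    block1 += _conv_stack(2, F, F, k, rng, "b1b")
    block1 += [activation(), nn.Pool2D(cfg.pool_type, stride=2)]

    blocks = {"block1": block1}
    for b, stacks in zip((2, 3, 4), cfg.stack_counts):
        n_inc, _ = BLOCK_UNITS[b]
        units: list[nn.Layer] = []
        for s in range(stacks):
            name = f"b{b}u{s}"
            inception = nn.Sequential(
                _conv_stack(n_inc, F, F, k, rng, f"{name}.inc")
                + [nn.Pool2D(cfg.pool_type, stride=1)]
            )
            resnet = nn.Sequential(_conv_stack(3, F, F, k, rng, f"{name}.res"))
            units.append(nn.ResidualUnit(
                inception, resnet, activation(),
                rsf_init=cfg.rsf_init if cfg.rsf_enabled else None,
                name=name,
            ))
        blocks[f"block{b}"] = units

    transitions = [nn.Pool2D(cfg.pool_type, stride=2) for _ in cfg.stack_counts]

    final_hw = cfg.input_size // (2 ** (2 + len(cfg.stack_counts)))
    head: list[nn.Layer] = []
    if cfg.head_type == "flatten":
        head.append(nn.Flatten())
        n_feat = F * final_hw * final_hw
    else:
        head.append(nn.GlobalPool(
            "average" if cfg.head_type == "global-average-pool" else "max"
        ))
        n_feat = F
    head.append(nn.Dense(n_feat, cfg.n_classes, rng, name="fc"))
    return InResModel(cfg, blocks, transitions, head)


# ---------------------------------------------------------------------------
# counting

def _count(layer, tally) -> None:
    if isinstance(layer, nn.Conv2D):
        tally["conv"] += 1
    elif isinstance(layer, (nn.Pool2D, nn.GlobalPool)):
        tally["pool"] += 1
    elif isinstance(layer, (nn.Activation, nn.PReLU)):
        tally["activation"] += 1
    elif isinstance(layer, nn.Dense):
        tally["fc"] += 1
    elif isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            _count(sub, tally)
    elif isinstance(layer, nn.ResidualUnit):
        _count(layer.inception, tally)
        _count(layer.resnet, tally)
        _count(layer.activation, tally)


def count_layers(model: InResModel) -> dict:
    """Per-block and total layer counts.

    The primary convention counts convolution and pooling layers inside the
    four blocks (transition pools and the head are listed separately);
    totals under conv-only and conv+pool+activation conventions are included
    for transparency.
    """
    report: dict = {"per_block": {}}
    totals = {"conv": 0, "pool": 0, "activation": 0, "fc": 0}
    for name, layers in model.blocks.items():
        tally = {"conv": 0, "pool": 0, "activation": 0, "fc": 0}
        for layer in layers:
            _count(layer, tally)
        report["per_block"][name] = {
            "conv": tally["conv"],
            "pool": tally["pool"],
            "conv_pool": tally["conv"] + tally["pool"],
        }
        for key in totals:
            totals[key] += tally[key]
    report["transitions"] = len(model.transitions)
    report["head_layers"] = len(model.head)
    report["total_conv_pool"] = totals["conv"] + totals["pool"]
    report["total_conv_only"] = totals["conv"]
    report["total_conv_pool_activation"] = (
        totals["conv"] + totals["pool"] + totals["activation"]
    )
    return report


def _walk_macs(layer, shape: tuple[int, int, int]) -> tuple[int, tuple[int, int, int]]:
    c, h, w = shape
    if isinstance(layer, nn.Conv2D):
        return h * w * layer.out_ch * layer.in_ch * layer.k * layer.k, \
            (layer.out_ch, h, w)
    if isinstance(layer, nn.Pool2D):
        if layer.stride == 2:
            return 0, (c, (h + 1) // 2, (w + 1) // 2)
        return 0, (c, h, w)
    if isinstance(layer, nn.GlobalPool):
        return 0, (c, 1, 1)
    if isinstance(layer, nn.Flatten):
        return 0, (c * h * w, 1, 1)
    if isinstance(layer, nn.Dense):
        n_in, n_out = layer.w.value.shape
        return n_in * n_out, (n_out, 1, 1)
    if isinstance(layer, nn.Sequential):
        total = 0
        for sub in layer.layers:
            m, shape = _walk_macs(sub, shape)
            total += m
        return total, shape
    if isinstance(layer, nn.ResidualUnit):
        mi, shape_i = _walk_macs(layer.inception, shape)
        mr, shape_r = _walk_macs(layer.resnet, shape)
        assert shape_i == shape_r
        return mi + mr, shape_i
    return 0, shape  # activations et al.


def count_macs(model: InResModel, input_size: int | None = None) -> int:
    """Multiply-accumulate count of one forward pass (conv + dense products)."""
    size = input_size if input_size is not None else model.cfg.input_size
    shape = (model.cfg.in_channels, size, size)
    total = 0
    for layer in model.network.layers:
        m, shape = _walk_macs(layer, shape)
        total += m
    return total


# ---------------------------------------------------------------------------
# training and evaluation

def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


def train(model: InResModel, x_train, y_train, x_val=None, y_val=None,
          epochs: int | None = None, seed: int = 0,
          restore_best: bool = True) -> TrainHistory:
    """Minibatch training with the configured loss/optimizer.

    Shuffling, and therefore the whole run, is deterministic for a fixed
    seed. When validation data is given, the parameters of the best
    validation-accuracy epoch are checkpointed (and restored at the end when
    ``restore_best``).
    """
    cfg = model.cfg
    if len(x_train) == 0:
        raise InputError("empty training set")
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    opt = nn.make_optimizer(cfg.optimizer, cfg.learning_rate)
    params = model.params()
    hist = TrainHistory()
    y_train = np.asarray(y_train)
    best_state = None
    best_acc = -1.0
    for epoch in range(epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(x_train))
        losses = []
        correct = 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb)
            loss, dz = nn.loss_and_grad(logits, _one_hot(yb, cfg.n_classes), cfg.loss)
            model.backward(dz)
            opt.step(params)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(correct / len(x_train))
        if x_val is not None and len(x_val):
            vloss, vacc = evaluate_loss(model, x_val, y_val)
            hist.val_loss.append(vloss)
            hist.val_acc.append(vacc)
            if vacc > best_acc:
                best_acc = vacc
                hist.best_epoch = epoch
                best_state = model.get_state()
        hist.epoch_seconds.append(time.perf_counter() - t0)
    if restore_best and best_state is not None:
        model.set_state(best_state)
    return hist


def evaluate_loss(model: InResModel, x, y) -> tuple[float, float]:
    y = np.asarray(y)
    cfg = model.cfg
    losses, correct = [], 0
    for i in range(0, len(x), 64):
        logits = model.forward(x[i:i + 64])
        loss, _ = nn.loss_and_grad(
            logits, _one_hot(y[i:i + 64], cfg.n_classes), cfg.loss
        )
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + 64]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def evaluate_model(model: InResModel, x, y, class_labels=None):
    """Confusion matrix (rows = actual, columns = predicted) plus scores."""
    from .evalkit import ConfusionMatrix

    labels = list(class_labels) if class_labels is not None else list(CLASSES)
    y = np.asarray(y)
    if y.max(initial=-1) >= len(labels):
        raise InputError("label index outside the class set")
    scores = model.predict_proba(x)
    pred = scores.argmax(axis=1)
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(y, pred):
        counts[a, p] += 1
    return ConfusionMatrix(counts, labels), scores


# ---------------------------------------------------------------------------
# synthetic image arrays for desk-scale training

#: Compact sheet used for desk-scale training runs: single-column layout so
#: the beat morphology survives downsampling to the reduced input size.
TRAIN_SHEET = None  # set below to avoid forward reference


def make_synthetic_arrays(n_per_class: int, image_size: int, seed: int,
                          sheet=None):
    """Render per-class sheets and return ``(X, y)`` model-ready arrays.

    Images are converted to ink-positive floats (``1 - I/255``) and resized
    to ``image_size``; labels are indices into :data:`paperecg.synthio.CLASSES`.
    """
    from skimage.transform import resize

    from . import synthio

    if sheet is None:
        sheet = TRAIN_SHEET
    xs, ys = [], []
    index = 0
    for ci, label in enumerate(CLASSES):
        for _ in range(n_per_class):
            img_seed = seed + index
            wf_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=img_seed, spawn_key=(1,))
            )
            wf = synthio.class_waveform_params(label, wf_rng)
            sample = synthio.render_sheet(label, sheet, wf, seed=img_seed)
            ink = 1.0 - sample.image.astype(np.float64) / 255.0
            small = resize(ink, (image_size, image_size), anti_aliasing=True)
            xs.append(small[None])
            ys.append(ci)
            index += 1
    return np.asarray(xs), np.asarray(ys)


def _default_train_sheet():
    from .synthio import SheetSpec

    return SheetSpec(
        width_px=256, height_px=192, minor_grid_spacing_px=4,
        label_band_top_px=16, label_band_bottom_px=16,
        n_lead_rows=2, n_lead_cols=1, page_noise_sd=2.0,
    )


TRAIN_SHEET = _default_train_sheet()
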