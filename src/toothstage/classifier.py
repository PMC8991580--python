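"""Six-stage (Demirjian C-H) convolutional classifier.

The reference network takes a 90x90 single-channel crop and produces six
softmax probabilities. Its layer stack is fixed by the reference layer
layout: four 3x3 conv stages of 64 filters (the 2nd and 4th downsample with
stride 3, the others are stride-1 "same"), a 2x2 max-pool after each
strided conv, a 30-unit dense layer and the 6-way output — feature-map
sides 90, 30, 15, 15, 5, 2, flattened length 256, and 119,320 trainable
parameters in total, every count reproducible from the closed forms
(k^2*c_in + 1)*c_out and (n_in + 1)*n_out.

Model selection utilities mirror the reference study protocol: a 27-point grid
over {dense layers} x {layer size} x {conv layers} ranked by final
validation loss, a four-way optimizer comparison at 50 epochs, and a
dropout study on the 30-unit dense layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from toothstage import nn
from toothstage.image import as_gray

STAGES: tuple[str, ...] = ("C", "D", "E", "F", "G", "H")
STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}


def stage_index(stage: str) -> int:
    """C -> 0 ... H -> 5; rejects anything outside the six staged classes."""
    try:
        return STAGE_TO_INDEX[stage]
    except KeyError:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}") from None


# --------------------------------------------------------------------------
# Architecture / training configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative network description.

    conv_filters   filters of each conv stage, in order
    conv_strides   stride per conv stage (1 = "same" padding, >1 = "valid")
    pool_after     conv-stage indices (0-based) followed by a 2x2 max-pool
    dense_widths   hidden dense widths between flatten and the output layer
    dropout_rate   inverted dropout on the first hidden dense layer, or None
    """

    conv_filters: tuple[int, ...] = (64, 64, 64, 64)
    conv_strides: tuple[int, ...] = (1, 3, 1, 3)
    pool_after: tuple[int, ...] = (1, 3)
    dense_widths: tuple[int, ...] = (30,)
    input_side: int = 90
    channels: int = 1
    n_classes: int = 6
    dropout_rate: float | None = None

    def __post_init__(self):
        if len(self.conv_filters) != len(self.conv_strides):
            raise ValueError("conv_filters and conv_strides must align")
        if any(w <= 0 for w in self.dense_widths):
            raise ValueError(f"dense widths must be positive, got {self.dense_widths}")
        if self.dropout_rate is not None and not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


def reference_spec(dropout_rate: float | None = None) -> ArchitectureSpec:
    """The reference staging network (119,320 parameters)."""
    return ArchitectureSpec(dropout_rate=dropout_rate)


def gridsearch_spec(conv_layers: int, layer_size: int, dense_layers: int) -> ArchitectureSpec:
    """Candidate for the model-selection grid: stride-1 convs, pool after each."""
    return ArchitectureSpec(
        conv_filters=(layer_size,) * conv_layers,
        conv_strides=(1,) * conv_layers,
        pool_after=tuple(range(conv_layers)),
        dense_widths=(layer_size,) * dense_layers,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol; the defaults are the reference protocol."""

    optimizer: str = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    train_fraction: float = 0.8
    val_fraction: float = 0.2   # carved out of the training portion, stratified
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch learning curves (train = running batch means)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


# --------------------------------------------------------------------------
# Model construction and bookkeeping
# --------------------------------------------------------------------------

def build_model(spec: ArchitectureSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the network; rejects specs whose spatial dims collapse."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    h = w = spec.input_side
    c = spec.channels
    for i, (filters, stride) in enumerate(zip(spec.conv_filters, spec.conv_strides)):
        padding = "same" if stride == 1 else "valid"
        conv = nn.Conv2D(c, filters, kernel=3, stride=stride, padding=padding, rng=rng)
        try:
            h, w = conv.out_hw(h, w)
        except ValueError as err:
            raise ValueError(f"conv stage {i}: {err}") from None
        layers += [conv, nn.ReLU()]
        c = filters
        if i in spec.pool_after:
            if h // 2 < 1 or w // 2 < 1:
                raise ValueError(f"pool after conv stage {i} collapses a {h}x{w} map")
            layers.append(nn.MaxPool2())
            h, w = h // 2, w // 2
    layers.append(nn.Flatten())
    n_in = h * w * c
    for j, width in enumerate(spec.dense_widths):
        layers += [nn.Dense(n_in, width, rng=rng), nn.ReLU()]
        if j == 0 and spec.dropout_rate:
            layers.append(nn.Dropout(spec.dropout_rate, rng=np.random.default_rng(seed + 1)))
        n_in = width
    layers.append(nn.Dense(n_in, spec.n_classes, rng=rng))
    return nn.Sequential(layers)


def count_parameters(model: nn.Sequential) -> tuple[list[tuple[str, int]], int]:
    """Per-layer (name, parameter count) pairs and their total.

    Counts come from the layers' actual arrays and therefore agree with the
    closed forms (k^2*c_in + 1)*c_out for convs and (n_in + 1)*n_out for
    dense layers.
    """
    per_layer = [(type(layer).__name__, layer.n_params()) for layer in model.layers]
    return per_layer, sum(n for _, n in per_layer)


def flatten_length(model: nn.Sequential, input_side: int = 90, channels: int = 1) -> int:
    """Length of the flattened feature vector for one pushed-through input."""
    x = np.zeros((1, input_side, input_side, channels), dtype=nn.F32)
    for layer in model.layers:
        x = layer.forward(x, training=False)
        if isinstance(layer, nn.Flatten):
            return int(x.shape[1])
    raise ValueError("model has no Flatten layer")


# --------------------------------------------------------------------------
# Data plumbing
# --------------------------------------------------------------------------

def _item_stage(item) -> str:
    for attr in ("stage", "label"):
        v = getattr(item, attr, None)
        if isinstance(v, str):
            return v
    if isinstance(item, (tuple, list)) and len(item) >= 2:
        return item[1]
    raise TypeError(f"cannot extract a stage label from {type(item).__name__}")


def _item_image(item) -> np.ndarray:
    v = getattr(item, "image", None)
    if v is not None:
        return np.asarray(v)
    if isinstance(item, (tuple, list)):
        return np.asarray(item[0])
    raise TypeError(f"cannot extract an image from {type(item).__name__}")


def to_input(images, side: int = 90) -> np.ndarray:
    """Stack [0,1] grayscale images into an (n, side, side, 1) float32 batch,
    resizing bilinearly when needed (e.g. 250x250 ROI -> 90x90)."""
    out = np.empty((len(images), side, side, 1), dtype=nn.F32)
    for i, img in enumerate(images):
        arr = as_gray(img)
        if arr.shape != (side, side):
            arr = _sk_resize(arr, (side, side), order=1, anti_aliasing=True)
        out[i, :, :, 0] = arr
    return out


def split_dataset(items, train_fraction: float = 0.8, seed: int = 0):
    """Stratified-by-stage split into (train_val, test); reproducible by seed."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    by_stage: dict[str, list[int]] = {}
    for i, item in enumerate(items):
        by_stage.setdefault(_item_stage(item), []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for stage in sorted(by_stage):
        idx = np.array(by_stage[stage])
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_idx += idx[:n_train].tolist()
        test_idx += idx[n_train:].tolist()
    return [items[i] for i in sorted(train_idx)], [items[i] for i in sorted(test_idx)]


def _prepare(items, side: int):
    X = to_input([_item_image(it) for it in items], side=side)
    y = np.array([stage_index(_item_stage(it)) for it in items], dtype=np.int64)
    return X, y


# --------------------------------------------------------------------------
# Training and prediction
# --------------------------------------------------------------------------

def _eval(model: nn.Sequential, X: np.ndarray, y: np.ndarray, batch: int = 64):
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        logits = model.forward(X[i:i + batch], training=False)
        loss, _ = nn.softmax_xent(logits, y[i:i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(model: nn.Sequential, train_val, config: TrainConfig,
          input_side: int = 90) -> TrainHistory:
    """Train in place on ``train_val`` items ((image, stage) pairs or
    objects with .image/.stage); an internal stratified validation split of
    ``config.val_fraction`` tracks the learning curves.

    Labels are checked against C-H before any weight is touched. Shuffling,
    initialization (via build_model's seed) and dropout are all seeded, so a
    fixed seed reproduces the history exactly.
    """
    for it in train_val:
        stage_index(_item_stage(it))
    tr_items, val_items = split_dataset(
        train_val, train_fraction=1.0 - config.val_fraction, seed=config.seed)
    X_tr, y_tr = _prepare(tr_items, input_side)
    if val_items:
        X_val, y_val = _prepare(val_items, input_side)
    else:  # set too small to carve out a validation part: report on train
        X_val, y_val = X_tr, y_tr

    opt = nn.make_optimizer(config.optimizer, lr=config.learning_rate,
                            beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed + 1)
    hist = TrainHistory()
    n = len(X_tr)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            sel = order[i:i + config.batch_size]
            xb, yb = X_tr[sel], y_tr[sel]
            logits = model.forward(xb, training=True)
            loss, dlogits = nn.softmax_xent(logits, yb)
            model.backward(dlogits)
            opt.step(model.params(), model.grads())
            losses.append(loss * len(sel))
            correct += int((logits.argmax(axis=1) == yb).sum())
        hist.train_loss.append(float(np.sum(losses) / n))
        hist.train_acc.append(correct / n)
        vl, va = _eval(model, X_val, y_val)
        hist.val_loss.append(vl)
        hist.val_acc.append(va)
    return hist


def predict_stage(model: nn.Sequential, image: np.ndarray,
                  input_side: int = 90) -> tuple[str, np.ndarray]:
    """Predicted stage letter and the six softmax probabilities.

    The label is the argmax with lowest-index tie-break; probabilities are
    nonnegative and sum to 1.
    """
    x = to_input([image], side=input_side)
    probs = model.predict_proba(x)[0]
    return STAGES[int(np.argmax(probs))], probs


def evaluate_on(model: nn.Sequential, items, input_side: int = 90):
    """(true stages, predicted stages) for a list of labeled items."""
    X, y = _prepare(items, input_side)
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    return [STAGES[i] for i in y], [STAGES[i] for i in pred]


# --------------------------------------------------------------------------
# Model-selection studies
# --------------------------------------------------------------------------

def grid_search(data, config: TrainConfig,
                dense_options=(0, 1, 2), size_options=(16, 32, 64),
                conv_options=(1, 2, 3), input_side: int = 90) -> pd.DataFrame:
    """Train every (dense, size, conv) combination and rank by final
    validation loss (ascending); the reference protocol's 3x3x3 = 27 grid.
    """
    rows = []
    for conv_layers in conv_options:
        for layer_size in size_options:
            for dense_layers in dense_options:
                spec = gridsearch_spec(conv_layers, layer_size, dense_layers)
                spec = replace(spec, input_side=input_side)
                model = build_model(spec, seed=config.seed)
                hist = train(model, data, config, input_side=input_side)
                rows.append({
                    "name": f"{conv_layers}-conv-{layer_size}-nodes-{dense_layers}-dense",
                    "conv_layers": conv_layers, "layer_size": layer_size,
                    "dense_layers": dense_layers,
                    "val_loss": hist.val_loss[-1], "val_acc": hist.val_acc[-1],
                })
    return (pd.DataFrame(rows)
            .sort_values("val_loss", kind="stable")
            .reset_index(drop=True))


def compare_optimizers(data, config: TrainConfig, epochs: int = 50,
                       optimizers=("adam", "sgd", "rmsprop", "adagrad"),
                       spec: ArchitectureSpec | None = None,
                       input_side: int = 90) -> dict[str, TrainHistory]:
    """One history per optimizer on identical splits and initial weights."""
    out: dict[str, TrainHistory] = {}
    base = spec or reference_spec()
    for name in optimizers:
        cfg = replace(config, optimizer=name, epochs=epochs)
        model = build_model(base, seed=config.seed)
        out[name] = train(model, data, cfg, input_side=input_side)
    return out


def dropout_study(data, config: TrainConfig,
                  rates=(None, 0.1, 0.5, 0.7, 0.9),
                  input_side: int = 90) -> pd.DataFrame:
    """Final train/validation accuracy per dropout rate on the 30-unit dense
    layer of the reference network; one row per rate."""
    rows = []
    for rate in rates:
        model = build_model(reference_spec(dropout_rate=rate), seed=config.seed)
        hist = train(model, data, config, input_side=input_side)
        rows.append({
            "dropout": 0.0 if rate is None else rate,
            "train_acc": hist.train_acc[-1],
            "val_acc": hist.val_acc[-1],
        })
    return pd.DataFrame(rows)
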