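"""Parallel multi-branch CNN for categorical or quantitative phenotype prediction.

One 1-D convolutional branch per omics layer reads that layer's encoded
tensor (channels = encoding channels): stacked 1-D convolutions along the
feature axis, each followed by leaky ReLU and non-overlapping max pooling,
then a flatten and a dense projection to a fixed-width representation closed
by batch normalization. Keeping position-specific weights after the shared
conv filters lets the network localize which features carry signal — a
global pooling of the conv maps would discard exactly that information.
Branch representations are concatenated and passed through a fully connected
network with leaky-ReLU activations and dropout after every hidden layer.
The head is softmax over classes (categorical, cross-entropy loss) or a
single linear unit (quantitative, mean squared error). Optimization is Adam
with early stopping on validation loss, restoring the best parameters.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .dataset import MultiOmicsDataset
from .io import ValidationError

FORMAT_VERSION = 1


@dataclass
class ModelSpec:
    """Architecture + training hyperparameters for the multi-branch CNN.

    ``conv_layers`` is a list of (kernel_size, n_filters) applied to every
    branch; a per-branch override may be given via ``branch_conv`` (one list
    per input layer). Kernels longer than a branch's feature axis are clamped
    to the axis length.
    """

    task: str = "categorical"
    n_classes: int = 2
    conv_layers: list[tuple[int, int]] = field(default_factory=lambda: [(4, 16), (4, 32)])
    branch_conv: list[list[tuple[int, int]]] | None = None
    pool_size: int = 2
    repr_width: int = 32
    fc_widths: list[int] = field(default_factory=lambda: [64, 16])
    dropout: float = 0.25
    leaky_slope: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.task not in ("categorical", "quantitative"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.task == "categorical" and self.n_classes < 2:
            raise ValidationError("categorical task needs n_classes >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if any(w <= 0 for w in self.fc_widths):
            raise ValidationError("fully connected widths must be positive")

    def branch_configs(self, n_branches: int) -> list[list[tuple[int, int]]]:
        if self.branch_conv is not None:
            if len(self.branch_conv) != n_branches:
                raise ValidationError(
                    f"branch_conv has {len(self.branch_conv)} configs for {n_branches} inputs"
                )
            return [list(map(tuple, b)) for b in self.branch_conv]
        return [list(map(tuple, self.conv_layers)) for _ in range(n_branches)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["conv_layers"] = [tuple(t) for t in d["conv_layers"]]
        if d.get("branch_conv") is not None:
            d["branch_conv"] = [[tuple(t) for t in b] for b in d["branch_conv"]]
        return cls(**d)


class ModelGraph:
    """Instantiated network: per-input conv branches plus the shared head."""

    def __init__(self, spec: ModelSpec, input_shapes: list[tuple[int, int]], seed: int = 0):
        if not 1 <= len(input_shapes) <= 3:
            raise ValidationError(f"need 1-3 input layers, got {len(input_shapes)}")
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.input_shapes = list(input_shapes)
        self.branches: list[nn.Sequential] = []
        widths = []
        for (n_feat, n_chan), conv_cfg in zip(input_shapes, spec.branch_configs(len(input_shapes))):
            layers: list[nn.Layer] = []
            length, c_in = n_feat, n_chan
            for kernel, filters in conv_cfg:
                k = min(kernel, length)
                layers.append(nn.Conv1D(c_in, filters, k, rng))
                layers.append(nn.LeakyReLU(spec.leaky_slope))
                length = length - k + 1
                if spec.pool_size > 1 and length > 1:
                    layers.append(nn.MaxPool1D(spec.pool_size))
                    length = -(-length // min(spec.pool_size, length))
                c_in = filters
            layers.append(nn.Flatten())
            layers.append(nn.Dense(length * c_in, spec.repr_width, rng))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            layers.append(nn.BatchNorm(spec.repr_width))
            self.branches.append(nn.Sequential(layers))
            widths.append(spec.repr_width)
        self.branch_widths = widths

        head: list[nn.Layer] = []
        d_in = sum(widths)
        for w in spec.fc_widths:
            head.append(nn.Dense(d_in, w, rng))
            head.append(nn.LeakyReLU(spec.leaky_slope))
            head.append(nn.Dropout(spec.dropout))
            d_in = w
        n_out = spec.n_classes if spec.task == "categorical" else 1
        head.append(nn.Dense(d_in, n_out, rng))
        self.head = nn.Sequential(head)

    @property
    def all_layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for b in self.branches:
            out.extend(b.layers)
        out.extend(self.head.layers)
        return out

    def forward(self, xs: list[np.ndarray], train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        reps = [b.forward(x, train, rng) for b, x in zip(self.branches, xs)]
        return self.head.forward(np.concatenate(reps, axis=1), train, rng)

    def backward(self, gout: np.ndarray) -> list[np.ndarray]:
        """Backprop to the inputs; returns per-branch input gradients."""
        g = self.head.backward(gout)
        grads = []
        ofs = 0
        for b, w in zip(self.branches, self.branch_widths):
            grads.append(b.backward(g[:, ofs:ofs + w]))
            ofs += w
        return grads


def build_model(spec: ModelSpec, input_shapes: list[tuple[int, int]],
                seed: int = 0) -> ModelGraph:
    """Construct an untrained graph with one conv branch per input layer."""
    return ModelGraph(spec, input_shapes, seed=seed)


@dataclass
class TrainedModel:
    spec: ModelSpec
    graph: ModelGraph
    preprocessing: dict  # per-layer omics type, feature IDs, channel order
    history: list[dict]
    seed: int
    classes: list[str] | None = None


def _preprocessing_state(d: MultiOmicsDataset) -> dict:
    return {
        "layers": [
            {"omics_type": lay.omics_type, "feature_ids": lay.feature_ids,
             "channels": lay.channels, "encoding_kind": lay.encoding_kind}
            for lay in d.layers
        ]
    }


def _check_compatible(pre: dict, d: MultiOmicsDataset) -> None:
    got = _preprocessing_state(d)["layers"]
    want = pre["layers"]
    if len(got) != len(want):
        raise ValidationError(f"model expects {len(want)} layers, dataset has {len(got)}")
    for i, (w, g) in enumerate(zip(want, got)):
        if w["feature_ids"] != g["feature_ids"]:
            missing = sorted(set(w["feature_ids"]) - set(g["feature_ids"]))[:5]
            extra = sorted(set(g["feature_ids"]) - set(w["feature_ids"]))[:5]
            raise ValidationError(
                f"layer {i} ({w['omics_type']}): feature mismatch; "
                f"missing={missing} extra={extra}"
            )
        if w["channels"] != g["channels"]:
            raise ValidationError(f"layer {i}: channel order mismatch")


def _epoch_metric(task: str, y: np.ndarray, out: np.ndarray) -> float:
    if task == "categorical":
        p = nn.softmax(out)
        if len(np.unique(y)) == 2:
            from .evaluation import roc_auc
            return roc_auc((y == y.max()).astype(int), p[:, int(y.max())])
        return float(np.mean(np.argmax(p, axis=1) == y))
    if np.std(out[:, 0]) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(y, out[:, 0])[0, 1])


def train_model(graph: ModelGraph, d_train: MultiOmicsDataset,
                d_val: MultiOmicsDataset, spec: ModelSpec,
                seed: int = 0) -> TrainedModel:
    """Fit the graph with Adam and early stopping on validation loss.

    Class weights (inverse class frequency) are applied to the cross-entropy
    when ``spec.class_weighting`` is set, guarding against the imbalanced
    cohorts typical of survival phenotypes.
    """
    pre = _preprocessing_state(d_train)
    _check_compatible(pre, d_val)
    rng = np.random.default_rng(seed)
    xs_train = d_train.tensors()
    xs_val = d_val.tensors()
    y_train = d_train.y_codes()
    y_val = d_val.y_codes()

    if spec.task == "categorical":
        counts = np.bincount(y_train, minlength=spec.n_classes).astype(float)
        if np.any(counts == 0):
            raise ValidationError("a class is absent from the training split")
        weights = (counts.sum() / (len(counts) * counts)) if spec.class_weighting \
            else np.ones_like(counts)
    else:
        weights = None

    opt = nn.Adam(graph.all_layers, lr=spec.learning_rate)
    n = len(y_train)
    history: list[dict] = []
    best_loss = np.inf
    best_snap = nn.snapshot_params(graph.all_layers)
    best_epoch = -1

    for epoch in range(spec.max_epochs):
        perm = rng.permutation(n)
        train_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = perm[start:start + spec.batch_size]
            out = graph.forward([x[idx] for x in xs_train], train=True, rng=rng)
            if spec.task == "categorical":
                loss, grad = nn.weighted_cross_entropy(out, y_train[idx], weights)
            else:
                loss, grad = nn.mse_loss(out, y_train[idx])
            graph.backward(grad)
            opt.step()
            train_loss += loss * len(idx)
        train_loss /= n

        val_out = graph.forward(xs_val, train=False)
        if spec.task == "categorical":
            val_loss, _ = nn.weighted_cross_entropy(val_out, y_val, weights)
        else:
            val_loss, _ = nn.mse_loss(val_out, y_val)
        history.append({"epoch": epoch, "train_loss": float(train_loss),
                        "val_loss": float(val_loss),
                        "val_metric": _epoch_metric(spec.task, y_val, val_out)})
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_snap = nn.snapshot_params(graph.all_layers)
            best_epoch = epoch
        elif epoch - best_epoch >= spec.patience:
            break

    nn.restore_params(graph.all_layers, best_snap)
    classes = d_train.labels.classes if spec.task == "categorical" else None
    return TrainedModel(spec, graph, pre, history, seed, classes)


def predict(model: TrainedModel, d: MultiOmicsDataset) -> np.ndarray:
    """Class-probability rows (categorical) or real values (quantitative),
    in the dataset's sample order."""
    _check_compatible(model.preprocessing, d)
    out = model.graph.forward(d.tensors(), train=False)
    if model.spec.task == "categorical":
        return nn.softmax(out)
    return out[:, 0]


def predict_logits(model: TrainedModel, d: MultiOmicsDataset) -> np.ndarray:
    _check_compatible(model.preprocessing, d)
    return model.graph.forward(d.tensors(), train=False)


def input_gradients(model: TrainedModel, d: MultiOmicsDataset,
                    target: int | None = None) -> list[np.ndarray]:
    """Gradient of one output unit w.r.t. every input entry.

    For categorical tasks the gradient is taken on the target class's logit
    (pre-softmax, saturation-safe); ``target`` defaults to the last class in
    sorted label order (the "positive" class of a binary problem).
    Returns one (samples, features, channels) array per input layer.
    """
    _check_compatible(model.preprocessing, d)
    out = model.graph.forward(d.tensors(), train=False)
    gout = np.zeros_like(out)
    if model.spec.task == "categorical":
        t = model.spec.n_classes - 1 if target is None else int(target)
        if not 0 <= t < model.spec.n_classes:
            raise ValidationError(f"target class {t} out of range")
        gout[:, t] = 1.0
    else:
        gout[:, 0] = 1.0
    return model.graph.backward(gout)


def save_model(model: TrainedModel, path) -> None:
    """Serialize to a single zip archive: JSON manifest + parameter blob."""
    manifest = {
        "format_version": FORMAT_VERSION,
        "spec": model.spec.to_dict(),
        "input_shapes": model.graph.input_shapes,
        "preprocessing": model.preprocessing,
        "history": model.history,
        "seed": model.seed,
        "classes": model.classes,
    }
    params = nn.collect_params(model.graph.all_layers)
    buf = _io.BytesIO()
    np.savez(buf, **params)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("params.npz", buf.getvalue())


def load_model(path) -> TrainedModel:
    """Inverse of :func:`save_model`; validates the format version."""
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            params = dict(np.load(_io.BytesIO(zf.read("params.npz"))))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot read model archive {path}: {exc}") from None
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValidationError(
            f"model archive version {manifest.get('format_version')} "
            f"not supported (expected {FORMAT_VERSION})"
        )
    spec = ModelSpec.from_dict(manifest["spec"])
    graph = build_model(spec, [tuple(s) for s in manifest["input_shapes"]],
                        seed=manifest["seed"])
    nn.restore_params(graph.all_layers, params)
    return TrainedModel(spec, graph, manifest["preprocessing"],
                        manifest["history"], manifest["seed"], manifest["classes"])
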