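"""The two spectrum classifiers and their confidence-averaging ensemble.

Two deliberately different architectures see the same binned spectra:

* a multilayer perceptron (1024- and 512-unit ReLU hidden layers, sigmoid
  output) that treats the feature vector as unordered, trained with a 2.5x
  loss weight on the positive class;
* a 12-layer 1-D convolutional network (kernel 9, no biases, batch
  normalization before layers 1-11, global average pooling into a sigmoid)
  that exploits the local correlation of adjacent m/z bins and is invariant
  to input length.

Each produces a per-spectrum confidence in [0, 1]; the ensemble prediction is
their plain average, thresholded at 0.5 (confidence strictly below the
threshold means the negative class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .featurize import FeatureMatrix


@dataclass(frozen=True)
class MLPSpec:
    """Multilayer perceptron: input -> 1024 -> 512 -> 1, all dense with biases."""

    input_dim: int
    hidden: tuple[int, ...] = (1024, 512)
    batch_size: int = 512
    momentum: float = 0.9
    schedule: tuple[tuple[int, float], ...] = ((20, 0.01), (10, 0.001))
    pos_class_weight: float = 2.5


@dataclass(frozen=True)
class ConvNetSpec:
    """12-layer 1-D conv net, kernel 9, no biases, BN before layers 1-11.

    Strides are 4 at layer 1 and 3 at layers 6 and 10, otherwise 1; global
    average pooling over the final single-channel map feeds the sigmoid, so
    the trainable-parameter count does not depend on the input length.
    """

    kernel: int = 9
    filters: tuple[int, ...] = (32, 16, 16, 16, 16, 32, 32, 32, 32, 32, 64, 1)
    strides: tuple[int, ...] = (4, 1, 1, 1, 1, 3, 1, 1, 1, 3, 1, 1)
    n_batchnorm: int = 11
    batch_size: int = 512
    momentum: float = 0.9
    schedule: tuple[tuple[int, float], ...] = ((5, 0.1), (5, 0.01), (1, 0.001))
    weight_decay: float = 1e-3


def count_trainable_params(spec: MLPSpec | ConvNetSpec) -> int:
    """Exact analytic count of trainable parameters for either architecture.

    Dense layers contribute ``d_in * d_out + d_out`` (weights + biases); conv
    layers ``c_in * c_out * kernel`` (no biases); each batch-normalization
    layer ``2 * c_in`` (scale and shift; running statistics are not trained).
    """
    if isinstance(spec, MLPSpec):
        dims = (spec.input_dim, *spec.hidden, 1)
        return int(sum(a * b + b for a, b in zip(dims[:-1], dims[1:])))
    if isinstance(spec, ConvNetSpec):
        channels = (1, *spec.filters[:-1])
        conv = sum(c_in * c_out * spec.kernel
                   for c_in, c_out in zip(channels, spec.filters))
        bn = sum(2 * c for c in channels[: spec.n_batchnorm])
        return int(conv + bn)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def build_network(spec: MLPSpec | ConvNetSpec, rng: np.random.Generator,
                  input_dim: int | None = None) -> nn.Network:
    """Instantiate a trainable network from its declarative description."""
    if isinstance(spec, MLPSpec):
        layers: list[nn.Layer] = []
        dims = (spec.input_dim, *spec.hidden)
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            layers.append(nn.Dense(d_in, d_out, rng, init="he"))
            layers.append(nn.ReLU())
        layers.append(nn.Dense(dims[-1], 1, rng, init="glorot"))
        return nn.Network(layers)
    if isinstance(spec, ConvNetSpec):
        layers = [nn.AddChannel()]
        channels = (1, *spec.filters[:-1])
        for i, (c_in, c_out, stride) in enumerate(
            zip(channels, spec.filters, spec.strides)
        ):
            if i < spec.n_batchnorm:
                layers.append(nn.BatchNorm1d(c_in))
            if i > 0:
                layers.append(nn.ReLU())
            layers.append(nn.Conv1d(c_in, c_out, spec.kernel, stride, rng))
        layers.append(nn.GlobalAvgPool1d())
        return nn.Network(layers)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


@dataclass
class TrainedEnsemble:
    """The fitted member networks plus the provenance needed to reuse them."""

    members: list[nn.Network]
    specs: list[MLPSpec | ConvNetSpec]
    seed: int
    input_dim: int
    training_accuracy: dict[str, float] = field(default_factory=dict)
    bin_spec: object | None = None


def _as_xy(m: FeatureMatrix | tuple[np.ndarray, np.ndarray]):
    if isinstance(m, FeatureMatrix):
        return m.X, m.labels
    X, y = m
    return np.asarray(X), np.asarray(y)


def train_ensemble(
    m: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    seed: int,
    specs: list[MLPSpec | ConvNetSpec] | None = None,
) -> TrainedEnsemble:
    """Train every member network on the same rows and bundle them.

    By default the members are the MLP (with input width taken from the data)
    and the conv net, each with its own training schedule. Training is fully
    seeded: member i draws from an independent stream spawned from ``seed``.

    Raises
    ------
    ValueError
        Fewer than 2 rows, a single class in the labels, or a spec whose
        input width disagrees with the data.
    """
    X, y = _as_xy(m)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if specs is None:
        specs = [MLPSpec(input_dim=X.shape[1]), ConvNetSpec()]
    for spec in specs:
        if isinstance(spec, MLPSpec) and spec.input_dim != X.shape[1]:
            raise ValueError(
                f"MLP expects {spec.input_dim} features, data has {X.shape[1]}"
            )

    seeds = np.random.SeedSequence(seed).spawn(len(specs))
    members, train_acc = [], {}
    for spec, ss in zip(specs, seeds):
        rng = np.random.default_rng(ss)
        net = build_network(spec, rng)
        kwargs = dict(
            schedule=spec.schedule,
            batch_size=spec.batch_size,
            momentum=spec.momentum,
            rng=rng,
        )
        if isinstance(spec, MLPSpec):
            kwargs["pos_class_weight"] = spec.pos_class_weight
        else:
            kwargs["weight_decay"] = spec.weight_decay
        nn.train_sgd(net, X, y, **kwargs)
        members.append(net)
        name = type(spec).__name__
        train_acc[name] = float(
            np.mean((net.predict_proba(X) >= 0.5).astype(int) == y)
        )
    return TrainedEnsemble(
        members=members, specs=list(specs), seed=seed,
        input_dim=X.shape[1], training_accuracy=train_acc,
    )


def predict_confidences(
    e: TrainedEnsemble, m: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Per-row mean of the member confidences; always within [0, 1]."""
    X = m.X if isinstance(m, FeatureMatrix) else np.asarray(m)
    if X.ndim != 2 or X.shape[1] != e.input_dim:
        raise ValueError(
            f"expected (n, {e.input_dim}) features, got {X.shape}"
        )
    preds = np.stack([net.predict_proba(X) for net in e.members])
    return preds.mean(axis=0)


def classify(confidences: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold confidences: strictly below -> negative (0), else positive (1)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    conf = np.asarray(confidences, dtype=float)
    if conf.size and (conf.min() < 0 or conf.max() > 1):
        raise ValueError("confidences must lie in [0, 1]")
    return (conf >= threshold).astype(np.int64)
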