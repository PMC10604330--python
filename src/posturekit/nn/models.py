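"""Network architectures: the per-timestep FNN and five LSTM variants.

The FNN is a linear stack of three fully connected layers (12 -> 7 ->
7 -> 7) closed by a softmax, applied independently at each timestep.
The LSTM variants place dropout, batch-normalization, fully connected
and leaky-ReLU layers around a 2-layer stacked LSTM in five different
orders (an ablation of layer placement); the fully connected layers
always have seven output nodes and every variant ends in a 7-class
softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import BatchNorm, Dense, Dropout, LeakyReLU, LSTM, Sequential, Softmax

N_CLASSES = 7
N_FEATURES = 12

#: Layer recipes for the five LSTM ablation groups.  Each entry is a
#: (kind, arg) pair in network order; "fc" widths are resolved at build
#: time (fully connected layers always output 7 nodes).
LSTM_GROUP_LAYERS: dict[int, list[tuple[str, float | None]]] = {
    1: [("dropout", 0.2), ("lstm", None), ("fc", None), ("bn", None),
        ("lrelu", None), ("dropout", 0.8), ("fc", None), ("softmax", None)],
    2: [("bn", None), ("lstm", None), ("dropout", 0.4), ("fc", None), ("softmax", None)],
    3: [("dropout", 0.4), ("lstm", None), ("fc", None), ("lrelu", None),
        ("dropout", 0.5), ("fc", None), ("softmax", None)],
    4: [("lstm", None), ("dropout", 0.8), ("fc", None), ("lrelu", None), ("softmax", None)],
    5: [("lstm", None), ("fc", None), ("bn", None), ("dropout", 0.8),
        ("fc", None), ("lrelu", None), ("softmax", None)],
}


@dataclass(frozen=True)
class NetworkSpec:
    """What to build: the FNN or one of the five LSTM groups."""

    kind: str = "lstm"  # "fnn" | "lstm"
    group_id: int = 5  # LSTM only
    hidden_units: int = 64  # LSTM only
    num_lstm_layers: int = 2
    fc_width: int = N_CLASSES
    leaky_slope: float = 0.01
    n_features: int = N_FEATURES
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.kind not in ("fnn", "lstm"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.kind == "lstm" and self.group_id not in LSTM_GROUP_LAYERS:
            raise ValueError(f"unknown LSTM group_id {self.group_id}; expected 1..5")


def build_network(spec: NetworkSpec, seed: int = 0) -> Sequential:
    """Instantiate the architecture with seeded initialisation.

    The returned model owns one RNG (derived from ``seed``) used by its
    dropout layers, so a (spec, seed) pair fully determines behaviour.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    if spec.kind == "fnn":
        layers = [
            Dense(spec.n_features, spec.fc_width, rng),
            Dense(spec.fc_width, spec.fc_width, rng),
            Dense(spec.fc_width, spec.n_classes, rng),
            Softmax(),
        ]
        return Sequential(layers)

    layers = []
    width = spec.n_features
    for kind, arg in LSTM_GROUP_LAYERS[spec.group_id]:
        if kind == "dropout":
            layers.append(Dropout(float(arg), rng))
        elif kind == "lstm":
            layers.append(LSTM(width, spec.hidden_units, spec.num_lstm_layers, rng))
            width = spec.hidden_units
        elif kind == "fc":
            layers.append(Dense(width, spec.fc_width, rng))
            width = spec.fc_width
        elif kind == "bn":
            layers.append(BatchNorm(width))
        elif kind == "lrelu":
            layers.append(LeakyReLU(spec.leaky_slope))
        elif kind == "softmax":
            layers.append(Softmax())
    return Sequential(layers)


def layer_sequence(spec: NetworkSpec) -> list[str]:
    """Human-readable layer ordering, e.g. for reports and tests."""
    if spec.kind == "fnn":
        return ["fc", "fc", "fc", "softmax"]
    out = []
    for kind, arg in LSTM_GROUP_LAYERS[spec.group_id]:
        out.append(f"dropout({arg})" if kind == "dropout" else kind)
    return out


def save_checkpoint(path, model: Sequential, spec: NetworkSpec, metadata: dict | None = None) -> None:
    """Persist weights plus the spec/metadata needed to rebuild the model."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.params())}
    bn_state = {}
    for i, layer in enumerate(model.layers):
        if isinstance(layer, BatchNorm):
            bn_state[f"bn_{i}_mean"] = layer.running_mean
            bn_state[f"bn_{i}_var"] = layer.running_var
    meta = {"spec": asdict(spec), "metadata": metadata or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays, **bn_state)


def load_checkpoint(path) -> tuple[Sequential, NetworkSpec, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = NetworkSpec(**meta["spec"])
        model = build_network(spec, seed=0)
        for i, p in enumerate(model.params()):
            p[...] = data[f"param_{i}"]
        for i, layer in enumerate(model.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = data[f"bn_{i}_mean"]
                layer.running_var[...] = data[f"bn_{i}_var"]
    return model, spec, meta["metadata"]
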