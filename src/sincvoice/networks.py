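"""Model architectures for raw-waveform voice-disorder classification.

Three families share one declarative :class:`NetworkSpec`:

* **SincNet** — a sinc band-pass filterbank front end (2 learnable cutoffs
  per channel) feeding conv + fully connected blocks;
* **CNN(1D)** — identical stack, but the front-end kernels are free-form
  (every tap learnable);
* **CNN(2D)** — a log-magnitude spectrogram image processed by (3,3)-kernel,
  (3,3)-stride conv blocks.

The default specs carry the reference configuration: 80 front-end channels
of length 251, two (60, 5) conv layers, three 2048-node fully connected
layers, leaky-ReLU, batch + layer normalization between hidden layers and
dropout 0.5 (conv) / 0.3 (fully connected).  A ``compact_*`` variant with
the same topology at reduced width is provided for desk-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nnet
from .sincfilters import SincFilterBank, init_filterbank

__all__ = [
    "NetworkSpec",
    "default_sincnet_spec",
    "default_cnn1d_spec",
    "default_cnn2d_spec",
    "compact_sincnet_spec",
    "compact_cnn1d_spec",
    "build_model",
    "VoiceNet",
    "count_learnable_params",
    "predict_chunk",
    "extract_embedding",
]


@dataclass
class NetworkSpec:
    """Declarative description of one model's layer stack."""

    front_end: dict
    conv_layers: list = field(default_factory=list)  # (channels, kernel, stride)
    pool_size: list = field(default_factory=list)  # per conv layer
    fc_layers: list = field(default_factory=lambda: [2048, 2048, 2048])
    dropout_conv: list = field(default_factory=list)  # per conv layer
    dropout_fc: list = field(default_factory=lambda: [0.3, 0.3, 0.3])
    activation: str = "leaky_relu"
    norm: str = "batch+layer"
    n_classes: int = 2
    sample_rate: float = 16000.0
    chunk_s: float = 0.2

    def __post_init__(self):
        self.conv_layers = [tuple(c) for c in self.conv_layers]
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for p in list(self.dropout_conv) + list(self.dropout_fc):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout fractions must lie in [0, 1)")
        if any(n <= 0 for n in self.fc_layers):
            raise ValueError("fc node counts must be positive")

    @property
    def chunk_len(self) -> int:
        return int(round(self.chunk_s * self.sample_rate))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        return cls.from_dict(yaml.safe_load(text))


def _sinc_front(n_filters: int, filter_len: int) -> dict:
    return {"kind": "sinc", "n_filters": n_filters, "kernel": filter_len,
            "window": "hamming", "min_low_hz": 50.0, "min_band_hz": 50.0,
            "init": "mel"}


def default_sincnet_spec(n_classes: int, sample_rate: float = 16000.0) -> NetworkSpec:
    """Reference SincNet: 80 sinc filters of length 251 (160 learnable
    scalars), two (60, 5) conv layers, three 2048-node FC layers."""
    return NetworkSpec(
        front_end=_sinc_front(80, 251),
        conv_layers=[(60, 5, 1), (60, 5, 1)],
        pool_size=[3, 3, 3],  # front-end pool + one per conv layer
        fc_layers=[2048, 2048, 2048],
        dropout_conv=[0.5, 0.5],
        dropout_fc=[0.3, 0.3, 0.3],
        n_classes=n_classes,
        sample_rate=sample_rate,
    )


def default_cnn1d_spec(n_classes: int, sample_rate: float = 16000.0) -> NetworkSpec:
    """1-D baseline: identical to SincNet except the front end is a fully
    learnable [80, 251] convolution."""
    spec = default_sincnet_spec(n_classes, sample_rate)
    spec.front_end = {"kind": "conv1d", "n_filters": 80, "kernel": 251}
    return spec


def default_cnn2d_spec(n_classes: int, sample_rate: float = 16000.0) -> NetworkSpec:
    """2-D baseline on a log-magnitude spectrogram: conv channels
    (80, 60, 60) with (3,3) kernels/strides/pools, dropout 0.5/0.4 on the
    last two conv layers and 0.3/0.2/0.2 on the three 2048-node FC layers."""
    return NetworkSpec(
        front_end={"kind": "conv2d-spectrogram", "win_s": 0.025, "hop_s": 0.010},
        conv_layers=[(80, 3, 3), (60, 3, 3), (60, 3, 3)],
        pool_size=[3, 3, 3],
        fc_layers=[2048, 2048, 2048],
        dropout_conv=[0.0, 0.5, 0.4],
        dropout_fc=[0.3, 0.2, 0.2],
        n_classes=n_classes,
        sample_rate=sample_rate,
    )


def compact_sincnet_spec(n_classes: int, sample_rate: float = 16000.0) -> NetworkSpec:
    """Same topology as the reference SincNet at reduced width, sized for
    CPU-scale experiments on the synthetic vowels."""
    return NetworkSpec(
        front_end=_sinc_front(32, 101),
        conv_layers=[(16, 5, 1), (16, 5, 1)],
        pool_size=[4, 4, 4],
        fc_layers=[64, 64],
        dropout_conv=[0.2, 0.2],
        dropout_fc=[0.1, 0.1],
        n_classes=n_classes,
        sample_rate=sample_rate,
    )


def compact_cnn1d_spec(n_classes: int, sample_rate: float = 16000.0) -> NetworkSpec:
    spec = compact_sincnet_spec(n_classes, sample_rate)
    spec.front_end = {"kind": "conv1d", "n_filters": 32, "kernel": 101}
    return spec


class VoiceNet:
    """A built model: front end + hidden stack + softmax head.

    The embedding of a chunk is the activation vector feeding the softmax
    layer (the output of the last fully connected block).
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self):
        spec = self.spec
        fe = spec.front_end
        layers: list[nnet.Layer] = []
        rng = self.rng
        kind = fe["kind"]
        n_t = spec.chunk_len

        if kind in ("sinc", "conv1d"):
            n_ch = fe["n_filters"]
            if kind == "sinc":
                bank = init_filterbank(
                    n_filters=n_ch,
                    sample_rate=spec.sample_rate,
                    scheme=fe.get("init", "mel"),
                    filter_len=fe["kernel"],
                    window=fe.get("window", "hamming"),
                    min_low_hz=fe.get("min_low_hz", 50.0),
                    min_band_hz=fe.get("min_band_hz", 50.0),
                )
                front = nnet.SincConv1d(bank)
            else:
                front = nnet.Conv1dFront(n_ch, fe["kernel"], rng)
            layers.append(front)
            n_t = n_t - fe["kernel"] + 1
            pool0 = spec.pool_size[0]
            layers += [nnet.MaxPool1d(pool0), nnet.BatchNorm(n_ch),
                       nnet.LayerNorm(), nnet.LeakyReLU()]
            n_t //= pool0
            for i, (ch, k, _stride) in enumerate(spec.conv_layers):
                layers.append(nnet.Conv1d(n_ch, ch, k, rng))
                n_t = n_t - k + 1
                pool = spec.pool_size[i + 1]
                layers += [nnet.MaxPool1d(pool), nnet.BatchNorm(ch),
                           nnet.LayerNorm(), nnet.LeakyReLU()]
                n_t //= pool
                if spec.dropout_conv[i] > 0:
                    layers.append(nnet.Dropout(spec.dropout_conv[i], rng))
                n_ch = ch
            flat = n_ch * n_t
        elif kind == "conv2d-spectrogram":
            front = nnet.SpectrogramFront(spec.sample_rate,
                                          fe.get("win_s", 0.025), fe.get("hop_s", 0.010))
            layers.append(front)
            n_f, n_t2 = front.out_shape(n_t)
            n_ch = 1
            for i, (ch, k, stride) in enumerate(spec.conv_layers):
                if k != stride:
                    raise ValueError("2-D blocks require kernel == stride")
                layers.append(nnet.Conv2dTiled(n_ch, ch, k, rng))
                n_f, n_t2 = -(-n_f // k), -(-n_t2 // k)
                pool = spec.pool_size[i]
                layers += [nnet.MaxPool2dTiled(pool), nnet.BatchNorm(ch),
                           nnet.LayerNorm(), nnet.LeakyReLU()]
                n_f, n_t2 = -(-n_f // pool), -(-n_t2 // pool)
                if spec.dropout_conv[i] > 0:
                    layers.append(nnet.Dropout(spec.dropout_conv[i], rng))
                n_ch = ch
            flat = n_ch * n_f * n_t2
        else:
            raise ValueError(f"unknown front end {kind!r}")

        layers.append(nnet.Flatten())
        n_in = flat
        for width, p in zip(spec.fc_layers, spec.dropout_fc):
            layers += [nnet.Linear(n_in, width, rng), nnet.BatchNorm(width),
                       nnet.LayerNorm(), nnet.LeakyReLU()]
            if p > 0:
                layers.append(nnet.Dropout(p, rng))
            n_in = width
        self.hidden = nnet.Sequential(layers)
        self.head = nnet.Linear(n_in, spec.n_classes, rng)
        self.embed_dim = n_in
        self.front = layers[0]

    # -- inference --------------------------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.spec.chunk_len:
            raise ValueError(
                f"chunk length {x.shape[1]} != configured {self.spec.chunk_len}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in input chunk")
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.hidden.forward(x, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        self.hidden.backward(self.head.backward(dlogits))

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        """(B, chunk_len) -> (B, n_classes) posterior rows (inference mode)."""
        return nnet.softmax(self.forward_logits(self._check_batch(x), train=False))

    def embed_batch(self, x: np.ndarray) -> np.ndarray:
        return self.hidden.forward(self._check_batch(x), train=False)

    # -- bookkeeping ------------------------------------------------------

    def params(self) -> list[nnet.Parameter]:
        return self.hidden.params() + self.head.params()

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for layer in self.hidden.layers:
            if isinstance(layer, nnet.BatchNorm):
                state += [layer.run_mean.copy(), layer.run_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        i = len(ps)
        for layer in self.hidden.layers:
            if isinstance(layer, nnet.BatchNorm):
                layer.run_mean[...] = state[i]
                layer.run_var[...] = state[i + 1]
                i += 2

    def front_kernels(self) -> np.ndarray:
        """Current (n_filters, kernel_len) front-end kernels (1-D models)."""
        f = self.front
        if isinstance(f, nnet.SincConv1d):
            return f._current_bank().kernels()
        if isinstance(f, nnet.Conv1dFront):
            return f.weight.value.copy()
        raise ValueError("2-D front end has no 1-D kernels")

    def front_bank(self) -> SincFilterBank:
        if not isinstance(self.front, nnet.SincConv1d):
            raise ValueError("model has no sinc front end")
        return self.front._current_bank()


def build_model(spec: NetworkSpec, seed: int = 0) -> VoiceNet:
    return VoiceNet(spec, seed=seed)


def count_learnable_params(spec: NetworkSpec) -> int:
    """Symbolic parameter count from the spec alone (audit oracle).

    Tracks only multiplies/adds declared by the spec: front end, conv
    weights+biases, batch-norm affine pairs, FC weights+biases and the
    softmax head.
    """
    fe = spec.front_end
    total = 0
    n_t = spec.chunk_len
    if fe["kind"] == "sinc":
        total += 2 * fe["n_filters"]
    elif fe["kind"] == "conv1d":
        total += fe["n_filters"] * fe["kernel"] + fe["n_filters"]
    if fe["kind"] in ("sinc", "conv1d"):
        n_ch = fe["n_filters"]
        n_t = (n_t - fe["kernel"] + 1) // spec.pool_size[0]
        total += 2 * n_ch  # batch-norm affine
        for i, (ch, k, _s) in enumerate(spec.conv_layers):
            total += ch * n_ch * k + ch + 2 * ch
            n_t = (n_t - k + 1) // spec.pool_size[i + 1]
            n_ch = ch
        flat = n_ch * n_t
    else:
        nperseg = int(round(fe.get("win_s", 0.025) * spec.sample_rate))
        hop = int(round(fe.get("hop_s", 0.010) * spec.sample_rate))
        n_f = nperseg // 2 + 1
        n_t = (spec.chunk_len - nperseg) // hop + 1
        n_ch = 1
        for i, (ch, k, _s) in enumerate(spec.conv_layers):
            total += ch * n_ch * k * k + ch + 2 * ch
            n_f = -(-(-(-n_f // k)) // spec.pool_size[i])  # ceil conv, ceil pool
            n_t = -(-(-(-n_t // k)) // spec.pool_size[i])
            n_ch = ch
        flat = n_ch * n_f * n_t
    n_in = flat
    for width in spec.fc_layers:
        total += n_in * width + width + 2 * width
        n_in = width
    total += n_in * spec.n_classes + spec.n_classes
    return total


def predict_chunk(model: VoiceNet, chunk: np.ndarray) -> np.ndarray:
    """Posterior probabilities for one normalized chunk (sums to 1)."""
    return model.predict_batch(np.asarray(chunk)[None, :])[0]


def extract_embedding(model: VoiceNet, chunk: np.ndarray) -> np.ndarray:
    """Activation vector feeding the softmax layer, dropout off."""
    return model.embed_batch(np.asarray(chunk)[None, :])[0]
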