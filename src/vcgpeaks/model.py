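"""The compact 1-D encoder-decoder segmentation network.

Architecture (default input: 2048 samples x 3 VCG channels):

* Encoder: six convolutions with kernel sizes (9, 9, 6, 6, 3, 3) and filter
  counts (16, 16, 32, 32, 64, 64), 'same' padding, leaky-ReLU (slope 0.25).
  Each of the last five is followed by batch normalization and factor-2
  max-pooling, so the bottleneck length is input_length / 32.
* Decoder: the exact mirror — five stride-2 transposed convolutions with
  kernels (3, 3, 6, 6, 9) and filters (64, 32, 32, 16, 16), each followed
  by leaky-ReLU and batch normalization, then concatenation with the
  encoder feature that entered the mirrored encoder convolution. Dropout
  (rate 0.25) acts on the first decoder block only.
* Head: a single-filter kernel-9 convolution with sigmoid activation
  emitting one R-peak probability per input sample (no batch norm,
  mirroring the first encoder convolution).

With the default configuration the network has exactly 79,409 trainable
parameters (convolution kernels and biases plus batch-norm scale/shift;
running statistics excluded). The count is a pure function of the
configuration and serves as the architecture's fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import (Adam, BatchNorm, Conv1D, ConvTranspose1D, Dropout,
                 LeakyReLU, MaxPool1D, sigmoid)

ENCODER_KERNELS = (9, 9, 6, 6, 3, 3)
ENCODER_FILTERS = (16, 16, 32, 32, 64, 64)
DECODER_KERNELS = (3, 3, 6, 6, 9)
DECODER_FILTERS = (64, 32, 32, 16, 16)
FINAL_KERNEL = 9


@dataclass
class ModelConfig:
    """Hyperparameters fixing the network topology."""

    input_length: int = 2048
    in_channels: int = 3
    encoder_kernels: tuple = ENCODER_KERNELS
    encoder_filters: tuple = ENCODER_FILTERS
    dropout_rate: float = 0.25
    negative_slope: float = 0.25

    def validate(self):
        if self.input_length % 32 != 0:
            raise ValueError(
                f"input_length must be divisible by 32 (five pooling "
                f"stages); got {self.input_length}")
        if not 1 <= self.in_channels <= 8:
            raise ValueError("in_channels must be between 1 and 8")
        if len(self.encoder_kernels) != 6 or len(self.encoder_filters) != 6:
            raise ValueError("encoder schedule must list 6 layers")


class SegmentationModel:
    """1-D U-Net mapping a normalized window to per-sample probabilities."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        ek, ef = config.encoder_kernels, config.encoder_filters
        a = config.negative_slope

        self.enc_convs, self.enc_acts, self.enc_bns, self.enc_pools = [], [], [], []
        cin = config.in_channels
        for i in range(6):
            self.enc_convs.append(Conv1D(cin, ef[i], ek[i], rng))
            self.enc_acts.append(LeakyReLU(a))
            self.enc_bns.append(BatchNorm(ef[i]) if i > 0 else None)
            self.enc_pools.append(MaxPool1D(2) if i > 0 else None)
            cin = ef[i]

        # mirror schedule; skip sources are the inputs of encoder convs 6..2
        skip_ch = [ef[4], ef[3], ef[2], ef[1], ef[0]]
        self.dec_convs, self.dec_acts, self.dec_bns = [], [], []
        c = ef[5]
        for i in range(5):
            self.dec_convs.append(
                ConvTranspose1D(c, DECODER_FILTERS[i], DECODER_KERNELS[i],
                                rng, stride=2))
            self.dec_acts.append(LeakyReLU(a))
            self.dec_bns.append(BatchNorm(DECODER_FILTERS[i]))
            c = DECODER_FILTERS[i] + skip_ch[i]
        self.dropout = Dropout(config.dropout_rate, rng)
        self.final_conv = Conv1D(c, 1, FINAL_KERNEL, rng)

        self._skip_split = skip_ch

    # -- plumbing -----------------------------------------------------------

    def layers(self):
        out = list(self.enc_convs)
        out += [b for b in self.enc_bns if b is not None]
        out += self.dec_convs + self.dec_bns + [self.final_conv]
        return out

    def named_params(self):
        for i, l in enumerate(self.enc_convs):
            yield f"enc_conv{i+1}", l
        for i, l in enumerate(self.enc_bns):
            if l is not None:
                yield f"enc_bn{i+1}", l
        for i, l in enumerate(self.dec_convs):
            yield f"dec_tconv{i+1}", l
        for i, l in enumerate(self.dec_bns):
            yield f"dec_bn{i+1}", l
        yield "final_conv", self.final_conv

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x, training=False):
        """Raw pre-sigmoid outputs, shape (batch, length)."""
        from .nn import DTYPE
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.input_length or \
                x.shape[2] != self.config.in_channels:
            raise ValueError(
                f"window shape {x.shape[1:]} does not match config "
                f"({self.config.input_length}, {self.config.in_channels})")
        skips = []
        h = x
        for i in range(6):
            skips.append(h)
            h = self.enc_acts[i].forward(self.enc_convs[i].forward(h, training))
            if self.enc_bns[i] is not None:
                h = self.enc_bns[i].forward(h, training)
                h = self.enc_pools[i].forward(h)
        # skips[1:] are the inputs of encoder convs 2..6; decoder uses 6..2
        self._skip_cache = skips
        for i in range(5):
            h = self.dec_convs[i].forward(h, training)
            h = self.dec_acts[i].forward(h)
            h = self.dec_bns[i].forward(h, training)
            if i == 0:
                h = self.dropout.forward(h, training)
            h = np.concatenate([h, skips[5 - i]], axis=2)
        z = self.final_conv.forward(h, training)
        return z[:, :, 0]

    def backward(self, dz):
        """Backpropagate d(loss)/d(logits); fills layer gradients."""
        d = self.final_conv.backward(dz[:, :, None])
        dskips = [None] * 6
        for i in range(4, -1, -1):
            own = self.dec_convs[i].cout
            d, dskip = d[:, :, :own], d[:, :, own:]
            dskips[5 - i] = dskip
            if i == 0:
                d = self.dropout.backward(d)
            d = self.dec_bns[i].backward(d)
            d = self.dec_acts[i].backward(d)
            d = self.dec_convs[i].backward(d)
        for i in range(5, -1, -1):
            if self.enc_bns[i] is not None:
                d = self.enc_pools[i].backward(d)
                d = self.enc_bns[i].backward(d)
            d = self.enc_acts[i].backward(d)
            d = self.enc_convs[i].backward(d)
            if dskips[i] is not None:
                d = d + dskips[i]
        return d

    # -- inference ----------------------------------------------------------

    def predict(self, windows):
        """Per-sample probabilities for a batch of windows (eval mode:
        dropout off, batch norm uses running statistics)."""
        z = self.forward_logits(np.asarray(windows), training=False)
        return sigmoid(z)

    # -- persistence --------------------------------------------------------

    def get_weights(self):
        state = {}
        for name, layer in self.named_params():
            for key, val in layer.params.items():
                state[f"{name}.{key}"] = val.copy()
            if isinstance(layer, BatchNorm):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def set_weights(self, state):
        for name, layer in self.named_params():
            for key in layer.params:
                layer.params[key][...] = state[f"{name}.{key}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]

    def save(self, path):
        """Save weights (.npz) plus a JSON manifest of layer shapes."""
        state = self.get_weights()
        np.savez(path, **state)
        manifest = {
            "config": {
                "input_length": self.config.input_length,
                "in_channels": self.config.in_channels,
            },
            "n_trainable": count_trainable_parameters(self),
            "arrays": {k: list(v.shape) for k, v in state.items()},
        }
        with open(str(path).replace(".npz", "") + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, path, config: ModelConfig | None = None, seed: int = 0):
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        if config is None:
            mpath = str(path).replace(".npz", "") + ".manifest.json"
            with open(mpath) as fh:
                m = json.load(fh)["config"]
            config = ModelConfig(input_length=m["input_length"],
                                 in_channels=m["in_channels"])
        model = cls(config, seed=seed)
        model.set_weights({k: data[k] for k in data.files})
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0
                ) -> SegmentationModel:
    """Build the segmentation network (Xavier-uniform initialized)."""
    return SegmentationModel(config or ModelConfig(), seed=seed)


def count_trainable_parameters(model: SegmentationModel) -> int:
    """Number of independently optimized scalars (conv kernels/biases and
    batch-norm scale/shift; running statistics excluded)."""
    return int(sum(layer.n_trainable for layer in model.layers()))


def predict_window(model: SegmentationModel, window) -> np.ndarray:
    """Probability trace for a single (length, channels) window."""
    return model.predict(np.asarray(window)[None])[0]
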