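"""Truncated AlexNet feature extractor.

The dense layers of AlexNet are removed entirely; only the five-convolution
stack remains, which drops the trainable parameter count from ~61 M to
~2.47 M. Three taps are exposed for the attention module:

* ``layer5`` — output of the 4th convolution block (256 x 13 x 13),
* ``layer6`` — output of the 5th convolution block (256 x 13 x 13),
* ``last``   — the final max-pooled map L (256 x 6 x 6).

The two middle taps are the only adjacent same-resolution 256-channel pair
in the stack, which is what the attention-gate shape algebra requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, MaxPool2d, ReLU

__all__ = [
    "FeatureMap",
    "TruncatedAlexNet",
    "build_truncated_alexnet",
    "alexnet_total_params",
    "INPUT_SIZE",
]

INPUT_SIZE = 224

# (c_in, c_out, kernel, stride, pad) for the canonical AlexNet convolutions
_CONV_SPECS = [
    (3, 64, 11, 4, 2),
    (64, 192, 5, 1, 2),
    (192, 384, 3, 1, 1),
    (384, 256, 3, 1, 1),
    (256, 256, 3, 1, 1),
]


@dataclass
class FeatureMap:
    """A C x h x w activation block (leading batch axis) from a named tap."""

    values: np.ndarray  # (N, C, h, w)
    tap: str  # layer5 | layer6 | last

    @property
    def shape(self):
        return self.values.shape


def alexnet_total_params() -> int:
    """Closed-form trainable-parameter count of the original AlexNet.

    Convolution stack plus the three dense layers (9216-4096, 4096-4096,
    4096-1000), biases included. Evaluates to 61,100,840.
    """
    n = 0
    for c_in, c_out, k, _, _ in _CONV_SPECS:
        n += c_out * c_in * k * k + c_out
    for f_in, f_out in [(256 * 6 * 6, 4096), (4096, 4096), (4096, 1000)]:
        n += f_in * f_out + f_out
    return n


class TruncatedAlexNet:
    """AlexNet convolutional stack with all dense layers removed."""

    def __init__(self, rng: np.random.Generator):
        self.convs = [Conv2d(ci, co, k, s, p, rng) for ci, co, k, s, p in _CONV_SPECS]
        self.relus = [ReLU() for _ in self.convs]
        self.pool1 = MaxPool2d(3, 2)
        self.pool2 = MaxPool2d(3, 2)
        self.pool3 = MaxPool2d(3, 2)

    def parameters(self):
        out = []
        for i, conv in enumerate(self.convs):
            for name, v, g in conv.parameters():
                out.append((f"conv{i + 1}.{name}", v, g))
        return out

    def num_params(self) -> int:
        return sum(v.size for _, v, _ in self.parameters())

    def forward_features(self, x: np.ndarray):
        """Run the stack and return the (layer5, layer6, last) taps.

        Input must be a normalized float32 batch of shape (N, 3, 224, 224).
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2:] != (INPUT_SIZE, INPUT_SIZE):
            raise ValueError(
                f"expected input of shape (N, 3, {INPUT_SIZE}, {INPUT_SIZE}), "
                f"got {x.shape}")
        h = self.convs[0].forward(x, need_input_grad=False)
        h = self.relus[0].forward(h)
        h = self.pool1.forward(h)
        h = self.convs[1].forward(h)
        h = self.relus[1].forward(h)
        h = self.pool2.forward(h)
        h = self.convs[2].forward(h)
        h = self.relus[2].forward(h)
        h = self.convs[3].forward(h)
        m5 = self.relus[3].forward(h)
        h = self.convs[4].forward(m5)
        m6 = self.relus[4].forward(h)
        last = self.pool3.forward(m6)
        return (FeatureMap(m5, "layer5"), FeatureMap(m6, "layer6"),
                FeatureMap(last, "last"))

    def backward(self, g_m5: np.ndarray, g_m6: np.ndarray, g_last: np.ndarray) -> None:
        """Backpropagate gradients arriving at the three taps."""
        g = self.pool3.backward(g_last) + g_m6
        g = self.relus[4].backward(g)
        g = self.convs[4].backward(g)
        g = g + g_m5
        g = self.relus[3].backward(g)
        g = self.convs[3].backward(g)
        g = self.relus[2].backward(g)
        g = self.convs[2].backward(g)
        g = self.pool2.backward(g)
        g = self.relus[1].backward(g)
        g = self.convs[1].backward(g)
        g = self.pool1.backward(g)
        g = self.relus[0].backward(g)
        self.convs[0].backward(g)  # input gradient not needed

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: v.copy() for name, v, _ in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, v, _ in self.parameters():
            v[...] = weights[name]


def build_truncated_alexnet(pretrained: bool = False,
                            checkpoint: str | None = None,
                            init_seed: int = 0) -> TruncatedAlexNet:
    """Build the truncated AlexNet backbone.

    With ``pretrained=False`` (default) convolution weights use Kaiming-normal
    initialization seeded by ``init_seed``. With ``pretrained=True`` a
    checkpoint of ImageNet-trained convolution weights must be supplied;
    no download is ever attempted.
    """
    net = TruncatedAlexNet(np.random.default_rng(init_seed))
    if pretrained:
        if checkpoint is None:
            raise FileNotFoundError(
                "pretrained=True requires an ImageNet convolution-weight "
                "checkpoint path; none was provided and downloads are not "
                "attempted")
        with np.load(checkpoint) as data:
            net.set_weights({k: data[k] for k in data.files})
    return net
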