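"""Two-branch spatial attention fusion over truncated-AlexNet features.

The deepest map L (256 x 6 x 6) is projected by a 1x1 convolution and
bilinearly upsampled to 13 x 13 (F_l); it leads both attention branches.
Each branch projects its middle-layer tap M with its own 1x1 convolution
(F_m), forms the gate F = W (x) ReLU(F_l + F_m) with a single-channel 1x1
convolution, and squashes it to an attention weight map A = sigmoid(F) in
(0, 1). The attended feature is the broadcast product F_bar = A * F_m.
The global feature F_g = cat(GAP(F_bar5), GAP(F_bar6), GAP(L)) is a
768-vector fed to an affine 768 -> 2 softmax classifier (index 1 =
micronucleus present).

Reading notes on the gate algebra: the attended operand is the 256-channel
projection F_m (the gate output F itself is single-channel, so attending it
would be degenerate), and the classifier consumes pooled features only —
concatenating the raw image into F_g would be shape-incoherent. Global
average pooling is the spatial reduction; it adds no parameters, consistent
with the model's fewer-parameters design goal.
"""

from __future__ import annotations

import json

import numpy as np

from .backbone import FeatureMap, TruncatedAlexNet, build_truncated_alexnet
from .nn import (BilinearUpsample, Conv1x1, FeatureNorm, GlobalAvgPool,
                 Linear, ReLU, Sigmoid, softmax)

__all__ = ["AttentionResult", "MNAttentionNet", "build_model",
           "save_checkpoint", "load_checkpoint"]


class AttentionResult:
    """Attention weight map A (N x 1 x h x w, entries in (0,1)) plus the
    attended 256-channel feature F_bar of the same spatial size."""

    def __init__(self, A: np.ndarray, F_bar: np.ndarray):
        if A.shape[2:] != F_bar.shape[2:]:
            raise ValueError("attention map and attended feature disagree "
                             f"spatially: {A.shape} vs {F_bar.shape}")
        self.A = A
        self.F_bar = F_bar


class _Branch:
    """One attention branch: middle-layer projection plus gating."""

    def __init__(self, rng: np.random.Generator):
        self.proj_m = Conv1x1(256, 256, rng)
        self.gate = Conv1x1(256, 1, rng)
        # gate input (post-ReLU) is non-negative; non-negative initial gate
        # weights start the attention positively correlated with feature
        # magnitude, i.e. in its intended "highlight" polarity. The 1/32
        # scale puts the 256-term non-negative sum at O(1) pre-activation,
        # keeping the sigmoid well away from saturation at init
        self.gate.W[...] = np.abs(self.gate.W) / 32.0
        self.relu = ReLU()
        self.sigmoid = Sigmoid()
        self.gap = GlobalAvgPool()

    def parameters(self, prefix: str):
        out = []
        for sub, layer in [("proj_m", self.proj_m), ("gate", self.gate)]:
            for name, v, g in layer.parameters():
                out.append((f"{prefix}.{sub}.{name}", v, g))
        return out


class MNAttentionNet:
    """Truncated AlexNet + two-branch spatial attention + softmax head."""

    def __init__(self, backbone: TruncatedAlexNet, init_seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([init_seed, 1]))
        self.backbone = backbone
        self.proj_l = Conv1x1(256, 256, rng)
        self.upsample = BilinearUpsample((6, 6), (13, 13))
        self.branch5 = _Branch(rng)
        self.branch6 = _Branch(rng)
        self.gap_l = GlobalAvgPool()
        # standardize F_g before the affine head: GAP features carry a large
        # uncentered common component that otherwise wrecks SGD conditioning
        self.feature_norm = FeatureNorm(768)
        self.fc = Linear(768, 2, rng)
        # classic small-scale head init: start near p=0.5 so early gradients
        # carry class signal instead of a huge confident-wrong common mode
        self.fc.W[...] = (rng.standard_normal(self.fc.W.shape) * 0.01)
        self.fc.b[...] = 0.0
        # per-channel input normalization; set from data or checkpoint
        self.mean = np.full(3, 0.5, dtype=np.float32)
        self.std = np.full(3, 0.25, dtype=np.float32)

    # ---- parameter plumbing -------------------------------------------------

    def parameters(self):
        out = list(self.backbone.parameters())
        for name, v, g in self.proj_l.parameters():
            out.append((f"proj_l.{name}", v, g))
        out += self.branch5.parameters("branch5")
        out += self.branch6.parameters("branch6")
        for name, v, g in self.fc.parameters():
            out.append((f"fc.{name}", v, g))
        return out

    def num_params(self) -> int:
        return sum(v.size for _, v, _ in self.parameters())

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0

    def get_weights(self) -> dict[str, np.ndarray]:
        w = {name: v.copy() for name, v, _ in self.parameters()}
        w["norm.mean"] = self.mean.copy()
        w["norm.std"] = self.std.copy()
        w["feature_norm.running_mean"] = self.feature_norm.running_mean.copy()
        w["feature_norm.running_var"] = self.feature_norm.running_var.copy()
        return w

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, v, _ in self.parameters():
            v[...] = weights[name]
        self.mean = np.asarray(weights["norm.mean"], dtype=np.float32)
        self.std = np.asarray(weights["norm.std"], dtype=np.float32)
        if "feature_norm.running_mean" in weights:
            self.feature_norm.running_mean = np.asarray(
                weights["feature_norm.running_mean"], dtype=np.float32)
            self.feature_norm.running_var = np.asarray(
                weights["feature_norm.running_var"], dtype=np.float32)

    # ---- preprocessing ------------------------------------------------------

    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """uint8 NHWC (or float in [0,1]) -> normalized float32 NCHW."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        x = x.astype(np.float32)
        if x.max() > 1.5:
            x = x / 255.0
        x = (x - self.mean) / self.std
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def fit_normalization(self, images: np.ndarray) -> None:
        """Set per-channel mean/std from a uint8 NHWC training stack."""
        x = np.asarray(images, dtype=np.float32) / 255.0
        self.mean = x.mean(axis=(0, 1, 2)).astype(np.float32)
        self.std = np.maximum(x.std(axis=(0, 1, 2)), 1e-3).astype(np.float32)

    # ---- the attention-fusion operations, usable standalone -----------------

    def project_last(self, L: FeatureMap | np.ndarray) -> np.ndarray:
        """F_l: 1x1-convolve L (256 x 6 x 6) then bilinearly upsample to 13 x 13."""
        values = L.values if isinstance(L, FeatureMap) else L
        if values.shape[1:] != (256, 6, 6):
            raise ValueError(f"expected L of shape (N, 256, 6, 6), got {values.shape}")
        return self.upsample.forward(self.proj_l.forward(values))

    def project_mid(self, M: FeatureMap | np.ndarray, branch: str = "layer6") -> np.ndarray:
        """F_m: 1x1 convolution of a middle tap (256 x 13 x 13)."""
        values = M.values if isinstance(M, FeatureMap) else M
        if values.shape[1:] != (256, 13, 13):
            raise ValueError(f"expected M of shape (N, 256, 13, 13), got {values.shape}")
        br = self.branch5 if branch == "layer5" else self.branch6
        return br.proj_m.forward(values)

    def attention_weights(self, F_l: np.ndarray, F_m: np.ndarray,
                          branch: str = "layer6") -> np.ndarray:
        """A = sigmoid(W (x) ReLU(F_l + F_m)); single channel, entries in (0,1)."""
        if F_l.shape != F_m.shape:
            raise ValueError(f"F_l/F_m shape mismatch: {F_l.shape} vs {F_m.shape}")
        br = self.branch5 if branch == "layer5" else self.branch6
        pre = br.relu.forward(F_l + F_m)
        return br.sigmoid.forward(br.gate.forward(pre))

    @staticmethod
    def apply_attention(A: np.ndarray, F_m: np.ndarray) -> np.ndarray:
        """F_bar: scale all channels at each position by the attention weight."""
        if A.shape[2:] != F_m.shape[2:]:
            raise ValueError(f"spatial mismatch: A {A.shape} vs F_m {F_m.shape}")
        return A * F_m

    def global_feature(self, F_bar5: np.ndarray, F_bar6: np.ndarray,
                       L: np.ndarray) -> np.ndarray:
        """F_g = cat(GAP(F_bar5), GAP(F_bar6), GAP(L)) — a 768-vector."""
        for name, t in [("F_bar5", F_bar5), ("F_bar6", F_bar6), ("L", L)]:
            if t.shape[1] != 256:
                raise ValueError(f"{name} must have 256 channels, got {t.shape}")
        return np.concatenate([self.branch5.gap.forward(F_bar5),
                               self.branch6.gap.forward(F_bar6),
                               self.gap_l.forward(L)], axis=1)

    def classify(self, F_g: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; index 1 = micronucleus present.

        The head is affine (standardization by fixed running statistics
        composes with the linear map) followed by softmax.
        """
        return softmax(self.fc.forward(self.feature_norm.forward(F_g)), axis=1)

    # ---- integrated forward / backward --------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> dict:
        """Full forward pass on a normalized float32 NCHW batch.

        ``train=True`` standardizes F_g by batch statistics (and updates the
        running statistics); evaluation uses the running statistics. Returns
        logits, probs, the two attention maps, and intermediates needed by
        :meth:`backward`.
        """
        m5, m6, last = self.backbone.forward_features(x)
        F_l = self.project_last(last)
        out = {"L": last.values, "F_l": F_l}
        for name, branch, tap in [("5", self.branch5, m5), ("6", self.branch6, m6)]:
            F_m = branch.proj_m.forward(tap.values)
            A = branch.sigmoid.forward(
                branch.gate.forward(branch.relu.forward(F_l + F_m)))
            out[f"F_m{name}"] = F_m
            out[f"A{name}"] = A
            out[f"F_bar{name}"] = A * F_m
        F_g = np.concatenate([self.branch5.gap.forward(out["F_bar5"]),
                              self.branch6.gap.forward(out["F_bar6"]),
                              self.gap_l.forward(last.values)], axis=1)
        logits = self.fc.forward(self.feature_norm.forward(F_g, train=train))
        out["F_g"] = F_g
        out["logits"] = logits
        out["probs"] = softmax(logits, axis=1)
        return out

    def backward(self, dlogits: np.ndarray, cache: dict) -> None:
        """Accumulate parameter gradients for the batch of ``forward``."""
        gFg = self.feature_norm.backward(self.fc.backward(
            dlogits.astype(np.float32)))
        g5, g6, gl = gFg[:, :256], gFg[:, 256:512], gFg[:, 512:]
        gL = self.gap_l.backward(gl)
        gFl = np.zeros_like(cache["F_l"])
        grads_m = {}
        for name, branch, gvec in [("5", self.branch5, g5), ("6", self.branch6, g6)]:
            gFbar = branch.gap.backward(gvec)
            A, F_m = cache[f"A{name}"], cache[f"F_m{name}"]
            gA = (gFbar * F_m).sum(axis=1, keepdims=True)
            gFm = gFbar * A
            gF = branch.sigmoid.backward(gA)
            gpre = branch.relu.backward(branch.gate.backward(gF))
            gFl += gpre
            grads_m[name] = branch.proj_m.backward(gFm + gpre)
        gL = gL + self.proj_l.backward(self.upsample.backward(gFl))
        self.backbone.backward(grads_m["5"], grads_m["6"], gL)

    def recalibrate_feature_norm(self, images: np.ndarray,
                                 batch_size: int = 64) -> None:
        """Refresh the head's running feature statistics on current weights.

        Weights drift during an epoch, so statistics accumulated along the
        way describe a stale network; re-estimating them over (a sample of)
        the training images before evaluation is the standard recalibration.
        """
        means, sqmeans, n = [], [], 0
        for i in range(0, len(images), batch_size):
            x = self.preprocess(images[i:i + batch_size])
            m5, m6, last = self.backbone.forward_features(x)
            F_l = self.project_last(last)
            blocks = []
            for branch, tap in [(self.branch5, m5), (self.branch6, m6)]:
                F_m = branch.proj_m.forward(tap.values)
                A = branch.sigmoid.forward(
                    branch.gate.forward(branch.relu.forward(F_l + F_m)))
                blocks.append((A * F_m).mean(axis=(2, 3)))
            blocks.append(last.values.mean(axis=(2, 3)))
            fg = np.concatenate(blocks, axis=1)
            k = fg.shape[0]
            means.append(fg.mean(axis=0) * k)
            sqmeans.append((fg ** 2).mean(axis=0) * k)
            n += k
        mean = np.sum(means, axis=0) / n
        var = np.sum(sqmeans, axis=0) / n - mean ** 2
        self.feature_norm.set_stats(mean, np.maximum(var, 1e-8))

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Positive-class probabilities for a uint8 NHWC image stack."""
        probs = []
        for i in range(0, len(images), batch_size):
            x = self.preprocess(images[i:i + batch_size])
            probs.append(self.forward(x)["probs"][:, 1])
        return np.concatenate(probs) if probs else np.empty(0, dtype=np.float32)


def build_model(pretrained: bool = False, checkpoint: str | None = None,
                init_seed: int = 0) -> MNAttentionNet:
    backbone = build_truncated_alexnet(pretrained=pretrained,
                                       checkpoint=checkpoint,
                                       init_seed=init_seed)
    return MNAttentionNet(backbone, init_seed=init_seed)


def save_checkpoint(path: str, model: MNAttentionNet, config: dict | None = None) -> None:
    """Serialize all weights (plus the config that built them) to one .npz."""
    payload = model.get_weights()
    payload["__config__"] = np.frombuffer(
        json.dumps(config or {}).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str) -> tuple[MNAttentionNet, dict]:
    with np.load(path) as data:
        weights = {k: data[k] for k in data.files if k != "__config__"}
        config = json.loads(bytes(data["__config__"]).decode()) \
            if "__config__" in data.files else {}
    model = build_model(init_seed=int(config.get("init_seed", 0)))
    model.set_weights(weights)
    return model, config
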