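"""The Wavelet-CNN grading architecture.

A VGG-style stack of 3x3/pad-1 convolutions in which spatial resolution is
halved by stride-2 convolutions (never pooling).  The input image is also
run through a T-level Haar multiresolution analysis; at every scale the
four sub-band planes of each colour channel are concatenated channel-wise
into the feature maps of matching spatial size, and a 1x1 projection
convolution restores the stage width where the concatenation changed the
channel count.  Batch normalisation precedes every ReLU.  The trunk ends in
global average pooling, whose output is both the feature vector handed to
the classical classifier heads and the input of a linear softmax head used
when the network is trained end to end.

Layer widths are a free choice in this family of architectures; the default
table below (stem 64, stage widths 128/256/456/572, feature conv 355) was
calibrated once so that the 224x224x3, T=4, 5-class instantiation has
exactly 11,799,109 trainable scalars, and is frozen.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn, wavelet

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "WaveletCNN",
    "build_network",
    "count_parameters",
    "train",
    "extract_features",
    "tiny_config",
]

#: stage widths frozen after calibrating the trainable-parameter budget
DEFAULT_STEM = 64
DEFAULT_BLOCKS = (128, 256, 456, 572)
DEFAULT_FEATURE = 355


@dataclass
class ModelConfig:
    input_side: int = 224
    input_channels: int = 3
    levels: int = 4
    stem_width: int = DEFAULT_STEM
    block_widths: tuple[int, ...] = DEFAULT_BLOCKS
    feature_width: int = DEFAULT_FEATURE
    num_classes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_widths = tuple(self.block_widths)
        if self.input_side % (2 ** self.levels):
            raise ValueError(
                f"input_side={self.input_side} must be divisible by 2**levels={2 ** self.levels}"
            )
        if len(self.block_widths) != self.levels:
            raise ValueError(
                f"block_widths has {len(self.block_widths)} entries; expected one per "
                f"decomposition level ({self.levels})"
            )
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    early_stopping_patience: int = 5
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def _build_table(cfg: ModelConfig) -> list[dict]:
    """The architecture as data: one row per layer, auditable and exportable."""
    rows: list[dict] = []
    side = cfg.input_side
    c_in = cfg.input_channels
    sub_ch = 4 * cfg.input_channels

    def conv(name, k, s, p, ci, co, si, so, shortcut=False):
        rows.append(dict(name=name, kind="conv", kernel=k, stride=s, padding=p,
                         in_ch=ci, out_ch=co, side_in=si, side_out=so,
                         shortcut=shortcut, injection=None))

    def bn_relu(name, c, s):
        rows.append(dict(name=f"{name}.bn", kind="bn", kernel=None, stride=None,
                         padding=None, in_ch=c, out_ch=c, side_in=s, side_out=s,
                         shortcut=False, injection=None))
        rows.append(dict(name=f"{name}.relu", kind="relu", kernel=None, stride=None,
                         padding=None, in_ch=c, out_ch=c, side_in=s, side_out=s,
                         shortcut=False, injection=None))

    conv("stem.conv", 3, 1, 1, c_in, cfg.stem_width, side, side)
    bn_relu("stem", cfg.stem_width, side)
    prev = cfg.stem_width
    for t, w in enumerate(cfg.block_widths, start=1):
        conv(f"stage{t}.down", 3, 2, 1, prev, w, side, side // 2)
        side //= 2
        bn_relu(f"stage{t}.down", w, side)
        rows.append(dict(name=f"stage{t}.inject", kind="inject", kernel=None,
                         stride=None, padding=None, in_ch=w, out_ch=w + sub_ch,
                         side_in=side, side_out=side, shortcut=False, injection=t))
        conv(f"stage{t}.proj", 1, 1, 0, w + sub_ch, w, side, side, shortcut=True)
        bn_relu(f"stage{t}.proj", w, side)
        conv(f"stage{t}.conv", 3, 1, 1, w, w, side, side)
        bn_relu(f"stage{t}.conv", w, side)
        prev = w
    conv("feature.conv", 3, 1, 1, prev, cfg.feature_width, side, side)
    bn_relu("feature", cfg.feature_width, side)
    rows.append(dict(name="gap", kind="gap", kernel=None, stride=None, padding=None,
                     in_ch=cfg.feature_width, out_ch=cfg.feature_width,
                     side_in=side, side_out=1, shortcut=False, injection=None))
    rows.append(dict(name="head", kind="linear", kernel=None, stride=None, padding=None,
                     in_ch=cfg.feature_width, out_ch=cfg.num_classes,
                     side_in=1, side_out=1, shortcut=False, injection=None))
    return rows


class WaveletCNN:
    """A built network: the layer table plus its trainable state."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        self.layer_table = _build_table(config)
        self.trained = False
        self.history: list[dict] = []
        rng = np.random.default_rng(config.seed)
        self._ops: list[tuple[str, object]] = []
        for row in self.layer_table:
            if row["kind"] == "conv":
                layer = nn.Conv2d(row["in_ch"], row["out_ch"], row["kernel"],
                                  row["stride"], row["padding"], rng=rng)
            elif row["kind"] == "bn":
                layer = nn.BatchNorm2d(row["in_ch"])
            elif row["kind"] == "relu":
                layer = nn.ReLU()
            elif row["kind"] == "gap":
                layer = nn.GlobalAvgPool()
            elif row["kind"] == "linear":
                layer = nn.Linear(row["in_ch"], row["out_ch"], rng=rng)
            elif row["kind"] == "inject":
                layer = None
            else:  # pragma: no cover
                raise ValueError(f"unknown layer kind {row['kind']}")
            self._ops.append((row["kind"], layer, row))
        self._verify_injection_scales()

    # -- construction checks ------------------------------------------------
    def _verify_injection_scales(self) -> None:
        for kind, _layer, row in self._ops:
            if kind == "inject":
                t = row["injection"]
                expected = self.config.input_side // (2 ** t)
                if row["side_in"] != expected:
                    raise ValueError(
                        f"layer {row['name']}: feature-map side {row['side_in']} does not "
                        f"match level-{t} sub-band side {expected}"
                    )

    # -- execution ----------------------------------------------------------
    def _subband_stacks(self, images: np.ndarray) -> list[np.ndarray]:
        """Per-level sub-band batches, shape (N, 4*C, side/2^t, side/2^t)."""
        per_image = [wavelet.decompose_multichannel(img, self.config.levels)
                     for img in images]
        return [np.stack([s[t] for s in per_image]).astype(nn.DTYPE)
                for t in range(self.config.levels)]

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=nn.DTYPE)
        s, c = self.config.input_side, self.config.input_channels
        if images.ndim == 3:
            images = images[None]
        if images.shape[1:] != (s, s, c):
            raise ValueError(
                f"expected images of shape (n, {s}, {s}, {c}), got {images.shape}"
            )
        return images

    def forward(self, images: np.ndarray, training: bool = False,
                subbands: list[np.ndarray] | None = None,
                return_features: bool = False) -> np.ndarray:
        images = self._check_input(images)
        if subbands is None:
            subbands = self._subband_stacks(images)
        x = np.transpose(images, (0, 3, 1, 2)).astype(nn.DTYPE)
        self._inject_splits: list[int] = []
        features = None
        for kind, layer, row in self._ops:
            if kind == "inject":
                sb = subbands[row["injection"] - 1]
                if sb.shape[2] != x.shape[2]:
                    raise ValueError(
                        f"{row['name']}: sub-band side {sb.shape[2]} != "
                        f"feature-map side {x.shape[2]}"
                    )
                self._inject_splits.append(x.shape[1])
                x = np.concatenate([x, sb], axis=1)
            else:
                x = layer.forward(x, training=training)
                if kind == "gap":
                    features = x
                    if return_features:
                        return features.astype(np.float64)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        splits = list(self._inject_splits)
        for kind, layer, _row in reversed(self._ops):
            if kind == "inject":
                d = d[:, :splits.pop(), :, :]  # sub-band branch is not trainable
            else:
                d = layer.backward(d)

    # -- state --------------------------------------------------------------
    @property
    def layers(self) -> list[nn.Layer]:
        return [l for k, l, _ in self._ops if l is not None]

    def state_dict(self) -> dict:
        state = {}
        for i, (kind, layer, row) in enumerate(self._ops):
            if layer is None or not isinstance(layer, nn.Layer):
                continue
            for k, v in layer.params.items():
                state[f"{i}:{row['name']}:{k}"] = v.copy()
            if isinstance(layer, nn.BatchNorm2d):
                state[f"{i}:{row['name']}:running_mean"] = layer.running_mean.copy()
                state[f"{i}:{row['name']}:running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, (kind, layer, row) in enumerate(self._ops):
            if layer is None or not isinstance(layer, nn.Layer):
                continue
            for k in layer.params:
                layer.params[k] = state[f"{i}:{row['name']}:{k}"].copy()
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = state[f"{i}:{row['name']}:running_mean"].copy()
                layer.running_var = state[f"{i}:{row['name']}:running_var"].copy()

    def save(self, path) -> None:
        state = self.state_dict()
        meta = dict(config=asdict(self.config), trained=self.trained, history=self.history)
        np.savez_compressed(path, __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "WaveletCNN":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        net = cls(ModelConfig(**meta["config"]))
        net.load_state_dict(state)
        net.trained = meta["trained"]
        net.history = meta["history"]
        return net

    def export_layer_table(self, path=None) -> str:
        payload = json.dumps(self.layer_table, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def build_network(config: ModelConfig | None = None) -> WaveletCNN:
    """Instantiate the Wavelet CNN for ``config`` with seeded weight init."""
    return WaveletCNN(config or ModelConfig())


def count_parameters(network: WaveletCNN) -> int:
    """Sum of all trainable scalars: conv weights/biases, BN scale/shift, head.

    The Haar analysis filters are fixed, not learned, and are never counted.
    """
    return int(sum(layer.n_params() for layer in network.layers))


def tiny_config(num_classes: int = 5, seed: int = 0) -> ModelConfig:
    """The desk-scale instantiation used by the test-suite: 64x64, T=2."""
    return ModelConfig(input_side=64, levels=2, stem_width=8,
                       block_widths=(12, 16), feature_width=24,
                       num_classes=num_classes, seed=seed)


def train(network: WaveletCNN, images: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig | None = None) -> WaveletCNN:
    """Fit the network end to end with Adam on softmax cross-entropy.

    ``images`` must already be preprocessed to ``(n, side, side, channels)``
    in [0, 1].  Per-epoch loss and training accuracy are recorded in
    ``network.history``; training halts early when accuracy has not improved
    for ``early_stopping_patience`` epochs, and the best weights are
    restored.  Fully reproducible given the seed.
    """
    cfg = cfg or TrainConfig()
    images = network._check_input(images)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    if labels.shape[0] != images.shape[0]:
        raise ValueError("images and labels length mismatch")
    k = network.config.num_classes
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")

    # sub-bands depend only on the input; compute them once
    all_sb = network._subband_stacks(images)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(network.layers, lr=cfg.learning_rate)
    n = images.shape[0]
    best_acc, best_state, since_best = -1.0, None, 0
    network.history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = images[idx]
            sb = [lev[idx] for lev in all_sb]
            logits = network.forward(batch, training=True, subbands=sb)
            loss, dlogits = nn.cross_entropy(logits, labels[idx])
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
        acc = correct / n
        network.history.append(dict(epoch=epoch, loss=float(np.mean(losses)),
                                    accuracy=float(acc)))
        if acc > best_acc:
            best_acc, since_best = acc, 0
            best_state = network.state_dict()
        else:
            since_best += 1
            if since_best >= cfg.early_stopping_patience:
                break
        if acc >= 1.0 and epoch >= 1:
            break
    if best_state is not None:
        network.load_state_dict(best_state)
    network.trained = True
    return network


def extract_features(network: WaveletCNN, images: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    """Global-average-pooling output per image (n x d), evaluation mode."""
    images = network._check_input(images)
    feats = []
    for start in range(0, images.shape[0], batch_size):
        batch = images[start:start + batch_size]
        feats.append(network.forward(batch, training=False, return_features=True))
    if not feats:
        d = network.config.feature_width
        return np.empty((0, d))
    out = np.concatenate(feats, axis=0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite feature values")
    return out
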