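"""Model definitions and training loops.

Three models share one convolutional encoder family over the 23x8 guide
encoding:

* a denoising autoencoder whose encoder, after unsupervised pretraining on
  unlabeled guide windows, becomes the reusable *parent* encoder;
* an on-target efficacy predictor: parent encoder copy + convolutional
  head, softmax output for classification or identity output for
  regression, with the parent fine-tuned at a lower learning rate;
* a two-branch off-target pair predictor: two parent copies (fine-tuned
  separately into distinct branch encoders), channel-wise concatenation of
  the two latent feature maps, then a convolutional head.

Off-target training data are extremely imbalanced (roughly one detected
site per 250 candidate loci), so training consumes bootstrap-balanced
mini-batches: every batch holds exactly half positives and half negatives,
the minority class resampled with replacement while one epoch makes a
single pass over the majority class.

All training is deterministic given (config, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .encoder import CHANNELS, GUIDE_LEN, EncodedGuide, encode_guide, stack_encodings
from .nn import (Adam, BatchNorm, Conv1D, Crop, Dense, Dropout, Flatten,
                 GlobalAvgPool, ReLU, Sequential, Upsample, mse_loss,
                 softmax_cross_entropy, softmax_probs)

__all__ = [
    "LayerSpec",
    "NetworkConfig",
    "ParentEncoder",
    "OnTargetModel",
    "OffTargetModel",
    "EnsembleModel",
    "corrupt_input",
    "corrupt_batch",
    "pretrain_parent",
    "balanced_batches",
    "train_ontarget",
    "train_offtarget",
    "predict_ontarget",
    "predict_offtarget",
]

N_CHANNELS = len(CHANNELS)


@dataclass(frozen=True)
class LayerSpec:
    channels: int
    kernel: int = 3
    stride: int = 1
    batch_norm: bool = True


@dataclass
class NetworkConfig:
    """Architecture + training hyperparameters; the seed is mandatory."""

    seed: int
    task: str = "classification"
    encoder_layers: tuple = (LayerSpec(32, 3, 1), LayerSpec(64, 3, 2),
                             LayerSpec(64, 3, 2))
    head_layers: tuple = (LayerSpec(64, 3, 1), LayerSpec(64, 3, 1))
    mask_prob: float = 0.05
    epi_noise: float = 0.1
    lr_head: float = 1e-3
    lr_parent: float = 1e-4   # fine-tuning rate, 10x below the head's
    batch_size: int = 64
    epochs: int = 20
    finetune: bool = True
    balanced: bool = True
    readout: str = "flatten"  # or "global_avg"
    dropout: float = 0.0
    label_smoothing: float = 0.1
    weight_decay: float = 0.05
    mixup_alpha: float = 0.0   # convex input/target mixing (0 = off)
    skip: bool = True          # linear shortcut input -> output
    ensemble: int = 3
    warmup_frac: float = 0.0   # pair model: fraction of epochs with frozen branches

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must lie in [0, 1]")
        if self.epi_noise < 0:
            raise ValueError("epi_noise must be non-negative")
        if not self.encoder_layers:
            raise ValueError("need at least one encoder layer")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.readout not in ("flatten", "global_avg"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must lie in [0, 1)")
        if self.mixup_alpha < 0:
            raise ValueError("mixup_alpha must be non-negative")
        if self.ensemble < 1:
            raise ValueError("ensemble must be >= 1")
        if not 0.0 <= self.warmup_frac <= 1.0:
            raise ValueError("warmup_frac must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_layers"] = [asdict(s) for s in self.encoder_layers]
        d["head_layers"] = [asdict(s) for s in self.head_layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["encoder_layers"] = tuple(LayerSpec(**s) for s in d["encoder_layers"])
        d["head_layers"] = tuple(LayerSpec(**s) for s in d["head_layers"])
        return cls(**d)

    @classmethod
    def for_ontarget(cls, seed: int, **overrides) -> "NetworkConfig":
        """On-target training defaults: mixup on (labels are noisy and the
        rule largely additive), 30 epochs, 3-member ensemble."""
        kw = dict(mixup_alpha=1.0, epochs=30, ensemble=3)
        kw.update(overrides)
        return cls(seed=seed, **kw)

    @classmethod
    def for_offtarget(cls, seed: int, **overrides) -> "NetworkConfig":
        """Pair-model defaults: no mixup (the label hinges on exact
        guide/site equality per position, which convex mixing destroys),
        bootstrap-balanced batches, single member."""
        kw = dict(mixup_alpha=0.0, epochs=8, ensemble=1, warmup_frac=0.75,
                  lr_parent=2e-5)
        kw.update(overrides)
        return cls(seed=seed, **kw)


def _build_conv_stack(specs, c_in: int, rng) -> tuple[Sequential, int]:
    layers: list[nn.Layer] = []
    c = c_in
    for spec in specs:
        layers.append(Conv1D(c, spec.channels, spec.kernel, spec.stride, rng))
        if spec.batch_norm:
            layers.append(BatchNorm(spec.channels))
        layers.append(ReLU())
        c = spec.channels
    return Sequential(layers), c


def _encoder_out_len(specs, L: int = GUIDE_LEN) -> int:
    for spec in specs:
        L = (L + 2 * (spec.kernel // 2) - spec.kernel) // spec.stride + 1
    return L


def build_encoder(config: NetworkConfig, rng) -> Sequential:
    net, _ = _build_conv_stack(config.encoder_layers, N_CHANNELS, rng)
    return net


def build_decoder(config: NetworkConfig, rng) -> Sequential:
    """Mirror of the encoder: upsample across strided stages, end at 23x8."""
    specs = list(config.encoder_layers)
    c_ins = [N_CHANNELS] + [s.channels for s in specs[:-1]]
    layers: list[nn.Layer] = []
    c = specs[-1].channels
    for spec, c_target in zip(reversed(specs), reversed(c_ins)):
        if spec.stride > 1:
            layers.append(Upsample(spec.stride))
        layers.append(Conv1D(c, c_target, spec.kernel, 1, rng))
        if c_target != N_CHANNELS:
            layers.append(BatchNorm(c_target))
            layers.append(ReLU())
        c = c_target
    layers.append(Crop(GUIDE_LEN))
    return Sequential(layers)


class ParentEncoder:
    """The pretrained (or freshly initialized) encoder shared by all models."""

    def __init__(self, net: Sequential, config: NetworkConfig,
                 loss_trace: list[float] | None = None):
        self.net = net
        self.config = config
        self.loss_trace = loss_trace or []

    @property
    def latent_len(self) -> int:
        return _encoder_out_len(self.config.encoder_layers)

    @property
    def latent_channels(self) -> int:
        return self.config.encoder_layers[-1].channels

    def clone(self) -> Sequential:
        return copy.deepcopy(self.net)

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(X, dtype=np.float64), train=False)

    @classmethod
    def fresh(cls, config: NetworkConfig) -> "ParentEncoder":
        rng = np.random.default_rng(config.seed)
        return cls(build_encoder(config, rng), config)

    def to_state(self) -> dict:
        return {"kind": "parent", "config": self.config.to_dict(),
                "parts": {"encoder": self.net.state_arrays(),
                          "loss_trace": [np.asarray(self.loss_trace)]}}

    @classmethod
    def from_state(cls, state: dict) -> "ParentEncoder":
        config = NetworkConfig.from_dict(state["config"])
        parent = cls.fresh(config)
        parent.net.load_state_arrays(state["parts"]["encoder"])
        parent.loss_trace = list(state["parts"]["loss_trace"][0])
        return parent


# ---------------------------------------------------------------------------
# Input corruption + denoising pretraining
# ---------------------------------------------------------------------------

def corrupt_batch(X: np.ndarray, mask_prob: float, epi_noise: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Corrupt a batch (N, 23, 8): random one-hot swaps + epigenetic noise.

    Each position's nucleotide one-hot is replaced, with probability
    ``mask_prob``, by a uniformly random one-hot (which may equal the
    original). Epigenetic channels get additive Gaussian noise clipped to
    [0, 1]. The nucleotide block stays exactly one-hot.
    """
    X = np.array(X, dtype=np.float64, copy=True)
    n, L = X.shape[0], X.shape[1]
    mask = rng.random((n, L)) < mask_prob
    random_bases = rng.integers(0, 4, size=(n, L))
    onehot = np.eye(4)[random_bases]
    X[:, :, :4] = np.where(mask[:, :, None], onehot, X[:, :, :4])
    if epi_noise > 0:
        X[:, :, 4:] = np.clip(
            X[:, :, 4:] + rng.normal(0.0, epi_noise, size=X[:, :, 4:].shape),
            0.0, 1.0)
    return X


def corrupt_input(x: EncodedGuide, config: NetworkConfig, seed: int) -> EncodedGuide:
    rng = np.random.default_rng(seed)
    out = corrupt_batch(x.values[None], config.mask_prob, config.epi_noise, rng)
    return EncodedGuide(out[0])


def pretrain_parent(X_unlabeled: np.ndarray, config: NetworkConfig) -> ParentEncoder:
    """Train the denoising autoencoder; return its encoder with loss trace."""
    X = np.asarray(X_unlabeled, dtype=np.float64)
    if X.shape[0] < config.batch_size:
        raise ValueError("need at least one full batch of unlabeled guides")
    rng = np.random.default_rng(config.seed)
    encoder = build_encoder(config, rng)
    decoder = build_decoder(config, rng)
    params = encoder.params() + decoder.params()
    opt = Adam(params, lr=config.lr_head)
    trace: list[float] = []
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            clean = X[idx]
            noisy = corrupt_batch(clean, config.mask_prob, config.epi_noise, rng)
            z = encoder.forward(noisy, train=True)
            recon = decoder.forward(z, train=True)
            loss, dloss = mse_loss(recon, clean)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"reconstruction loss diverged at epoch {epoch}: {loss}; "
                    f"trace so far: {trace}")
            for p in params:
                p.grad[...] = 0.0
            encoder.backward(decoder.backward(dloss))
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    parent = ParentEncoder(encoder, config, trace)
    parent.decoder = decoder  # kept for reconstruction diagnostics
    return parent


def reconstruct(parent: ParentEncoder, X: np.ndarray) -> np.ndarray:
    """Run the full autoencoder (requires a pretrained parent)."""
    z = parent.net.forward(np.asarray(X, dtype=np.float64), train=False)
    return parent.decoder.forward(z, train=False)


# ---------------------------------------------------------------------------
# Bootstrap-balanced batching
# ---------------------------------------------------------------------------

def balanced_batches(labels, batch_size: int, seed: int):
    """Index batches for one epoch with exactly equal class counts.

    The majority class is shuffled and partitioned across the epoch (a
    trailing chunk smaller than ``batch_size/2`` is dropped); the minority
    class is bootstrap-resampled with replacement to fill its half of each
    batch. When class counts are equal both classes are partitioned, so
    every sample appears exactly once per epoch.
    """
    labels = np.asarray(labels)
    if batch_size % 2:
        raise ValueError("batch_size must be even")
    half = batch_size // 2
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("balanced batching requires both classes present")
    if len(pos) >= len(neg):
        major, minor = pos, neg
    else:
        major, minor = neg, pos
    rng = np.random.default_rng(seed)
    major = rng.permutation(major)
    n_batches = len(major) // half
    equal = len(minor) == len(major)
    if equal:
        minor = rng.permutation(minor)
    for b in range(n_batches):
        major_half = major[b * half: (b + 1) * half]
        if equal:
            minor_half = minor[b * half: (b + 1) * half]
        else:
            minor_half = rng.choice(minor, size=half, replace=True)
        yield np.concatenate([major_half, minor_half])


# ---------------------------------------------------------------------------
# Supervised models
# ---------------------------------------------------------------------------

def _build_head(config: NetworkConfig, c_in: int, latent_len: int, rng
                ) -> Sequential:
    stack, c = _build_conv_stack(config.head_layers, c_in, rng)
    layers = list(stack.layers)
    if config.readout == "global_avg":
        layers.append(GlobalAvgPool())
        n_feat = c
    else:
        layers.append(Flatten())
        n_feat = c * latent_len
    if config.dropout > 0:
        layers.append(Dropout(config.dropout,
                              np.random.default_rng(rng.integers(2 ** 31))))
    n_out = 2 if config.task == "classification" else 1
    layers.append(Dense(n_feat, n_out, rng))
    return Sequential(layers)


class _SupervisedModel:
    task: str

    def _forward(self, inputs, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _output_to_score(self, out: np.ndarray) -> np.ndarray:
        if self.task == "classification":
            return softmax_probs(out)[:, 1]
        return out[:, 0]


class OnTargetModel(_SupervisedModel):
    """Encoder copy + convolutional head (+ optional linear shortcut).

    The shortcut is a dense layer straight from the flattened 23x8 input
    to the output: position-specific nucleotide and chromatin effects are
    largely additive, so giving the model an explicit low-capacity linear
    path improves generalization from small labeled sets while the
    convolutional path captures interactions.
    """

    def __init__(self, encoder: Sequential, head: Sequential,
                 config: NetworkConfig, skip: Dense | None = None,
                 log: list | None = None):
        self.encoder, self.head, self.config = encoder, head, config
        self.skip = skip
        self.task = config.task
        self.log = log or []

    def _nets(self):
        nets_ = [self.encoder, self.head]
        if self.skip is not None:
            nets_.append(self.skip)
        return nets_

    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        out = self.head.forward(self.encoder.forward(X, train), train)
        if self.skip is not None:
            out = out + self.skip.forward(X.reshape(len(X), -1), train)
        return out

    def _backward(self, X: np.ndarray, dy: np.ndarray) -> np.ndarray:
        dx = self.encoder.backward(self.head.backward(dy))
        if self.skip is not None:
            dx = dx + self.skip.backward(dy).reshape(X.shape)
        return dx

    def params(self):
        return [p for net in self._nets() for p in net.params()]

    def zero_grad(self):
        for net in self._nets():
            net.zero_grad()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability (classification) or real score (regression)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != (GUIDE_LEN, N_CHANNELS):
            raise ValueError(f"expected (N, {GUIDE_LEN}, {N_CHANNELS}) input")
        return self._output_to_score(self._forward(X, train=False))

    def input_grad(self, X: np.ndarray, class_idx: int = 1) -> np.ndarray:
        """d(class score)/d(input), eval mode.

        For classification the class score is the logit margin
        (logit of ``class_idx`` minus the other class's logit) — with a
        two-class softmax only the margin is identifiable, and evidence a
        model encodes by lowering the opposing logit would be invisible
        to a single-logit gradient. Regression uses the output itself.
        """
        X = np.asarray(X, dtype=np.float64)
        out = self._forward(X, train=False)
        dy = np.zeros_like(out)
        if self.task == "classification":
            dy[:, class_idx] = 1.0
            dy[:, 1 - class_idx] = -1.0
        else:
            dy[:, 0] = 1.0
        self.zero_grad()
        dx = self._backward(X, dy)
        self.zero_grad()
        return dx

    def class_score(self, X: np.ndarray, class_idx: int = 1) -> np.ndarray:
        """Logit margin (classification) or raw output (regression)."""
        out = self._forward(np.asarray(X, dtype=np.float64), train=False)
        if self.task == "classification":
            return out[:, class_idx] - out[:, 1 - class_idx]
        return out[:, 0]

    def to_state(self) -> dict:
        parts = {"encoder": self.encoder.state_arrays(),
                 "head": self.head.state_arrays()}
        if self.skip is not None:
            parts["skip"] = [self.skip.W.value, self.skip.b.value]
        return {"kind": "ontarget", "config": self.config.to_dict(),
                "parts": parts}

    @classmethod
    def from_state(cls, state: dict) -> "OnTargetModel":
        config = NetworkConfig.from_dict(state["config"])
        model = _init_ontarget(None, config,
                               np.random.default_rng(config.seed))
        model.encoder.load_state_arrays(state["parts"]["encoder"])
        model.head.load_state_arrays(state["parts"]["head"])
        if "skip" in state["parts"]:
            model.skip.W.value[...] = state["parts"]["skip"][0]
            model.skip.b.value[...] = state["parts"]["skip"][1]
        return model


class OffTargetModel(_SupervisedModel):
    """Two branch encoders + channel-wise merge + convolutional head."""

    def __init__(self, encoder_a: Sequential, encoder_b: Sequential,
                 head: Sequential, config: NetworkConfig,
                 skip: Dense | None = None, log: list | None = None):
        self.encoder_a, self.encoder_b = encoder_a, encoder_b
        self.head, self.config = head, config
        self.skip = skip
        self.task = config.task
        self.log = log or []

    def _nets(self):
        nets_ = [self.encoder_a, self.encoder_b, self.head]
        if self.skip is not None:
            nets_.append(self.skip)
        return nets_

    def _forward(self, inputs, train: bool) -> np.ndarray:
        Xg, Xs = inputs
        za = self.encoder_a.forward(Xg, train)
        zb = self.encoder_b.forward(Xs, train)
        self._split = za.shape[2]
        out = self.head.forward(np.concatenate([za, zb], axis=2), train)
        if self.skip is not None:
            # matched-filter shortcut: the elementwise product of the two
            # parts makes per-position guide/site agreement (the mismatch
            # indicator basis) linearly readable
            self._pair_cache = (Xg, Xs)
            out = out + self.skip.forward((Xg * Xs).reshape(len(Xg), -1), train)
        return out

    def _backward_pair(self, shapes, dy):
        dz = self.head.backward(dy)
        dxa = self.encoder_a.backward(dz[:, :, : self._split])
        dxb = self.encoder_b.backward(dz[:, :, self._split:])
        if self.skip is not None:
            Xg, Xs = self._pair_cache
            dprod = self.skip.backward(dy).reshape(shapes)
            dxa = dxa + dprod * Xs
            dxb = dxb + dprod * Xg
        return dxa, dxb

    def params(self):
        return [p for net in self._nets() for p in net.params()]

    def zero_grad(self):
        for net in self._nets():
            net.zero_grad()

    def predict(self, Xg: np.ndarray, Xs: np.ndarray) -> np.ndarray:
        Xg = np.asarray(Xg, dtype=np.float64)
        Xs = np.asarray(Xs, dtype=np.float64)
        if Xg.shape != Xs.shape or Xg.shape[1:] != (GUIDE_LEN, N_CHANNELS):
            raise ValueError("guide/site parts must both be (N, 23, 8)")
        return self._output_to_score(self._forward((Xg, Xs), train=False))

    def input_grad(self, Xg, Xs, class_idx: int = 1):
        """Pair-input gradients of the class score (margin for
        classification, output for regression)."""
        Xg = np.asarray(Xg, float)
        Xs = np.asarray(Xs, float)
        out = self._forward((Xg, Xs), train=False)
        dy = np.zeros_like(out)
        if self.task == "classification":
            dy[:, class_idx] = 1.0
            dy[:, 1 - class_idx] = -1.0
        else:
            dy[:, 0] = 1.0
        self.zero_grad()
        dxa, dxb = self._backward_pair(Xg.shape, dy)
        self.zero_grad()
        return dxa, dxb

    def class_score(self, Xg, Xs, class_idx: int = 1) -> np.ndarray:
        out = self._forward((np.asarray(Xg, float), np.asarray(Xs, float)),
                            train=False)
        if self.task == "classification":
            return out[:, class_idx] - out[:, 1 - class_idx]
        return out[:, 0]

    def to_state(self) -> dict:
        parts = {"encoder_a": self.encoder_a.state_arrays(),
                 "encoder_b": self.encoder_b.state_arrays(),
                 "head": self.head.state_arrays()}
        if self.skip is not None:
            parts["skip"] = [self.skip.W.value, self.skip.b.value]
        return {"kind": "offtarget", "config": self.config.to_dict(),
                "parts": parts}

    @classmethod
    def from_state(cls, state: dict) -> "OffTargetModel":
        config = NetworkConfig.from_dict(state["config"])
        model = _init_offtarget(None, config,
                                np.random.default_rng(config.seed))
        model.encoder_a.load_state_arrays(state["parts"]["encoder_a"])
        model.encoder_b.load_state_arrays(state["parts"]["encoder_b"])
        model.head.load_state_arrays(state["parts"]["head"])
        if "skip" in state["parts"]:
            model.skip.W.value[...] = state["parts"]["skip"][0]
            model.skip.b.value[...] = state["parts"]["skip"][1]
        return model


class EnsembleModel(_SupervisedModel):
    """Mean-aggregated ensemble of identically configured members.

    Averaging a few independently initialized members suppresses the
    idiosyncratic noise each one memorizes from small, noisily labeled
    training sets; predictions, class scores and input gradients are the
    member means.
    """

    def __init__(self, members: list):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.task = members[0].task
        self.config = members[0].config

    @property
    def log(self):
        return self.members[0].log

    def predict(self, *arrays) -> np.ndarray:
        return np.mean([m.predict(*arrays) for m in self.members], axis=0)

    def class_score(self, *args, **kw) -> np.ndarray:
        return np.mean([m.class_score(*args, **kw) for m in self.members], axis=0)

    def input_grad(self, *args, **kw):
        grads = [m.input_grad(*args, **kw) for m in self.members]
        if isinstance(grads[0], tuple):
            return tuple(np.mean([g[i] for g in grads], axis=0)
                         for i in range(len(grads[0])))
        return np.mean(grads, axis=0)

    def to_state(self) -> dict:
        parts = {}
        kinds = []
        for i, m in enumerate(self.members):
            st = m.to_state()
            kinds.append(st["kind"])
            for name, arrs in st["parts"].items():
                parts[f"m{i}__{name}"] = arrs
        return {"kind": "ensemble", "config": self.config.to_dict(),
                "parts": parts, "member_kinds": kinds}

    @classmethod
    def from_state(cls, state: dict) -> "EnsembleModel":
        groups: dict[int, dict] = {}
        for name, arrs in state["parts"].items():
            tag, sub = name.split("__", 1)
            groups.setdefault(int(tag[1:]), {})[sub] = arrs
        kinds = state.get("member_kinds") or ["ontarget"] * len(groups)
        members = []
        for i in sorted(groups):
            mcls = OnTargetModel if kinds[i] == "ontarget" else OffTargetModel
            members.append(mcls.from_state(
                {"kind": kinds[i], "config": state["config"],
                 "parts": groups[i]}))
        return cls(members)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_labels(y: np.ndarray, task: str) -> np.ndarray:
    y = np.asarray(y)
    if task == "classification":
        if not np.isin(y, (0, 1)).all():
            raise ValueError("classification task requires 0/1 labels")
        return y.astype(np.int64)
    y = y.astype(np.float64)
    if not np.isfinite(y).all():
        raise ValueError("regression task requires finite labels")
    return y


def _targets(y: np.ndarray, task: str, label_smoothing: float) -> np.ndarray:
    """Per-sample training targets (class distribution or real value)."""
    if task == "classification":
        n = len(y)
        t = np.full((n, 2), label_smoothing / 2)
        t[np.arange(n), y] += 1.0 - label_smoothing
        return t
    return np.asarray(y, float)[:, None]


def _loss_and_grad_targets(out: np.ndarray, target: np.ndarray, task: str):
    if task == "classification":
        probs = softmax_probs(out)
        loss = float(-np.mean((target * np.log(probs + 1e-12)).sum(axis=1)))
        return loss, (probs - target) / len(target)
    diff = out - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def _mixup(xs: list[np.ndarray], target: np.ndarray, alpha: float,
           rng: np.random.Generator):
    """Convex input/target mixing; biases the model toward additive
    structure and blunts label-noise memorization."""
    n = len(target)
    lam = rng.beta(alpha, alpha, size=n)
    perm = rng.permutation(n)
    lam_x = lam[:, None, None]
    mixed = [lam_x * x + (1 - lam_x) * x[perm] for x in xs]
    target = lam[:, None] * target + (1 - lam[:, None]) * target[perm]
    return mixed, target


def _member_config(config: NetworkConfig, k: int) -> NetworkConfig:
    if k == 0:
        return config
    d = config.to_dict()
    d["seed"] = (config.seed + 7919 * k) % (2 ** 31)
    return NetworkConfig.from_dict(d)


def _init_ontarget(parent: ParentEncoder | None, config: NetworkConfig, rng
                   ) -> OnTargetModel:
    if parent is None:
        encoder = build_encoder(config, rng)
        ref = ParentEncoder(encoder, config)
        scale = 1.0
    else:
        encoder = parent.clone()
        ref = parent
        scale = 0.0 if not config.finetune else config.lr_parent / config.lr_head
    encoder.set_lr_scale(scale)
    head = _build_head(config, ref.latent_channels, ref.latent_len, rng)
    skip = (Dense(GUIDE_LEN * N_CHANNELS,
                  2 if config.task == "classification" else 1, rng)
            if config.skip else None)
    return OnTargetModel(encoder, head, config, skip)


def _init_offtarget(parent: ParentEncoder | None, config: NetworkConfig, rng
                    ) -> OffTargetModel:
    if parent is None:
        enc_a = build_encoder(config, rng)
        enc_b = build_encoder(config, rng)
        ref = ParentEncoder(enc_a, config)
        scale = 1.0
    else:
        enc_a = parent.clone()
        enc_b = parent.clone()
        ref = parent
        scale = 0.0 if not config.finetune else config.lr_parent / config.lr_head
    enc_a.set_lr_scale(scale)
    enc_b.set_lr_scale(scale)
    head = _build_head(config, 2 * ref.latent_channels, ref.latent_len, rng)
    skip = (Dense(GUIDE_LEN * N_CHANNELS,
                  2 if config.task == "classification" else 1, rng)
            if config.skip else None)
    return OffTargetModel(enc_a, enc_b, head, config, skip)


def _fit(model, X_parts: tuple, y: np.ndarray, config: NetworkConfig,
         rng: np.random.Generator, epochs: int | None = None,
         opt: Adam | None = None) -> None:
    """Shared mini-batch loop for both supervised models."""
    if opt is None:
        opt = Adam(model.params(), lr=config.lr_head,
                   weight_decay=config.weight_decay)
    n = len(y)
    bs = min(config.batch_size, n)
    use_balance = config.balanced and config.task == "classification"
    paired = len(X_parts) == 2
    for epoch in range(config.epochs if epochs is None else epochs):
        if use_balance:
            batch_iter = balanced_batches(y, bs, int(rng.integers(2 ** 31)))
        else:
            order = rng.permutation(n)
            batch_iter = (order[lo: lo + bs] for lo in range(0, n, bs))
        losses = []
        for idx in batch_iter:
            xs = [x[idx] for x in X_parts]
            target = _targets(y[idx], config.task, config.label_smoothing)
            if config.mixup_alpha > 0:
                xs, target = _mixup(xs, target, config.mixup_alpha, rng)
            inputs = (xs[0], xs[1]) if paired else xs[0]
            out = model._forward(inputs, train=True)
            loss, dout = _loss_and_grad_targets(out, target, config.task)
            if not np.isfinite(loss):
                raise RuntimeError(f"training loss diverged at epoch {epoch}")
            model.zero_grad()
            if paired:
                model._backward_pair(xs[0].shape, dout)
            else:
                model._backward(xs[0], dout)
            opt.step()
            losses.append(loss)
        model.log.append({"epoch": epoch, "loss": float(np.mean(losses))})


def train_ontarget(parent: ParentEncoder | None, X: np.ndarray, y: np.ndarray,
                   config: NetworkConfig):
    """Fine-tune the parent encoder and train a fresh head.

    ``parent=None`` trains from scratch (the no-pretraining ablation); with
    ``config.finetune`` off the parent copy inside the model stays frozen
    bit-exactly. ``config.ensemble`` > 1 trains that many members from
    distinct initialization seeds and returns their mean-aggregated
    :class:`EnsembleModel`.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _check_labels(y, config.task)
    members = []
    for k in range(max(1, config.ensemble)):
        mconfig = _member_config(config, k)
        rng = np.random.default_rng(mconfig.seed)
        model = _init_ontarget(parent, mconfig, rng)
        _fit(model, (X,), y, mconfig, rng)
        members.append(model)
    return members[0] if len(members) == 1 else EnsembleModel(members)


def train_offtarget(parent: ParentEncoder | None, Xg: np.ndarray, Xs: np.ndarray,
                    y: np.ndarray, config: NetworkConfig):
    """Train the two-branch pair model on bootstrap-balanced batches.

    With ``config.warmup_frac`` > 0 training is staged: first the
    matched-filter shortcut and output layer learn with the branch
    encoders and convolutional head frozen (the final head dense starts
    at zero so the untrained convolutional pathway cannot drown the
    shortcut), then every pathway trains jointly with the convolutional
    parameters at the fine-tuning rate ``lr_parent``. With a handful of
    unique positives bootstrap-replicated into every balanced batch, an
    unconstrained high-capacity pathway memorizes them within an epoch
    and the model never learns the general mismatch rule; the warm start
    avoids that failure mode.
    """
    Xg = np.asarray(Xg, dtype=np.float64)
    Xs = np.asarray(Xs, dtype=np.float64)
    y = _check_labels(y, config.task)
    members = []
    for k in range(max(1, config.ensemble)):
        mconfig = _member_config(config, k)
        rng = np.random.default_rng(mconfig.seed)
        model = _init_offtarget(parent, mconfig, rng)
        conv_nets = (model.encoder_a, model.encoder_b, model.head)
        warm_epochs = int(round(mconfig.warmup_frac * mconfig.epochs))
        if mconfig.warmup_frac > 0 and model.skip is not None:
            model.head.layers[-1].W.value[...] = 0.0
            saved_scales = [[p.lr_scale for p in net.params()]
                            for net in conv_nets]
            for net in conv_nets:
                net.set_lr_scale(0.0)
            _fit(model, (Xg, Xs), y, mconfig, rng, epochs=warm_epochs)
            joint_scale = mconfig.lr_parent / mconfig.lr_head
            for net, saved in zip(conv_nets, saved_scales):
                for p, s0 in zip(net.params(), saved):
                    p.lr_scale = joint_scale if s0 > 0 else s0
            _fit(model, (Xg, Xs), y, mconfig, rng,
                 epochs=mconfig.epochs - warm_epochs)
        else:
            _fit(model, (Xg, Xs), y, mconfig, rng)
        members.append(model)
    return members[0] if len(members) == 1 else EnsembleModel(members)


def predict_ontarget(model: OnTargetModel, guides) -> np.ndarray:
    """Score encoded guides; accepts an (N,23,8) array or EncodedGuide list."""
    if isinstance(guides, (list, tuple)) and guides and isinstance(
            guides[0], EncodedGuide):
        guides = stack_encodings(list(guides))
    return model.predict(guides)


def predict_offtarget(model: OffTargetModel, pairs) -> np.ndarray:
    """Score encoded pairs; accepts (Xg, Xs) arrays or EncodedPair list."""
    if isinstance(pairs, tuple) and len(pairs) == 2:
        Xg, Xs = pairs
    else:
        Xg = np.stack([p.guide_part.values for p in pairs])
        Xs = np.stack([p.site_part.values for p in pairs])
    return model.predict(Xg, Xs)
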