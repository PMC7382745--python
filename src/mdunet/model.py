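"""The multitask dense-connection U-Net (MDU-Net) computation graph.

Architecture, front to back:

* **Backbone encoder** — a stem stage (3x3 convolution, batch norm, rectifier
  at full resolution) followed by four stages of {transition: 1x1 convolution
  halving the channels + 2x2 average pooling} then {dense block}.  Within a
  dense block every layer receives the concatenation of the block input and
  all previous layer outputs and contributes ``growth_rate`` new channels, so
  a block of L layers widens its input by L x growth_rate.  Five encoder
  stages give four 2x downsamplings; the deepest feature sits at 1/16 scale.
* **Feature adaptation (FA)** — each skip connection passes through a 1x1
  convolution that maps the encoder feature to the decoder's working width,
  balancing the channel budget before fusion.
* **Backbone decoder** — four stages of {2x transposed convolution,
  concatenation with the FA-adapted skip, two 3x3 convolution + batch norm +
  rectifier layers}, restoring full resolution.
* **Feature separation network** — one branch per task (clavicle, anterior
  ribs, posterior ribs, all bones): two 3x3 convolution + rectifier layers
  and a 1x1 convolution to two planes with a per-pixel softmax, emitting the
  (P1 foreground, P2 background) probability pair the mask codec decodes.

The full-scale profile mirrors the dense-201 encoder layout (blocks
[6, 12, 48, 32], growth 32, input 512); the desk profile (input 64, growth 8,
blocks [2, 2, 2, 2]) trains the identical topology on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, relu, avg_pool2x2, softmax_channels, nhwc_to_nchw
from .codec import TASK_NAMES
from .layers import BatchNorm2d, Conv2d, ConvTranspose2x2

__all__ = [
    "ModelConfig", "ConfigurationError", "IncompatibleBackboneError",
    "MDUNet", "build_model", "load_pretrained_backbone",
    "desk_config", "full_config", "DENSE201_BLOCKS", "DENSE201_GROWTH",
]

DENSE201_BLOCKS = (6, 12, 48, 32)
DENSE201_GROWTH = 32


class ConfigurationError(ValueError):
    pass


class IncompatibleBackboneError(RuntimeError):
    """Pretrained weight layout does not match the configured encoder."""


@dataclass(frozen=True)
class ModelConfig:
    n_encoders: int = 5
    n_decoders: int = 4
    n_tasks: int = 4
    input_size: int = 512
    initial_channels: int = 64
    growth_rate: int = 32
    block_lengths: tuple[int, ...] = DENSE201_BLOCKS
    fa_channels: tuple[int, ...] | None = None
    branch_channels: int = 64
    use_pretrained_backbone: bool = False

    def validate(self):
        problems = []
        if self.n_encoders != self.n_decoders + 1:
            problems.append(f"n_encoders ({self.n_encoders}) must equal n_decoders + 1 "
                            f"({self.n_decoders + 1})")
        if len(self.block_lengths) != self.n_encoders - 1:
            problems.append(f"block_lengths must list {self.n_encoders - 1} dense blocks, "
                            f"got {len(self.block_lengths)}")
        if self.fa_channels is not None and len(self.fa_channels) != self.n_decoders:
            problems.append(f"fa_channels must list {self.n_decoders} widths, "
                            f"got {len(self.fa_channels)}")
        for name in ("n_tasks", "initial_channels", "growth_rate", "branch_channels"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.fa_channels is not None and any(c < 1 for c in self.fa_channels):
            problems.append("all fa_channels must be >= 1")
        if any(l < 1 for l in self.block_lengths):
            problems.append("all block_lengths must be >= 1")
        stride = 2 ** (self.n_encoders - 1)
        if self.input_size % stride:
            problems.append(f"input_size ({self.input_size}) must be divisible by "
                            f"2^(n_encoders - 1) = {stride}")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def encoder_channels(self) -> tuple[list[int], int]:
        """Per-skip channel counts (shallow to deep) and the bottleneck width."""
        skips = [self.initial_channels]
        c = self.initial_channels
        for i, length in enumerate(self.block_lengths):
            c = max(1, c // 2) + length * self.growth_rate
            if i < len(self.block_lengths) - 1:
                skips.append(c)
        return skips, c

    def resolved_fa_channels(self) -> tuple[int, ...]:
        """FA widths per decoder, deepest first.

        Defaults to the channel count of the corresponding encoder skip, i.e.
        the FA width D follows the encoder it adapts.
        """
        if self.fa_channels is not None:
            return tuple(self.fa_channels)
        skips, _ = self.encoder_channels()
        return tuple(reversed(skips))


def desk_config(**overrides) -> ModelConfig:
    """Desk-scale profile: the full topology at CPU-trainable size."""
    base = dict(input_size=64, initial_channels=8, growth_rate=8,
                block_lengths=(2, 2, 2, 2), branch_channels=8)
    base.update(overrides)
    return ModelConfig(**base)


def full_config(**overrides) -> ModelConfig:
    """Full-scale profile mirroring the dense-201 encoder at input 512."""
    return ModelConfig(**overrides)


class _DenseBlock:
    def __init__(self, cin, n_layers, growth, rng, name):
        self.name = name
        self.entry_channels = cin
        self.growth = growth
        self.layers = []
        for k in range(n_layers):
            conv = Conv2d(cin + k * growth, growth, 3, rng, name=f"{name}.layer{k}.conv")
            bn = BatchNorm2d(growth, name=f"{name}.layer{k}.bn")
            self.layers.append((conv, bn))
        self.out_channels = cin + n_layers * growth

    def __call__(self, x, training):
        feats = x
        for conv, bn in self.layers:
            y = relu(bn(conv(feats), training))
            feats = concat([feats, y], axis=-1)
        return feats

    def modules(self):
        for conv, bn in self.layers:
            yield conv
            yield bn


class _Transition:
    """1x1 channel compression + 2x2 average pooling between encoder stages."""

    def __init__(self, cin, rng, name):
        self.out_channels = max(1, cin // 2)
        self.conv = Conv2d(cin, self.out_channels, 1, rng, name=f"{name}.conv")
        self.bn = BatchNorm2d(self.out_channels, name=f"{name}.bn")

    def __call__(self, x, training):
        return avg_pool2x2(relu(self.bn(self.conv(x), training)))

    def modules(self):
        yield self.conv
        yield self.bn


class _DecoderStage:
    def __init__(self, cin, skip_ch, width, rng, name):
        self.up = ConvTranspose2x2(cin, width, rng, name=f"{name}.up")
        self.fa = Conv2d(skip_ch, width, 1, rng, name=f"{name}.fa")
        self.conv1 = Conv2d(2 * width, width, 3, rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(width, name=f"{name}.bn1")
        self.conv2 = Conv2d(width, width, 3, rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(width, name=f"{name}.bn2")
        self.out_channels = width

    def __call__(self, x, skip, training):
        fused = concat([self.up(x), self.fa(skip)], axis=-1)
        y = relu(self.bn1(self.conv1(fused), training))
        return relu(self.bn2(self.conv2(y), training))

    def modules(self):
        yield from (self.up, self.fa, self.conv1, self.bn1, self.conv2, self.bn2)


class _Branch:
    """One feature-separation branch: selects task features, emits 2 planes."""

    def __init__(self, cin, width, rng, name):
        self.conv1 = Conv2d(cin, width, 3, rng, name=f"{name}.conv1")
        self.conv2 = Conv2d(width, width, 3, rng, name=f"{name}.conv2")
        self.out = Conv2d(width, 2, 1, rng, name=f"{name}.out")

    def __call__(self, x):
        y = relu(self.conv1(x))
        y = relu(self.conv2(y))
        return softmax_channels(self.out(y))

    def modules(self):
        yield from (self.conv1, self.conv2, self.out)


class MDUNet:
    """Instantiated MDU-Net graph; build with :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(np.random.PCG64(seed))
        skips, bottleneck = config.encoder_channels()
        fa = config.resolved_fa_channels()

        self.stem_conv = Conv2d(1, config.initial_channels, 3, rng, name="encoder.stem.conv")
        self.stem_bn = BatchNorm2d(config.initial_channels, name="encoder.stem.bn")
        self.transitions = []
        self.blocks = []
        c = config.initial_channels
        for i, length in enumerate(config.block_lengths):
            tr = _Transition(c, rng, name=f"encoder.trans{i}")
            blk = _DenseBlock(tr.out_channels, length, config.growth_rate, rng,
                              name=f"encoder.block{i}")
            self.transitions.append(tr)
            self.blocks.append(blk)
            c = blk.out_channels
        assert c == bottleneck

        self.decoders = []
        cin = bottleneck
        for j in range(config.n_decoders):
            skip_ch = skips[config.n_decoders - 1 - j]
            dec = _DecoderStage(cin, skip_ch, fa[j], rng, name=f"decoder{j}")
            self.decoders.append(dec)
            cin = dec.out_channels

        self.branches = []
        self.task_names = TASK_NAMES[: config.n_tasks] if config.n_tasks <= len(TASK_NAMES) \
            else tuple(f"task{t}" for t in range(config.n_tasks))
        for t in range(config.n_tasks):
            self.branches.append(_Branch(cin, config.branch_channels, rng, name=f"branch{t}"))

    # -- introspection -----------------------------------------------------

    @property
    def n_encoder_stages(self):
        return 1 + len(self.blocks)

    @property
    def n_decoder_stages(self):
        return len(self.decoders)

    @property
    def n_branches(self):
        return len(self.branches)

    def describe(self):
        skips, bottleneck = self.config.encoder_channels()
        return {
            "encoder_stages": self.n_encoder_stages,
            "decoder_stages": self.n_decoder_stages,
            "separation_branches": self.n_branches,
            "skip_channels": skips,
            "bottleneck_channels": bottleneck,
            "fa_channels": list(self.config.resolved_fa_channels()),
            "dense_block_widths": [(b.entry_channels, b.out_channels) for b in self.blocks],
        }

    def _modules(self):
        yield self.stem_conv
        yield self.stem_bn
        for tr, blk in zip(self.transitions, self.blocks):
            yield from tr.modules()
            yield from blk.modules()
        for dec in self.decoders:
            yield from dec.modules()
        for br in self.branches:
            yield from br.modules()

    def parameters(self):
        out = []
        for m in self._modules():
            out.extend(m.parameters())
        return out

    def named_parameters(self):
        return {p.name: p for p in self.parameters()}

    def encoder_parameter_names(self):
        return [p.name for p in self.parameters() if p.name.startswith("encoder.")]

    def branch_parameter_names(self, task_index):
        prefix = f"branch{task_index}."
        return [p.name for p in self.parameters() if p.name.startswith(prefix)]

    def state_dict(self):
        state = {p.name: p.data.copy() for p in self.parameters()}
        for m in self._modules():
            if isinstance(m, BatchNorm2d):
                state[f"{m.name}.running_mean"] = m.running_mean.copy()
                state[f"{m.name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        params = self.named_parameters()
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"state dict is missing parameter '{name}'")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for '{name}': "
                                 f"{state[name].shape} vs {p.data.shape}")
            p.data = np.array(state[name], dtype=p.data.dtype)
        for m in self._modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.array(state[f"{m.name}.running_mean"],
                                          dtype=m.running_mean.dtype)
                m.running_var = np.array(state[f"{m.name}.running_var"],
                                         dtype=m.running_var.dtype)

    # -- forward -----------------------------------------------------------

    def forward(self, images, training=False):
        """Images (N, 1, S, S) in [0, 1] -> list of n_tasks (N, 2, S, S) Tensors."""
        arr = images.data if isinstance(images, Tensor) else np.asarray(images, dtype=np.float32)
        if arr.ndim != 4 or arr.shape[1] != 1:
            raise ValueError(f"expected images of shape (N, 1, S, S), got {arr.shape}")
        s = self.config.input_size
        if arr.shape[2] != s or arr.shape[3] != s:
            raise ValueError(f"expected spatial size {s}x{s}, "
                             f"got {arr.shape[2]}x{arr.shape[3]}")
        if arr.min() < -1e-6 or arr.max() > 1.0 + 1e-6:
            raise ValueError("image intensities must lie in [0, 1]")
        # channels-last internally; inputs carry no gradient
        x = Tensor(np.ascontiguousarray(arr.transpose(0, 2, 3, 1)))

        feats = relu(self.stem_bn(self.stem_conv(x), training))
        skips = [feats]
        for tr, blk in zip(self.transitions, self.blocks):
            feats = blk(tr(feats, training), training)
            if blk is not self.blocks[-1]:
                skips.append(feats)
        y = feats
        for j, dec in enumerate(self.decoders):
            y = dec(y, skips[len(skips) - 1 - j], training)
        return [nhwc_to_nchw(branch(y)) for branch in self.branches]

    def predict_probs(self, images):
        """Inference-mode forward returning plain probability arrays."""
        return [t.data for t in self.forward(images, training=False)]


def build_model(config: ModelConfig, seed: int = 0) -> MDUNet:
    """Validate the configuration and instantiate the graph with seeded init."""
    return MDUNet(config, seed=seed)


def load_pretrained_backbone(model: MDUNet, weights_source) -> int:
    """Replace the encoder weights with pretrained values from a local archive.

    The configured encoder must match the published dense-201 layout (blocks
    [6, 12, 48, 32], growth 32, 64 stem channels); anything else raises
    :class:`IncompatibleBackboneError`.  ``weights_source`` is a local ``.npz``
    path keyed by encoder parameter names; every encoder tensor must be
    present with the right shape or nothing is loaded.  Decoders, FA layers
    and branches keep their fresh initialization.  Returns the number of
    tensors loaded.  No download ever happens here.
    """
    cfg = model.config
    if (tuple(cfg.block_lengths) != DENSE201_BLOCKS or cfg.growth_rate != DENSE201_GROWTH
            or cfg.initial_channels != 64):
        raise IncompatibleBackboneError(
            f"encoder layout blocks={tuple(cfg.block_lengths)}, growth={cfg.growth_rate}, "
            f"stem={cfg.initial_channels} does not match the dense-201 layout "
            f"blocks={DENSE201_BLOCKS}, growth={DENSE201_GROWTH}, stem=64")
    import os
    if not os.path.exists(str(weights_source)):
        raise FileNotFoundError(f"pretrained backbone weights not found: {weights_source}")
    archive = np.load(str(weights_source))
    params = model.named_parameters()
    encoder_names = model.encoder_parameter_names()
    staged = {}
    for name in encoder_names:
        if name not in archive:
            raise IncompatibleBackboneError(f"weight archive is missing encoder tensor '{name}'")
        w = np.asarray(archive[name])
        if w.shape != params[name].data.shape:
            raise IncompatibleBackboneError(
                f"shape mismatch for '{name}': archive {w.shape} vs model "
                f"{params[name].data.shape}")
        staged[name] = w
    for name, w in staged.items():  # all-or-nothing: staged only after full check
        params[name].data = w.astype(params[name].data.dtype)
    return len(staged)
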