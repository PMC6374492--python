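"""Two-pathway multi-scale patch network for voxel-wise lesion probability.

The architecture follows the multi-scale patch-classification family used for
3D brain-lesion segmentation: a normal-resolution pathway sees a small patch
around the output voxels, a second pathway sees a three-times-larger context
window downsampled by the same factor, their feature maps are fused on the
output grid and passed through 1x1x1 fused layers into a two-class softmax.
Depth, widths and patch sizes are configurable; the default is a deliberately
small CPU-trainable instance of the same mechanism (an 11-layer-deep clinical
scale is reachable through :class:`NetworkConfig`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..grid import ConfigurationError
from .layers import (
    Conv3d,
    LeakyReLU,
    center_crop,
    center_crop_backward,
    softmax_channels,
    upsample_repeat,
    upsample_repeat_backward,
)


@dataclass(frozen=True)
class NetworkConfig:
    """Shape of the segmentation network.

    ``output_patch`` voxels (cubed) are classified per forward pass; the
    normal pathway consumes ``output_patch + 2 * len(filters)`` voxels per
    side (valid 3x3x3 convolutions), the context pathway a window
    ``context_downsample_factor`` times larger, downsampled by block
    averaging.
    """

    n_input_channels: int = 2
    filters: tuple[int, ...] = (8, 8, 16, 16)
    kernel_size: int = 3
    n_pathways: int = 2
    context_downsample_factor: int = 3
    fc_widths: tuple[int, ...] = (24,)
    output_patch: int = 9
    input_patch_override: int | None = None

    def __post_init__(self):
        if self.n_input_channels not in (1, 2, 3):
            raise ConfigurationError("n_input_channels must be 1, 2 or 3")
        if self.n_pathways not in (1, 2):
            raise ConfigurationError("n_pathways must be 1 or 2")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd")
        if self.output_patch < 1 or self.output_patch % 2 != 1:
            raise ConfigurationError("output_patch must be a positive odd size")
        if self.receptive_field > self.input_patch:
            raise ConfigurationError(
                f"receptive field {self.receptive_field} exceeds input patch {self.input_patch}"
            )
        if self.input_patch != self.output_patch + self.shrink_per_pathway:
            raise ConfigurationError(
                f"input patch {self.input_patch} does not align with output patch "
                f"{self.output_patch} after {len(self.filters)} valid convolutions"
            )

    @property
    def n_layers(self) -> int:
        """Weighted-layer depth (per-pathway convs + fused 1x1x1 + classifier)."""
        return len(self.filters) + len(self.fc_widths) + 1

    @property
    def shrink_per_pathway(self) -> int:
        return len(self.filters) * (self.kernel_size - 1)

    @property
    def receptive_field(self) -> int:
        return 1 + self.shrink_per_pathway

    @property
    def input_patch(self) -> int:
        if self.input_patch_override is not None:
            return self.input_patch_override
        return self.output_patch + self.shrink_per_pathway

    @property
    def context_output(self) -> int:
        return math.ceil(self.output_patch / self.context_downsample_factor)

    @property
    def context_input(self) -> int:
        return self.context_output + self.shrink_per_pathway

    @property
    def context_extent(self) -> int:
        """Full-resolution voxels covered by the context window."""
        return self.context_input * self.context_downsample_factor


class MultiScalePatchNet:
    """The network object: seed-deterministic weights, forward and backward."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = config.kernel_size

        def conv_stack(widths):
            layers = []
            c_in = config.n_input_channels
            for w in widths:
                layers.append(Conv3d(c_in, w, k, rng))
                layers.append(LeakyReLU())
                c_in = w
            return layers

        self.normal_path = conv_stack(config.filters)
        self.context_path = conv_stack(config.filters) if config.n_pathways == 2 else []

        fused_in = config.filters[-1] * config.n_pathways
        self.fused = []
        c_in = fused_in
        for w in config.fc_widths:
            self.fused.append(Conv3d(c_in, w, 1, rng))
            self.fused.append(LeakyReLU())
            c_in = w
        self.classifier = Conv3d(c_in, 2, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def _convs(self):
        for layer in self.normal_path + self.context_path + self.fused + [self.classifier]:
            if isinstance(layer, Conv3d):
                yield layer

    def parameters(self):
        for conv in self._convs():
            yield from conv.parameters()

    def zero_grad(self):
        for conv in self._convs():
            conv.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p, _, _ in self.parameters())

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x_normal, x_context):
        cfg = self.config
        if x_normal.shape[1] != cfg.n_input_channels:
            raise ConfigurationError(
                f"network expects {cfg.n_input_channels} channel(s), got {x_normal.shape[1]}"
            )
        if x_normal.shape[2:] != (cfg.input_patch,) * 3:
            raise ConfigurationError(
                f"normal-pathway patch must be {cfg.input_patch}^3, got {x_normal.shape[2:]}"
            )
        if cfg.n_pathways == 2:
            if x_context is None:
                raise ConfigurationError("two-pathway network needs a context patch")
            if x_context.shape[2:] != (cfg.context_input,) * 3:
                raise ConfigurationError(
                    f"context patch must be {cfg.context_input}^3, got {x_context.shape[2:]}"
                )

    def forward_logits(self, x_normal: np.ndarray, x_context: np.ndarray | None = None) -> np.ndarray:
        self._check_input(x_normal, x_context)
        cfg = self.config
        h = x_normal
        for layer in self.normal_path:
            h = layer.forward(h)
        feats = h
        if cfg.n_pathways == 2:
            hc = x_context
            for layer in self.context_path:
                hc = layer.forward(hc)
            up = upsample_repeat(hc, cfg.context_downsample_factor)
            self._ctx_up_shape = up.shape
            cropped, self._ctx_offs = center_crop(up, cfg.output_patch)
            feats = np.concatenate([h, cropped], axis=1)
            self._split = h.shape[1]
        h = feats
        for layer in self.fused:
            h = layer.forward(h)
        return self.classifier.forward(h)

    def forward(self, x_normal: np.ndarray, x_context: np.ndarray | None = None) -> np.ndarray:
        """Per-voxel class probabilities (B, 2, o, o, o), summing to 1."""
        return softmax_channels(self.forward_logits(x_normal, x_context))

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config
        d = self.classifier.backward(dlogits)
        for layer in reversed(self.fused):
            d = layer.backward(d)
        if cfg.n_pathways == 2:
            d_norm, d_ctx = d[:, : self._split], d[:, self._split :]
            d_up = center_crop_backward(d_ctx, self._ctx_up_shape, self._ctx_offs)
            dc = upsample_repeat_backward(d_up, cfg.context_downsample_factor)
            for layer in reversed(self.context_path):
                dc = layer.backward(dc)
            d = d_norm
        for layer in reversed(self.normal_path):
            d = layer.backward(d)

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict:
        state = {"config": self.config.__dict__ | {}, "seed": self.seed}
        for i, conv in enumerate(self._convs()):
            state[f"w{i}"] = conv.w.copy()
            state[f"b{i}"] = conv.b.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, conv in enumerate(self._convs()):
            conv.w[...] = state[f"w{i}"]
            conv.b[...] = state[f"b{i}"]

    def save(self, path) -> None:
        import json

        cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.config.__dict__.items()}
        arrays = {}
        for i, conv in enumerate(self._convs()):
            arrays[f"w{i}"] = conv.w
            arrays[f"b{i}"] = conv.b
        np.savez(path, __meta__=json.dumps({"config": cfg, "seed": self.seed}), **arrays)

    @classmethod
    def load(cls, path) -> "MultiScalePatchNet":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = {k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["config"].items()}
            net = cls(NetworkConfig(**cfg), seed=meta["seed"])
            for i, conv in enumerate(net._convs()):
                conv.w[...] = data[f"w{i}"]
                conv.b[...] = data[f"b{i}"]
        return net


def build_network(config: NetworkConfig, seed: int = 0) -> MultiScalePatchNet:
    """Construct a seed-deterministic network from its configuration."""
    return MultiScalePatchNet(config, seed)
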