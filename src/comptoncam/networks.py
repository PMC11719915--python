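"""Residual 3D encoder-decoder networks for reconstruction denoising.

All three variants map a few-iteration MLEM volume (normalized to
[0, 1]) to a many-iteration-quality volume, learning only the residual
degradation: ``output = input + n_theta(input)``, so a zero-initialized
network is exactly the identity.  They share the convolutional stages
(3x3x3 conv, batch norm, ReLU) and differ *only* in how the encoder
halves resolution and how the decoder merges the skip branch:

* ``standard`` — orthonormal average pooling/unpooling with channel
  concatenation skips (no frame condition: the low-frequency branch is
  duplicated);
* ``dual_frame`` — the canonical dual-frame synthesis
  ``(I − ΦΦ⊤/2)·skip + Φ·deep/2`` (frame condition holds; condition
  number 2 noise amplification);
* ``tight_frame`` — the 3D Haar tight filter bank (8 subbands): the
  low-pass subband descends a level, the 7 detail subbands skip, and
  the merge is a weighted sum of nine tensors (8 per-subband syntheses
  plus the bypass) with learnable scalar weights — 9 parameters per
  merge point instead of a concatenation convolution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .grids import GridSpec, ImageVolume
from .nn import (
    Adam,
    ConvBlock,
    Conv3d,
    spatial_avg_pool,
    spatial_avg_unpool,
    spatial_haar_analysis,
    spatial_haar_synthesis,
)

__all__ = ["NetworkSpec", "FrameletUNet", "build_network", "predict"]

_VARIANTS = ("standard", "dual_frame", "tight_frame")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``levels`` is the number of resolution halvings (the tight-frame
    network is two-level by default); ``base_channels`` doubles per
    level.  ``residual`` enables the identity skip around the whole
    network.  ``zero_init_output`` starts the last convolution at zero
    so the untrained residual network is the identity map.
    """

    variant: str = "tight_frame"
    levels: int = 2
    base_channels: int = 8
    n_convs: int = 2
    residual: bool = True
    zero_init_output: bool = True

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.levels < 1 or self.base_channels < 1:
            raise ValueError("levels and base_channels must be >= 1")


class FrameletUNet:
    """One of the three encoder-decoder variants (see module docstring)."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.spec = spec
        L = spec.levels
        ch = [spec.base_channels * 2**l for l in range(L + 1)]
        self.enc_blocks = []
        self.dec_blocks = []
        self.merge_weights: list[np.ndarray] = []
        self.merge_grads: list[np.ndarray] = []
        for l in range(L):
            c_in = 1 if l == 0 else ch[l - 1]
            self.enc_blocks.append(ConvBlock(c_in, ch[l], spec.n_convs, rng))
            out_c = spec.base_channels if l == 0 else ch[l - 1]
            merge_c = 2 * ch[l] if spec.variant == "standard" else ch[l]
            self.dec_blocks.append(ConvBlock(merge_c, out_c, spec.n_convs, rng))
            if spec.variant == "tight_frame":
                self.merge_weights.append(np.ones(9))
                self.merge_grads.append(np.zeros(9))
        self.bottleneck_in = ConvBlock(ch[L - 1], ch[L], 1, rng)
        self.bottleneck_out = ConvBlock(ch[L], ch[L - 1], 1, rng)
        self.head = Conv3d(
            spec.base_channels, 1, rng=rng, zero_init=spec.zero_init_output
        )
        self._cache: list[dict] = [{} for _ in range(L)]
        self._cache_top: dict = {}

    # ------------------------------------------------------------ plumbing
    @property
    def params(self):
        blocks = (
            self.enc_blocks
            + self.dec_blocks
            + [self.bottleneck_in, self.bottleneck_out, self.head]
        )
        out = [p for b in blocks for p in b.params]
        return out + self.merge_weights

    @property
    def grads(self):
        blocks = (
            self.enc_blocks
            + self.dec_blocks
            + [self.bottleneck_in, self.bottleneck_out, self.head]
        )
        out = [g for b in blocks for g in b.grads]
        return out + self.merge_grads

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def merge_param_count(self, level: int) -> int:
        """Learnable parameters in the skip merge at ``level``.

        9 scalars for the tight-frame weighted sum; for the other
        variants the merge itself is parameter-free (concatenation or
        the fixed dual-frame synthesis) and the cost shows up in the
        following decoder convolution instead.
        """
        if self.spec.variant == "tight_frame":
            return 9
        return 0

    def _check_shape(self, x: np.ndarray) -> None:
        div = 2**self.spec.levels
        bad = [s for s in x.shape[1:] if s % div]
        if bad:
            raise ValueError(
                f"spatial sizes {x.shape[1:]} must be divisible by {div} "
                f"(levels={self.spec.levels}); pad the input"
            )

    # ------------------------------------------------------------ forward
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Channel-first forward pass; ``x`` has shape (1, X, Y, Z)."""
        x = np.asarray(x, float)
        self._check_shape(x)
        body = self._level_forward(x, 0, training)
        out = self.head.forward(body, training)
        if self.spec.residual:
            out = out + x
        if training:
            self._cache_top = {"residual": self.spec.residual}
        return out

    def _level_forward(self, x, l, training):
        if l == self.spec.levels:
            mid = self.bottleneck_in.forward(x, training)
            return self.bottleneck_out.forward(mid, training)
        variant = self.spec.variant
        enc = self.enc_blocks[l].forward(x, training)
        cache = {}
        if variant == "tight_frame":
            bands = spatial_haar_analysis(enc)
            deep = self._level_forward(bands[0], l + 1, training)
            w = self.merge_weights[l]
            synth = spatial_haar_synthesis(
                [w[0] * deep] + [w[k] * bands[k] for k in range(1, 8)]
            )
            merged = synth + w[8] * enc
            if training:
                cache = {"enc": enc, "bands": bands, "deep": deep}
        else:
            down = spatial_avg_pool(enc)
            deep = self._level_forward(down, l + 1, training)
            if variant == "standard":
                up = spatial_avg_unpool(deep)
                merged = np.concatenate([enc, up], axis=0)
            else:  # dual_frame
                merged = (
                    enc
                    - spatial_avg_unpool(spatial_avg_pool(enc)) / 2.0
                    + spatial_avg_unpool(deep) / 2.0
                )
            if training:
                cache = {"enc_channels": enc.shape[0]}
        if training:
            self._cache[l] = cache
        return self.dec_blocks[l].forward(merged, training)

    # ----------------------------------------------------------- backward
    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate parameter gradients for one sample."""
        g = self.head.backward(np.asarray(grad_out, float))
        self._level_backward(g, 0)

    def _level_backward(self, g_out, l):
        if l == self.spec.levels:
            g = self.bottleneck_out.backward(g_out)
            return self.bottleneck_in.backward(g)
        variant = self.spec.variant
        g_merged = self.dec_blocks[l].backward(g_out)
        if variant == "tight_frame":
            cache = self._cache[l]
            enc, bands, deep = cache["enc"], cache["bands"], cache["deep"]
            w = self.merge_weights[l]
            gw = self.merge_grads[l]
            gw[8] += float(np.vdot(g_merged, enc))
            g_enc = w[8] * g_merged
            g_bands_all = spatial_haar_analysis(g_merged)  # adjoint of synthesis
            gw[0] += float(np.vdot(g_bands_all[0], deep))
            g_deep = w[0] * g_bands_all[0]
            g_b = [None] * 8
            for k in range(1, 8):
                gw[k] += float(np.vdot(g_bands_all[k], bands[k]))
                g_b[k] = w[k] * g_bands_all[k]
            g_b[0] = self._level_backward(g_deep, l + 1)
            g_enc = g_enc + spatial_haar_synthesis(g_b)  # adjoint of analysis
        elif variant == "standard":
            c = self._cache[l]["enc_channels"]
            g_enc = g_merged[:c]
            g_deep = spatial_avg_pool(g_merged[c:])  # adjoint of unpool
            g_down = self._level_backward(g_deep, l + 1)
            g_enc = g_enc + spatial_avg_unpool(g_down)  # adjoint of pool
        else:  # dual_frame
            g_enc = g_merged - spatial_avg_unpool(spatial_avg_pool(g_merged)) / 2.0
            g_deep = spatial_avg_pool(g_merged) / 2.0
            g_down = self._level_backward(g_deep, l + 1)
            g_enc = g_enc + spatial_avg_unpool(g_down)
        self._cache[l] = {}
        return self.enc_blocks[l].backward(g_enc)

    # --------------------------------------------------------- persistence
    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params, self.grads, lr=lr)

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        bn_state = {}
        i = 0
        for block in self.enc_blocks + self.dec_blocks + [
            self.bottleneck_in,
            self.bottleneck_out,
        ]:
            for layer in block.layers:
                if hasattr(layer, "running_mean"):
                    bn_state[f"rm{i}"] = layer.running_mean
                    bn_state[f"rv{i}"] = layer.running_var
                    i += 1
        np.savez(
            path, spec=json.dumps(asdict(self.spec)), **arrays, **bn_state
        )

    @classmethod
    def load(cls, path: str | Path) -> "FrameletUNet":
        data = np.load(path, allow_pickle=False)
        spec = NetworkSpec(**json.loads(str(data["spec"])))
        model = cls(spec)
        for i, p in enumerate(model.params):
            p[...] = data[f"p{i}"]
        i = 0
        for block in model.enc_blocks + model.dec_blocks + [
            model.bottleneck_in,
            model.bottleneck_out,
        ]:
            for layer in block.layers:
                if hasattr(layer, "running_mean"):
                    layer.running_mean[...] = data[f"rm{i}"]
                    layer.running_var[...] = data[f"rv{i}"]
                    i += 1
        return model


def build_network(
    spec: NetworkSpec, rng: np.random.Generator | int = 0
) -> FrameletUNet:
    """Construct one of the three variants from its spec."""
    return FrameletUNet(spec, rng)


def predict(model: FrameletUNet, volume: ImageVolume | np.ndarray) -> ImageVolume:
    """Evaluation-mode prediction, clamped to non-negative intensities.

    The input is expected on the [0, 1] normalized scale used for
    training; a maximum noticeably above 1 triggers a warning.
    """
    arr = volume.values if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    if arr.max() > 1.0 + 1e-6:
        import logging

        logging.getLogger(__name__).warning(
            "input maximum %.3g exceeds 1; expected [0,1]-normalized volumes",
            arr.max(),
        )
    out = model.forward(arr[None], training=False)[0]
    out = np.maximum(out, 0.0)
    grid = (
        volume.grid
        if isinstance(volume, ImageVolume)
        else GridSpec(shape=out.shape, spacing=(1.0, 1.0, 1.0))
    )
    return ImageVolume(grid, out)
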