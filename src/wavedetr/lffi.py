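"""Low-Frequency Feature Integrator (LFFI).

Repeated convolutional downsampling suppresses the low-frequency content that
carries the global shape of large targets. Each LFFI unit re-injects that
content into the backbone's feature stream from two sources and then updates
a running summary:

1. the *approximate image* ``b_n`` — the LL sub-band of the n-th wavelet
   decomposition of the original image (``b_0`` is the image itself, pooled
   by iterated LL extraction to the first injection resolution);
2. the *memory feature* ``a_n`` — the LL sub-band of the previous unit's
   fused output, accumulating low-frequency information across scales
   (initialized ``a_0 = b_0``).

Both are channel-adjusted by 1x1 projections (spatial resolution untouched)
and added element-wise to the main feature map; the fused map's LL sub-band
becomes ``a_{n+1}`` at half resolution. Only LL is kept — the three detail
sub-bands are discarded by design.

This module exposes a plain-numpy functional API (used directly by the tests'
closed-form oracles) and :class:`LFFICascade`, the trainable module the
detector embeds. Projections there are zero-initialized so a fresh model
starts exactly at the unmodified backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .wavelet import WaveletFilterPair, haar_filters, ll_downsample

__all__ = [
    "LFFIState",
    "LFFIUnitConfig",
    "lffi_init",
    "lffi_unit",
    "build_lffi_cascade",
    "LFFIUnit",
    "LFFICascade",
]


@dataclass
class LFFIState:
    """Cascade state after unit ``level``: memory a_n and approximate image b_n."""

    memory: np.ndarray  # (C_feat, H, W)
    approx: np.ndarray  # (C_img, H, W)
    level: int = 0

    def __post_init__(self) -> None:
        if self.memory.shape[-2:] != self.approx.shape[-2:]:
            raise ValueError("memory and approx must share spatial dims")


@dataclass
class LFFIUnitConfig:
    in_channels_image: int = 3
    feature_channels: int = 64
    projection_kind: str = "conv1x1+groupnorm"
    wavelet: str = "haar"

    def __post_init__(self) -> None:
        if self.feature_channels <= 0:
            raise ValueError("feature_channels must be > 0")


def _ll_levels(image: np.ndarray, levels: int, filters: WaveletFilterPair) -> np.ndarray:
    out = image
    for _ in range(levels):
        out = ll_downsample(out, filters)
    return out


def lffi_init(
    image: np.ndarray,
    levels_to_first_unit: int = 0,
    filters: WaveletFilterPair | None = None,
) -> LFFIState:
    """Level-0 state: ``a_0 = b_0``.

    ``b_0`` is the original image pooled by ``levels_to_first_unit``
    applications of LL extraction so its spatial dims match the first
    injection point (0 keeps the raw image).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 2:
        image = image[None]
    filters = filters or haar_filters()
    b0 = _ll_levels(image, levels_to_first_unit, filters)
    return LFFIState(memory=b0.copy(), approx=b0, level=0)


def lffi_unit(
    state: LFFIState,
    main_feature: np.ndarray,
    proj_a: np.ndarray | None = None,
    proj_b: np.ndarray | None = None,
    filters: WaveletFilterPair | None = None,
    next_approx: np.ndarray | None = None,
) -> tuple[np.ndarray, LFFIState]:
    """One functional LFFI unit.

    ``proj_a``/``proj_b`` are channel-mixing matrices (C_out x C_in) standing
    for the 1x1 convolutions; ``None`` means a zero map (additive identity).
    Returns the fused feature (same shape as ``main_feature``) and the next
    state: memory = LL of the fused map (half resolution), approx = the next
    pyramid level (computed as LL of the current approx unless supplied).
    """
    filters = filters or haar_filters()
    main = np.asarray(main_feature, dtype=np.float64)
    if main.shape[-2:] != state.memory.shape[-2:]:
        raise ValueError(
            f"spatial dims of main feature {main.shape[-2:]} != state {state.memory.shape[-2:]}"
        )
    fused = main.copy()
    if proj_b is not None:
        fused += np.einsum("oc,chw->ohw", proj_b, state.approx)
    if proj_a is not None:
        fused += np.einsum("oc,chw->ohw", proj_a, state.memory)
    next_memory = ll_downsample(fused, filters)
    if next_approx is None:
        next_approx = ll_downsample(state.approx, filters)
    return fused, LFFIState(memory=next_memory, approx=np.asarray(next_approx, dtype=np.float64),
                            level=state.level + 1)


def build_lffi_cascade(
    image: np.ndarray,
    n_units: int,
    filters: WaveletFilterPair | None = None,
    feature_channels: tuple[int, ...] | None = None,
) -> tuple[list[np.ndarray], list[LFFIUnitConfig]]:
    """Approximation pyramid b_0..b_{n_units} plus per-unit configs.

    ``b_n`` is the n-fold LL extraction of the original image (``b_0`` the
    image itself).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    if min(image.shape[-2:]) < 2**n_units:
        raise ValueError(f"image too small for {n_units} units")
    filters = filters or haar_filters()
    pyramid = [image]
    for _ in range(n_units):
        pyramid.append(ll_downsample(pyramid[-1], filters))
    channels = feature_channels or tuple(64 * 2**i for i in range(n_units))
    configs = [
        LFFIUnitConfig(in_channels_image=image.shape[0], feature_channels=c,
                       wavelet=filters.name)
        for c in channels
    ]
    return pyramid, configs


# --- trainable cascade -------------------------------------------------------


class LFFIUnit(nn.Module):
    """Channel projections of one unit: 1x1 conv + GroupNorm, zero-initialized."""

    def __init__(self, c_image: int, c_memory: int, c_feature: int, rng: np.random.Generator):
        self.proj_b = nn.Conv2d(c_image, c_feature, 1, rng, zero_init=True)
        self.norm_b = nn.GroupNorm(c_feature)
        self.proj_a = nn.Conv2d(c_memory, c_feature, 1, rng, zero_init=True)
        self.norm_a = nn.GroupNorm(c_feature)

    def forward(self, main: nn.Tensor, approx: nn.Tensor, memory: nn.Tensor) -> nn.Tensor:
        return main + self.norm_b(self.proj_b(approx)) + self.norm_a(self.proj_a(memory))


class LFFICascade(nn.Module):
    """The trainable cascade the detector embeds at its injection points.

    ``feature_channels[i]`` is the backbone width at injection point i; the
    memory entering unit i has the width of the previous fused map (or the
    image channel count at i = 0, since a_0 = b_0).
    """

    def __init__(
        self,
        feature_channels: tuple[int, ...],
        rng: np.random.Generator,
        c_image: int = 3,
        wavelet: str = "haar",
    ):
        from .wavelet import get_filters

        self.filters = get_filters(wavelet)
        self.c_image = c_image
        mem_channels = (c_image,) + feature_channels[:-1]
        self.units = [
            LFFIUnit(c_image, cm, cf, rng)
            for cm, cf in zip(mem_channels, feature_channels)
        ]

    def build_pyramid(self, image: np.ndarray, levels_to_first: int, n_units: int) -> list[nn.Tensor]:
        """b_n tensors for each injection point (constants w.r.t. the graph)."""
        b = _ll_levels(np.asarray(image, dtype=np.float64), levels_to_first, self.filters)
        pyramid = [nn.Tensor(b)]
        for _ in range(n_units - 1):
            b = ll_downsample(b, self.filters)
            pyramid.append(nn.Tensor(b))
        return pyramid

    def apply_unit(self, i: int, main: nn.Tensor, approx: nn.Tensor, memory: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Fuse at injection point i; return (fused, next memory at half res)."""
        fused = self.units[i](main, approx, memory)
        return fused, nn.ll_downsample(fused, self.filters)
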