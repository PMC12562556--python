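"""Separable filter-bank discrete wavelet transform (1-D and 2-D).

The low-frequency feature integrator consumes the LL sub-band of a 2-D
decomposition; this module provides that decomposition, its inverse, and the
multi-level cascade.

Conventions (fixed here because libraries disagree):

* Analysis: ``y_low[i] = sum_k h[k] x[2i + k]``, ``y_high[i] = sum_k g[k] x[2i + k]``
  with periodic extension of ``x``; synthesis is the adjoint, which for an
  orthonormal filter pair is the exact inverse.
* Sub-band naming: ``lh`` = rows low-passed (filtering along axis 1),
  columns high-passed (filtering along axis 0) — the horizontal-detail band
  (a horizontal edge varies down the columns, so the column high-pass sees
  it); ``hl`` is the vertical-detail band. PyWavelets' ``(cH, cV)`` match
  ``(lh, hl)`` here; libraries disagree on this naming, hence the fixed rule.
* Filters are orthonormal (Haar default: ``h = [1/sqrt2, 1/sqrt2]``), so a
  constant field of value ``c`` has LL entries ``2c`` per level and energy is
  conserved across the four sub-bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveletFilterPair",
    "SubbandSet",
    "haar_filters",
    "get_filters",
    "dwt1d",
    "idwt1d",
    "dwt2d",
    "idwt2d",
    "wavedec2d",
]


@dataclass(frozen=True)
class WaveletFilterPair:
    """An orthonormal analysis filter pair.

    ``g`` is derived from ``h`` through the quadrature-mirror relation
    ``g[k] = (-1)^k h[1-k]`` (indices over the filter support), which makes the
    two-scale pair biorthogonal.
    """

    h: np.ndarray
    g: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=np.float64))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=np.float64))
        if self.h.ndim != 1 or self.g.ndim != 1 or self.h.size != self.g.size:
            raise ValueError("h and g must be 1-D filters of equal length")

    @property
    def length(self) -> int:
        return int(self.h.size)


def _mirror(h: np.ndarray) -> np.ndarray:
    """Quadrature mirror g(k) = (-1)^k h(1-k), support re-anchored to 0..L-1.

    Over the natural support the relation places g on indices [2-L, 1];
    shifting by the even amount L-2 (legal under dyadic subsampling) gives
    the equivalent alternating flip g[k] = (-1)^k h[L-1-k].
    """
    L = h.size
    k = np.arange(L)
    return ((-1.0) ** k) * h[L - 1 - k]


def haar_filters() -> WaveletFilterPair:
    """Orthonormal Haar pair: h = [1/sqrt2, 1/sqrt2], g = [1/sqrt2, -1/sqrt2]."""
    h = np.array([1.0, 1.0]) / np.sqrt(2.0)
    return WaveletFilterPair(h=h, g=_mirror(h), name="haar")


def get_filters(name: str) -> WaveletFilterPair:
    """Look up an orthonormal filter pair by name ('haar', 'db2', ...).

    Non-Haar coefficients come from PyWavelets; the high-pass is always
    re-derived from the mirror relation so the pair obeys this module's
    sign convention.
    """
    if name in ("haar", "db1"):
        return haar_filters()
    import pywt

    h = np.asarray(pywt.Wavelet(name).dec_lo, dtype=np.float64)
    if not np.isclose(h @ h, 1.0, atol=1e-10):
        raise ValueError(f"wavelet {name!r} is not orthonormal")
    return WaveletFilterPair(h=h, g=_mirror(h), name=name)


@dataclass
class SubbandSet:
    """The four half-resolution sub-bands of one 2-D decomposition level.

    ``orig_size`` records the pre-padding input (H, W) so the inverse can
    crop an odd-dimension input back exactly.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    level: int = 1
    orig_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(f"sub-band shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ll.shape


def _analyze_axis(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Periodic correlate + stride-2 subsample along one axis (vectorized)."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    if n % 2:
        raise ValueError("axis length must be even")
    L = filt.size
    ext = np.concatenate([x, x[..., : L - 1]], axis=-1) if L > 1 else x
    out = np.zeros(x.shape[:-1] + (n // 2,), dtype=np.result_type(x, np.float32))
    for k in range(L):
        out += filt[k] * ext[..., k : k + n : 2]
    return np.moveaxis(out, -1, axis)


def _synthesize_axis(lo: np.ndarray, hi: np.ndarray, filters: WaveletFilterPair, axis: int) -> np.ndarray:
    """Adjoint of :func:`_analyze_axis` for both channels, summed."""
    lo = np.moveaxis(lo, axis, -1)
    hi = np.moveaxis(hi, axis, -1)
    m = lo.shape[-1]
    n = 2 * m
    L = filters.length
    out = np.zeros(lo.shape[:-1] + (n + L - 1,), dtype=np.result_type(lo, np.float32))
    for k in range(L):
        out[..., k : k + n : 2] += filters.h[k] * lo + filters.g[k] * hi
    if L > 1:  # fold the periodic tail back
        out[..., : L - 1] += out[..., n : n + L - 1]
    out = out[..., :n]
    return np.moveaxis(out, -1, axis)


def _as_float_2d(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={image.ndim}")
    if image.size == 0:
        raise ValueError("empty input image")
    if image.dtype.kind in "iub":
        image = image.astype(np.float64)
    elif image.dtype == np.float16:
        image = image.astype(np.float32)
    return image


def pad_to_even(image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad odd spatial dims to the next even size.

    Returns the padded image and the original (H, W) for inverse cropping.
    """
    h, w = image.shape[-2:]
    ph, pw = h % 2, w % 2
    if ph or pw:
        pad = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
        image = np.pad(image, pad, mode="reflect")
    return image, (h, w)


def dwt2d(image: np.ndarray, filters: WaveletFilterPair | None = None) -> SubbandSet:
    """One-level 2-D decomposition into LL/LH/HL/HH.

    Separable: filter + subsample along axis 0, then along axis 1. Odd
    dimensions are reflect-padded to even first. See the module docstring
    for the sub-band naming rule.
    """
    filters = filters or haar_filters()
    image = _as_float_2d(image)
    image, orig_size = pad_to_even(image)
    lo = _analyze_axis(image, filters.h, axis=0)  # columns low-passed
    hi = _analyze_axis(image, filters.g, axis=0)  # columns high-passed
    return SubbandSet(
        ll=_analyze_axis(lo, filters.h, axis=1),
        lh=_analyze_axis(hi, filters.h, axis=1),  # horizontal detail
        hl=_analyze_axis(lo, filters.g, axis=1),  # vertical detail
        hh=_analyze_axis(hi, filters.g, axis=1),
        level=1,
        orig_size=orig_size,
    )


def idwt2d(subbands: SubbandSet, filters: WaveletFilterPair | None = None) -> np.ndarray:
    """Inverse of :func:`dwt2d`; exact for orthonormal filters and even dims."""
    filters = filters or haar_filters()
    lo = _synthesize_axis(subbands.ll, subbands.hl, filters, axis=1)
    hi = _synthesize_axis(subbands.lh, subbands.hh, filters, axis=1)
    out = _synthesize_axis(lo, hi, filters, axis=0)
    if subbands.orig_size is not None:
        out = out[: subbands.orig_size[0], : subbands.orig_size[1]]
    return out


def wavedec2d(image: np.ndarray, levels: int, filters: WaveletFilterPair | None = None) -> list[SubbandSet]:
    """Multi-level cascade: level n decomposes the LL of level n-1."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    image = _as_float_2d(image)
    if 2**levels > min(image.shape):
        raise ValueError(
            f"levels={levels} too deep for image of shape {image.shape}"
        )
    out: list[SubbandSet] = []
    cur = image
    for n in range(1, levels + 1):
        sb = dwt2d(cur, filters)
        sb.level = n
        out.append(sb)
        cur = sb.ll
    return out


# --- helpers used by the LFFI module (batched, per-channel) -----------------


def ll_downsample(x: np.ndarray, filters: WaveletFilterPair | None = None) -> np.ndarray:
    """LL sub-band along the last two axes of an N-D array (depthwise).

    Used by LFFI's memory update; leading axes (batch, channels) pass through.
    """
    filters = filters or haar_filters()
    x = np.asarray(x)
    if x.shape[-1] % 2 or x.shape[-2] % 2:
        x, _ = pad_to_even(x)
    lo = _analyze_axis(x, filters.h, axis=-2)
    return _analyze_axis(lo, filters.h, axis=-1)


def ll_upsample_adjoint(g: np.ndarray, filters: WaveletFilterPair | None = None) -> np.ndarray:
    """Adjoint of :func:`ll_downsample` (synthesis with zero detail bands)."""
    filters = filters or haar_filters()
    z = np.zeros_like(g)
    lo = _synthesize_axis(g, z, filters, axis=-1)
    zz = np.zeros_like(lo)
    return _synthesize_axis(lo, zz, filters, axis=-2)
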