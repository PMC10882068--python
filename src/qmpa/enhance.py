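"""Statistical contrast enhancement for low-contrast grayscale images.

The pipeline adjusts local and global contrast separately and then fuses
the two results:

1. *Contrast-stretching transform* (CST): a sigmoidal remap centred at the
   image mean ``m``, ``k = 1 / (1 + (m / g)**E)``, with slope constant
   ``E > 0`` (default 0.5).
2. *Global logistic transform*: ``j = exp(g) / (1 + exp(g))``, a standard
   logistic applied to the normalized image.
3. *LIP fusion*: the bounded logarithmic-image-processing addition
   ``(k + j) / (1 + k * j)`` raised to an enhancement exponent ``W > 0``;
   larger ``W`` amplifies contrast.
4. *Linear stretch*: an affine map ``t = alpha * f - beta`` with
   ``alpha = 1 / (max - min)`` and ``beta = min / (max - min)`` so the
   output attains exactly 0 and 1.

All stages operate on intensities normalized to [0, 1]; every stage is
monotone in pixel value, so ordering of intensities is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateImageError",
    "EnhancementParams",
    "normalize_intensity",
    "contrast_stretch_transform",
    "global_logistic",
    "lip_fuse",
    "adaptive_linear_stretch",
    "enhance_image",
]


class DegenerateImageError(ValueError):
    """Raised for inputs the pipeline cannot meaningfully enhance
    (empty, non-finite, all-zero or constant where a spread is required)."""


@dataclass
class EnhancementParams:
    """Tunable parameters of the enhancement pipeline.

    E : slope of the contrast-stretching transform (> 0).
    W : LIP enhancement exponent (> 0); higher values amplify contrast.
    The remaining fields (mean ``m``, stretch coefficients ``alpha`` and
    ``beta``) are computed from the image, not user-set.
    """

    E: float = 0.5
    W: float = 2.0
    m: float | None = field(default=None)
    alpha: float | None = field(default=None)
    beta: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"E must be > 0, got {self.E}")
        if self.W <= 0:
            raise ValueError(f"W must be > 0, got {self.W}")


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.size == 0:
        raise DegenerateImageError("empty image")
    if not np.all(np.isfinite(arr)):
        raise DegenerateImageError("image contains non-finite values")
    return arr


def normalize_intensity(img) -> np.ndarray:
    """Min-max scale an arbitrary-range grayscale array to [0, 1].

    A constant image maps to all 0.5 (there is no contrast to place at
    either end of the range, so the midpoint is the neutral choice).
    """
    arr = _as_image(img)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def contrast_stretch_transform(img, E: float = 0.5) -> np.ndarray:
    """Local contrast-stretching transform k = 1 / (1 + (m/g)**E).

    ``m`` is the mean of the (normalized) input; pixels equal to the mean
    map to 0.5.  ``k`` is extended continuously with k = 0 at g = 0
    (the E > 0 limit).  Raises for an all-zero image, whose mean makes
    the transform undefined everywhere.
    """
    arr = _as_image(img)
    if E <= 0:
        raise ValueError(f"E must be > 0, got {E}")
    m = arr.mean()
    if m <= 0:
        raise DegenerateImageError("all-zero image: CST mean is zero")
    out = np.zeros_like(arr)
    pos = arr > 0
    out[pos] = 1.0 / (1.0 + (m / arr[pos]) ** E)
    return out


def global_logistic(img) -> np.ndarray:
    """Global logistic remap j = exp(g) / (1 + exp(g)).

    On [0, 1] inputs the output lies in [0.5, e/(1+e)] and is monotone.
    """
    arr = _as_image(img)
    return 1.0 / (1.0 + np.exp(-arr))


def lip_fuse(k, j, W: float = 2.0) -> np.ndarray:
    """LIP fusion f = ((k + j) / (1 + k*j))**W of two [0, 1] images.

    The bounded addition (k+j)/(1+kj) stays within [0, 1] because
    (1-k)(1-j) >= 0; raising to W > 0 preserves the range.
    """
    ka, ja = _as_image(k), _as_image(j)
    if ka.shape != ja.shape:
        raise ValueError(f"shape mismatch: {ka.shape} vs {ja.shape}")
    if W <= 0:
        raise ValueError(f"W must be > 0, got {W}")
    return ((ka + ja) / (1.0 + ka * ja)) ** W


def adaptive_linear_stretch(f) -> np.ndarray:
    """Affine stretch t = alpha*f - beta with alpha = 1/(max-min),
    beta = min/(max-min), so the output spans exactly [0, 1].

    Raises :class:`DegenerateImageError` for a constant image (max == min).
    """
    arr = _as_image(f)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise DegenerateImageError("constant image: stretch undefined")
    alpha = 1.0 / (hi - lo)
    beta = lo / (hi - lo)
    return alpha * arr - beta


def enhance_image(img, params: EnhancementParams | None = None) -> np.ndarray:
    """Run the full enhancement pipeline on a raw grayscale array.

    normalize -> CST and logistic branches -> LIP fusion (exponent W)
    -> linear stretch.  Non-degenerate inputs come out spanning [0, 1]
    exactly.  Constant inputs return all 0.5 with a warning rather than
    failing, so a batch run survives blank frames.
    """
    if params is None:
        params = EnhancementParams()
    g = normalize_intensity(img)
    if g.min() == g.max():
        warnings.warn("constant image: returning neutral 0.5 output",
                      stacklevel=2)
        return np.full_like(g, 0.5)
    k = contrast_stretch_transform(g, params.E)
    j = global_logistic(g)
    f = lip_fuse(k, j, params.W)
    params.m = float(g.mean())
    if f.min() == f.max():  # pragma: no cover - needs pathological input
        warnings.warn("degenerate fused image: returning neutral 0.5 output",
                      stacklevel=2)
        return np.full_like(g, 0.5)
    lo, hi = float(f.min()), float(f.max())
    params.alpha = 1.0 / (hi - lo)
    params.beta = lo / (hi - lo)
    return adaptive_linear_stretch(f)
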