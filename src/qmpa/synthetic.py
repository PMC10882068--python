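"""Synthetic phantom images and feature matrices for pipeline testing.

Two generators make every stage of the pipeline exercisable without any
external download:

* :func:`make_phantom_images` builds three classes of low-contrast
  grayscale phantoms.  Each class has its own blob configuration (blob
  count, radius range and intensity offset), all intensities are
  squeezed into a narrow band (default 0.35-0.65) so the contrast stage
  has real work to do, and the default class counts (708, 1426, 930)
  mirror a strongly imbalanced three-class study population.  Phantoms
  are geometric, not anatomical.

* :func:`make_feature_dataset` emulates sigmoid-activated pooled CNN
  features: every value lies strictly in (0, 1); a known subset of
  columns carries class signal (logistic-squashed class-shifted
  Gaussians) and the rest are pure noise.  The permutation placing the
  informative columns is recorded so recovery tests know the planted
  indices.

* :func:`toy_feature_extractor` is a deterministic hand-crafted
  extractor (histogram + coarse grid means + gradient statistics)
  standing in for a CNN backbone behind the same interface.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fusion import LabeledFeatureMatrix

__all__ = [
    "PhantomSpec",
    "FeatureSpec",
    "make_phantom_images",
    "make_feature_dataset",
    "toy_feature_extractor",
]


@dataclass
class PhantomSpec:
    class_counts: tuple = (708, 1426, 930)
    image_side: int = 64
    intensity_band: tuple = (0.35, 0.65)
    noise_sigma: float = 0.02
    seed: int = 0
    # per class: (n_blobs, (r_min_frac, r_max_frac), intensity_offset)
    blob_params: list = field(default_factory=lambda: [
        (2, (0.10, 0.20), 0.9),
        (4, (0.06, 0.12), 0.7),
        (1, (0.20, 0.35), 1.0),
    ])

    def __post_init__(self) -> None:
        lo, hi = self.intensity_band
        if not lo < hi:
            raise ValueError("intensity_band must satisfy low < high")
        if any(c < 1 for c in self.class_counts):
            raise ValueError("class counts must be >= 1")
        if len(self.blob_params) < len(self.class_counts):
            raise ValueError("need blob_params per class")


def _render_phantom(side: int, n_blobs: int, r_frac, offset: float,
                    rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    img = np.zeros((side, side))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.2 * side, 0.8 * side, size=2)
        r = rng.uniform(r_frac[0] * side, r_frac[1] * side)
        # smooth-edged disk so downstream gradients are informative
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        img += offset * np.clip(1.0 - (dist / r) ** 2, 0.0, 1.0)
    return img


def make_phantom_images(spec: PhantomSpec | None = None):
    """Generate the phantom set: (images (N, s, s), labels (N,), manifest).

    The manifest is a list of dicts (index, class, n_blobs) useful for
    CSV export.  Deterministic given the spec's seed.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.intensity_band
    images, labels, manifest = [], [], []
    for ci, count in enumerate(spec.class_counts):
        n_blobs, r_frac, offset = spec.blob_params[ci]
        for k in range(count):
            raw = _render_phantom(spec.image_side, n_blobs, r_frac, offset, rng)
            rmin, rmax = raw.min(), raw.max()
            if rmax > rmin:
                raw = (raw - rmin) / (rmax - rmin)
            img = lo + (hi - lo) * raw
            # noise truncated at +/- 1.5 sigma: its spread stays <= 3 sigma,
            # so each image's dynamic range is bounded by
            # (high - low) + 3 * noise_sigma by construction
            noise = np.clip(rng.normal(0.0, spec.noise_sigma, size=raw.shape),
                            -1.5 * spec.noise_sigma, 1.5 * spec.noise_sigma)
            images.append(np.clip(img + noise, 0.0, 1.0))
            labels.append(ci)
            manifest.append({"index": len(images) - 1, "class": ci,
                             "n_blobs": n_blobs})
    return np.asarray(images), np.asarray(labels), manifest


@dataclass
class FeatureSpec:
    n_per_class: int = 100
    n_classes: int = 3
    d: int = 128
    n_informative: int = 5
    class_sep: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.d:
            raise ValueError("n_informative must be <= d")
        if self.n_per_class < 1 or self.n_classes < 2:
            raise ValueError("need n_per_class >= 1 and >= 2 classes")


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


def make_feature_dataset(spec: FeatureSpec | None = None) -> LabeledFeatureMatrix:
    """Class-labeled feature matrix with values strictly in (0, 1).

    Informative columns are logistic(class_sep * center_{c,j} + N(0,1))
    with per-class unit-normal centers; the rest are logistic(N(0,1))
    noise.  The planted informative column indices (after permutation)
    are stored on the returned matrix as ``informative_indices``.
    """
    if spec is None:
        spec = FeatureSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    centers = rng.normal(0.0, 1.0, size=(spec.n_classes, spec.n_informative))
    raw = rng.normal(0.0, 1.0, size=(n, spec.d))
    raw[:, :spec.n_informative] += spec.class_sep * centers[labels]
    values = _sigmoid(raw)
    perm = rng.permutation(spec.d)
    values = values[:, perm]
    informative = np.flatnonzero(np.isin(perm, np.arange(spec.n_informative)))
    out = LabeledFeatureMatrix(values, labels)
    out.informative_indices = informative
    return out


def toy_feature_extractor(images: np.ndarray, labels: np.ndarray,
                          d_out: int = 128) -> LabeledFeatureMatrix:
    """Deterministic hand-crafted image features, squashed to (0, 1).

    Per image: a 16-bin intensity histogram, 4x4 grid means, and gradient
    magnitude statistics (mean, std, max, plus quartiles), padded with
    smooth harmonics of the existing features (or truncated) to d_out.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] == 0:
        raise ValueError("need a non-empty (N, H, W) image stack")
    feats = []
    for img in images:
        hist, _ = np.histogram(img, bins=16, range=(0.0, 1.0))
        hist = hist / img.size
        gh, gw = 4, 4
        h, w = img.shape
        grid = img[:h - h % gh, :w - w % gw].reshape(
            gh, (h - h % gh) // gh, gw, (w - w % gw) // gw).mean(axis=(1, 3))
        gy, gx = np.gradient(img)
        gm = np.sqrt(gy ** 2 + gx ** 2)
        stats = np.array([gm.mean(), gm.std(), gm.max(),
                          *np.percentile(gm, [25, 50, 75])])
        v = np.concatenate([hist, grid.ravel(), stats])
        feats.append(v)
    F = np.asarray(feats)
    # standardize each base feature, then squash
    mu, sd = F.mean(axis=0), F.std(axis=0)
    F = (F - mu) / np.where(sd > 0, sd, 1.0)
    if F.shape[1] < d_out:
        reps = []
        k = 1
        while sum(b.shape[1] for b in reps) + F.shape[1] < d_out:
            reps.append(np.sin(k * F))  # deterministic nonlinear expansions
            k += 1
        F = np.hstack([F, *reps])[:, :d_out]
    else:
        F = F[:, :d_out]
    return LabeledFeatureMatrix(_sigmoid(F), np.asarray(labels))
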