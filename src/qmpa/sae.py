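"""Single-hidden-layer sparse autoencoder and minority-class augmentation.

The autoencoder has logistic activations on both layers and is trained by
full-batch gradient descent with momentum on the loss

    L = MSE(X, Xhat) + l2 * (sum of squared weights)
        + beta * sum_h KL(rho || rho_hat_h)

where ``rho_hat_h`` is the mean activation of hidden unit ``h`` over the
batch and KL is the Bernoulli Kullback-Leibler divergence.  The KL term
drives mean hidden activations toward the target sparsity proportion
``rho``; the L2 term is weight decay on the weight matrices only (not the
biases).

Augmentation brings each class up to a target count by decoding jittered
encodings of real class members: a random real observation is encoded,
Gaussian noise is added to its code, and the decoder output becomes a new
synthetic observation.  This yields non-duplicate samples, unlike flips
or rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SAEConfig",
    "SparseAutoencoderModel",
    "sae_loss",
    "sae_loss_and_grads",
    "train_sae",
    "reconstruct",
    "augment_dataset",
]

_EPS = 1e-8


@dataclass
class SAEConfig:
    """Sparse-autoencoder training configuration.

    Defaults follow the standard configuration for this augmentation task:
    300 hidden units, 2000 epochs, L2 weight 0.001, sparsity weight 4,
    sparsity proportion 0.15.
    """

    hidden_size: int = 300
    max_epochs: int = 2000
    l2_weight: float = 0.001
    sparsity_reg: float = 4.0
    sparsity_prop: float = 0.15
    learning_rate: float = 0.05
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.max_epochs < 0:
            raise ValueError("hidden_size >= 1 and max_epochs >= 0 required")
        if not 0 < self.sparsity_prop < 1:
            raise ValueError("sparsity_prop must lie in (0, 1)")
        if self.l2_weight < 0 or self.sparsity_reg < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class SparseAutoencoderModel:
    """Trained parameters: logistic encoder and logistic decoder."""

    encoder_weights: np.ndarray  # (hidden, p)
    encoder_bias: np.ndarray     # (hidden,)
    decoder_weights: np.ndarray  # (p, hidden)
    decoder_bias: np.ndarray     # (p,)
    loss_history: list = field(default_factory=list, repr=False)

    @property
    def input_dim(self) -> int:
        return self.encoder_weights.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.encoder_weights.shape[0]


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))


def _init_model(p: int, hidden: int, rng: np.random.Generator) -> SparseAutoencoderModel:
    # Glorot-uniform init keeps logistic pre-activations in the linear regime
    s1 = np.sqrt(6.0 / (p + hidden))
    s2 = np.sqrt(6.0 / (hidden + p))
    return SparseAutoencoderModel(
        encoder_weights=rng.uniform(-s1, s1, size=(hidden, p)),
        encoder_bias=np.zeros(hidden),
        decoder_weights=rng.uniform(-s2, s2, size=(p, hidden)),
        decoder_bias=np.zeros(p),
    )


def encode(model: SparseAutoencoderModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim} columns, got {X.shape[1]}")
    return _sigmoid(X @ model.encoder_weights.T + model.encoder_bias)


def decode(model: SparseAutoencoderModel, H: np.ndarray) -> np.ndarray:
    H = np.atleast_2d(np.asarray(H, dtype=float))
    return _sigmoid(H @ model.decoder_weights.T + model.decoder_bias)


def reconstruct(model: SparseAutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Encode then decode; output has the shape of ``X`` with values in (0, 1)."""
    X2 = np.atleast_2d(np.asarray(X, dtype=float))
    out = decode(model, encode(model, X2))
    return out.reshape(np.shape(X)) if np.ndim(X) == 1 else out


def _kl_bernoulli(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    rh = np.clip(rho_hat, _EPS, 1.0 - _EPS)
    return rho * np.log(rho / rh) + (1 - rho) * np.log((1 - rho) / (1 - rh))


def sae_loss(model: SparseAutoencoderModel, X: np.ndarray, cfg: SAEConfig) -> float:
    """Full training loss: MSE + L2 weight penalty + KL sparsity penalty."""
    return sae_loss_and_grads(model, X, cfg)[0]


def sae_loss_and_grads(model: SparseAutoencoderModel, X: np.ndarray,
                       cfg: SAEConfig):
    """Loss and its analytic gradients w.r.t. all four parameter arrays.

    MSE is averaged over every matrix element; the L2 term is
    ``l2_weight * (||W1||^2 + ||W2||^2)``; the sparsity term is
    ``sparsity_reg * sum_h KL(rho || rho_hat_h)`` with rho_hat clamped
    away from {0, 1} before the KL.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    W1, b1 = model.encoder_weights, model.encoder_bias
    W2, b2 = model.decoder_weights, model.decoder_bias

    H = _sigmoid(X @ W1.T + b1)          # (n, h)
    Xhat = _sigmoid(H @ W2.T + b2)       # (n, p)

    resid = Xhat - X
    mse = float(np.mean(resid ** 2))
    l2 = cfg.l2_weight * (float(np.sum(W1 ** 2)) + float(np.sum(W2 ** 2)))
    rho = cfg.sparsity_prop
    rho_hat = H.mean(axis=0)
    kl = cfg.sparsity_reg * float(np.sum(_kl_bernoulli(rho, rho_hat)))
    loss = mse + l2 + kl

    # backprop
    d_xhat = 2.0 * resid / resid.size
    d_a2 = d_xhat * Xhat * (1.0 - Xhat)
    gW2 = d_a2.T @ H + 2.0 * cfg.l2_weight * W2
    gb2 = d_a2.sum(axis=0)

    rh = np.clip(rho_hat, _EPS, 1.0 - _EPS)
    d_rho_hat = cfg.sparsity_reg * (-(rho / rh) + (1 - rho) / (1 - rh))
    d_h = d_a2 @ W2 + d_rho_hat / n
    d_a1 = d_h * H * (1.0 - H)
    gW1 = d_a1.T @ X + 2.0 * cfg.l2_weight * W1
    gb1 = d_a1.sum(axis=0)

    return loss, {"encoder_weights": gW1, "encoder_bias": gb1,
                  "decoder_weights": gW2, "decoder_bias": gb2}


def train_sae(X: np.ndarray, cfg: SAEConfig | None = None) -> SparseAutoencoderModel:
    """Train by full-batch gradient descent with momentum.

    Deterministic given ``cfg.seed``.  Aborts with a diagnostic if the
    loss goes non-finite (divergence, e.g. too large a learning rate).
    """
    if cfg is None:
        cfg = SAEConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    rng = np.random.default_rng(cfg.seed)
    model = _init_model(X.shape[1], cfg.hidden_size, rng)
    vel = {k: np.zeros_like(getattr(model, k))
           for k in ("encoder_weights", "encoder_bias",
                     "decoder_weights", "decoder_bias")}
    for epoch in range(cfg.max_epochs):
        loss, grads = sae_loss_and_grads(model, X, cfg)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={loss}; "
                "reduce learning_rate")
        model.loss_history.append(loss)
        for k, g in grads.items():
            vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * g
            setattr(model, k, getattr(model, k) + vel[k])
    model.loss_history.append(sae_loss(model, X, cfg))
    return model


def augment_dataset(images: np.ndarray, labels: np.ndarray,
                    target_per_class: int, cfg: SAEConfig | None = None,
                    *, jitter_sigma: float = 0.05, per_class: bool = True):
    """Bring every class up to ``max(original count, target_per_class)``.

    images : (N, ...) array; trailing dimensions are flattened for the SAE
        and restored on output.  Values must lie in [0, 1].
    labels : (N,) class identifiers.
    per_class : train one SAE per class (default) or a single global one.

    Returns ``(aug_images, aug_labels, provenance)`` where provenance is a
    boolean array, True for original rows and False for synthetic ones.
    Classes already at or above the target pass through unchanged.
    """
    if cfg is None:
        cfg = SAEConfig()
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("images and labels must align")
    tail_shape = images.shape[1:]
    flat = images.reshape(images.shape[0], -1)

    classes = np.unique(labels)
    rng = np.random.default_rng(cfg.seed)
    global_model = None
    if not per_class:
        global_model = train_sae(flat, cfg)

    # real rows keep their original order; synthetic rows are appended
    out_rows = [flat]
    out_labels = list(labels)
    out_real = [True] * len(labels)
    for ci, c in enumerate(classes):
        idx = np.flatnonzero(labels == c)
        Xc = flat[idx]
        deficit = target_per_class - len(idx)
        if deficit <= 0:
            continue
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 observations")
        if per_class:
            ccfg = SAEConfig(**{**cfg.__dict__, "seed": cfg.seed + ci + 1})
            model = train_sae(Xc, ccfg)
        else:
            model = global_model
        picks = rng.integers(0, len(idx), size=deficit)
        codes = encode(model, Xc[picks])
        codes = codes + rng.normal(0.0, jitter_sigma, size=codes.shape)
        synth = decode(model, codes)
        out_rows.append(synth)
        out_labels.extend([c] * deficit)
        out_real.extend([False] * deficit)

    aug = np.vstack(out_rows).reshape(-1, *tail_shape) if tail_shape else np.vstack(out_rows)
    return aug, np.asarray(out_labels), np.asarray(out_real, dtype=bool)
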