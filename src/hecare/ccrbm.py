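"""Centered Convolutional Restricted Boltzmann Machine with probabilistic max-pooling.

The model couples a real-valued visible layer (features in [0, 1], treated
with Bernoulli-probability semantics) to a convolutional detection layer and
a pooling layer.  Filters are shared across positions (1-D, valid-mode
correlation); detection units are partitioned into pooling blocks, and within
each block at most one unit may be active — a block-softmax in which the
"all off" outcome has logit 0 and drives the pooled unit.  Energy, with
centering offsets alpha_v (visible) and alpha_h (hidden) subtracted from unit
states:

    F(v, h) = - sum_l sum_k (h[l,k] - alpha_h[l,k])
                          * ((w_l * (v - alpha_v))[k] + b_l)
              - o * sum_j (v[j] - alpha_v[j])

With zero offsets this reduces exactly to the plain convolutional RBM energy.
Centering keeps unit activations near zero mean, which removes the large
global-bias component from the gradient and stabilizes contrastive-divergence
learning.  Offsets are initialized to sigmoid(bias) and tracked as an
exponential moving average of batch mean activations; when they move, the
(per-filter / global) biases receive the standard compensation terms so the
conditionals are preserved on average.

Training is CD-k: hidden units sampled from the block-softmax conditional,
visible reconstructions taken as mean-field probabilities.  A logistic
readout on the pooled features (P(block on | v) per filter and block) turns
the generative model into a binary classifier with a confidence score.

An exact-enumeration oracle (:func:`enumerate_joint`) is included for small
models; it computes exp(-F)/Z over every valid state and is the reference
the conditionals and Gibbs sampler are validated against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CCRBMError",
    "BlockConstraintError",
    "UntrainedModelError",
    "CCRBMStructure",
    "CCRBMParameters",
    "LayerState",
    "bottom_up_signal",
    "energy",
    "hidden_conditional",
    "visible_conditional",
    "sample_hidden",
    "sample_visible",
    "extract_features",
    "cd_gradients",
    "cd_update",
    "update_offsets",
    "reconstruction_error",
    "train_ccrbm",
    "enumerate_joint",
    "LogisticReadout",
    "train_readout",
    "CCRBMModel",
]

MODEL_FORMAT_VERSION = 1


class CCRBMError(ValueError):
    pass


class BlockConstraintError(CCRBMError):
    """A hidden configuration activates more than one unit in a pooling block."""


class UntrainedModelError(CCRBMError):
    """Prediction requested from a model without a trained readout."""


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


# --------------------------------------------------------------------------
# structure and parameters


@dataclass(frozen=True)
class CCRBMStructure:
    """Network shape: visible width, filter bank, pooling block size.

    ``detection_length = visible_length - filter_width + 1`` (valid-mode
    correlation).  If ``pool_block`` does not divide the detection length the
    final block is simply smaller (no padding).
    """

    visible_length: int = 5
    n_filters: int = 2
    filter_width: int = 3
    pool_block: int = 3

    def __post_init__(self) -> None:
        if min(self.visible_length, self.n_filters, self.filter_width, self.pool_block) < 1:
            raise CCRBMError("all structure dimensions must be positive")
        if self.detection_length < 1:
            raise CCRBMError(
                f"filter width {self.filter_width} exceeds visible length "
                f"{self.visible_length}"
            )

    @property
    def detection_length(self) -> int:
        return self.visible_length - self.filter_width + 1

    @property
    def blocks(self) -> tuple[tuple[int, ...], ...]:
        d, b = self.detection_length, self.pool_block
        return tuple(
            tuple(range(start, min(start + b, d))) for start in range(0, d, b)
        )

    @property
    def n_pool(self) -> int:
        return len(self.blocks)

    @property
    def feature_dim(self) -> int:
        return self.n_filters * self.n_pool

    @property
    def n_flat_params(self) -> int:
        """Filters (row-major) + per-filter hidden biases + one visible bias."""
        return self.n_filters * self.filter_width + self.n_filters + 1


@dataclass
class CCRBMParameters:
    """Filters, biases, centering offsets and the learning rate.

    ``alpha_h`` is per hidden unit (L x detection_length); ``alpha_v`` per
    visible unit.  Both live in [0, 1] (they track mean activations).
    """

    filters: np.ndarray          # (L, filter_width)
    hidden_bias: np.ndarray      # (L,)
    visible_bias: float
    alpha_h: np.ndarray          # (L, detection_length)
    alpha_v: np.ndarray          # (visible_length,)
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        self.visible_bias = float(self.visible_bias)
        self.alpha_h = np.asarray(self.alpha_h, dtype=float)
        self.alpha_v = np.asarray(self.alpha_v, dtype=float)
        for arr in (self.filters, self.hidden_bias, self.alpha_h, self.alpha_v):
            if not np.all(np.isfinite(arr)):
                raise CCRBMError("parameters must be finite")
        if not math.isfinite(self.visible_bias):
            raise CCRBMError("visible bias must be finite")
        if self.learning_rate <= 0:
            raise CCRBMError("learning rate must be positive")
        if (self.alpha_h < 0).any() or (self.alpha_h > 1).any():
            raise CCRBMError("alpha_h must lie in [0, 1]")
        if (self.alpha_v < 0).any() or (self.alpha_v > 1).any():
            raise CCRBMError("alpha_v must lie in [0, 1]")

    @classmethod
    def initial(
        cls,
        structure: CCRBMStructure,
        rng: np.random.Generator | None = None,
        scale: float = 0.01,
        learning_rate: float = 0.1,
    ) -> "CCRBMParameters":
        """Small random filters, zero biases, offsets at sigmoid(bias) = 0.5."""
        rng = rng or np.random.default_rng(0)
        l, w = structure.n_filters, structure.filter_width
        filters = rng.normal(0.0, scale, size=(l, w))
        hidden_bias = np.zeros(l)
        visible_bias = 0.0
        params = cls(
            filters=filters,
            hidden_bias=hidden_bias,
            visible_bias=visible_bias,
            alpha_h=np.zeros((l, structure.detection_length)),
            alpha_v=np.zeros(structure.visible_length),
            learning_rate=learning_rate,
        )
        return initialize_offsets(params, structure)

    def copy(self) -> "CCRBMParameters":
        return CCRBMParameters(
            filters=self.filters.copy(),
            hidden_bias=self.hidden_bias.copy(),
            visible_bias=self.visible_bias,
            alpha_h=self.alpha_h.copy(),
            alpha_v=self.alpha_v.copy(),
            learning_rate=self.learning_rate,
        )

    def zero_offsets(self) -> "CCRBMParameters":
        out = self.copy()
        out.alpha_h = np.zeros_like(out.alpha_h)
        out.alpha_v = np.zeros_like(out.alpha_v)
        return out


def initialize_offsets(
    params: CCRBMParameters, structure: CCRBMStructure
) -> CCRBMParameters:
    """Set alpha_h = sigmoid(hidden bias), alpha_v = sigmoid(visible bias)."""
    out = params.copy()
    out.alpha_h = np.repeat(
        sigmoid(params.hidden_bias)[:, None], structure.detection_length, axis=1
    )
    out.alpha_v = np.full(structure.visible_length, float(sigmoid(params.visible_bias)))
    return out


@dataclass
class LayerState:
    """One joint configuration: visible v, hidden h, pooled z."""

    visible: np.ndarray  # (V,)
    hidden: np.ndarray   # (L, D) binary
    pooled: np.ndarray   # (L, n_pool) binary

    def validate(self, structure: CCRBMStructure) -> None:
        for bi, block in enumerate(structure.blocks):
            per_block = self.hidden[:, list(block)].sum(axis=1)
            if (per_block > 1).any():
                raise BlockConstraintError(
                    f"block {bi} has more than one active hidden unit"
                )
            if not np.array_equal(self.pooled[:, bi], (per_block > 0).astype(int)):
                raise CCRBMError("pooled units inconsistent with hidden blocks")


def _pool_from_hidden(h: np.ndarray, structure: CCRBMStructure) -> np.ndarray:
    return np.stack(
        [(h[:, list(b)].sum(axis=1) > 0).astype(int) for b in structure.blocks], axis=1
    )


# --------------------------------------------------------------------------
# signals and conditionals (batched internals, single-vector public surface)


def _as_batch(v: np.ndarray) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        return v[None, :], True
    return v, False


def _signal(vb: np.ndarray, params: CCRBMParameters, structure: CCRBMStructure,
            centered: bool) -> np.ndarray:
    """Bottom-up signal S[n, l, k] = b_l + sum_i w[l, i] * vc[n, k + i]."""
    if vb.shape[1] != structure.visible_length:
        raise CCRBMError(
            f"visible length {vb.shape[1]} != structure {structure.visible_length}"
        )
    vc = vb - params.alpha_v if centered else vb
    windows = sliding_window_view(vc, structure.filter_width, axis=1)  # (N, D, w)
    s = np.einsum("ndw,lw->nld", windows, params.filters)
    return s + params.hidden_bias[None, :, None]


def bottom_up_signal(
    v: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    centered: bool = True,
) -> np.ndarray:
    """Detection-layer input S (L x detection_length) for one visible vector."""
    vb, single = _as_batch(v)
    s = _signal(vb, params, structure, centered)
    return s[0] if single else s


def _hidden_probs(
    s: np.ndarray, structure: CCRBMStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Block-softmax probabilities from signals.

    Within each pooling block the outcomes are {unit k active}_k plus
    "all off" with logit 0:
        P(h[l,k] = 1 | v) = exp(S[l,k]) / (1 + sum_block exp(S))
        P(block off | v)  = 1           / (1 + sum_block exp(S))
    Log-sum-exp guarded against overflow.
    """
    if np.isnan(s).any():
        raise CCRBMError("NaN in bottom-up signal")
    n = s.shape[0]
    p = np.empty_like(s)
    p_off = np.empty((n, s.shape[1], structure.n_pool))
    for bi, block in enumerate(structure.blocks):
        sb = s[:, :, list(block)]
        m = np.maximum(sb.max(axis=2), 0.0)
        exp_sb = np.exp(sb - m[:, :, None])
        denom = np.exp(-m) + exp_sb.sum(axis=2)
        p[:, :, list(block)] = exp_sb / denom[:, :, None]
        p_off[:, :, bi] = np.exp(-m) / denom
    return p, p_off


def hidden_conditional(
    v: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    centered: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit activation probabilities and per-block off-probabilities.

    Returns ``(P, P_off)`` with shapes (L, D) and (L, n_pool); within every
    block the unit probabilities and the off-probability sum to one.
    """
    vb, single = _as_batch(v)
    p, p_off = _hidden_probs(_signal(vb, params, structure, centered), structure)
    if single:
        return p[0], p_off[0]
    return p, p_off


def _transpose_tensor(params: CCRBMParameters, structure: CCRBMStructure) -> np.ndarray:
    """T[l, k, j] = w[l, j - k] for 0 <= j - k < width (full correlation back-map)."""
    l, d, v = structure.n_filters, structure.detection_length, structure.visible_length
    t = np.zeros((l, d, v))
    for k in range(d):
        t[:, k, k : k + structure.filter_width] = params.filters
    return t


def _visible_probs(
    hb: np.ndarray, params: CCRBMParameters, structure: CCRBMStructure, centered: bool
) -> np.ndarray:
    hc = hb - params.alpha_h if centered else hb
    pre = np.einsum("nld,ldj->nj", hc, _transpose_tensor(params, structure))
    return sigmoid(pre + params.visible_bias)


def visible_conditional(
    h: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    centered: bool = True,
) -> np.ndarray:
    """P(v_j = 1 | h) = sigmoid(sum_l (w_l (*) (h_l - alpha_h))_j + o)."""
    h = np.asarray(h, dtype=float)
    single = h.ndim == 2
    hb = h[None] if single else h
    if hb.shape[1:] != (structure.n_filters, structure.detection_length):
        raise CCRBMError("hidden state shape mismatch")
    p = _visible_probs(hb, params, structure, centered)
    return p[0] if single else p


def energy(
    v: np.ndarray,
    h: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    centered: bool = True,
) -> float:
    """Joint energy of one (v, h) configuration.

    Plain (``centered=False``):
        F = -sum_{l,k} h[l,k] ((w_l * v)[k] + b_l) - o sum_j v[j]
    Centered: h -> h - alpha_h, v -> v - alpha_v throughout.
    Raises :class:`BlockConstraintError` if a pooling block has two active units.
    """
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    for block in structure.blocks:
        if (h[:, list(block)].sum(axis=1) > 1).any():
            raise BlockConstraintError("more than one active unit in a pooling block")
    if centered:
        vc = v - params.alpha_v
        hc = h - params.alpha_h
    else:
        vc = v
        hc = h
    windows = sliding_window_view(vc, structure.filter_width)  # (D, w)
    conv = np.einsum("dw,lw->ld", windows, params.filters)     # (L, D)
    interaction = (hc * (conv + params.hidden_bias[:, None])).sum()
    return float(-interaction - params.visible_bias * vc.sum())


# --------------------------------------------------------------------------
# sampling


def _sample_hidden_batch(
    p: np.ndarray, p_off: np.ndarray, structure: CCRBMStructure,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-block categorical draw over {units..., off}; at most one unit fires."""
    n, l, _ = p.shape
    h = np.zeros_like(p)
    for bi, block in enumerate(structure.blocks):
        probs = np.concatenate(
            [p[:, :, list(block)], p_off[:, :, bi][:, :, None]], axis=2
        )
        cum = np.cumsum(probs, axis=2)
        u = rng.random((n, l, 1))
        choice = (u > cum).sum(axis=2)  # index into block + [off]
        for j, k in enumerate(block):
            h[:, :, k] = np.where(choice == j, 1.0, h[:, :, k])
    return h


def sample_hidden(
    v: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    rng: np.random.Generator,
    centered: bool = True,
) -> LayerState:
    """Sample a hidden/pooled configuration from P(h | v)."""
    vb, _ = _as_batch(v)
    p, p_off = _hidden_probs(_signal(vb, params, structure, centered), structure)
    h = _sample_hidden_batch(p, p_off, structure, rng)[0]
    return LayerState(
        visible=np.asarray(v, dtype=float),
        hidden=h.astype(int),
        pooled=_pool_from_hidden(h.astype(int), structure),
    )


def sample_visible(
    h: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    rng: np.random.Generator,
    centered: bool = True,
) -> np.ndarray:
    """Independent Bernoulli draw of the visible layer from P(v | h)."""
    p = visible_conditional(h, params, structure, centered)
    return (rng.random(p.shape) < p).astype(int)


# --------------------------------------------------------------------------
# features and readout


def extract_features(
    v: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    centered: bool = True,
) -> np.ndarray:
    """Pooled activation probabilities 1 - P(block off | v).

    Deterministic; one value per (filter, block), flattened filter-major to a
    vector of length ``structure.feature_dim``.  Accepts a single vector or a
    batch (N, V) and returns (feature_dim,) or (N, feature_dim).
    """
    vb, single = _as_batch(v)
    _, p_off = _hidden_probs(_signal(vb, params, structure, centered), structure)
    feats = 1.0 - p_off.reshape(vb.shape[0], -1)
    return feats[0] if single else feats


@dataclass
class LogisticReadout:
    """Logistic-regression head on the pooled features.

    Features are standardized internally (the pooled probabilities often
    occupy a narrow band, which would badly condition plain gradient
    descent); the standardization constants are part of the readout.
    """

    weights: np.ndarray
    bias: float
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def logits(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if self.feature_mean is not None:
            x = (x - self.feature_mean) / self.feature_scale
        return x @ self.weights + self.bias

    def confidence(self, features: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(features))


def train_readout(
    features: np.ndarray,
    labels: np.ndarray,
    epochs: int = 1500,
    lr: float = 2.0,
    l2: float = 1e-5,
) -> LogisticReadout:
    """Full-batch gradient descent on the regularized logistic loss.

    Deterministic (zero initialization, fixed schedule, internal feature
    standardization); adequate for the low-dimensional pooled-feature inputs
    this model produces.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0.0] = 1.0
    xs = (x - mean) / scale
    w = np.zeros(x.shape[1])
    b = 0.0
    n = len(y)
    for _ in range(epochs):
        p = sigmoid(xs @ w + b)
        err = p - y
        w -= lr * (xs.T @ err / n + l2 * w)
        b -= lr * float(err.mean())
    return LogisticReadout(weights=w, bias=b, feature_mean=mean, feature_scale=scale)


# --------------------------------------------------------------------------
# contrastive divergence


def cd_gradients(
    v_batch: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    rng: np.random.Generator,
    k: int = 1,
    centered: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """CD-k gradient estimate of the log-likelihood.

    Data term uses exact hidden probabilities; the negative phase runs k
    Gibbs half-steps with sampled hidden states and mean-field visible
    reconstructions.  Gradients are data-minus-model centered statistics:

        dW[l, i] = < (p_h - alpha_h)[l, k] (v - alpha_v)[k + i] >_data
                 - same under the model distribution
        db[l]    = < p_h[l, .] >_data - < p_h[l, .] >_model   (summed over k)
        do       = < v >_data - < v >_model                    (summed over j)

    Returns ``(grad_filters, grad_hidden_bias, grad_visible_bias, stats)``
    where ``stats`` carries the batch mean activations used for offset updates.
    """
    vb = np.asarray(v_batch, dtype=float)
    if vb.ndim != 2 or vb.shape[0] == 0:
        raise CCRBMError("v_batch must be a non-empty (N, V) matrix")
    if k < 1:
        raise CCRBMError("k_steps must be >= 1")
    n = vb.shape[0]

    p0, p0_off = _hidden_probs(_signal(vb, params, structure, centered), structure)
    h = _sample_hidden_batch(p0, p0_off, structure, rng)
    vk = vb
    pk = p0
    for _ in range(k):
        vk = _visible_probs(h, params, structure, centered)
        pk, pk_off = _hidden_probs(_signal(vk, params, structure, centered), structure)
        h = _sample_hidden_batch(pk, pk_off, structure, rng)

    if centered:
        ah, av = params.alpha_h, params.alpha_v
    else:
        ah = np.zeros_like(params.alpha_h)
        av = np.zeros_like(params.alpha_v)

    w0 = sliding_window_view(vb - av, structure.filter_width, axis=1)  # (N, D, w)
    wk = sliding_window_view(vk - av, structure.filter_width, axis=1)
    grad_w = (
        np.einsum("nld,ndw->lw", p0 - ah, w0) - np.einsum("nld,ndw->lw", pk - ah, wk)
    ) / n
    grad_b = (p0 - pk).sum(axis=2).mean(axis=0)
    grad_o = float((vb - vk).sum(axis=1).mean())

    if not (
        np.all(np.isfinite(grad_w))
        and np.all(np.isfinite(grad_b))
        and math.isfinite(grad_o)
    ):
        raise CCRBMError("non-finite CD gradient (diverging parameters?)")

    stats = {
        "mean_v": vb.mean(axis=0),
        "mean_h": p0.mean(axis=0),
    }
    return grad_w, grad_b, grad_o, stats


def update_offsets(
    params: CCRBMParameters,
    mean_v: np.ndarray,
    mean_h: np.ndarray,
    ema_rate: float,
) -> CCRBMParameters:
    """Exponential-moving-average refresh of the centering offsets.

    alpha <- (1 - ema_rate) * alpha + ema_rate * batch mean activation.
    ``ema_rate`` must lie in (0, 1]; 1 replaces the offsets outright.
    """
    if not 0.0 < ema_rate <= 1.0:
        raise CCRBMError("ema_rate must lie in (0, 1]")
    out = params.copy()
    out.alpha_v = np.clip((1 - ema_rate) * out.alpha_v + ema_rate * mean_v, 0.0, 1.0)
    out.alpha_h = np.clip((1 - ema_rate) * out.alpha_h + ema_rate * mean_h, 0.0, 1.0)
    return out


def cd_update(
    v_batch: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    rng: np.random.Generator,
    k: int = 1,
    centered: bool = True,
    ema_rate: float = 0.01,
) -> CCRBMParameters:
    """One CD-k parameter update with offset tracking.

    Applies the learning-rate-scaled gradients, then (in the centered regime)
    moves the offsets toward the batch mean activations and compensates the
    per-filter hidden biases and global visible bias so the conditionals are
    preserved on average under the offset shift.
    """
    grad_w, grad_b, grad_o, stats = cd_gradients(
        v_batch, params, structure, rng, k=k, centered=centered
    )
    lr = params.learning_rate
    out = params.copy()
    out.filters = out.filters + lr * grad_w
    out.hidden_bias = out.hidden_bias + lr * grad_b
    out.visible_bias = out.visible_bias + lr * grad_o

    if centered and ema_rate > 0:
        d_av = ema_rate * (stats["mean_v"] - out.alpha_v)
        d_ah = ema_rate * (stats["mean_h"] - out.alpha_h)
        # bias compensation: shifting alpha_v by d changes every signal
        # S[l,k] by -(w_l . d_window); absorb the mean into the filter bias
        windows = sliding_window_view(d_av, structure.filter_width)  # (D, w)
        out.hidden_bias = out.hidden_bias + np.einsum(
            "dw,lw->l", windows, out.filters
        ) / structure.detection_length
        t = _transpose_tensor(out, structure)
        out.visible_bias = out.visible_bias + float(
            np.einsum("ld,ldj->j", d_ah, t).mean()
        )
        out = update_offsets(out, stats["mean_v"], stats["mean_h"], ema_rate)
    return out


def reconstruction_error(
    v_batch: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    centered: bool = True,
) -> float:
    """Deterministic mean-field reconstruction MSE.

    v -> P(h | v) (probabilities, no sampling) -> P(v | h) and back-compare.
    """
    vb = np.asarray(v_batch, dtype=float)
    p, _ = _hidden_probs(_signal(vb, params, structure, centered), structure)
    vrec = _visible_probs(p, params, structure, centered)
    return float(np.mean((vb - vrec) ** 2))


def train_ccrbm(
    v_data: np.ndarray,
    params: CCRBMParameters,
    structure: CCRBMStructure,
    epochs: int,
    rng: np.random.Generator,
    batch_size: int = 64,
    k: int = 1,
    centered: bool = True,
    ema_rate: float = 0.01,
) -> tuple[CCRBMParameters, list[dict]]:
    """Mini-batch CD training loop.

    Shuffles per epoch with the supplied generator (fully deterministic given
    its seed) and logs the mean-field reconstruction error per epoch; the
    entry at epoch 0 is the pre-training error.
    """
    vb = np.asarray(v_data, dtype=float)
    log = [
        {
            "epoch": 0,
            "reconstruction_error": reconstruction_error(vb, params, structure, centered),
            "mean_alpha_h": float(params.alpha_h.mean()),
            "mean_alpha_v": float(params.alpha_v.mean()),
        }
    ]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(vb))
        for start in range(0, len(vb), batch_size):
            batch = vb[order[start : start + batch_size]]
            params = cd_update(
                batch, params, structure, rng, k=k, centered=centered, ema_rate=ema_rate
            )
        log.append(
            {
                "epoch": epoch,
                "reconstruction_error": reconstruction_error(
                    vb, params, structure, centered
                ),
                "mean_alpha_h": float(params.alpha_h.mean()),
                "mean_alpha_v": float(params.alpha_v.mean()),
            }
        )
    return params, log


# --------------------------------------------------------------------------
# exact enumeration oracle


def _enumerate_hidden(structure: CCRBMStructure) -> np.ndarray:
    """All valid hidden configurations (at most one active unit per block)."""
    import itertools

    d = structure.detection_length
    per_filter: list[np.ndarray] = []
    block_choices = [list(b) + [-1] for b in structure.blocks]  # -1 = block off
    filter_configs = []
    for combo in itertools.product(*block_choices):
        h = np.zeros(d)
        for pos in combo:
            if pos >= 0:
                h[pos] = 1.0
        filter_configs.append(h)
    per_filter = filter_configs
    out = []
    for combo in itertools.product(per_filter, repeat=structure.n_filters):
        out.append(np.stack(combo))
    return np.stack(out)  # (n_h, L, D)


def enumerate_joint(
    params: CCRBMParameters,
    structure: CCRBMStructure,
    centered: bool = True,
    max_states: int = 1 << 16,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact Boltzmann distribution exp(-F)/Z over all valid (v, h) states.

    Visible units are enumerated as binary.  Returns
    ``(visible_states, hidden_states, probabilities)`` with shapes
    (S, V), (S, L, D) and (S,); probabilities sum to 1.  Refuses state spaces
    larger than ``max_states``.
    """
    import itertools

    v_len = structure.visible_length
    hiddens = _enumerate_hidden(structure)
    n_states = (2**v_len) * len(hiddens)
    if n_states > max_states:
        raise CCRBMError(f"state space {n_states} exceeds limit {max_states}")

    vs, hs, energies = [], [], []
    for bits in itertools.product((0.0, 1.0), repeat=v_len):
        v = np.array(bits)
        for h in hiddens:
            vs.append(v)
            hs.append(h)
            energies.append(energy(v, h, params, structure, centered))
    e = np.array(energies)
    e -= e.min()
    w = np.exp(-e)
    probs = w / w.sum()
    return np.stack(vs), np.stack(hs), probs


# --------------------------------------------------------------------------
# trained model container


@dataclass
class CCRBMModel:
    """Structure + generative parameters + (optionally) a trained readout."""

    structure: CCRBMStructure
    params: CCRBMParameters
    readout: LogisticReadout | None = None
    centered: bool = True

    def predict(self, v: np.ndarray) -> tuple[int, float]:
        """Label (1 iff confidence >= 0.5) and confidence for one record."""
        if self.readout is None:
            raise UntrainedModelError("model has no trained readout")
        feats = extract_features(v, self.params, self.structure, self.centered)
        conf = float(self.readout.confidence(feats))
        return (1 if conf >= 0.5 else 0), conf

    def predict_batch(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.readout is None:
            raise UntrainedModelError("model has no trained readout")
        feats = extract_features(
            np.asarray(v, dtype=float), self.params, self.structure, self.centered
        )
        conf = self.readout.confidence(feats)
        return (conf >= 0.5).astype(int), conf

    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "structure": {
                "visible_length": self.structure.visible_length,
                "n_filters": self.structure.n_filters,
                "filter_width": self.structure.filter_width,
                "pool_block": self.structure.pool_block,
            },
            "centered": self.centered,
            "params": {
                "filters": self.params.filters.tolist(),
                "hidden_bias": self.params.hidden_bias.tolist(),
                "visible_bias": self.params.visible_bias,
                "alpha_h": self.params.alpha_h.tolist(),
                "alpha_v": self.params.alpha_v.tolist(),
                "learning_rate": self.params.learning_rate,
            },
            "readout": None
            if self.readout is None
            else {
                "weights": self.readout.weights.tolist(),
                "bias": self.readout.bias,
                "feature_mean": None
                if self.readout.feature_mean is None
                else self.readout.feature_mean.tolist(),
                "feature_scale": None
                if self.readout.feature_scale is None
                else self.readout.feature_scale.tolist(),
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CCRBMModel":
        doc = json.loads(text)
        structure = CCRBMStructure(**doc["structure"])
        p = doc["params"]
        params = CCRBMParameters(
            filters=np.array(p["filters"]),
            hidden_bias=np.array(p["hidden_bias"]),
            visible_bias=p["visible_bias"],
            alpha_h=np.array(p["alpha_h"]),
            alpha_v=np.array(p["alpha_v"]),
            learning_rate=p["learning_rate"],
        )
        readout = None
        if doc.get("readout") is not None:
            r = doc["readout"]
            readout = LogisticReadout(
                weights=np.array(r["weights"]),
                bias=r["bias"],
                feature_mean=None
                if r.get("feature_mean") is None
                else np.array(r["feature_mean"]),
                feature_scale=None
                if r.get("feature_scale") is None
                else np.array(r["feature_scale"]),
            )
        return cls(
            structure=structure,
            params=params,
            readout=readout,
            centered=doc.get("centered", True),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CCRBMModel":
        with open(path) as fh:
            return cls.from_json(fh.read())
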