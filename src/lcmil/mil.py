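"""Multiple-instance predictors for label cleaning, with focal loss.

The slide's noisily-labeled patch pools S_P and S_N are resampled (with
replacement) into MIL bags: a positive bag draws all its instances from S_P,
a negative bag from S_N.  Because the *majority* of labels in each pool is
assumed correct, bag labels are far cleaner than instance labels, and a bag
classifier can be trained reliably even though individual patches are
mislabeled.

Two bag predictors are provided:

* ``attention`` — instance embeddings ``h_ij`` are pooled by a learned
  softmax attention ``w_ij ∝ exp(W tanh(V h_ij))`` into a bag embedding
  ``z_j = Σ_i w_ij h_ij`` scored by a linear classifier,
  ``P_j = sigmoid(<g, z_j>)``;
* ``minet`` — the bag score is the arithmetic mean of per-instance
  classifier outputs ``P_j = (1/n_j) Σ_i sigmoid(<g, h_ij>)``.

Training minimizes the focal loss

    L = -( Y (1-P)^gamma log P  +  (1-Y) P^gamma log(1-P) ),

with gamma = 5 while the predicted positive-class probability is in
[0, 0.2) and gamma = 3 on [0.2, 1], which down-weights easy bags and keeps
the predicted probabilities better calibrated than plain cross-entropy — a
property the singleton-bag inference step depends on.

The embedding layer ``h = tanh(A phi + b)`` sits on top of frozen
convolutional features ``phi`` (see :mod:`lcmil.features`); only
``A, b, V, W, g`` are trained, one Adam step per bag, with a step-decay
learning-rate schedule on the bag counter.  Gradients are derived
analytically, so training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ConfigError, InfeasibleError, LCMILError
from .slide import NoisyPatchSet

__all__ = [
    "MILBag",
    "TrainConfig",
    "MILModel",
    "build_bags",
    "attention_pool",
    "focal_gamma",
    "focal_loss",
    "fit_mil",
]

CLAMP_EPS = 1e-7


@dataclass
class MILBag:
    """An ordered multiset of patch indices sharing one bag label."""

    instance_ids: np.ndarray
    label: int
    slide_id: int = 0

    def __post_init__(self) -> None:
        self.instance_ids = np.asarray(self.instance_ids, dtype=np.int64)
        if len(self.instance_ids) < 1:
            raise ConfigError("a bag needs at least one instance")
        if self.label not in (0, 1):
            raise ConfigError("bag label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.instance_ids)


@dataclass
class TrainConfig:
    """Hyper-parameters of one MIL training run.

    ``n_bags`` (M) and ``bag_size`` (n_j) control the resampled MIL dataset;
    ``lr0`` decays by ``lr_decay`` every ``lr_decay_every`` bags (one Adam
    step per bag).  ``embed_dim``/``attn_dim`` are the embedding and
    attention widths d_h and d_a.
    """

    n_bags: int = 1000
    bag_size: int = 10
    pos_fraction: float = 0.5
    lr0: float = 0.002
    lr_decay: float = 0.5
    lr_decay_every: int = 100
    embed_dim: int = 128
    attn_dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bags < 1:
            raise ConfigError("n_bags must be >= 1")
        if self.bag_size < 1:
            raise ConfigError("bag_size must be >= 1")
        if not 0.0 <= self.pos_fraction <= 1.0:
            raise ConfigError("pos_fraction must lie in [0, 1]")
        if self.lr0 <= 0:
            raise ConfigError("lr0 must be positive")

    def lr_at(self, bag_index: int) -> float:
        """Learning rate applied at a given (0-based) bag counter."""
        return self.lr0 * self.lr_decay ** (bag_index // self.lr_decay_every)


def build_bags(
    pset: NoisyPatchSet,
    n_bags: int,
    bag_size: int,
    pos_fraction: float = 0.5,
    seed: int = 0,
    slide_id: int = 0,
) -> list[MILBag]:
    """Resample S_P / S_N into MIL bags.

    ``round(pos_fraction * n_bags)`` positive bags draw ``bag_size``
    instances i.i.d. uniformly *with replacement* from S_P; the remaining
    negative bags draw from S_N.  The bag order is shuffled by the seed.
    """
    pos_ids, neg_ids = pset.positive_ids, pset.negative_ids
    n_pos = int(round(pos_fraction * n_bags))
    n_neg = n_bags - n_pos
    if n_pos > 0 and len(pos_ids) == 0:
        raise InfeasibleError("cannot build positive bags: S_P is empty")
    if n_neg > 0 and len(neg_ids) == 0:
        raise InfeasibleError("cannot build negative bags: S_N is empty")
    ss = np.random.SeedSequence((seed, 0xBA6, slide_id))
    sample_rng, order_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    bags = [
        MILBag(sample_rng.choice(pos_ids, size=bag_size, replace=True), 1, slide_id)
        for _ in range(n_pos)
    ] + [
        MILBag(sample_rng.choice(neg_ids, size=bag_size, replace=True), 0, slide_id)
        for _ in range(n_neg)
    ]
    order_rng.shuffle(bags)
    return bags


def attention_pool(
    embeddings: np.ndarray, V: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gated softmax attention pooling.

    ``embeddings`` is (n, d_h).  Returns ``(z, w)`` with
    ``w_i = softmax_i(W tanh(V h_i))`` and ``z = sum_i w_i h_i``; the
    weights are non-negative and sum to 1.
    """
    H = np.asarray(embeddings, dtype=float)
    if H.ndim != 2 or len(H) < 1:
        raise ConfigError("embeddings must be a non-empty (n, d_h) array")
    scores = (W @ np.tanh(V @ H.T)).ravel()
    scores = scores - scores.max()  # shift-invariant softmax
    e = np.exp(scores)
    w = e / e.sum()
    return H.T @ w, w


def focal_gamma(p_positive: float) -> float:
    """Focusing exponent schedule keyed on the predicted P(Y=1)."""
    return 5.0 if p_positive < 0.2 else 3.0


def focal_loss(
    y: float | np.ndarray, p: float | np.ndarray, gamma: float | np.ndarray
) -> float | np.ndarray:
    """Focal loss for a bag label/score pair; gamma=0 is cross-entropy."""
    p = np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS)
    return -(
        y * (1.0 - p) ** gamma * np.log(p)
        + (1.0 - y) * p**gamma * np.log(1.0 - p)
    )


def _focal_dloss_dp(y: float, p: float, gamma: float) -> float:
    """d/dP of the focal loss at fixed gamma (gamma schedule is detached)."""
    p = float(np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS))
    if y == 1:
        return gamma * (1.0 - p) ** (gamma - 1.0) * np.log(p) - (1.0 - p) ** gamma / p
    return -gamma * p ** (gamma - 1.0) * np.log(1.0 - p) + p**gamma / (1.0 - p)


def _sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    return expit(x)


@dataclass
class MILModel:
    """A trained MIL predictor (attention or mi-Net variant).

    Holds the trainable post-conv parameters and the frozen-feature
    standardization moments needed to score held-out patches.  All scoring
    paths funnel through :meth:`bag_score`, so singleton-bag inference is
    bit-identical to bag scoring by construction.
    """

    variant: str
    params: dict[str, np.ndarray]
    feature_stats: tuple[np.ndarray, np.ndarray] | None = None
    config: TrainConfig | None = None
    history: list[tuple[int, float, float]] = field(default_factory=list)

    def embed(self, phi: np.ndarray) -> np.ndarray:
        """Instance embeddings h = tanh(A phi + b); phi is (n, F)."""
        A, b = self.params["A"], self.params["b"]
        return np.tanh(np.atleast_2d(phi) @ A.T + b)

    def bag_score(self, phi: np.ndarray) -> float:
        """Bag-level score P_j for the instances with features phi (n, F)."""
        H = self.embed(phi)
        g = self.params["g"]
        if self.variant == "attention":
            z, _ = attention_pool(H, self.params["V"], self.params["W"])
            return float(_sigmoid(g @ z))
        if self.variant == "minet":
            return float(np.mean(_sigmoid(H @ g)))
        raise ConfigError(f"unknown variant {self.variant!r}")

    def instance_scores(self, phi: np.ndarray) -> np.ndarray:
        """Singleton-bag score of every row of phi."""
        return np.array([self.bag_score(phi[i : i + 1]) for i in range(len(phi))])


def _init_params(
    variant: str, n_features: int, cfg: TrainConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    d_h, d_a = cfg.embed_dim, cfg.attn_dim
    params = {
        "A": rng.normal(0.0, 1.0 / np.sqrt(n_features), size=(d_h, n_features)),
        "b": np.zeros(d_h),
        "g": rng.normal(0.0, 0.01, size=d_h),
    }
    if variant == "attention":
        params["V"] = rng.normal(0.0, 1.0 / np.sqrt(d_h), size=(d_a, d_h))
        params["W"] = rng.normal(0.0, 1.0 / np.sqrt(d_a), size=(1, d_a))
    return params


def _bag_gradients(
    model: MILModel, phi: np.ndarray, y: int
) -> tuple[float, float, dict[str, np.ndarray]]:
    """Forward + analytic backward pass for one bag.

    Returns (loss, P, gradients).  The gamma schedule reads the current
    predicted P and is treated as a constant in the gradient.
    """
    A, b, g = model.params["A"], model.params["b"], model.params["g"]
    X = np.atleast_2d(phi)  # (n, F)
    pre = X @ A.T + b  # (n, d_h)
    H = np.tanh(pre)
    grads: dict[str, np.ndarray] = {}
    if model.variant == "attention":
        V, W = model.params["V"], model.params["W"]
        T = np.tanh(H @ V.T)  # (n, d_a)
        a = (T @ W.ravel())  # (n,)
        a_shift = a - a.max()
        e = np.exp(a_shift)
        w = e / e.sum()
        z = H.T @ w  # (d_h,)
        logit = float(g @ z)
        P = float(_sigmoid(logit))
        gamma = focal_gamma(P)
        loss = float(focal_loss(y, P, gamma))
        Pc = float(np.clip(P, CLAMP_EPS, 1.0 - CLAMP_EPS))
        dlogit = _focal_dloss_dp(y, Pc, gamma) * Pc * (1.0 - Pc)
        grads["g"] = dlogit * z
        dz = dlogit * g  # (d_h,)
        dw = H @ dz  # (n,)
        da = w * (dw - float(w @ dw))  # softmax backward
        grads["W"] = (T.T @ da)[None, :]  # (1, d_a)
        dT = np.outer(da, W.ravel())  # (n, d_a)
        dpreV = dT * (1.0 - T**2)  # (n, d_a)
        grads["V"] = dpreV.T @ H  # (d_a, d_h)
        dH = np.outer(w, dz) + dpreV @ V  # (n, d_h)
    elif model.variant == "minet":
        s = _sigmoid(H @ g)  # (n,)
        P = float(s.mean())
        gamma = focal_gamma(P)
        loss = float(focal_loss(y, P, gamma))
        Pc = float(np.clip(P, CLAMP_EPS, 1.0 - CLAMP_EPS))
        dP = _focal_dloss_dp(y, Pc, gamma)
        dlogits = dP / len(s) * s * (1.0 - s)  # (n,)
        grads["g"] = H.T @ dlogits
        dH = np.outer(dlogits, g)
    else:
        raise ConfigError(f"unknown variant {model.variant!r}")
    dpre = dH * (1.0 - H**2)
    grads["A"] = dpre.T @ X
    grads["b"] = dpre.sum(axis=0)
    return loss, P, grads


class _Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, gk in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def fit_mil(
    bags: list[MILBag],
    features_by_slide: dict[int, np.ndarray],
    cfg: TrainConfig,
    variant: str = "attention",
    feature_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> MILModel:
    """Train a MIL predictor on pre-built bags over frozen features.

    One Adam step per bag; the learning rate follows the step-decay
    schedule of ``cfg``.  ``features_by_slide`` maps each bag's slide_id to
    that slide's standardized feature matrix.  Aborts on non-finite loss.
    """
    if not bags:
        raise ConfigError("training requires at least one bag")
    n_features = next(iter(features_by_slide.values())).shape[1]
    init_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x1417)))
    model = MILModel(
        variant=variant,
        params=_init_params(variant, n_features, cfg, init_rng),
        feature_stats=feature_stats,
        config=cfg,
    )
    opt = _Adam(model.params)
    for i, bag in enumerate(bags):
        phi = features_by_slide[bag.slide_id][bag.instance_ids]
        loss, p, grads = _bag_gradients(model, phi, bag.label)
        if not np.isfinite(loss):
            raise LCMILError(
                f"non-finite loss at bag {i} (label={bag.label}, P={p}); aborting"
            )
        lr = cfg.lr_at(i)
        opt.step(model.params, grads, lr)
        model.history.append((i, loss, lr))
    return model


def train(
    pset: NoisyPatchSet,
    features: np.ndarray,
    cfg: TrainConfig,
    variant: str = "attention",
    feature_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> MILModel:
    """Single-slide convenience wrapper: build bags from S_P/S_N and fit."""
    bags = build_bags(pset, cfg.n_bags, cfg.bag_size, cfg.pos_fraction, cfg.seed)
    return fit_mil(bags, {0: features}, cfg, variant, feature_stats)
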