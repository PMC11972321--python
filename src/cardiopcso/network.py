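"""Dense binary classifier whose flattened weight vector is the PCSO search point.

Architecture: input -> 128 -> 64 -> 32 -> 1, ReLU hidden units, sigmoid
output.  Each hidden layer may carry batch normalization; for population
search the normalization moments are computed once from the training batch
and then frozen, so the loss of a weight vector is a deterministic function
of (weights, data).  Dropout exists only for the optional gradient
refinement; inference is always deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "WeightLayout",
    "n_params",
    "unflatten",
    "flatten",
    "compute_bn_stats",
    "forward",
    "predict_proba",
    "predict_label",
    "weighted_bce",
    "refine_with_adam",
]

_BN_EPS = 1e-5
_CLIP_EPS = 1e-7


@dataclass
class NetworkSpec:
    input_dim: int
    hidden: tuple = (128, 64, 32)
    batch_norm: bool = True
    dropout_rate: float = 0.1
    class_weight: float = 1.0

    def __post_init__(self):
        if self.input_dim < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("layer sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class WeightLayout:
    """Slice map from the flat vector to named parameter arrays."""

    entries: list = field(default_factory=list)  # (name, shape, start, stop)

    @property
    def size(self) -> int:
        return self.entries[-1][3] if self.entries else 0


def _layer_dims(spec: NetworkSpec) -> list[tuple[int, int]]:
    dims = [spec.input_dim, *spec.hidden, 1]
    return list(zip(dims[:-1], dims[1:]))


def layout_for(spec: NetworkSpec) -> WeightLayout:
    lo = WeightLayout()
    pos = 0
    for li, (d_in, d_out) in enumerate(_layer_dims(spec)):
        for name, shape in (
            (f"W{li}", (d_in, d_out)),
            (f"b{li}", (d_out,)),
        ):
            n = int(np.prod(shape))
            lo.entries.append((name, shape, pos, pos + n))
            pos += n
        if spec.batch_norm and li < len(spec.hidden):  # hidden layers only
            for name in (f"gamma{li}", f"beta{li}"):
                lo.entries.append((name, (d_out,), pos, pos + d_out))
                pos += d_out
    return lo


def n_params(spec: NetworkSpec) -> int:
    return layout_for(spec).size


def unflatten(spec: NetworkSpec, vector: np.ndarray) -> dict:
    lo = layout_for(spec)
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (lo.size,):
        raise ValueError(f"expected weight vector of length {lo.size}, got {vector.shape}")
    return {name: vector[a:b].reshape(shape) for name, shape, a, b in lo.entries}


def flatten(spec: NetworkSpec, params: dict) -> np.ndarray:
    lo = layout_for(spec)
    return np.concatenate([np.asarray(params[name], dtype=float).ravel() for name, *_ in lo.entries])


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def compute_bn_stats(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray) -> list:
    """Per-hidden-layer pre-activation moments on a reference batch
    (typically the training split).  Frozen stats make the forward pass a
    pure function of (weights, X)."""
    p = unflatten(spec, weights)
    stats = []
    h = np.asarray(X, dtype=float)
    for li in range(len(spec.hidden)):
        z = h @ p[f"W{li}"] + p[f"b{li}"]
        if spec.batch_norm:
            mu, var = z.mean(axis=0), z.var(axis=0)
            stats.append((mu, var))
            z = p[f"gamma{li}"] * (z - mu) / np.sqrt(var + _BN_EPS) + p[f"beta{li}"]
        else:
            stats.append(None)
        h = np.maximum(z, 0.0)
    return stats


def forward(
    spec: NetworkSpec,
    weights: np.ndarray,
    X: np.ndarray,
    bn_stats: list | None = None,
) -> np.ndarray:
    """Class-1 probabilities in (0, 1) for each row of ``X``.

    With batch normalization, moments come from ``bn_stats`` when given
    (inference with stored statistics) or from ``X`` itself otherwise.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"expected {spec.input_dim} input columns, got {X.shape[1]}")
    p = unflatten(spec, weights)
    h = X
    for li in range(len(spec.hidden)):
        z = h @ p[f"W{li}"] + p[f"b{li}"]
        if spec.batch_norm:
            if bn_stats is not None:
                mu, var = bn_stats[li]
            else:
                mu, var = z.mean(axis=0), z.var(axis=0)
            z = p[f"gamma{li}"] * (z - mu) / np.sqrt(var + _BN_EPS) + p[f"beta{li}"]
        h = np.maximum(z, 0.0)
    lo = len(spec.hidden)
    logit = (h @ p[f"W{lo}"] + p[f"b{lo}"]).ravel()
    return _sigmoid(logit)


predict_proba = forward


def predict_label(spec, weights, X, bn_stats=None, threshold: float = 0.5) -> np.ndarray:
    return (forward(spec, weights, X, bn_stats) >= threshold).astype(int)


def weighted_bce(probabilities, y, class_weight: float = 1.0, eps: float = _CLIP_EPS) -> float:
    """Mean of -[w y log p + (1-y) log(1-p)] with p clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(probabilities, dtype=float), eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    return float(-(class_weight * y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def refine_with_adam(
    spec: NetworkSpec,
    weights: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 20,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> np.ndarray:
    """Optional gradient polish of a weight vector (off by default in the
    training pipeline).  Batch-norm moments are recomputed from the full
    training set each epoch and treated as constants, so normalization is a
    fixed affine map inside each epoch and backprop stays simple.  Dropout
    is applied to hidden activations during these updates.
    """
    rng = np.random.default_rng(seed)
    p = unflatten(spec, np.asarray(weights, dtype=float).copy())
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v_) for k, v_ in p.items()}
    t = 0
    L = len(spec.hidden)
    for _ in range(epochs):
        stats = compute_bn_stats(spec, flatten(spec, p), X)
        order = rng.permutation(len(X))
        for start in range(0, len(X), batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], np.asarray(y, dtype=float)[idx]
            # forward with caches
            h = xb
            caches = []
            for li in range(L):
                z = h @ p[f"W{li}"] + p[f"b{li}"]
                if spec.batch_norm:
                    mu, var = stats[li]
                    zhat = (z - mu) / np.sqrt(var + _BN_EPS)
                    zb = p[f"gamma{li}"] * zhat + p[f"beta{li}"]
                else:
                    zhat, zb = None, z
                a = np.maximum(zb, 0.0)
                if spec.dropout_rate > 0:
                    keep = (rng.random(a.shape) >= spec.dropout_rate) / (1 - spec.dropout_rate)
                    a = a * keep
                else:
                    keep = None
                caches.append((h, zhat, zb, a, keep))
                h = a
            logit = (h @ p[f"W{L}"] + p[f"b{L}"]).ravel()
            prob = _sigmoid(logit)
            # weighted BCE gradient wrt logit
            w_pos = spec.class_weight
            dlogit = ((1 - yb) * prob - w_pos * yb * (1 - prob)) / len(yb)
            grads = {}
            grads[f"W{L}"] = h.T @ dlogit[:, None]
            grads[f"b{L}"] = dlogit.sum(keepdims=True)
            dh = dlogit[:, None] @ p[f"W{L}"].T
            for li in range(L - 1, -1, -1):
                h_in, zhat, zb, a, keep = caches[li]
                if keep is not None:
                    dh = dh * keep
                dz = dh * (zb > 0)
                if spec.batch_norm:
                    mu, var = stats[li]
                    grads[f"gamma{li}"] = (dz * zhat).sum(axis=0)
                    grads[f"beta{li}"] = dz.sum(axis=0)
                    dz = dz * p[f"gamma{li}"] / np.sqrt(var + _BN_EPS)
                grads[f"W{li}"] = h_in.T @ dz
                grads[f"b{li}"] = dz.sum(axis=0)
                dh = dz @ p[f"W{li}"].T
            t += 1
            for k in p:
                g = grads[k].reshape(p[k].shape)
                m[k] = 0.9 * m[k] + 0.1 * g
                v[k] = 0.999 * v[k] + 0.001 * g**2
                mhat = m[k] / (1 - 0.9**t)
                vhat = v[k] / (1 - 0.999**t)
                p[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
    return flatten(spec, p)
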