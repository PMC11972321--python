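"""PCSO-trained CVD classifier with a model-agnostic explanation layer.

The dense network's flattened weight vector is searched directly by PCSO
inside a symmetric box (default [-3, 3] per weight, sized for z-scored
inputs); the fitness of a weight vector is its weighted binary cross-entropy
on an internal validation split, which guards the search against
memorizing the training split.

Explanations are deliberately simple and model-agnostic: global importance
is permutation importance (mean increase in validation loss when one
feature column is shuffled, with its s.d. over repeats), local attribution
is a central finite-difference sensitivity of the predicted probability.
Both are reported next to the information-gain ranking for cross-reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cardiopcso import network as net
from cardiopcso.pcso import OptimizationResult, PCSOConfig, optimize
from cardiopcso.preprocessing import stratified_split

__all__ = [
    "FittedClassifier",
    "ExplanationReport",
    "fitness_from_weights",
    "train_with_pcso",
    "explain",
    "local_sensitivity",
    "save_fitted",
    "load_fitted",
]


@dataclass
class FittedClassifier:
    """Weights + spec + frozen batch-norm statistics; everything needed for
    deterministic inference."""

    spec: net.NetworkSpec
    weights: np.ndarray
    bn_stats: list

    def predict_proba(self, X) -> np.ndarray:
        return net.forward(self.spec, self.weights, X, self.bn_stats)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def fitness_from_weights(
    weights: np.ndarray,
    spec: net.NetworkSpec,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
) -> float:
    """Weighted BCE on the validation part, with batch-norm moments frozen
    from the training part — the minimization target handed to PCSO."""
    X_tr, _ = train
    X_val, y_val = val
    if len(X_val) == 0:
        raise ValueError("empty validation set")
    bn = net.compute_bn_stats(spec, weights, X_tr) if spec.batch_norm else None
    probs = net.forward(spec, weights, X_val, bn)
    return net.weighted_bce(probs, y_val, spec.class_weight)


def train_with_pcso(
    spec: net.NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    pcso_config: PCSOConfig | None = None,
    val_fraction: float = 0.2,
    weight_bound: float = 3.0,
    seed: int = 0,
    refine: bool = False,
    refine_epochs: int = 20,
) -> tuple[FittedClassifier, OptimizationResult]:
    """Optimize the network weights by PCSO over [-weight_bound, weight_bound].

    The data are split (stratified) into an internal train/validation pair;
    fitness is validation weighted BCE.  ``refine=True`` additionally
    polishes the best weights with Adam (learning rate 1e-3), off by default.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    tr_idx, val_idx = stratified_split(y, fraction=1 - val_fraction, seed=seed)
    train = (X[tr_idx], y[tr_idx])
    val = (X[val_idx], y[val_idx])

    dim = net.n_params(spec)
    if pcso_config is None:
        pcso_config = PCSOConfig(
            dim=dim, lower=-weight_bound, upper=weight_bound,
            pop_size=30, max_iters=150, seed=seed,
        )
    elif pcso_config.dim != dim:
        raise ValueError(f"pcso_config.dim={pcso_config.dim} != n_params={dim}")

    result = optimize(lambda w: fitness_from_weights(w, spec, train, val), pcso_config)
    weights = result.best_position
    if refine:
        weights = net.refine_with_adam(
            spec, weights, train[0], train[1], epochs=refine_epochs, seed=seed
        )
    bn = net.compute_bn_stats(spec, weights, train[0]) if spec.batch_norm else None
    return FittedClassifier(spec, weights, bn), result


@dataclass
class ExplanationReport:
    feature_names: list
    importance_mean: np.ndarray  # mean validation-loss increase per feature
    importance_sd: np.ndarray
    local: np.ndarray | None = None  # per-sample finite-difference dP/dx
    ig_rank: list | None = None  # feature names by information gain, best first
    n_repeats: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def global_rank(self) -> list:
        order = np.argsort(-self.importance_mean, kind="stable")
        return [self.feature_names[i] for i in order]

    def to_dict(self) -> dict:
        d = {
            "method": "permutation importance (global), central finite differences (local)",
            "n_repeats": self.n_repeats,
            "global": [
                {"name": n, "importance": float(m), "sd": float(s)}
                for n, m, s in zip(self.feature_names, self.importance_mean, self.importance_sd)
            ],
            "global_rank": self.global_rank,
        }
        if self.ig_rank is not None:
            d["information_gain_rank"] = list(self.ig_rank)
        if self.local is not None:
            d["local_sensitivity"] = np.asarray(self.local).tolist()
        return d


def local_sensitivity(
    model: FittedClassifier, X: np.ndarray, eps: float = 1e-4
) -> np.ndarray:
    """Central finite-difference sensitivity dP/dx_j per sample and feature."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    sens = np.empty((n, p))
    for j in range(p):
        up, dn = X.copy(), X.copy()
        up[:, j] += eps
        dn[:, j] -= eps
        sens[:, j] = (model.predict_proba(up) - model.predict_proba(dn)) / (2 * eps)
    return sens


def explain(
    model: FittedClassifier,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    feature_names: list | None = None,
    ig_rank: list | None = None,
    local_rows: int | None = 20,
) -> ExplanationReport:
    """Permutation importance over ``n_repeats`` shuffles per feature, plus
    local sensitivities for the first ``local_rows`` samples."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    base = net.weighted_bce(model.predict_proba(X), y, model.spec.class_weight)
    p = X.shape[1]
    deltas = np.empty((n_repeats, p))
    for r in range(n_repeats):
        for j in range(p):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            loss = net.weighted_bce(model.predict_proba(Xp), y, model.spec.class_weight)
            deltas[r, j] = loss - base
    names = feature_names or [f"x{j}" for j in range(p)]
    local = local_sensitivity(model, X[: local_rows or 0]) if local_rows else None
    return ExplanationReport(
        feature_names=list(names),
        importance_mean=deltas.mean(axis=0),
        importance_sd=deltas.std(axis=0, ddof=1),
        local=local,
        ig_rank=ig_rank,
        n_repeats=n_repeats,
        meta={"baseline_loss": base},
    )


def save_fitted(model: FittedClassifier, prefix) -> None:
    """Weights to ``<prefix>.npz``; layout and spec to ``<prefix>.json``."""
    prefix = Path(prefix)
    bn = model.bn_stats or []
    np.savez(
        prefix.with_suffix(".npz"),
        weights=model.weights,
        **{f"bn_mu{i}": s[0] for i, s in enumerate(bn) if s is not None},
        **{f"bn_var{i}": s[1] for i, s in enumerate(bn) if s is not None},
    )
    layout = net.layout_for(model.spec)
    prefix.with_suffix(".json").write_text(json.dumps({
        "spec": {
            "input_dim": model.spec.input_dim,
            "hidden": list(model.spec.hidden),
            "batch_norm": model.spec.batch_norm,
            "dropout_rate": model.spec.dropout_rate,
            "class_weight": model.spec.class_weight,
        },
        "layout": [
            {"name": n, "shape": list(s), "start": a, "stop": b}
            for n, s, a, b in layout.entries
        ],
    }, indent=2))


def load_fitted(prefix) -> FittedClassifier:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    spec = net.NetworkSpec(
        input_dim=meta["spec"]["input_dim"],
        hidden=tuple(meta["spec"]["hidden"]),
        batch_norm=meta["spec"]["batch_norm"],
        dropout_rate=meta["spec"]["dropout_rate"],
        class_weight=meta["spec"]["class_weight"],
    )
    data = np.load(prefix.with_suffix(".npz"))
    bn = None
    if spec.batch_norm:
        bn = [
            (data[f"bn_mu{i}"], data[f"bn_var{i}"]) for i in range(len(spec.hidden))
        ]
    return FittedClassifier(spec, data["weights"], bn)
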