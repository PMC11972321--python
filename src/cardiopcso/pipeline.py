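"""End-to-end pipeline and the stratified k-fold harness.

The pipeline chains: simulate (or load) -> clean/standardize ->
information-gain feature selection -> PCSO-trained dense classifier ->
metrics -> explanation, logging every stage and emitting a reproducibility
manifest (config echo, seeds, library versions).  All per-fold fitting —
standardization statistics, feature scores, classifier weights — uses only
the training folds, so the harness is leakage-free by construction.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from cardiopcso import igfs, metrics, network as net, synthetic
from cardiopcso.classifier import explain, train_with_pcso
from cardiopcso.pcso import PCSOConfig
from cardiopcso.preprocessing import (
    apply_zscore,
    impute_missing,
    smote_oversample,
    stratified_split,
    zscore_normalize,
)

__all__ = [
    "PipelineConfig",
    "stratified_kfold",
    "kfold_evaluate",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One record drives the whole run; serializable to/from YAML."""

    n_samples: int = 600
    seed: int = 0
    imbalance_ratio: float = 0.3
    informative_names: tuple = ("LVEF", "Age", "TC")
    effect_sizes: tuple = (2.0, 1.5, 1.0)
    missing_rate: float = 0.0
    use_igfs: bool = True
    igfs_bins: int = 10
    igfs_threshold_rule: object = "mean_ig"
    use_smote: bool = True
    smote_k: int = 5
    smote_target_ratio: float = 1.0
    class_weight: float = 1.0
    split_fraction: float = 0.8
    pop_size: int = 20
    max_iters: int = 60
    weight_bound: float = 1.0
    hidden: tuple = (128, 64, 32)
    explain_repeats: int = 5
    input_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for f in ("informative_names", "effect_sizes", "hidden"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        for f in ("informative_names", "effect_sizes", "hidden"):
            d[f] = list(d[f])
        Path(path).write_text(yaml.safe_dump(d))


def stratified_kfold(
    y: np.ndarray, k: int = 5, seed: int = 0, sample_ids: np.ndarray | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k folds: every sample validates exactly once and fold
    sizes differ by at most one.  Fold assignment is keyed to ``sample_ids``
    (default 0..n-1), so metrics do not depend on row order.
    """
    y = np.asarray(y)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    totals = np.zeros(k, dtype=int)
    for c in np.unique(y):
        pos = np.flatnonzero(y == c)
        if pos.size < k:
            raise ValueError(f"class {c!r} has fewer than k={k} members")
        # deterministic order by id, then a seeded shuffle of that order
        pos = pos[np.argsort(ids[pos], kind="stable")]
        pos = pos[rng.permutation(pos.size)]
        base, extra = divmod(pos.size, k)
        # remainders go to the currently smallest folds so totals stay within 1
        order = np.argsort(totals, kind="stable")
        counts = np.full(k, base)
        counts[order[:extra]] += 1
        assign = np.repeat(np.arange(k), counts)
        fold_of[pos] = assign
        totals += counts
    return [
        (np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f)) for f in range(k)
    ]


def _prior_correct(p: np.ndarray, fitted_prior: float, true_prior: float) -> np.ndarray:
    """Posterior re-weighting after training under a shifted class prior
    (e.g. SMOTE-balanced data): Bayes-correct p back to ``true_prior``."""
    eps = 1e-12
    num = p * true_prior / max(fitted_prior, eps)
    den = num + (1 - p) * (1 - true_prior) / max(1 - fitted_prior, eps)
    return num / np.maximum(den, eps)


def _fit_and_score(cfg: PipelineConfig, dataset, tr_idx, te_idx, seed):
    """Fit preprocess -> IGFS -> PCSO classifier on the training rows only,
    then score the held-out rows.  Returns (report, extras)."""
    schema = dataset.schema
    X_tr, y_tr = dataset.X[tr_idx], dataset.y[tr_idx]
    X_te, y_te = dataset.X[te_idx], dataset.y[te_idx]

    X_tr = impute_missing(X_tr, schema)
    X_te = impute_missing(X_te, schema)

    numeric = [j for j, s in enumerate(schema) if s.kind == "numeric"]
    X_tr, stats = zscore_normalize(X_tr, numeric)
    X_te = apply_zscore(X_te, stats)

    keep = np.arange(len(schema))
    score_table = None
    if cfg.use_igfs:
        score_table = igfs.select_features(
            synthetic.TabularDataset(X_tr, schema, y_tr),
            bins=cfg.igfs_bins,
            threshold_rule=cfg.igfs_threshold_rule,
        )
        keep = np.flatnonzero(score_table.selected)
        if keep.size == 0:  # degenerate threshold: fall back to the top feature
            keep = score_table.rank[:1]
    X_tr_sel, X_te_sel = X_tr[:, keep], X_te[:, keep]

    prior = float(y_tr.mean())
    if cfg.use_smote:
        X_tr_sel, y_tr_fit = smote_oversample(
            X_tr_sel, y_tr, k=cfg.smote_k, target_ratio=cfg.smote_target_ratio, seed=seed
        )
    else:
        y_tr_fit = y_tr

    spec = net.NetworkSpec(
        input_dim=keep.size, hidden=cfg.hidden, class_weight=cfg.class_weight
    )
    pcso_cfg = PCSOConfig(
        dim=net.n_params(spec),
        lower=-cfg.weight_bound,
        upper=cfg.weight_bound,
        pop_size=cfg.pop_size,
        max_iters=cfg.max_iters,
        seed=seed,
    )
    model, opt_result = train_with_pcso(
        spec, X_tr_sel, y_tr_fit, pcso_config=pcso_cfg, seed=seed
    )
    scores = model.predict_proba(X_te_sel)
    if cfg.use_smote:
        # oversampling rebalanced the training prior; map the balanced-prior
        # posterior back to the original prevalence before thresholding
        scores = _prior_correct(scores, fitted_prior=float(y_tr_fit.mean()), true_prior=prior)
    report = metrics.report_from_predictions(y_te, (scores >= 0.5).astype(int), scores)
    extras = {
        "selected_features": [schema[j].name for j in keep],
        "score_table": score_table,
        "model": model,
        "opt_result": opt_result,
        "keep": keep,
        "X_test": X_te_sel,
        "y_test": y_te,
    }
    return report, extras


def kfold_evaluate(
    cfg: PipelineConfig, dataset: synthetic.TabularDataset, k: int = 5, seed: int = 0
) -> metrics.MetricReport:
    """Per-fold train/evaluate with everything fitted on the training folds;
    reports per-fold metrics plus their mean and s.d."""
    folds = stratified_kfold(dataset.y, k=k, seed=seed)
    fold_reports = []
    for f, (tr, te) in enumerate(folds):
        t0 = time.perf_counter()
        report, _ = _fit_and_score(cfg, dataset, tr, te, seed=seed + f)
        log.info("fold %d: acc=%.3f (%.1fs)", f, report.accuracy, time.perf_counter() - t0)
        fold_reports.append(report)
    names = ["accuracy", "precision", "recall", "f1", "tpr", "fpr", "auc"]
    mean = {m: float(np.mean([getattr(r, m) for r in fold_reports])) for m in names}
    sd = {m: float(np.std([getattr(r, m) for r in fold_reports], ddof=1)) for m in names}
    out = metrics.MetricReport(**{m: mean[m] for m in names})
    out.folds = [
        {"fold": f, **{m: getattr(r, m) for m in names}} for f, r in enumerate(fold_reports)
    ]
    out.folds.append({"fold": "mean", **mean})
    out.folds.append({"fold": "sd", **sd})
    return out


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> tuple[metrics.MetricReport, dict]:
    """Execute the full flow on one train/test split and return the metric
    report plus an artifact dict (manifest, feature scores, explanation)."""
    t_start = time.perf_counter()
    if cfg.input_csv:
        dataset = synthetic.dataset_from_csv(cfg.input_csv)
        log.info("loaded %d rows from %s", dataset.n, cfg.input_csv)
    else:
        dataset = synthetic.gen_tabular(
            n=cfg.n_samples,
            seed=cfg.seed,
            imbalance_ratio=cfg.imbalance_ratio,
            informative_names=list(cfg.informative_names),
            effect_sizes=list(cfg.effect_sizes),
            missing_rate=cfg.missing_rate,
        )
        log.info("simulated %d rows (prevalence %.3f)", dataset.n, dataset.y.mean())

    tr, te = stratified_split(dataset.y, fraction=cfg.split_fraction, seed=cfg.seed)
    report, extras = _fit_and_score(cfg, dataset, tr, te, seed=cfg.seed)

    score_table = extras["score_table"]
    exp = explain(
        extras["model"],
        extras["X_test"],
        extras["y_test"],
        n_repeats=max(2, cfg.explain_repeats),
        seed=cfg.seed,
        feature_names=extras["selected_features"],
        ig_rank=score_table.ranked_names if score_table else None,
    )

    manifest = {
        "config": {**asdict(cfg), "informative_names": list(cfg.informative_names),
                   "effect_sizes": list(cfg.effect_sizes), "hidden": list(cfg.hidden)},
        "seed": cfg.seed,
        "versions": {"cardiopcso": _version(), "numpy": np.__version__},
        "selected_features": extras["selected_features"],
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }
    artifacts = {
        "manifest": manifest,
        "feature_scores": score_table.to_dict() if score_table else None,
        "explanation": exp.to_dict(),
        "optimizer_history": extras["opt_result"].history.tolist(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out_dir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out_dir / "explanation.json").write_text(json.dumps(artifacts["explanation"], indent=2))
        if artifacts["feature_scores"]:
            (out_dir / "feature_scores.json").write_text(
                json.dumps(artifacts["feature_scores"], indent=2)
            )
    return report, artifacts


def _version() -> str:
    from cardiopcso import __version__

    return __version__
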