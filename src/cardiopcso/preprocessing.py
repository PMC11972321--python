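"""Cleaning, normalization, balancing, splitting and augmentation.

The stages are deliberately small, composable functions: Gaussian denoising
for images, z-score standardization with reusable fitted statistics (so the
held-out split receives the training transform — no leakage), statistical
outlier flagging, mean/mode imputation, SMOTE minority oversampling, paired
image/mask augmentation, and a stratified train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cardiopcso.synthetic import FeatureSpec, PhantomPair

__all__ = [
    "PreprocessConfig",
    "ZScoreStats",
    "gaussian_filter",
    "zscore_normalize",
    "apply_zscore",
    "flag_outliers",
    "impute_missing",
    "smote_oversample",
    "augment_images",
    "stratified_split",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Knobs for the cleaning pipeline; all stages are also callable alone."""

    gaussian_sigma: float = 1.0
    z_outlier_threshold: float = 3.0
    smote_k: int = 5
    smote_target_ratio: float = 1.0
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.z_outlier_threshold <= 0:
            raise ValueError("z_outlier_threshold must be > 0")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if not 0 < self.smote_target_ratio <= 1:
            raise ValueError("smote_target_ratio must lie in (0, 1]")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")


def gaussian_filter(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian convolution with reflect boundary handling.

    ``sigma=0`` returns the input unchanged (as a copy).  Reflect padding
    keeps borders from darkening, and with a unit-sum kernel a constant
    image passes through untouched.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")


@dataclass
class ZScoreStats:
    """Fitted per-column mean/sd, reusable on held-out data."""

    columns: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def zscore_normalize(
    matrix: np.ndarray, columns=None, ddof: int = 0
) -> tuple[np.ndarray, ZScoreStats]:
    """Standardize the selected columns to mean 0, sd 1 (population sd by
    default; ``ddof=1`` switches to the sample convention).

    Returns the transformed matrix and the fitted statistics so the same
    transform can be applied to held-out rows via :func:`apply_zscore`.
    """
    matrix = np.asarray(matrix, dtype=float)
    cols = np.arange(matrix.shape[1]) if columns is None else np.asarray(columns)
    mean = matrix[:, cols].mean(axis=0)
    sd = matrix[:, cols].std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {cols[bad].tolist()}")
    out = matrix.copy()
    out[:, cols] = (matrix[:, cols] - mean) / sd
    return out, ZScoreStats(cols, mean, sd)


def apply_zscore(matrix: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    out = matrix.copy()
    out[:, stats.columns] = (matrix[:, stats.columns] - stats.mean) / stats.sd
    return out


def flag_outliers(column: np.ndarray, z_threshold: float) -> np.ndarray:
    """True where the column's |z-score| exceeds ``z_threshold``."""
    column = np.asarray(column, dtype=float)
    if column.size < 3:
        raise ValueError("need at least 3 values")
    sd = column.std()
    if sd == 0:
        raise ValueError("zero-variance column")
    z = (column - column.mean()) / sd
    return np.abs(z) > z_threshold


def impute_missing(matrix: np.ndarray, schema: list[FeatureSpec]) -> np.ndarray:
    """Replace NaN sentinels: numeric columns by the observed mean,
    categorical columns by the observed mode (smallest code on ties)."""
    matrix = np.asarray(matrix, dtype=float)
    out = matrix.copy()
    for j, spec in enumerate(schema):
        col = out[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"column {spec.name!r} is fully missing")
        if spec.kind == "numeric":
            fill = obs.mean()
        else:
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]
        col[miss] = fill
    return out


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, target_ratio: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: synthesize minority rows by interpolating towards one of the
    k nearest minority neighbours, ``x_new = x_i + u (x_nn - x_i)`` with
    ``u ~ U(0,1)``, until minority/majority >= ``target_ratio``.  Majority
    rows are untouched and original rows are preserved in order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE here is defined for binary labels")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= k:
        raise ValueError(f"minority count {n_min} must exceed k={k}")
    n_target = int(np.ceil(target_ratio * n_maj))
    n_new = max(0, n_target - n_min)
    if n_new == 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    # pairwise distances within the minority class; self excluded
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]

    base = rng.integers(0, n_min, size=n_new)
    pick = nn[base, rng.integers(0, k, size=n_new)]
    u = rng.random((n_new, 1))
    X_new = Xm[base] + u * (Xm[pick] - Xm[base])

    log.info("SMOTE: %d -> %d minority rows (majority %d)", n_min, n_min + n_new, n_maj)
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]),
    )


def augment_images(
    pairs: list[PhantomPair],
    seed: int = 0,
    contrast_range: tuple[float, float] = (0.8, 1.2),
) -> list[PhantomPair]:
    """Random 90-degree rotations, horizontal/vertical flips and linear
    contrast scaling.  The identical geometric transform is applied to the
    mask (labels stay integer); contrast touches the image only."""
    rng = np.random.default_rng(seed)
    out = []
    for pair in pairs:
        img, mask = pair.image, pair.mask
        rot = int(rng.integers(0, 4))
        img, mask = np.rot90(img, rot), np.rot90(mask, rot)
        if rng.random() < 0.5:
            img, mask = img[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            img, mask = img[::-1, :], mask[::-1, :]
        scale = rng.uniform(*contrast_range)
        img = img.mean() + scale * (img - img.mean())
        meta = dict(pair.meta, augmented=True)
        out.append(PhantomPair(np.ascontiguousarray(img), np.ascontiguousarray(mask), meta))
    return out


def stratified_split(
    y: np.ndarray, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Index-level stratified partition into (train, test).

    Test counts per class follow largest-remainder allocation of the exact
    fractional shares, so the total test size is ``round(n (1 - fraction))``
    and class proportions match the overall split to within one sample.
    """
    y = np.asarray(y)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    sizes = np.array([(y == c).sum() for c in classes])
    if sizes.min() < 2:
        raise ValueError("every class needs at least 2 members")
    exact = sizes * (1 - fraction)
    n_test_c = np.floor(exact).astype(int)
    short = int(round(len(y) * (1 - fraction))) - n_test_c.sum()
    if short > 0:
        order = np.argsort(-(exact - n_test_c), kind="stable")
        n_test_c[order[:short]] += 1
    train_idx, test_idx = [], []
    for c, n_test in zip(classes, n_test_c):
        idx = rng.permutation(np.flatnonzero(y == c))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return train, test
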