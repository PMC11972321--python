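"""Synthetic data generators.

Two fixtures make the whole pipeline runnable without clinical data:

* a tabular generator that mirrors the 15-feature MACCE schema (age, LVEF,
  haemoglobin, ... plus binary comorbidity flags) with a planted logistic
  label dependence and configurable class imbalance, and
* an annulus phantom generator producing short-axis-like left-ventricle
  slices (bright blood-pool cavity inside a mid-grey myocardial ring on a
  dark background) with exact ground-truth masks.

Both are seeded and bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureSpec",
    "TabularDataset",
    "PhantomPair",
    "LABEL_NAME",
    "default_cvd_schema",
    "gen_tabular",
    "gen_separable",
    "gen_phantoms",
    "dataset_to_csv",
    "dataset_from_csv",
    "save_phantom_png",
    "save_phantom_nifti",
]

LABEL_NAME = "MACCE"

#: grey levels used for phantom rendering: background, cavity (blood pool),
#: myocardium.  Cavity is brightest, as in balanced-SSFP cine frames.
PHANTOM_INTENSITIES = (0.15, 0.9, 0.5)


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one tabular feature.

    ``range`` is ``(lo, hi)`` for numeric features and the tuple of category
    codes for categorical ones.  ``informative`` marks features participating
    in the label model by default.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    range: tuple
    informative: bool = False

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "numeric":
            lo, hi = self.range
            if not lo < hi:
                raise ValueError(f"{self.name}: need lo < hi, got {self.range}")
        elif len(self.range) == 0:
            raise ValueError(f"{self.name}: empty category code set")


@dataclass
class TabularDataset:
    """Feature matrix with a typed schema and binary labels."""

    X: np.ndarray
    schema: list[FeatureSpec]
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[1] != len(self.schema):
            raise ValueError("schema length does not match number of columns")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.schema]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "TabularDataset":
        return TabularDataset(self.X[idx], self.schema, self.y[idx])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[LABEL_NAME] = self.y
        return df


@dataclass
class PhantomPair:
    """Grayscale image + label mask (0 background, 1 cavity, 2 myocardium)."""

    image: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def default_cvd_schema() -> list[FeatureSpec]:
    """The 15-predictor MACCE schema (plus the label, handled separately).

    Numeric ranges: Age 20–86 years, LVEF 18–88 %, haemoglobin 55–193.2 g/L,
    blood urea nitrogen 0.7–119.0, total cholesterol 73–589.  Binary flags
    use codes {0, 1}; revascularisation type (PCI/CABG) uses {1, 2} and the
    number of stenosed coronary vessels uses {0..3}.
    """
    b = (0, 1)
    return [
        FeatureSpec("Sex", "categorical", b),
        FeatureSpec("Stable_CAD", "categorical", b),
        FeatureSpec("Age", "numeric", (20.0, 86.0)),
        FeatureSpec("CVD_history", "categorical", b),
        FeatureSpec("Smoke", "categorical", b),
        FeatureSpec("Nitrate", "categorical", b),
        FeatureSpec("LVEF", "numeric", (18.0, 88.0)),
        FeatureSpec("HBG", "numeric", (55.0, 193.2)),
        FeatureSpec("BUN", "numeric", (0.7, 119.0)),
        FeatureSpec("TC", "numeric", (73.0, 589.0)),
        FeatureSpec("SCV_number", "categorical", (0, 1, 2, 3)),
        FeatureSpec("DM", "categorical", b),
        FeatureSpec("REV_type", "categorical", (1, 2)),
        FeatureSpec("LM_lesion", "categorical", b),
        FeatureSpec("ASA", "categorical", b),
    ]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def gen_tabular(
    schema: Sequence[FeatureSpec] | None = None,
    n: int = 1000,
    seed: int = 0,
    imbalance_ratio: float = 0.3,
    informative_names: Sequence[str] | None = None,
    effect_sizes: Mapping[str, float] | Sequence[float] | None = None,
    missing_rate: float = 0.0,
) -> TabularDataset:
    """Draw a synthetic clinical table with a planted logistic label model.

    Numeric features are uniform within their declared range; categorical
    features are uniform over their codes.  The label is Bernoulli with
    logit ``b0 + sum_j beta_j * z_j`` over the standardized informative
    columns; the intercept ``b0`` is solved on the realized sample so the
    class-1 prevalence matches ``imbalance_ratio``.
    """
    if schema is None:
        schema = default_cvd_schema()
    schema = list(schema)
    if n < 10:
        raise ValueError("n must be at least 10")
    if not 0.0 < imbalance_ratio <= 1.0:
        raise ValueError("imbalance_ratio must lie in (0, 1]")
    names = [s.name for s in schema]
    if informative_names is None:
        informative_names = [s.name for s in schema if s.informative]
    unknown = set(informative_names) - set(names)
    if unknown:
        raise ValueError(f"unknown informative feature(s): {sorted(unknown)}")
    if effect_sizes is None:
        betas = {f: 1.0 for f in informative_names}
    elif isinstance(effect_sizes, Mapping):
        betas = {f: float(effect_sizes[f]) for f in informative_names}
    else:
        if len(effect_sizes) != len(informative_names):
            raise ValueError("effect_sizes length must match informative_names")
        betas = dict(zip(informative_names, map(float, effect_sizes)))

    rng = np.random.default_rng(seed)
    cols = []
    for s in schema:
        if s.kind == "numeric":
            lo, hi = s.range
            cols.append(rng.uniform(lo, hi, size=n))
        else:
            cols.append(rng.choice(np.asarray(s.range, dtype=float), size=n))
    X = np.column_stack(cols)

    logit = np.zeros(n)
    for f, beta in betas.items():
        col = X[:, names.index(f)]
        sd = col.std()
        if sd > 0:
            logit += beta * (col - col.mean()) / sd
    # solve the intercept on the realized logits so prevalence ~= target
    lo_b, hi_b = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo_b + hi_b)
        if _sigmoid(logit + mid).mean() < imbalance_ratio:
            lo_b = mid
        else:
            hi_b = mid
    b0 = 0.5 * (lo_b + hi_b)
    y = (rng.random(n) < _sigmoid(logit + b0)).astype(int)

    if missing_rate > 0:
        miss = rng.random(X.shape) < missing_rate
        X = X.copy()
        X[miss] = np.nan

    return TabularDataset(X, schema, y)


def gen_separable(
    n: int = 400,
    dim: int = 2,
    margin: float = 1.0,
    seed: int = 0,
    box: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly separable toy data for classifier calibration.

    Points are uniform in ``[-box, box]^dim`` with any point within
    ``margin/2`` of the separating hyperplane rejected; the label is the
    side of the hyperplane.  Returns ``(X, y)``.
    """
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(dim)
    w /= np.linalg.norm(w)
    X = np.empty((0, dim))
    while len(X) < n:
        cand = rng.uniform(-box, box, size=(n, dim))
        X = np.vstack([X, cand[np.abs(cand @ w) > margin / 2]])
    X = X[:n]
    return X, (X @ w > 0).astype(int)


def gen_phantoms(
    n: int = 50,
    size: int = 64,
    seed: int = 0,
    noise_sigma: float = 0.05,
    radius_range: tuple[float, float] = (0.10, 0.18),
    wall_range: tuple[float, float] = (0.08, 0.14),
) -> list[PhantomPair]:
    """Generate annulus left-ventricle phantoms with ground-truth masks.

    Each phantom places a disc cavity (label 1) of radius ``r_in`` inside a
    myocardial annulus (label 2) of outer radius ``r_in + wall`` at a random
    centre.  ``radius_range`` and ``wall_range`` are fractions of ``size``.
    Intensities are the three class base levels plus i.i.d. Gaussian noise.
    """
    if size < 32:
        raise ValueError("size must be at least 32")
    r_out_max = (radius_range[1] + wall_range[1]) * size
    if 2 * r_out_max >= size:
        raise ValueError("radii exceed image bounds")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    pairs = []
    for k in range(n):
        r_in = rng.uniform(*radius_range) * size
        wall = rng.uniform(*wall_range) * size
        r_out = r_in + wall
        cy = rng.uniform(r_out + 1, size - r_out - 1)
        cx = rng.uniform(r_out + 1, size - r_out - 1)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask = np.zeros((size, size), dtype=np.int64)
        mask[d2 <= r_out**2] = 2
        mask[d2 <= r_in**2] = 1
        image = np.asarray(PHANTOM_INTENSITIES, dtype=float)[mask]
        if noise_sigma > 0:
            image = image + rng.normal(0.0, noise_sigma, size=image.shape)
        meta = {
            "center": (float(cy), float(cx)),
            "r_inner": float(r_in),
            "r_outer": float(r_out),
            "noise_sigma": float(noise_sigma),
            "seed": int(seed),
            "index": k,
        }
        pairs.append(PhantomPair(image, mask, meta))
    return pairs


# ---------------------------------------------------------------------------
# writers


def dataset_to_csv(dataset: TabularDataset, path, sidecar: dict | None = None) -> None:
    """Write the dataset as CSV (header = feature names + label) and an
    optional JSON sidecar with generation parameters."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def dataset_from_csv(path, schema: Sequence[FeatureSpec] | None = None) -> TabularDataset:
    import pandas as pd

    df = pd.read_csv(path)
    if LABEL_NAME not in df.columns:
        raise ValueError(f"CSV lacks label column {LABEL_NAME!r}")
    y = df.pop(LABEL_NAME).to_numpy()
    if schema is None:
        by_name = {s.name: s for s in default_cvd_schema()}
        schema = [
            by_name.get(c, FeatureSpec(c, "numeric", (float(df[c].min()) - 1e-9, float(df[c].max()) + 1e-9)))
            for c in df.columns
        ]
    return TabularDataset(df.to_numpy(dtype=float), list(schema), y)


def save_phantom_png(pair: PhantomPair, image_path, mask_path=None) -> None:
    """8-bit PNG export; mask written with raw label values 0/1/2."""
    from PIL import Image

    img = np.clip(pair.image, 0.0, 1.0)
    Image.fromarray((img * 255).round().astype(np.uint8)).save(image_path)
    if mask_path is not None:
        Image.fromarray(pair.mask.astype(np.uint8)).save(mask_path)


def save_phantom_nifti(pair: PhantomPair, image_path, mask_path=None) -> None:
    import nibabel as nib

    affine = np.eye(4)
    nib.save(nib.Nifti1Image(pair.image.astype(np.float32), affine), image_path)
    if mask_path is not None:
        nib.save(nib.Nifti1Image(pair.mask.astype(np.int16), affine), mask_path)
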