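# cardiopcso

Cardiovascular-disease risk modelling with **Predator Crow Search
Optimization (PCSO)**: information-gain feature selection, a PCSO-trained
dense classifier with a model-agnostic explanation layer, and a U-Net for
left-ventricle segmentation — all exercisable end-to-end on built-in
synthetic data, so nothing requires access-gated clinical datasets.

## Who this is for

Researchers and students working on tabular CVD risk prediction (MACCE —
major adverse cardiac and cerebrovascular events — as the outcome) and
short-axis cardiac-MRI segmentation who want a tested, seeded, pure
scientific-Python implementation of:

* a hybrid population metaheuristic (predator-style Brownian/Lévy phase
  steps towards a best-so-far elite, masked raid jumps, and crow-search
  steps towards other agents' memorized bests, blended 50/50 and accepted
  greedily);
* entropy-based feature selection, SMOTE balancing, leakage-free
  standardization, and a stratified 5-fold harness;
* direct neural-network weight optimization by population search, with
  permutation-importance/finite-difference explanations;
* a depth-5 U-Net (8→128 encoder channels) with Dice loss and a
  "perfect ROI" cropping protocol.

## The core algorithm

PCSO minimizes `f(x)` over a box `[Smin, Smax]`. With `Q` the iteration,
`Qmax` the budget and `M(Q) = (1 − Q/Qmax)^(2Q/Qmax)`:

* early iterations (Q < Qmax/3) move every prey by Brownian steps
  `Y_A ⊗ (elite − Y_A ⊗ prey)`;
* the middle third splits the population between Lévy steps against the
  elite and M-scaled Brownian steps;
* the final third uses M-scaled Lévy steps `Y_R ⊗ (Y_R ⊗ elite − prey)`.

Each agent then proposes a masked raid jump
`prey + M·(Smin + Y ⊗ (Smax − Smin)) ⊗ H`, a crow step
`crow + rand·FL·(mem_j − crow)`, and evaluates their midpoint, accepting
per agent only on improvement. For the classifier, `x` is the flattened
weight vector of a 128/64/32 dense network and `f` is the weighted binary
cross-entropy on an internal validation split.

Feature selection scores each feature by `IG(X,Y) = H(Y) − H(Y|X)` (bits,
numeric features discretized to 10 equal-width bins) and keeps those above
the mean gain. Metrics follow the confusion-matrix definitions, with
`F1 = 2PR/(P+R)`, trapezoidal AUC, Dice and `IoU = Dice/(2 − Dice)`.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from cardiopcso import igfs, network as net, synthetic
from cardiopcso.classifier import train_with_pcso, explain
from cardiopcso.pcso import PCSOConfig
from cardiopcso.preprocessing import stratified_split, zscore_normalize, apply_zscore

# a synthetic clinical table: 15 features, LVEF/Age/TC carry the signal
ds = synthetic.gen_tabular(n=2000, seed=7, imbalance_ratio=0.4,
                           informative_names=["LVEF", "Age", "TC"],
                           effect_sizes=[2.0, 1.5, 1.0])

table = igfs.select_features(ds)           # information-gain ranking
print(table.ranked_names[:5])
print("selected:", table.selected_names)   # mean-IG threshold
keep = np.flatnonzero(table.selected)

tr, te = stratified_split(ds.y, 0.8, seed=7)
numeric = [j for j, s in enumerate(ds.schema) if s.kind == "numeric"]
Xtr, stats = zscore_normalize(ds.X[tr], numeric)
Xte = apply_zscore(ds.X[te], stats)        # training statistics only

spec = net.NetworkSpec(input_dim=len(keep))
cfg = PCSOConfig(dim=net.n_params(spec), lower=-1, upper=1,
                 pop_size=20, max_iters=60, seed=7)
model, result = train_with_pcso(spec, Xtr[:, keep], ds.y[tr],
                                pcso_config=cfg, seed=7)
acc = (model.predict(Xte[:, keep]) == ds.y[te]).mean()
print(f"held-out accuracy {acc:.3f}, final fitness {result.best_fitness:.4f}")

rep = explain(model, Xte[:, keep], ds.y[te], n_repeats=10, seed=7,
              feature_names=[ds.feature_names[j] for j in keep], local_rows=0)
print("top importance:", rep.global_rank)
```

Output:

```
['LVEF', 'Age', 'TC', 'BUN', 'HBG']
selected: ['Age', 'LVEF', 'TC']
held-out accuracy 0.812, final fitness 0.4032
top importance: ['LVEF', 'Age', 'TC']
```

The selector ranks the three planted features first and the mean-gain
threshold keeps exactly them; the PCSO-trained network beats the 0.6
majority rate by a wide margin on this noisy logistic problem (the planted
model's own Bayes accuracy is in the mid-0.8s); and permutation importance
recovers the planted ordering on the held-out split.

The same components run from the shell:

```bash
cardiopcso simulate tabular --n 1000 --seed 1 --out data.csv
cardiopcso select data.csv --threshold-rule mean_ig
cardiopcso optimize --benchmark sphere --dim 5 --pop 20 --iters 200 --seed 1
cardiopcso run --seed 1 --out pipeline_out     # full pipeline + manifest
cardiopcso segment --n 50 --epochs 20 --seed 1 # U-Net on phantoms
```

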