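# ovimorph

Non-invasive estimation of sheep live weight and carcass traits from
paired dorsal/lateral photographs plus two cheap tabular covariates (body
condition score and size category).  The package is aimed at precision-
livestock and computer-vision researchers who want to study **multimodal
image–tabular fusion for multi-target regression** — three architectures,
an uncertainty-weighted multi-task loss, animal-level validation, agreement
statistics and Grad-CAM explainability — without access to a real
CT-phenotyped flock: a calibrated synthetic-flock generator makes the whole
pipeline runnable and testable on a laptop.

## The model

Each animal contributes a dorsal image, a lateral image and a tabular
record; the model predicts four traits jointly: live weight (LW), carcass
weight (CW), fat mass (FM) and lean mass (LM), all in kg.  Three fusion
families share this contract:

| family | fusion mechanism |
|---|---|
| `BaselineConcatRegressor` | conv backbone per view, features concatenated with a tabular MLP (feature-level fusion) |
| `AttentionFusionRegressor` | CBAM-extended backbone; the tabular encoding *queries* the visual tokens via cross-modal attention |
| `TokenFusionRegressor` | patch tokens of both views + one tabular token in a single transformer sequence; the tabular token's terminal state is read out |

Training minimizes the homoscedastic task-uncertainty loss

```
L = Σ_t  exp(−s_t) · MSE_t  +  s_t ,        s_t learnable, init −0.5
```

so the per-task weights are learned log-variances rather than hand-set
coefficients.  The estimators follow the scikit-learn contract
(`fit`/`predict`/`get_params`), so `sklearn.base.clone` drives the grid
search, the animal-level k-fold cross-validation and the single-change
ablation harness.

The synthetic flock draws live weight from a truncated normal calibrated so
the *observed* mean/SD are 62.4/8.7 kg on [48.0, 88.5] kg, fat mass from a
correlated truncated lognormal on [0.88, 17.64] kg, and renders silhouettes
whose geometry encodes the targets — with the fat-mass effect modulated by
size category, so fat mass is only decodable jointly with the tabular
record.  See `docs/methods.md` for the full model.

## Worked example

```python
import numpy as np
from ovimorph import sample_flock, build_arrays, TokenFusionRegressor
from ovimorph.synth import RenderConfig
from ovimorph.evaluation import metrics_table

flock = sample_flock(150, seed=11)                      # phenotypes + covariates
cfg = RenderConfig(background_noise_sd=0.0, texture_noise_sd=0.0)
data = build_arrays(flock, cfg, seed=3)                 # rendered, normalized arrays
ids = sorted(data.animal_ids)
train, test = data.subset(ids[:120]), data.subset(ids[120:])

model = TokenFusionRegressor(max_epochs=30, seed=42).fit(train)
pred = model.predict(test)
print(metrics_table(test.y, pred, model="ViT token fusion").round(3).to_string(index=False))
print("learned log-variances:", np.round(model.logvars_[0].values, 3))
```

prints (30 held-out animals, a few minutes on one CPU):

```
           model         target  mae_kg  rmse_kg    r2  mape_pct   ccc
ViT token fusion    live_weight   1.561    2.362 0.937     2.330 0.968
ViT token fusion carcass_weight   0.748    1.136 0.927     2.586 0.958
ViT token fusion       fat_mass   0.749    0.974 0.928    10.342 0.963
ViT token fusion      lean_mass   0.985    1.265 0.851     7.643 0.915
learned log-variances: [-0.536 -0.587 -0.524 -0.541]
```

Reading it: the tiny transformer recovers live weight on animals it has
never seen with an MAE of 1.6 kg and R² 0.94 on the zero-noise synthetic
benchmark; fat mass — only decodable by combining image geometry with the
tabular record — reaches R² 0.93, and its MAPE is the largest of the four
targets because fat mass is the smallest quantity.  CCC close to 1 means
predictions agree with truth on the identity line, not merely correlate.
The learned log-variances stay near their −0.5 init because the targets
are z-scored per task, leaving the four tasks roughly balanced.

The same pipeline is scriptable from the shell:

```bash
ovimorph simulate --n 156 --seed 42 --out flock/
ovimorph split    --flock flock/flock.csv --out splits/     # 109/24/23 animals
ovimorph train    --flock flock/flock.csv --split splits/split.csv --out run/
ovimorph evaluate --checkpoint run/checkpoint.npz --flock flock/flock.csv \
                  --split splits/split.csv --out eval/
ovimorph explain  --checkpoint run/checkpoint.npz --flock flock/flock.csv --out cam/
```

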