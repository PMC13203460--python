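"""Multi-task training machinery: the homoscedastic task-uncertainty loss,
learning-rate schedules, stability reporting, and the harnesses (grid
search, animal-level cross-validation, ablation) that operate on the
estimator classes.

The loss
--------
With per-task mean squared errors ``m_t`` and learnable log-variances
``s_t`` the combined objective is

    L = sum_t [ exp(-s_t) * m_t + s_t ]

so each task is inversely weighted by its learned noise level and the
``+ s_t`` term stops the trivial escape of inflating every variance.  At
the optimum ``s_t = ln(m_t)``.  Setting every ``s_t = 0`` recovers the
plain sum of MSEs.  All four log-variances are initialized to the same
value (default -0.5) so the targets start with identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import ParameterGrid

from .nn import Tensor
from .synth import AnimalPhenotype
from .data import assign_folds

__all__ = [
    "TaskLogVars",
    "uncertainty_weighted_loss",
    "scheduled_lr",
    "TrainHistory",
    "stability_report",
    "grid_search",
    "run_cross_validation",
    "run_ablation",
    "multi_run_stability",
    "derive_run_seeds",
]

LOGVAR_INIT = -0.5  # equal initial task weighting


class TaskLogVars:
    """The four learnable per-task log-variance parameters."""

    def __init__(self, init_value: float = LOGVAR_INIT, n_tasks: int = 4):
        self.init_value = float(init_value)
        self.s = Tensor(np.full(n_tasks, float(init_value)), requires_grad=True)

    @property
    def values(self) -> np.ndarray:
        return self.s.data.copy()


def uncertainty_weighted_loss(mse, logvars) -> Tensor:
    """Combined multi-task loss; differentiable in both arguments.

    ``mse`` may be a Tensor of per-task mean squared errors or an array;
    ``logvars`` a :class:`TaskLogVars`, Tensor or array.
    """
    m = mse if isinstance(mse, Tensor) else Tensor(np.asarray(mse, dtype=float))
    if isinstance(logvars, TaskLogVars):
        s = logvars.s
    elif isinstance(logvars, Tensor):
        s = logvars
    else:
        s = Tensor(np.asarray(logvars, dtype=float))
    if not (np.all(np.isfinite(m.data)) and np.all(np.isfinite(s.data))):
        raise ValueError("non-finite loss inputs")
    if np.any(m.data < 0):
        raise ValueError("mean squared errors must be non-negative")
    return (m * (-s).exp() + s).sum()


def scheduled_lr(scheduler: str, epoch: int, base_lr: float, *, step_size: int = 20,
                 gamma: float = 0.5, t_max: int = 50, warmup_epochs: int = 5) -> float:
    """Learning rate at `epoch` (0-based); beyond the horizon the schedule
    clamps at its final value."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if scheduler == "constant":
        return base_lr
    if scheduler == "step_decay":
        return base_lr * gamma ** (epoch // step_size)
    if scheduler == "cosine":
        e = min(epoch, t_max)
        return base_lr * (1.0 + np.cos(np.pi * e / t_max)) / 2.0
    if scheduler == "warmup_cosine":
        if epoch < warmup_epochs:
            return base_lr * epoch / warmup_epochs
        e = min(epoch - warmup_epochs, t_max)
        return base_lr * (1.0 + np.cos(np.pi * e / t_max)) / 2.0
    raise ValueError(f"unknown scheduler {scheduler!r}")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_mae: list = field(default_factory=list)  # per-epoch (4,) arrays, kg
    val_loss: list = field(default_factory=list)
    val_mae: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in range(len(self)):
            row = {"epoch": e, "train_loss": self.train_loss[e],
                   "val_loss": self.val_loss[e], "lr": self.lr[e]}
            for t, name in enumerate(("lw", "cw", "fm", "lm")):
                row[f"train_mae_{name}"] = self.train_mae[e][t]
                row[f"val_mae_{name}"] = self.val_mae[e][t]
            rows.append(row)
        return pd.DataFrame(rows)


def stability_report(history: TrainHistory, window: int = 10) -> dict:
    """Mean +/- SD of train and validation MAE over the last `window`
    epochs, and the generalization gap (val - train), per target."""
    if len(history) < window:
        raise ValueError(f"history shorter than window ({len(history)} < {window})")
    train = np.asarray(history.train_mae[-window:], dtype=float)
    val = np.asarray(history.val_mae[-window:], dtype=float)
    return {
        "window": window,
        "train_mae_mean": train.mean(axis=0),
        "train_mae_sd": train.std(axis=0, ddof=1),
        "val_mae_mean": val.mean(axis=0),
        "val_mae_sd": val.std(axis=0, ddof=1),
        "generalization_gap": val.mean(axis=0) - train.mean(axis=0),
    }


def grid_search(estimator, param_grid: dict, train_data, val_data):
    """Exhaustive search; winner = lowest validation MAE averaged across the
    four targets; ties broken by first-seen order.

    Returns (best_estimator, best_params, results list).
    """
    grid = list(ParameterGrid(param_grid))
    if not grid:
        raise ValueError("empty search space")
    results = []
    best = None
    for params in grid:
        est = clone(estimator).set_params(**params)
        est.fit(train_data, validation_data=val_data)
        pred = est.predict(val_data)
        mae = float(np.mean(np.abs(pred - val_data.y)))
        if not np.isfinite(mae):  # diverged run: rank last
            mae = np.inf
        results.append({"params": params, "val_mae": mae})
        if best is None or mae < best[0]:
            best = (mae, params, est)
    return best[2], best[1], results


def run_cross_validation(estimator, flock: list[AnimalPhenotype], k: int = 10,
                         seed: int = 42, render_seed: int = 0,
                         render_config=None) -> dict:
    """k-fold cross-validation partitioned at the animal level.

    Every image (both views) of an animal lives in exactly one fold; each
    fold in turn is the held-out set.  Returns per-fold records plus
    mean +/- SD aggregates of R^2 and MAE per target.
    """
    from .data import build_arrays  # local to avoid import cycle at module load
    from .evaluation import regression_metrics

    if k < 2:
        raise ValueError("k must be >= 2")
    flock = sorted(flock, key=lambda a: a.animal_id)  # roster-order invariance
    ids = [a.animal_id for a in flock]
    manifest = assign_folds(ids, k, seed)
    data = build_arrays(flock, render_config, render_seed)
    folds = []
    for fold_idx in range(k):
        held = set(manifest.fold(fold_idx))
        train_ds = data.subset([i for i in data.animal_ids if i not in held])
        val_ds = data.subset([i for i in data.animal_ids if i in held])
        est = clone(estimator)
        est.fit(train_ds)
        pred = est.predict(val_ds)
        record = {"fold": fold_idx, "animals": sorted(held)}
        for t, name in enumerate(("live_weight", "carcass_weight", "fat_mass", "lean_mass")):
            m = regression_metrics(val_ds.y[:, t], pred[:, t])
            record[f"r2_{name}"] = m.r2
            record[f"mae_{name}"] = m.mae
        folds.append(record)
    agg = {}
    for key in folds[0]:
        if key in ("fold", "animals"):
            continue
        vals = np.array([f[key] for f in folds], dtype=float)
        agg[key] = (float(vals.mean()), float(vals.std(ddof=1)))
    return {"folds": folds, "aggregate": agg, "k": k}


ABLATION_VARIANTS = ("backbone_swap", "single_task", "image_only",
                     "concat_fusion", "no_aug_no_reg")


def run_ablation(estimator, train_data, test_data, variants=ABLATION_VARIANTS) -> list[dict]:
    """Train the full model plus each requested single-change variant under
    identical seed/split/augmentation settings; report MAE and R^2 per
    target per variant."""
    from .estimators import BaselineConcatRegressor
    from .evaluation import regression_metrics

    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {v!r}")

    def evaluate(est, label, config_note):
        pred = est.predict(test_data)
        row = {"variant": label, "config": config_note}
        for t, name in enumerate(("live_weight", "carcass_weight", "fat_mass", "lean_mass")):
            m = regression_metrics(test_data.y[:, t], pred[:, t])
            row[f"mae_{name}"] = m.mae
            row[f"r2_{name}"] = m.r2
        return row

    table = []
    full = clone(estimator)
    full.fit(train_data)
    table.append(evaluate(full, "full", "unmodified estimator"))

    for variant in variants:
        if variant == "backbone_swap":
            est = BaselineConcatRegressor(
                seed=estimator.seed, max_epochs=estimator.max_epochs,
                batch_size=estimator.batch_size, base_lr=estimator.base_lr,
                augmentation_mode=estimator.augmentation_mode,
            )
            note = "convolutional backbone replaces the transformer"
        elif variant == "single_task":
            est = clone(estimator).set_params(single_task=True)
            note = "four independent single-target models"
        elif variant == "image_only":
            est = clone(estimator).set_params(use_tabular=False)
            note = "tabular branch zeroed"
        elif variant == "concat_fusion":
            est = clone(estimator)
            if "fusion_mode" in est.get_params():
                est.set_params(fusion_mode="concat")
            note = "token-level fusion replaced by feature concatenation"
        elif variant == "no_aug_no_reg":
            est = clone(estimator).set_params(
                augmentation_mode="none", weight_decay=0.0, dropout=0.0
            )
            note = "no augmentation, no weight decay, no dropout"
        est.fit(train_data)
        table.append(evaluate(est, variant, note))
    return table


def derive_run_seeds(base_seed: int, n_runs: int = 5) -> list[int]:
    """Distinct initialization seeds derived deterministically from one base
    seed (used by the multi-run stability protocol)."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n_runs) % (2**31)]


def multi_run_stability(estimator, train_data, val_data, n_runs: int = 5) -> dict:
    """Repeat training with `n_runs` derived init seeds; report the SD of
    the validation MAE per target across runs."""
    maes = []
    for s in derive_run_seeds(estimator.seed, n_runs):
        est = clone(estimator).set_params(seed=s)
        est.fit(train_data, validation_data=val_data)
        pred = est.predict(val_data)
        maes.append(np.mean(np.abs(pred - val_data.y), axis=0))
    maes = np.asarray(maes)
    return {"val_mae_runs": maes, "val_mae_sd": maes.std(axis=0, ddof=1),
            "val_mae_mean": maes.mean(axis=0)}
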