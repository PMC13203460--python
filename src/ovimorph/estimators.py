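"""Scikit-learn style estimators wrapping the three fusion architectures.

Each estimator takes an :class:`~ovimorph.data.ArrayDataset` (or an
``(dorsal, lateral, tabular)`` tuple plus ``y``) and learns the four
targets jointly under the homoscedastic task-uncertainty loss.  They follow
the sklearn contract — ``get_params``/``set_params``, ``fit`` returning
``self``, fitted attributes with a trailing underscore — so they compose
with ``sklearn.base.clone`` and the grid-search/CV harnesses.

Defaults are desk-scale (64 px images, tiny backbones, 30 epochs); the
published full-scale hyperparameter rows are available from
:func:`published_presets` for reference.  Training is single-threaded and
fully deterministic given ``seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import Tensor
from .nn.optim import build_optimizer
from .data import ArrayDataset
from .models import IMAGENET_MEAN, IMAGENET_SD, N_TARGETS, build_net
from .training import (
    LOGVAR_INIT,
    TaskLogVars,
    TrainHistory,
    scheduled_lr,
    uncertainty_weighted_loss,
)

__all__ = [
    "BaselineConcatRegressor",
    "AttentionFusionRegressor",
    "TokenFusionRegressor",
    "published_presets",
]


def published_presets() -> dict:
    """The full-scale hyperparameter rows of the three architectures, for
    reference; desk-scale defaults below deviate (smaller backbones, fewer
    epochs, schedules re-spanned to the shorter run)."""
    return {
        "baseline_concat": {
            "backbone": "resnet18_like", "tabular_widths": (16, 32, 16),
            "activation": "relu", "weight_decay": 1e-4, "dropout": 0.30,
            "max_epochs": 100, "optimizer": "adamw", "base_lr": 1e-3,
            "batch_size": 32, "scheduler": "step_decay",
            "scheduler_params": {"step_size": 20, "gamma": 0.5}, "patience": 15,
        },
        "attention_fusion": {
            "backbone": "efficientnet_b3_like", "tabular_widths": (32, 64, 32),
            "activation": "swish", "weight_decay": 1e-4, "dropout": 0.40,
            "max_epochs": 100, "optimizer": "adamw", "base_lr": 5e-4,
            "batch_size": 16, "scheduler": "cosine",
            "scheduler_params": {"t_max": 50}, "patience": 15,
        },
        "token_fusion": {
            "tabular_widths": (64, 128, 64), "activation": "gelu",
            "weight_decay": 1e-5, "dropout": 0.20, "max_epochs": 100,
            "optimizer": "adamw", "base_lr": 1e-4, "batch_size": 8,
            "scheduler": "warmup_cosine",
            "scheduler_params": {"warmup_epochs": 5, "t_max": 95}, "patience": 15,
        },
    }


def _resolve(X, y):
    if isinstance(X, ArrayDataset):
        return X.dorsal, X.lateral, X.tabular, X.y if y is None else np.asarray(y)
    dorsal, lateral, tabular = X
    return (np.asarray(dorsal), np.asarray(lateral), np.asarray(tabular),
            None if y is None else np.asarray(y))


class _FusionRegressorBase(RegressorMixin, BaseEstimator):
    """Shared training loop; subclasses configure the network family."""

    _family: str = ""

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None, validation_data=None):
        dorsal, lateral, tabular, y = _resolve(X, y)
        if y is None:
            raise ValueError("targets are required to fit")
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        n = dorsal.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        if not self.use_tabular:
            tabular = np.zeros_like(tabular)

        self.y_mean_ = y.mean(axis=0)
        self.y_sd_ = y.std(axis=0)
        self.y_sd_ = np.where(self.y_sd_ > 0, self.y_sd_, 1.0)
        ys = (y - self.y_mean_) / self.y_sd_

        val = None
        if validation_data is not None:
            if isinstance(validation_data, ArrayDataset):
                vd, vl, vt, vy = _resolve(validation_data, None)
            else:
                vd, vl, vt, vy = _resolve(*validation_data) if len(validation_data) == 2 \
                    else _resolve(validation_data, None)
            if not self.use_tabular:
                vt = np.zeros_like(vt)
            val = (vd, vl, vt, (vy - self.y_mean_) / self.y_sd_)

        rng = np.random.default_rng(self.seed)
        task_sets = [[t] for t in range(N_TARGETS)] if self.single_task else [list(range(N_TARGETS))]
        self.nets_ = []
        self.logvars_ = []
        history = TrainHistory()

        # one net per task set: a single shared net normally, four
        # independent nets in the single-task ablation
        states = []
        for tasks in task_sets:
            net = self._build_net(np.random.default_rng(rng.integers(2**31)))
            logvars = TaskLogVars(self.logvar_init, n_tasks=len(tasks))
            self.nets_.append(net)
            self.logvars_.append(logvars)
            states.append({"net": net, "logvars": logvars, "tasks": tasks})

        params = [p for st in states for p in st["net"].parameters()]
        params += [st["logvars"].s for st in states]
        opt = build_optimizer(self.optimizer, params, self.base_lr, self.weight_decay)

        sched = dict(self.scheduler_params or {})
        if self.scheduler == "cosine":
            sched.setdefault("t_max", max(self.max_epochs, 1))
        elif self.scheduler == "warmup_cosine":
            sched.setdefault("warmup_epochs", 5)
            sched.setdefault("t_max", max(self.max_epochs - sched["warmup_epochs"], 1))

        best_val = np.inf
        best_states = None
        epochs_since_best = 0
        stopped = self.max_epochs - 1

        for epoch in range(self.max_epochs):
            lr = scheduled_lr(self.scheduler, epoch, self.base_lr, **sched)
            opt.lr = lr
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            abs_err = np.zeros(N_TARGETS)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                bd, bl, bt = dorsal[idx], lateral[idx], tabular[idx]
                if self.augmentation_mode == "stochastic":
                    bd = self._augment_arrays(bd, rng)
                    bl = self._augment_arrays(bl, rng)
                by = ys[idx]
                opt.zero_grad()
                loss_val = 0.0
                diverged = False
                for st in states:
                    st["net"].train()
                    pred = st["net"](Tensor(bd), Tensor(bl), Tensor(bt))
                    err = pred[:, st["tasks"]] - Tensor(by[:, st["tasks"]])
                    with np.errstate(over="ignore", invalid="ignore"):
                        mse = (err**2).mean(axis=0)
                        if not np.all(np.isfinite(mse.data)):
                            diverged = True
                            break
                        loss = uncertainty_weighted_loss(mse, st["logvars"])
                        loss.backward()
                    loss_val += loss.item()
                    abs_err[st["tasks"]] += np.abs(err.data).sum(axis=0)
                if diverged:
                    break
                opt.step()
                epoch_loss += loss_val
                n_batches += 1
            if diverged:
                # divergence guard: abandon the run, keep the best checkpoint
                stopped = epoch
                break

            # running train MAE over the epoch's (pre-update) batch predictions
            train_mae = abs_err / n * self.y_sd_
            history.train_loss.append(epoch_loss / n_batches)
            history.train_mae.append(train_mae)
            history.lr.append(lr)
            if val is not None:
                vloss, vmae = self._eval_loss(states, *val)
            else:
                vloss, vmae = epoch_loss / n_batches, train_mae
            history.val_loss.append(vloss)
            history.val_mae.append(vmae)

            if vloss < best_val - 1e-12:
                best_val = vloss
                best_states = [
                    (st["net"].state_dict(), st["logvars"].s.data.copy()) for st in states
                ]
                history.best_epoch = epoch
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= self.patience:
                    stopped = epoch
                    break
            stopped = epoch

        history.stopped_epoch = stopped
        if best_states is not None:
            for st, (sd, lv) in zip(states, best_states):
                st["net"].load_state_dict(sd)
                st["logvars"].s.data[...] = lv
        self.history_ = history
        self._task_sets_ = task_sets
        return self

    # ----------------------------------------------------------- inference

    def predict(self, X):
        dorsal, lateral, tabular, _ = _resolve(X, None)
        if not self.use_tabular:
            tabular = np.zeros_like(tabular)
        out = np.empty((dorsal.shape[0], N_TARGETS))
        for net, tasks in zip(self.nets_, self._task_sets_):
            net.eval()
            pred = net(Tensor(dorsal), Tensor(lateral), Tensor(tabular)).data
            out[:, tasks] = pred[:, tasks]
        return out * self.y_sd_ + self.y_mean_

    def _eval_loss(self, states, vd, vl, vt, vys):
        # validation loss uses the uncertainty weighting with the *current*
        # (frozen) log-variances, mirroring the training objective
        total = 0.0
        mae = np.empty(N_TARGETS)
        for st in states:
            st["net"].eval()
            pred = st["net"](Tensor(vd), Tensor(vl), Tensor(vt)).data
            err = pred[:, st["tasks"]] - vys[:, st["tasks"]]
            mse = (err**2).mean(axis=0)
            s = st["logvars"].s.data
            total += float(np.sum(np.exp(-s) * mse + s))
            mae[st["tasks"]] = np.abs(err).mean(axis=0) * self.y_sd_[st["tasks"]]
        return total, mae

    def _augment_arrays(self, batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Stochastic flip/rotate/brightness on normalized (N,3,H,W) arrays."""
        mean = IMAGENET_MEAN[:, None, None]
        sd = IMAGENET_SD[:, None, None]
        out = np.empty_like(batch)
        for i, img in enumerate(batch):
            raw = img * sd + mean
            if rng.random() < 0.5:
                raw = raw[:, :, ::-1]
            angle = rng.uniform(-8.0, 8.0)
            fill = float(np.median(raw[:, [0, -1], :]))
            raw = ndimage.rotate(raw, angle, axes=(2, 1), reshape=False, order=1,
                                 mode="constant", cval=fill)
            raw = np.clip(raw * (1.0 + rng.uniform(-0.2, 0.2)), 0.0, 1.0)
            out[i] = (raw - mean) / sd
        return out

    # -------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights plus an embedded copy of the configuration."""
        arrays = {}
        for i, (net, lv) in enumerate(zip(self.nets_, self.logvars_)):
            for k, v in net.state_dict().items():
                arrays[f"net{i}.{k}"] = v
            arrays[f"logvars{i}"] = lv.s.data
        arrays["y_mean"] = self.y_mean_
        arrays["y_sd"] = self.y_sd_
        config = {"class": type(self).__name__, "params": self.get_params()}
        np.savez(path, __config__=json.dumps(config, default=list), **arrays)

    @classmethod
    def load(cls, path: str | Path):
        with np.load(path, allow_pickle=False) as z:
            config = json.loads(str(z["__config__"]))
            params = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in config["params"].items()}
            if config["class"] != cls.__name__:
                klass = {c.__name__: c for c in
                         (BaselineConcatRegressor, AttentionFusionRegressor,
                          TokenFusionRegressor)}[config["class"]]
            else:
                klass = cls
            est = klass(**{k: v for k, v in params.items()
                           if k in klass().get_params()})
            est.y_mean_ = z["y_mean"]
            est.y_sd_ = z["y_sd"]
            task_sets = [[t] for t in range(N_TARGETS)] if est.single_task \
                else [list(range(N_TARGETS))]
            est.nets_ = []
            est.logvars_ = []
            rng = np.random.default_rng(0)
            for i, tasks in enumerate(task_sets):
                net = est._build_net(rng)
                net.load_state_dict(
                    {k[len(f"net{i}."):]: z[k] for k in z.files
                     if k.startswith(f"net{i}.")}
                )
                lv = TaskLogVars(est.logvar_init, n_tasks=len(tasks))
                lv.s.data[...] = z[f"logvars{i}"]
                est.nets_.append(net)
                est.logvars_.append(lv)
            est._task_sets_ = task_sets
            est.history_ = TrainHistory()
        return est


class BaselineConcatRegressor(_FusionRegressorBase):
    """Concatenation baseline: conv backbone + tabular MLP, feature-level
    fusion, fully connected head (ReLU activations)."""

    _family = "baseline_concat"

    def __init__(self, backbone="tiny_cnn", tabular_widths=(16, 32, 16),
                 head_widths=(64,), activation="relu", shared_backbone=True,
                 dropout=0.30, max_epochs=30, batch_size=16, optimizer="adamw",
                 base_lr=1e-3, weight_decay=1e-4, scheduler="step_decay",
                 scheduler_params=None, patience=15, seed=42,
                 logvar_init=LOGVAR_INIT, augmentation_mode="none",
                 use_tabular=True, single_task=False):
        self.backbone = backbone
        self.tabular_widths = tabular_widths
        self.head_widths = head_widths
        self.activation = activation
        self.shared_backbone = shared_backbone
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.base_lr = base_lr
        self.weight_decay = weight_decay
        self.scheduler = scheduler
        self.scheduler_params = scheduler_params
        self.patience = patience
        self.seed = seed
        self.logvar_init = logvar_init
        self.augmentation_mode = augmentation_mode
        self.use_tabular = use_tabular
        self.single_task = single_task

    def _build_net(self, rng):
        return build_net("baseline_concat", rng, backbone=self.backbone,
                         tabular_widths=self.tabular_widths,
                         head_widths=self.head_widths, dropout=self.dropout,
                         activation=self.activation,
                         shared_backbone=self.shared_backbone)


class AttentionFusionRegressor(_FusionRegressorBase):
    """CBAM-extended backbone with tabular-query cross-modal attention
    (Swish activations)."""

    _family = "attention_fusion"

    def __init__(self, backbone="tiny_cnn", tabular_widths=(32, 64, 32),
                 head_widths=(64,), attn_dim=32, activation="swish",
                 shared_backbone=True, dropout=0.40, max_epochs=30,
                 batch_size=16, optimizer="adamw", base_lr=5e-4,
                 weight_decay=1e-4, scheduler="cosine", scheduler_params=None,
                 patience=15, seed=42, logvar_init=LOGVAR_INIT,
                 augmentation_mode="none", use_tabular=True, single_task=False):
        self.backbone = backbone
        self.tabular_widths = tabular_widths
        self.head_widths = head_widths
        self.attn_dim = attn_dim
        self.activation = activation
        self.shared_backbone = shared_backbone
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.base_lr = base_lr
        self.weight_decay = weight_decay
        self.scheduler = scheduler
        self.scheduler_params = scheduler_params
        self.patience = patience
        self.seed = seed
        self.logvar_init = logvar_init
        self.augmentation_mode = augmentation_mode
        self.use_tabular = use_tabular
        self.single_task = single_task

    def _build_net(self, rng):
        return build_net("attention_fusion", rng, backbone=self.backbone,
                         tabular_widths=self.tabular_widths,
                         head_widths=self.head_widths, attn_dim=self.attn_dim,
                         dropout=self.dropout, activation=self.activation,
                         shared_backbone=self.shared_backbone)


class TokenFusionRegressor(_FusionRegressorBase):
    """Transformer with token-level fusion of patch tokens from both views
    plus a dedicated tabular token (GELU activations)."""

    _family = "token_fusion"

    def __init__(self, image_size=64, patch_size=8, embed_dim=64, n_heads=4,
                 n_layers=2, mlp_ratio=2.0, tabular_widths=(64, 128, 64),
                 fusion_mode="token", activation="gelu", dropout=0.20,
                 max_epochs=30, batch_size=16, optimizer="adamw", base_lr=1e-3,
                 weight_decay=1e-5, scheduler="warmup_cosine",
                 scheduler_params=None, patience=15, seed=42,
                 logvar_init=LOGVAR_INIT, augmentation_mode="none",
                 use_tabular=True, single_task=False):
        self.image_size = image_size
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.mlp_ratio = mlp_ratio
        self.tabular_widths = tabular_widths
        self.fusion_mode = fusion_mode
        self.activation = activation
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.base_lr = base_lr
        self.weight_decay = weight_decay
        self.scheduler = scheduler
        self.scheduler_params = scheduler_params
        self.patience = patience
        self.seed = seed
        self.logvar_init = logvar_init
        self.augmentation_mode = augmentation_mode
        self.use_tabular = use_tabular
        self.single_task = single_task

    def _build_net(self, rng):
        return build_net("token_fusion", rng, image_size=self.image_size,
                         patch_size=self.patch_size, embed_dim=self.embed_dim,
                         n_heads=self.n_heads, n_layers=self.n_layers,
                         mlp_ratio=self.mlp_ratio,
                         tabular_widths=self.tabular_widths,
                         fusion_mode=self.fusion_mode,
                         dropout=self.dropout, activation=self.activation)
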