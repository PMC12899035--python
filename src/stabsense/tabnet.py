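"""Sequential-attention tabular classifier with sparsemax feature masks.

A from-scratch TabNet-style architecture: an input batch-norm feeds a
feature transformer (2 shared + 2 step-specific gated-linear-unit blocks
with sqrt(0.5) residual scaling) whose output splits into a decision part
(width ``n_d``) and an attention part (width ``n_a``). At each decision
step an attentive transformer maps the attention part to per-feature
scores, multiplies them by a prior, and projects through sparsemax to a
sparse mask; the prior is relaxed by ``prior <- prior * (gamma - mask)``
so features spent at one step are discouraged (and with gamma <= 1
effectively barred) from later steps. ReLU'd decision outputs are summed
across steps into the final logit; mask entropies form the sparsity
penalty added to the cross-entropy loss with weight ``lambda_sparse``.

Per-sample masks make the classifier instance-wise interpretable: the
aggregate importance of feature j for record i is the step-sum of
mask_{ij} weighted by that step's decision contribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from ._autograd import Tensor, bce_with_logits, no_grad, sparsemax_t, _sparsemax_np
from ._nn import BatchNorm1d, Dense, GLUBlock
from .errors import TrainingError, ValidationError

__all__ = [
    "sparsemax",
    "attentive_step",
    "TabNetConfig",
    "MaskTrace",
    "TabNetClassifier",
    "tabnet_forward",
    "train_tabnet",
    "SearchSpace",
    "hyperparameter_search",
    "train_baselines",
]

_ENTROPY_EPS = 1e-10


def sparsemax(z) -> np.ndarray:
    """Euclidean projection of score vector(s) onto the probability simplex.

    Accepts a 1-D vector or a 2-D batch (row-wise). The output is
    nonnegative, sums to 1 per row, and is typically sparse; it is
    invariant to adding a constant to all scores.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValidationError("sparsemax input must be non-empty")
    if not np.all(np.isfinite(z)):
        raise ValidationError("sparsemax input must be finite")
    out = _sparsemax_np(z)
    return out[0] if z.ndim == 1 else out


def attentive_step(a: np.ndarray, prior: np.ndarray, W: np.ndarray,
                   b: np.ndarray | None = None, gamma: float = 1.0):
    """One attentive-transformer step (numpy reference form).

    ``mask = sparsemax(prior * (a @ W + b))``; the returned updated prior
    is ``prior * (gamma - mask)``. Shapes: a (n, n_a), W (n_a, d),
    prior (n, d) or (d,).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    scores = a @ W + (0.0 if b is None else b)
    prior = np.broadcast_to(np.asarray(prior, dtype=np.float64), scores.shape)
    if prior.shape != scores.shape:
        raise ValidationError(
            f"prior shape {prior.shape} incompatible with scores {scores.shape}"
        )
    mask = _sparsemax_np(prior * scores)
    return mask, prior * (gamma - mask)


@dataclass(frozen=True)
class TabNetConfig:
    """Hyperparameters; defaults are the tuned soft-sensor configuration.

    ``reg_coef`` is the general regularization strength (decoupled weight
    decay in AdamW; its natural search range is 1e-3 to 1e-1), distinct
    from ``gamma``, the sparsemax prior-relaxation coefficient whose
    conventional range starts at 1 (gamma = 1 forbids reusing a fully
    spent feature at later steps; larger values relax that).
    """

    n_d: int = 62
    n_a: int = 20
    n_steps: int = 3
    gamma: float = 1.3
    reg_coef: float = 0.038
    lambda_sparse: float = 0.026
    learning_rate: float = 0.012
    batch_size: int = 58
    max_epochs: int = 60
    patience: int = 15

    def validate(self):
        for name in ("n_d", "n_a", "n_steps", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if self.reg_coef < 0:
            raise ValidationError("reg_coef must be >= 0")
        if self.lambda_sparse < 0:
            raise ValidationError("lambda_sparse must be >= 0")


@dataclass
class MaskTrace:
    """Per-step masks plus the aggregate instance-wise importance."""

    step_masks: list                 # n_steps arrays of shape (n, d)
    aggregate: np.ndarray            # (n, d), rows sum to 1
    importance: np.ndarray           # (d,), sums to 1
    sparsity_penalty: float          # mean per-step mask entropy, >= 0


class _TabNetCore:
    """Parameter container + forward pass for the TabNet architecture."""

    def __init__(self, d_in, n_d, n_a, n_steps, gamma, rng):
        self.d_in, self.n_d, self.n_a = d_in, n_d, n_a
        self.n_steps, self.gamma = n_steps, gamma
        width = n_d + n_a
        self.input_bn = BatchNorm1d(d_in)
        # the two shared blocks share their linear weights across all
        # decision steps, but every call site keeps its own BN statistics:
        # step inputs are distributed very differently (unmasked vs masked),
        # so one running statistic per shared layer cannot serve them all
        self.shared_fc = [Dense(d_in, 2 * width, rng), Dense(width, 2 * width, rng)]
        self.shared_bn = [
            [BatchNorm1d(2 * width), BatchNorm1d(2 * width)]
            for _ in range(n_steps + 1)
        ]
        # step-specific pairs: index 0 is the initial transformer
        self.specific = [
            [GLUBlock(width, width, rng), GLUBlock(width, width, rng)]
            for _ in range(n_steps + 1)
        ]
        self.attentive = [Dense(n_a, d_in, rng) for _ in range(n_steps)]
        self.head = Dense(n_d, 1, rng)

    def params(self):
        ps = self.input_bn.params() + self.head.params()
        for fc in self.shared_fc:
            ps += fc.params()
        for pair in self.shared_bn:
            for bn in pair:
                ps += bn.params()
        for pair in self.specific:
            for blk in pair:
                ps += blk.params()
        for fc in self.attentive:
            ps += fc.params()
        return ps

    def set_training(self, mode: bool):
        self.input_bn.training = mode
        for pair in self.shared_bn:
            for bn in pair:
                bn.training = mode
        for pair in self.specific:
            for blk in pair:
                blk.set_training(mode)

    def _glu(self, fc: Dense, bn: BatchNorm1d, x: Tensor, width: int) -> Tensor:
        h = bn(fc(x))
        return h[:, :width] * h[:, width:].sigmoid()

    def _transform(self, x: Tensor, step: int) -> Tensor:
        scale = np.sqrt(0.5)
        width = self.n_d + self.n_a
        h = self._glu(self.shared_fc[0], self.shared_bn[step][0], x, width)
        h = (self._glu(self.shared_fc[1], self.shared_bn[step][1], h, width) + h) * scale
        for blk in self.specific[step]:
            h = (blk(h) + h) * scale
        return h

    def forward(self, X: np.ndarray):
        """Returns (logits Tensor, penalty Tensor, masks list, aggregate np)."""
        n = X.shape[0]
        bn_x = self.input_bn(Tensor(X))
        h = self._transform(bn_x, 0)
        a = h[:, self.n_d :]
        prior = Tensor(np.ones((n, self.d_in)))
        out_sum = None
        masks, etas = [], []
        penalty = None
        for step in range(1, self.n_steps + 1):
            scores = self.attentive[step - 1](a)
            mask = sparsemax_t(prior * scores)
            prior = prior * (self.gamma - mask)
            ent = (mask * -1.0 * (mask + _ENTROPY_EPS).log()).sum(axis=1).mean()
            penalty = ent if penalty is None else penalty + ent
            masked = mask * bn_x
            h = self._transform(masked, step)
            d_out = h[:, : self.n_d].relu()
            out_sum = d_out if out_sum is None else out_sum + d_out
            a = h[:, self.n_d :]
            masks.append(mask.data)
            etas.append(d_out.data.sum(axis=1))
        logits = self.head(out_sum)
        penalty = penalty * (1.0 / self.n_steps)

        agg = np.zeros((n, self.d_in))
        for m, e in zip(masks, etas):
            agg += e[:, None] * m
        row_sums = agg.sum(axis=1, keepdims=True)
        degenerate = row_sums.ravel() <= 0
        agg = np.where(row_sums > 0, agg / np.where(row_sums > 0, row_sums, 1.0),
                       1.0 / self.d_in)
        if degenerate.any():
            agg[degenerate] = 1.0 / self.d_in
        return logits, penalty, masks, agg


class TabNetClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style binary classifier built on the TabNet core.

    ``fit`` accepts an optional validation set (``X_valid``/``y_valid``);
    the parameters from the best-validation epoch are restored at the end
    (best-training-loss epoch when no validation set is given). The
    decision threshold is fixed at probability 0.5; class imbalance is
    expected to be handled upstream by augmentation, not by reweighting.
    """

    def __init__(self, n_d=62, n_a=20, n_steps=3, gamma=1.3, reg_coef=0.038,
                 lambda_sparse=0.026, learning_rate=0.012, batch_size=58,
                 max_epochs=60, patience=15, random_state=0):
        self.n_d = n_d
        self.n_a = n_a
        self.n_steps = n_steps
        self.gamma = gamma
        self.reg_coef = reg_coef
        self.lambda_sparse = lambda_sparse
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, X_valid=None, y_valid=None):
        from ._nn import AdamW, cosine_lr

        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel().astype(np.int64)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise TrainingError("training data contains a single class")
        if X.shape[1] < 1:
            raise ValidationError("X must have at least one feature")

        rng = np.random.default_rng(self.random_state)
        self._core = _TabNetCore(
            X.shape[1], self.n_d, self.n_a, self.n_steps, self.gamma, rng
        )
        params = self._core.params()
        opt = AdamW(params, lr=self.learning_rate, weight_decay=self.reg_coef)

        n = len(X)
        bs = min(self.batch_size, n)
        steps_per_epoch = int(np.ceil(n / bs))
        total_steps = self.max_epochs * steps_per_epoch
        has_valid = X_valid is not None and y_valid is not None
        if has_valid:
            Xv = np.asarray(X_valid, dtype=np.float64)
            yv = np.asarray(y_valid).ravel().astype(np.int64)

        best_score = np.inf
        best_state = None
        best_epoch = 0
        self.loss_history_, self.valid_loss_history_ = [], []
        step = 0
        for epoch in range(self.max_epochs):
            self._core.set_training(True)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s0 in range(0, n, bs):
                idx = order[s0 : s0 + bs]
                logits, penalty, _, _ = self._core.forward(X[idx])
                loss = bce_with_logits(logits, y[idx][:, None]) + self.lambda_sparse * penalty
                if not np.isfinite(loss.data):
                    raise TrainingError("classifier loss became non-finite", epoch=epoch)
                opt.zero_grad()
                loss.backward()
                opt.lr = cosine_lr(self.learning_rate, step, total_steps)
                opt.step()
                step += 1
                epoch_loss += float(loss.data) * len(idx)
            self.loss_history_.append(epoch_loss / n)

            if has_valid:
                self._core.set_training(False)
                with no_grad():
                    logits, penalty, _, _ = self._core.forward(Xv)
                    score = float(bce_with_logits(logits, yv[:, None]).data)
                self.valid_loss_history_.append(score)
            else:
                score = self.loss_history_[-1]
            if score < best_score - 1e-9:
                best_score = score
                best_epoch = epoch
                best_state = (
                    [p.data.copy() for p in params],
                    [bn.running_mean.copy() for bn in self._bn_modules()],
                    [bn.running_var.copy() for bn in self._bn_modules()],
                )
            elif epoch - best_epoch >= self.patience:
                break

        if best_state is not None:
            for p, d in zip(params, best_state[0]):
                p.data = d
            for bn, m, v in zip(self._bn_modules(), best_state[1], best_state[2]):
                bn.running_mean, bn.running_var = m, v
        self.best_epoch_ = best_epoch
        self.best_score_ = best_score
        self.n_features_in_ = X.shape[1]

        # recalibrate every BN layer's running statistics under the final
        # weights with one large-batch pass, so eval-mode activations match
        # the statistics the restored parameters were trained against
        calib = X[: min(len(X), 4096)]
        for bn in self._bn_modules():
            bn.momentum = 1.0
        self._core.set_training(True)
        with no_grad():
            self._core.forward(calib)
        for bn in self._bn_modules():
            bn.momentum = 0.1
        self._core.set_training(False)

        with no_grad():
            _, _, _, agg = self._core.forward(X)
        imp = agg.mean(axis=0)
        self.feature_importances_ = imp / imp.sum()
        return self

    def _bn_modules(self):
        mods = [self._core.input_bn]
        for pair in self._core.shared_bn:
            mods.extend(pair)
        for pair in self._core.specific:
            for blk in pair:
                mods.append(blk.bn)
        return mods

    # ------------------------------------------------------------------
    def decision_function(self, X):
        check_is_fitted(self, "n_features_in_")
        self._core.set_training(False)
        X = np.asarray(X, dtype=np.float64)
        with no_grad():
            pieces = [
                self._core.forward(X[i : i + 8192])[0].data.ravel()
                for i in range(0, len(X), 8192)
            ]
        return np.concatenate(pieces)

    def predict_proba(self, X):
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def explain(self, X) -> MaskTrace:
        """Instance-wise feature attribution for the given records."""
        check_is_fitted(self, "n_features_in_")
        self._core.set_training(False)
        with no_grad():
            _, penalty, masks, agg = self._core.forward(np.asarray(X, dtype=np.float64))
        imp = agg.mean(axis=0)
        return MaskTrace(
            step_masks=masks,
            aggregate=agg,
            importance=imp / imp.sum(),
            sparsity_penalty=float(penalty.data),
        )

    _CONFIG_KEYS = ("n_d", "n_a", "n_steps", "gamma", "reg_coef", "lambda_sparse",
                    "learning_rate", "batch_size", "max_epochs", "patience",
                    "random_state")

    def save(self, path):
        """Persist the fitted model (architecture config + arrays) as .npz."""
        check_is_fitted(self, "n_features_in_")
        meta = {k: getattr(self, k) for k in self._CONFIG_KEYS}
        meta["n_features_in"] = int(self.n_features_in_)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self._core.params())}
        for i, bn in enumerate(self._bn_modules()):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TabNetClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        n_features = meta.pop("n_features_in")
        model = cls(**meta)
        rng = np.random.default_rng(model.random_state)
        model._core = _TabNetCore(
            n_features, model.n_d, model.n_a, model.n_steps, model.gamma, rng
        )
        for i, p in enumerate(model._core.params()):
            p.data = data[f"param_{i}"]
        for i, bn in enumerate(model._bn_modules()):
            bn.running_mean = data[f"bn_mean_{i}"]
            bn.running_var = data[f"bn_var_{i}"]
        model._core.set_training(False)
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = n_features
        return model


def tabnet_forward(X, model: TabNetClassifier):
    """Thin functional wrapper: logits plus the mask trace for ``X``."""
    logits = model.decision_function(X)
    return logits, model.explain(X)


def train_tabnet(X_train, y_train, X_valid=None, y_valid=None,
                 cfg: TabNetConfig | None = None, seed: int = 0) -> TabNetClassifier:
    """Fit a :class:`TabNetClassifier` from a config; deterministic given seed."""
    cfg = cfg or TabNetConfig()
    cfg.validate()
    model = TabNetClassifier(random_state=seed, **{k: v for k, v in asdict(cfg).items()})
    model.fit(X_train, y_train, X_valid=X_valid, y_valid=y_valid)
    return model


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter search ranges (log-uniform for rates/coefficients)."""

    n_d: tuple = (8, 64)
    n_a: tuple = (8, 64)
    n_steps: tuple = (3, 10)
    reg_coef: tuple = (1e-3, 1e-1)
    lambda_sparse: tuple = (1e-5, 1e-1)
    learning_rate: tuple = (1e-5, 1e-1)
    batch_size: tuple = (16, 128)
    n_trials: int = 50

    def validate(self):
        for name in ("n_d", "n_a", "n_steps", "reg_coef", "lambda_sparse",
                     "learning_rate", "batch_size"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"search range for {name} must have lower < upper")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")


def hyperparameter_search(space: SearchSpace, objective, seed: int = 0,
                          base_config: TabNetConfig | None = None):
    """Seeded random search over the TabNet hyperparameter space.

    ``objective(config) -> float`` is maximized (e.g. validation F1). A
    failing trial is logged with status "failed" and the search continues.
    Returns ``(best_config, trial_log)`` where the log is a DataFrame of
    every sampled configuration and score.
    """
    space.validate()
    rng = np.random.default_rng(seed)
    base = base_config or TabNetConfig()

    def log_uniform(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    records = []
    best_cfg, best_score = None, -np.inf
    for trial in range(space.n_trials):
        cfg = TabNetConfig(
            n_d=int(rng.integers(space.n_d[0], space.n_d[1] + 1)),
            n_a=int(rng.integers(space.n_a[0], space.n_a[1] + 1)),
            n_steps=int(rng.integers(space.n_steps[0], space.n_steps[1] + 1)),
            reg_coef=log_uniform(*space.reg_coef),
            lambda_sparse=log_uniform(*space.lambda_sparse),
            learning_rate=log_uniform(*space.learning_rate),
            batch_size=int(rng.integers(space.batch_size[0], space.batch_size[1] + 1)),
            max_epochs=base.max_epochs,
            patience=base.patience,
        )
        row = {"trial": trial, **asdict(cfg)}
        try:
            score = float(objective(cfg))
            row.update(score=score, status="ok")
            if score > best_score:
                best_score, best_cfg = score, cfg
        except Exception as exc:  # trial failure must not kill the search
            row.update(score=np.nan, status=f"failed: {exc}")
        records.append(row)
    log = pd.DataFrame(records)
    if best_cfg is None:
        raise TrainingError("all hyperparameter-search trials failed")
    return best_cfg, log


def train_baselines(X_train, y_train, kind: str, seed: int = 0):
    """Fit a comparison baseline with the shared predict interface.

    ``mlp``: two-hidden-layer perceptron with early stopping. ``gbdt``:
    gradient-boosted trees (500 trees, depth 6, learning rate 0.1).
    """
    y = np.asarray(y_train).ravel().astype(np.int64)
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    if kind == "mlp":
        model = MLPClassifier(
            hidden_layer_sizes=(64, 32), early_stopping=True,
            random_state=seed, max_iter=300,
        )
    elif kind == "gbdt":
        from lightgbm import LGBMClassifier

        model = LGBMClassifier(
            n_estimators=500, max_depth=6, learning_rate=0.1,
            random_state=seed, n_jobs=1, deterministic=True,
            force_row_wise=True, verbose=-1,
        )
    else:
        raise ValidationError(f"unknown baseline kind '{kind}'")
    model.fit(np.asarray(X_train, dtype=np.float64), y)
    return model
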