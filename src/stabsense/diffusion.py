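"""Constraint-aware tabular denoising diffusion for minority-class augmentation.

The rare ethanol-unstable class is enriched with synthetic records from a
denoising diffusion model: continuous indicators follow the standard
Gaussian forward process

    x_t = sqrt(alpha_t) x_{t-1} + sqrt(1 - alpha_t) eps_t,   eps_t ~ N(0, I)

with the closed form ``x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps``
(``abar_t`` the running product of ``alpha_i``), while categorical
indicators follow a multinomial process that flattens the one-hot
distribution toward uniform at rate ``beta_t``. A small MLP conditioned on
a sinusoidal timestep embedding predicts the added Gaussian noise (MSE
loss) and, for categorical columns, the original category (cross-entropy).

Two dairy-chemistry constraints are enforced by rejection sampling during
reverse generation: every selected indicator must be strictly positive,
and total solids must balance fat plus solids-not-fat to within a
tolerance (0.5 g/100 g by default). Candidates violating either are
discarded and regenerated, so every delivered record is physically
plausible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.base import BaseEstimator

from ._autograd import Tensor, no_grad, softmax_cross_entropy
from ._nn import MLP, AdamW, cosine_lr, timestep_embedding
from .cohort import INFORMATIVE_FEATURES, LABEL_COLUMN
from .errors import (
    CompositionError,
    GenerationError,
    SchemaError,
    TrainingError,
    ValidationError,
)

__all__ = [
    "DiffusionSchedule",
    "NoiseQuery",
    "CategoricalSpec",
    "ConstraintSet",
    "make_schedule",
    "forward_noise",
    "multinomial_forward",
    "TabularDiffusionGenerator",
    "marginal_fidelity",
    "AugmentationRecipe",
    "AugmentedDataset",
    "compose_augmented",
]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Noise-variance schedule: beta_t, alpha_t = 1 - beta_t, abar_t = prod alpha."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    def validate(self):
        if self.T < 1:
            raise ValidationError(f"T must be >= 1, got {self.T}")
        if not (np.all(self.beta > 0) and np.all(self.beta < 1)):
            raise ValidationError("all beta_t must lie strictly in (0, 1)")
        if not np.allclose(self.alpha, 1 - self.beta):
            raise ValidationError("alpha_t must equal 1 - beta_t")
        if not np.all(np.diff(self.alpha_bar) < 0):
            raise ValidationError("alpha_bar must be strictly decreasing")


def make_schedule(T: int, kind: str = "linear", beta_start: float = 1e-4,
                  beta_end: float = 0.02) -> DiffusionSchedule:
    """Build a beta schedule. ``linear`` interpolates beta_start..beta_end;
    ``cosine`` derives beta from the squared-cosine abar curve."""
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    if kind == "linear":
        beta = np.linspace(beta_start, beta_end, T)
    elif kind == "cosine":
        s = 0.008
        steps = np.arange(T + 1)
        f = np.cos((steps / T + s) / (1 + s) * np.pi / 2) ** 2
        abar = f / f[0]
        beta = np.clip(1 - abar[1:] / abar[:-1], 1e-8, 0.999)
    else:
        raise ValidationError(f"unknown schedule kind '{kind}'")
    alpha = 1.0 - beta
    schedule = DiffusionSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))
    schedule.validate()
    return schedule


@dataclass(frozen=True)
class NoiseQuery:
    """One forward-noising request: original vector, timestep, noise draw."""

    x0: np.ndarray
    t: int
    eps: np.ndarray


def forward_noise(q: NoiseQuery, s: DiffusionSchedule) -> np.ndarray:
    """Closed-form forward sample x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""
    if not 1 <= q.t <= s.T:
        raise IndexError(f"timestep t={q.t} outside [1, {s.T}]")
    ab = s.alpha_bar[q.t - 1]
    return np.sqrt(ab) * np.asarray(q.x0) + np.sqrt(1 - ab) * np.asarray(q.eps)


@dataclass(frozen=True)
class CategoricalSpec:
    """A K-category distribution (one-hot or already-diffused probabilities)."""

    K: int
    probs: np.ndarray

    def validate(self):
        if self.K < 2:
            raise ValidationError(f"K must be >= 2, got {self.K}")
        p = np.asarray(self.probs)
        if p.shape[-1] != self.K or np.any(p < 0) or not np.allclose(p.sum(-1), 1):
            raise ValidationError("probs must be a length-K probability vector")


def multinomial_forward(c: CategoricalSpec, t: int, s: DiffusionSchedule) -> np.ndarray:
    """One multinomial forward transition: (1-beta_t) p + beta_t / K."""
    c.validate()
    if not 1 <= t <= s.T:
        raise IndexError(f"timestep t={t} outside [1, {s.T}]")
    beta = s.beta[t - 1]
    return (1 - beta) * np.asarray(c.probs, dtype=np.float64) + beta / c.K


@dataclass(frozen=True)
class ConstraintSet:
    """Positivity on the selected indicators + the dairy mass balance."""

    positive_features: tuple = tuple(INFORMATIVE_FEATURES)
    mass_balance_tol: float = 0.5

    def validate(self):
        if self.mass_balance_tol <= 0:
            raise ValidationError(
                f"mass_balance_tol must be > 0, got {self.mass_balance_tol}"
            )


def check_constraints(records, constraints: ConstraintSet | None = None):
    """Vectorized constraint check.

    Accepts a DataFrame (returns a boolean Series) or a Series/dict for a
    single record (returns bool). True iff every selected feature is
    strictly positive and |TS - (Fat + SNF)| <= tolerance.
    """
    constraints = constraints or ConstraintSet()
    constraints.validate()
    single = not isinstance(records, pd.DataFrame)
    frame = pd.DataFrame([records]) if single else records
    needed = set(constraints.positive_features) | {"TS", "Fat", "SNF"}
    missing = sorted(needed - set(frame.columns))
    if missing:
        raise SchemaError(f"constraint check missing column(s): {', '.join(missing)}")
    ok = np.ones(len(frame), dtype=bool)
    for col in constraints.positive_features:
        ok &= frame[col].to_numpy(dtype=np.float64) > 0
    resid = (
        frame["TS"].to_numpy(dtype=np.float64)
        - frame["Fat"].to_numpy(dtype=np.float64)
        - frame["SNF"].to_numpy(dtype=np.float64)
    )
    ok &= np.abs(resid) <= constraints.mass_balance_tol
    return bool(ok[0]) if single else pd.Series(ok, index=frame.index)


class TabularDiffusionGenerator(BaseEstimator):
    """Denoising diffusion generator for mixed continuous/categorical tables.

    Parameters mirror the training setup used for the milk cohort: 1000
    epochs, batch 256, AdamW at 1e-3 with cosine annealing, T=1000 linear
    beta schedule. Continuous columns are z-scored before diffusion and
    restored to native units on sampling; categorical columns (if any)
    travel through the multinomial process as one-hot blocks.
    """

    def __init__(self, T=1000, schedule="linear", beta_start=1e-4, beta_end=0.02,
                 epochs=1000, batch_size=256,
                 lr=1e-3, weight_decay=1e-4, hidden=(128, 128), t_embed_dim=16,
                 categorical_features=None, random_state=0):
        self.T = T
        self.schedule = schedule
        self.beta_start = beta_start
        self.beta_end = beta_end
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.hidden = hidden
        self.t_embed_dim = t_embed_dim
        self.categorical_features = categorical_features
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 2:
            raise ValidationError("diffusion training requires at least 2 records")
        cat_cols = list(self.categorical_features or [])
        cont_cols = [c for c in X.columns if c not in cat_cols]
        self.continuous_columns_ = cont_cols
        self.categorical_columns_ = cat_cols

        Xc = X[cont_cols].to_numpy(dtype=np.float64)
        self.mean_ = Xc.mean(axis=0)
        self.scale_ = np.where(Xc.std(axis=0) > 0, Xc.std(axis=0), 1.0)
        Xz = (Xc - self.mean_) / self.scale_

        self.categories_ = {}
        onehots = []
        for col in cat_cols:
            cats = np.unique(X[col].to_numpy())
            if len(cats) < 2:
                raise ValidationError(f"categorical feature '{col}' has < 2 categories")
            self.categories_[col] = cats
            codes = np.searchsorted(cats, X[col].to_numpy())
            oh = np.zeros((len(X), len(cats)))
            oh[np.arange(len(X)), codes] = 1.0
            onehots.append(oh)
        X0_cat = np.concatenate(onehots, axis=1) if onehots else np.zeros((len(X), 0))

        self.schedule_ = make_schedule(self.T, kind=self.schedule,
                                       beta_start=self.beta_start, beta_end=self.beta_end)
        d_cont = Xz.shape[1]
        d_cat = X0_cat.shape[1]
        d_in = d_cont + d_cat + self.t_embed_dim
        d_out = d_cont + d_cat
        rng = np.random.default_rng(self.random_state)
        self._net = MLP([d_in, *self.hidden, d_out], rng)
        opt = AdamW(self._net.params(), lr=self.lr, weight_decay=self.weight_decay)

        n = len(X)
        bs = min(self.batch_size, n)
        steps_per_epoch = max(n // bs, 1)
        total_steps = self.epochs * steps_per_epoch
        ab = self.schedule_.alpha_bar
        cat_sizes = [len(self.categories_[c]) for c in cat_cols]
        cat_offsets = np.concatenate([[0], np.cumsum(cat_sizes)]).astype(int)

        self.loss_history_ = []
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s0 in range(0, steps_per_epoch * bs, bs):
                idx = order[s0 : s0 + bs]
                t = rng.integers(1, self.T + 1, size=len(idx))
                abt = ab[t - 1][:, None]
                eps = rng.standard_normal((len(idx), d_cont))
                xt = np.sqrt(abt) * Xz[idx] + np.sqrt(1 - abt) * eps

                if d_cat:
                    # q(x_t | x_0) = abar_t one_hot + (1 - abar_t)/K per block
                    xt_cat = np.zeros((len(idx), d_cat))
                    for b, col in enumerate(cat_cols):
                        K = cat_sizes[b]
                        sl = slice(cat_offsets[b], cat_offsets[b + 1])
                        probs = abt * X0_cat[idx][:, sl] + (1 - abt) / K
                        probs /= probs.sum(axis=1, keepdims=True)
                        cum = np.cumsum(probs, axis=1)
                        draws = (rng.random((len(idx), 1)) < cum).argmax(axis=1)
                        xt_cat[np.arange(len(idx)), sl.start + draws] = 1.0
                    net_in = np.concatenate(
                        [xt, xt_cat, timestep_embedding(t, self.t_embed_dim)], axis=1
                    )
                else:
                    net_in = np.concatenate(
                        [xt, timestep_embedding(t, self.t_embed_dim)], axis=1
                    )

                out = self._net(Tensor(net_in))
                loss = ((out[:, :d_cont] - Tensor(eps)) ** 2).mean() if d_cont else None
                if d_cat:
                    for b, col in enumerate(cat_cols):
                        sl = slice(d_cont + cat_offsets[b], d_cont + cat_offsets[b + 1])
                        ce = softmax_cross_entropy(out[:, sl], X0_cat[idx][:, cat_offsets[b]:cat_offsets[b + 1]])
                        loss = ce if loss is None else loss + ce
                if not np.isfinite(loss.data):
                    raise TrainingError("diffusion loss became non-finite", epoch=epoch)
                opt.zero_grad()
                loss.backward()
                opt.lr = cosine_lr(self.lr, step, total_steps)
                opt.step()
                step += 1
                epoch_loss += float(loss.data)
            self.loss_history_.append(epoch_loss / steps_per_epoch)
        self.n_features_in_ = len(X.columns)
        return self

    # ------------------------------------------------------------------
    def _reverse_sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Ancestral reverse diffusion for ``n`` candidate records."""
        sch = self.schedule_
        cont_cols, cat_cols = self.continuous_columns_, self.categorical_columns_
        d_cont = len(cont_cols)
        cat_sizes = [len(self.categories_[c]) for c in cat_cols]
        cat_offsets = np.concatenate([[0], np.cumsum(cat_sizes)]).astype(int)
        d_cat = int(sum(cat_sizes))

        x = rng.standard_normal((n, d_cont))
        xcat = np.zeros((n, d_cat))
        for b in range(len(cat_cols)):
            K = cat_sizes[b]
            draws = rng.integers(0, K, size=n)
            xcat[np.arange(n), cat_offsets[b] + draws] = 1.0

        for t in range(sch.T, 0, -1):
            emb = timestep_embedding(np.full(n, t), self.t_embed_dim)
            net_in = np.concatenate([x, xcat, emb], axis=1) if d_cat else np.concatenate([x, emb], axis=1)
            with no_grad():
                out = self._net(Tensor(net_in)).data
            eps_hat = out[:, :d_cont]
            beta = sch.beta[t - 1]
            alpha = sch.alpha[t - 1]
            abar = sch.alpha_bar[t - 1]
            mean = (x - beta / np.sqrt(1 - abar) * eps_hat) / np.sqrt(alpha)
            if t > 1:
                abar_prev = sch.alpha_bar[t - 2]
                sigma = np.sqrt(beta * (1 - abar_prev) / (1 - abar))
                x = mean + sigma * rng.standard_normal((n, d_cont))
            else:
                x = mean
            if d_cat:
                abar_prev = sch.alpha_bar[t - 2] if t > 1 else 1.0
                for b in range(len(cat_cols)):
                    K = cat_sizes[b]
                    sl = slice(cat_offsets[b], cat_offsets[b + 1])
                    logits = out[:, d_cont + cat_offsets[b] : d_cont + cat_offsets[b + 1]]
                    z = logits - logits.max(axis=1, keepdims=True)
                    p0 = np.exp(z)
                    p0 /= p0.sum(axis=1, keepdims=True)
                    # exact reverse kernel: mixture over x0 categories of the
                    # per-category posteriors (plugging the mean x0
                    # distribution inside the product biases toward uniform)
                    like = alpha * xcat[:, sl] + (1 - alpha) / K
                    post = np.zeros((n, K))
                    for c in range(K):
                        prior_c = abar_prev * np.eye(K)[c] + (1 - abar_prev) / K
                        theta = like * prior_c[None, :]
                        theta /= theta.sum(axis=1, keepdims=True)
                        post += p0[:, c : c + 1] * theta
                    cum = np.cumsum(post, axis=1)
                    draws = (rng.random((n, 1)) < cum).argmax(axis=1)
                    new_block = np.zeros((n, K))
                    new_block[np.arange(n), draws] = 1.0
                    xcat[:, sl] = new_block

        frame = pd.DataFrame(x * self.scale_ + self.mean_, columns=cont_cols)
        for b, col in enumerate(cat_cols):
            codes = xcat[:, cat_offsets[b] : cat_offsets[b + 1]].argmax(axis=1)
            frame[col] = self.categories_[col][codes]
        return frame

    def sample(self, n_target: int, constraints: ConstraintSet | None = None,
               random_state: int | None = None, max_attempts_factor: int = 100) -> pd.DataFrame:
        """Generate exactly ``n_target`` records satisfying the constraints.

        Candidates are drawn by reverse diffusion in batches and filtered
        through :func:`check_constraints`; rejected candidates are simply
        regenerated. Raises :class:`GenerationError` with per-constraint
        violation frequencies if the attempt budget is exhausted. Records
        the overall ``acceptance_rate_``.
        """
        if n_target < 1:
            raise ValidationError(f"n_target must be >= 1, got {n_target}")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        max_attempts = max_attempts_factor * n_target
        accepted, attempts = [], 0
        n_ok = 0
        viol = {"positivity": 0, "mass_balance": 0}
        cset = constraints or ConstraintSet()
        can_check = {"TS", "Fat", "SNF"} <= set(
            self.continuous_columns_ + self.categorical_columns_
        )

        while n_ok < n_target:
            batch_n = min(max(n_target - n_ok, 64), 4096)
            if attempts + batch_n > max_attempts:
                batch_n = max_attempts - attempts
                if batch_n <= 0:
                    raise GenerationError(
                        f"acceptance rate too low: {n_ok}/{attempts} accepted "
                        f"within {max_attempts} attempts",
                        violation_freq={k: v / max(attempts, 1) for k, v in viol.items()},
                    )
            batch = self._reverse_sample(batch_n, rng)
            attempts += batch_n
            if can_check:
                pos_ok = np.ones(len(batch), dtype=bool)
                for col in cset.positive_features:
                    if col in batch.columns:
                        pos_ok &= batch[col].to_numpy(dtype=np.float64) > 0
                resid = np.abs(
                    batch["TS"].to_numpy(dtype=np.float64)
                    - batch["Fat"].to_numpy(dtype=np.float64)
                    - batch["SNF"].to_numpy(dtype=np.float64)
                )
                mb_ok = resid <= cset.mass_balance_tol
                viol["positivity"] += int((~pos_ok).sum())
                viol["mass_balance"] += int((~mb_ok).sum())
                batch = batch[pos_ok & mb_ok]
            accepted.append(batch)
            n_ok += len(batch)

        self.acceptance_rate_ = n_ok / attempts
        self.violation_freq_ = {k: v / attempts for k, v in viol.items()}
        out = pd.concat(accepted, ignore_index=True).iloc[:n_target]
        return out.reset_index(drop=True)


def marginal_fidelity(generated: pd.DataFrame, real: pd.DataFrame,
                      n_bins: int = 50) -> pd.DataFrame:
    """Per-feature distributional agreement between generated and real data.

    Reports the histogram overlap coefficient (shared bins over the
    combined range; 1 = identical, 0 = disjoint) and the two-sample
    Kolmogorov-Smirnov distance for every column present in both tables.
    """
    if len(generated) == 0 or len(real) == 0:
        raise ValidationError("marginal_fidelity requires non-empty tables")
    shared = [c for c in real.columns if c in generated.columns]
    if not shared:
        raise ValidationError("tables share no columns")
    rows = {}
    for col in shared:
        g = generated[col].to_numpy(dtype=np.float64)
        r = real[col].to_numpy(dtype=np.float64)
        lo = min(g.min(), r.min())
        hi = max(g.max(), r.max())
        if hi == lo:
            hi = lo + 1e-12
        bins = np.linspace(lo, hi, n_bins + 1)
        pg, _ = np.histogram(g, bins=bins)
        pr, _ = np.histogram(r, bins=bins)
        overlap = np.minimum(pg / len(g), pr / len(r)).sum()
        ks = ks_2samp(g, r).statistic
        rows[col] = {"overlap": overlap, "ks_distance": ks}
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class AugmentationRecipe:
    """Augmented-set composition: each real positive appears twice (original
    + duplicate), ``gen_per_real`` generated positives per real one, and
    ``neg_per_pos`` negatives per total positive."""

    duplicate_real: bool = True
    gen_per_real: int = 4
    neg_per_pos: int = 3
    seed: int = 0


@dataclass
class AugmentedDataset:
    """The composed training table plus its bookkeeping counts."""

    n_real_pos: int
    n_dup_pos: int
    n_gen_pos: int
    n_neg: int
    records: pd.DataFrame

    @property
    def n_pos_total(self) -> int:
        return self.n_real_pos + self.n_dup_pos + self.n_gen_pos

    def __len__(self):
        return len(self.records)


def compose_augmented(real_pos: pd.DataFrame, generated_pos: pd.DataFrame,
                      negatives: pd.DataFrame,
                      recipe: AugmentationRecipe | None = None) -> AugmentedDataset:
    """Assemble the augmented training set.

    With the default recipe (duplicate reals, 4 generated per real, 3
    negatives per positive), 842 real positives and 3368 generated ones
    compose to 5052 positives and 15156 negatives. Raises
    :class:`CompositionError` when the generated count does not match the
    recipe or too few negatives are available. Rows are shuffled with the
    recipe seed; a ``source`` column tracks provenance.
    """
    recipe = recipe or AugmentationRecipe()
    n_real = len(real_pos)
    expected_gen = recipe.gen_per_real * n_real
    if len(generated_pos) != expected_gen:
        raise CompositionError(
            f"recipe expects {expected_gen} generated positives "
            f"({recipe.gen_per_real} per real), got {len(generated_pos)}"
        )
    n_dup = n_real if recipe.duplicate_real else 0
    n_pos_total = n_real + n_dup + expected_gen
    n_neg = recipe.neg_per_pos * n_pos_total
    if len(negatives) < n_neg:
        raise CompositionError(
            f"need {n_neg} negatives ({recipe.neg_per_pos} per positive), "
            f"only {len(negatives)} available"
        )

    feat_cols = [c for c in real_pos.columns if c != LABEL_COLUMN]
    rng = np.random.default_rng(recipe.seed)

    def block(frame, source, label):
        b = frame[feat_cols].copy().reset_index(drop=True)
        b.insert(0, LABEL_COLUMN, label)
        b["source"] = source
        return b

    pieces = [block(real_pos, "real", 1)]
    if recipe.duplicate_real:
        pieces.append(block(real_pos, "duplicate", 1))
    pieces.append(block(generated_pos, "generated", 1))
    neg_idx = rng.choice(len(negatives), size=n_neg, replace=False)
    pieces.append(block(negatives.iloc[neg_idx], "negative", 0))

    records = pd.concat(pieces, ignore_index=True)
    records = records.iloc[rng.permutation(len(records))].reset_index(drop=True)
    return AugmentedDataset(
        n_real_pos=n_real, n_dup_pos=n_dup, n_gen_pos=expected_gen,
        n_neg=n_neg, records=records,
    )
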