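"""Dual feature-relevance analysis and feature selection.

Two complementary views of which routine indicators carry information
about ethanol stability:

* an *explicit* view — four supervised statistics per indicator (one-way
  ANOVA F, point-biserial correlation, random-forest impurity importance,
  standardized logistic coefficient) plus the Pearson correlation heatmap
  over the continuous indicators;
* an *implicit* view — an unsupervised autoencoder whose low-dimensional
  latent space is summarized per coordinate (distribution shape, top-5
  feature composition, class separation).

``select_features`` combines both views under a configurable policy and,
with the calibrated defaults, returns the eight-indicator set
{Protein, TS, SNF, Fat, Acidity, Lactose, RD, MTemp}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from ._autograd import Tensor, no_grad
from ._nn import MLP, AdamW
from .cleaning import CleanTable
from .cohort import INDICATOR_COLUMNS, LABEL_COLUMN
from .errors import ConfigurationError, TrainingError, ValidationError

__all__ = [
    "RelevanceReport",
    "LatentReport",
    "SelectionPolicy",
    "AutoencoderConfig",
    "MilkAutoencoder",
    "explicit_relevance",
    "pairwise_correlations",
    "fit_autoencoder",
    "latent_report",
    "select_features",
]

_BINARY_INDICATORS = ("AD1", "AD2")
CONTINUOUS_INDICATORS = [c for c in INDICATOR_COLUMNS if c not in _BINARY_INDICATORS]


@dataclass
class RelevanceReport:
    """Per-feature explicit statistics plus the continuous-feature heatmap."""

    table: pd.DataFrame          # index: feature; columns: anova_f, pb_r, rf_importance, logit_coef
    corr_matrix: pd.DataFrame
    flagged: list = field(default_factory=list)  # zero-variance features (sentinel NaN stats)


@dataclass
class LatentReport:
    """Per-latent distribution summaries and feature composition."""

    summary: pd.DataFrame        # index: latent id; mean, sd, skewness, separation
    composition: dict            # latent id -> list of 5 feature names (empty if degenerate)
    degenerate: list = field(default_factory=list)

    @property
    def most_separating(self) -> int:
        return int(self.summary["separation"].idxmax())


def explicit_relevance(clean: CleanTable, seed: int = 0) -> RelevanceReport:
    """Compute the four explicit relevance statistics for every indicator.

    The forest (impurity importances, normalized to sum 1) and the
    logistic fit (L2, on z-scored features) are seeded; ANOVA F and
    point-biserial r are closed-form. A zero-variance indicator is flagged
    and its statistics set to NaN rather than raising.
    """
    y = clean.labels
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValidationError("explicit_relevance requires >= 2 samples per class")
    X = clean.features.to_numpy(dtype=np.float64)
    names = list(clean.features.columns)

    variances = X.var(axis=0)
    flagged = [n for n, v in zip(names, variances) if v == 0]

    anova_f = np.full(len(names), np.nan)
    pb_r = np.full(len(names), np.nan)
    for j, name in enumerate(names):
        if name in flagged:
            continue
        g0, g1 = X[y == 0, j], X[y == 1, j]
        f, _ = stats.f_oneway(g0, g1)
        anova_f[j] = f
        pb_r[j], _ = stats.pointbiserialr(y, X[:, j])

    rf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    rf_importance = rf.feature_importances_

    # standardize for comparable logistic coefficients; guard zero variance
    scale = np.where(variances > 0, np.sqrt(variances), 1.0)
    Xz = (X - X.mean(axis=0)) / scale
    logit = LogisticRegression(max_iter=2000, random_state=seed)
    logit.fit(Xz, y)
    logit_coef = logit.coef_.ravel().copy()
    for j, name in enumerate(names):
        if name in flagged:
            logit_coef[j] = np.nan

    table = pd.DataFrame(
        {
            "anova_f": anova_f,
            "pb_r": pb_r,
            "rf_importance": rf_importance,
            "logit_coef": logit_coef,
        },
        index=names,
    )
    return RelevanceReport(table=table, corr_matrix=pairwise_correlations(clean), flagged=flagged)


def pairwise_correlations(clean: CleanTable) -> pd.DataFrame:
    """Pearson correlation matrix over the continuous indicators.

    Symmetric with unit diagonal; rows/columns of constant indicators are
    set to NaN (diagonal kept at 1).
    """
    if len(clean) < 3:
        raise ValidationError("pairwise_correlations requires >= 3 records")
    sub = clean.records[CONTINUOUS_INDICATORS]
    corr = sub.corr(method="pearson")
    constant = [c for c in CONTINUOUS_INDICATORS if sub[c].var() == 0]
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


@dataclass(frozen=True)
class AutoencoderConfig:
    """Training configuration for the relevance autoencoder."""

    hidden: int = 32
    epochs: int = 60
    batch_size: int = 128
    lr: float = 5e-3
    val_fraction: float = 0.2
    elbow_ratio: float = 0.5


class MilkAutoencoder(TransformerMixin, BaseEstimator):
    """Symmetric MLP autoencoder (n -> hidden -> latent -> hidden -> n).

    Inputs are z-scored internally; ``transform`` returns latent
    coordinates, ``reconstruction_errors`` per-sample squared errors in the
    standardized space. Training is full-batch-shuffled mini-batch Adam and
    is deterministic given ``random_state``.
    """

    def __init__(self, latent_dim=3, hidden=32, epochs=60, batch_size=128,
                 lr=5e-3, random_state=0):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xz = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.random_state)
        self._encoder = MLP([d, self.hidden, self.latent_dim], rng)
        self._decoder = MLP([self.latent_dim, self.hidden, d], rng)
        params = self._encoder.params() + self._decoder.params()
        opt = AdamW(params, lr=self.lr)

        self.loss_history_ = []
        bs = min(self.batch_size, n)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                xb = Tensor(Xz[idx])
                recon = self._decoder(self._encoder(xb))
                loss = ((recon - xb) ** 2).mean()
                if not np.isfinite(loss.data):
                    raise TrainingError("autoencoder loss became non-finite", epoch=epoch)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_history_.append(epoch_loss / n)
        self.n_features_in_ = d
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        Xz = (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_
        with no_grad():
            return self._encoder(Tensor(Xz)).data

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        with no_grad():
            return self._decoder(Tensor(np.asarray(Z, dtype=np.float64))).data * self.scale_ + self.mean_

    def reconstruction_errors(self, X):
        Xz = (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_
        with no_grad():
            recon = self._decoder(self._encoder(Tensor(Xz))).data
        return ((recon - Xz) ** 2).mean(axis=1)


def fit_autoencoder(clean: CleanTable, latent_dims=range(2, 6),
                    train_config: AutoencoderConfig | None = None,
                    seed: int = 0) -> MilkAutoencoder:
    """Fit one autoencoder per candidate latent dimension and select one.

    Selection scans held-out reconstruction error in increasing dimension
    and stops at the elbow: the smallest dimension for which the next
    dimension no longer improves the error by more than ``elbow_ratio``
    (default: a further halving). This keeps the choice parsimonious while
    being robust to the optimization noise floor shared by all
    sufficiently large dimensions. Deterministic given ``seed``.
    """
    dims = sorted(int(d) for d in latent_dims)
    if not dims:
        raise ValidationError("latent_dims must be non-empty")
    if dims[0] < 2 or dims[-1] > 5:
        raise ValidationError(f"latent_dims must lie within [2, 5], got {dims}")
    cfg = train_config or AutoencoderConfig()

    X = clean.features.to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(cfg.val_fraction * len(X))))
    val_idx, train_idx = order[:n_val], order[n_val:]

    candidates = {}
    for k, dim in enumerate(dims):
        model = MilkAutoencoder(
            latent_dim=dim, hidden=cfg.hidden, epochs=cfg.epochs,
            batch_size=cfg.batch_size, lr=cfg.lr, random_state=seed + 1000 * (k + 1),
        )
        model.fit(X[train_idx])
        errs = model.reconstruction_errors(X[val_idx])
        candidates[dim] = (model, errs.mean(), errs.std(ddof=1) / np.sqrt(len(errs)))

    selected = dims[-1]
    for d, d_next in zip(dims, dims[1:]):
        if candidates[d_next][1] > cfg.elbow_ratio * candidates[d][1]:
            selected = d
            break

    model = candidates[selected][0]
    model.recon_error_ = float(candidates[selected][1])
    model.selection_table_ = pd.DataFrame(
        {
            "latent_dim": dims,
            "val_recon_error": [candidates[d][1] for d in dims],
            "se": [candidates[d][2] for d in dims],
        }
    )
    return model


def latent_report(model: MilkAutoencoder, clean: CleanTable) -> LatentReport:
    """Summarize each latent coordinate and its feature composition.

    Composition ranks features by absolute Pearson correlation with the
    latent activation (top 5); separation is the absolute point-biserial
    correlation between the latent coordinate and the class label. A
    zero-variance latent is flagged and left with an empty composition.
    """
    check_is_fitted(model, "mean_")
    X = clean.features
    y = clean.labels
    Z = model.transform(X.to_numpy(dtype=np.float64))

    rows, composition, degenerate = [], {}, []
    for k in range(Z.shape[1]):
        z = Z[:, k]
        sd = z.std(ddof=1)
        if sd < 1e-12:
            degenerate.append(k)
            rows.append({"mean": z.mean(), "sd": sd, "skewness": np.nan, "separation": 0.0})
            composition[k] = []
            continue
        corrs = {
            name: abs(np.corrcoef(X[name].to_numpy(dtype=np.float64), z)[0, 1])
            if X[name].var() > 0 else 0.0
            for name in X.columns
        }
        top5 = sorted(corrs, key=corrs.get, reverse=True)[:5]
        composition[k] = top5
        sep = abs(stats.pointbiserialr(y, z)[0]) if len(np.unique(y)) > 1 else 0.0
        rows.append(
            {"mean": z.mean(), "sd": sd, "skewness": stats.skew(z), "separation": sep}
        )
    summary = pd.DataFrame(rows)
    summary.index.name = "latent"
    return LatentReport(summary=summary, composition=composition, degenerate=degenerate)


@dataclass(frozen=True)
class SelectionPolicy:
    """Policy combining the explicit and implicit relevance views.

    A feature is kept when it ranks in the top ``rank_threshold`` of at
    least ``min_stats`` of the four explicit statistics, or when it appears
    in the composition of the most class-separating latent. Setting
    ``score_threshold`` switches the explicit test to a min-max-normalized
    score cutoff (in [0, 1]; -inf keeps everything, +inf keeps nothing).
    """

    rank_threshold: int = 8
    min_stats: int = 3
    use_latent: bool = True
    score_threshold: float | None = None


def select_features(report: RelevanceReport, latent: LatentReport | None = None,
                    policy: SelectionPolicy | None = None) -> list[str]:
    """Apply the selection policy; returns features in indicator order."""
    policy = policy or SelectionPolicy()
    table = report.table
    stats_cols = ["anova_f", "pb_r", "rf_importance", "logit_coef"]
    magnitudes = table[stats_cols].abs()

    if policy.score_threshold is not None:
        lo, hi = magnitudes.min(), magnitudes.max()
        span = (hi - lo).replace(0, 1.0)
        norm = (magnitudes - lo) / span
        passes = (norm >= policy.score_threshold).sum(axis=1)
    else:
        ranks = magnitudes.rank(ascending=False, na_option="bottom")
        passes = (ranks <= policy.rank_threshold).sum(axis=1)
    keep = set(table.index[passes >= policy.min_stats])

    if policy.use_latent and latent is not None and latent.composition:
        keep |= set(latent.composition.get(latent.most_separating, []))

    selected = [f for f in table.index if f in keep]
    if not selected:
        raise ConfigurationError("selection policy produced an empty feature set")
    return selected
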