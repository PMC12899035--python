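"""Seeded synthetic milk-intake cohorts.

The industrial intake data this pipeline was designed for are confidential,
so this module generates cohorts with the same statistical structure: 15
routine physicochemical indicators plus a binary ethanol-stability label
(1 = unstable/"positive"). Eight indicators (Protein, TS, SNF, Fat,
Acidity, Lactose, RD, MTemp) carry class-conditional mean shifts; the
remaining seven (TVC, SCC, Psychro, FP, Color, AD1, AD2) are uninformative
noise. Total solids are generated structurally as ``TS = Fat + SNF +
N(0, mass_balance_sd)`` with the Fat–SNF correlation solved so that the
sample Pearson correlation between Fat and TS hits a configurable target
(0.92 by default); the dairy mass-balance identity and the strong Fat–TS
correlation thus emerge from a single mechanism.

Class prevalence is exact by construction: the number of unstable records
is ``round(n_records * prevalence)``, not a binomial draw, so dataset
composition targets are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError

__all__ = [
    "LABEL_COLUMN",
    "INDICATOR_COLUMNS",
    "INFORMATIVE_FEATURES",
    "CURATED_PREVALENCE",
    "CLEANED_PREVALENCE",
    "PRODUCTION_PREVALENCE",
    "FeatureProfile",
    "CohortSpec",
    "MessinessSpec",
    "default_profiles",
    "default_cohort_spec",
    "generate_cohort",
    "inject_messiness",
]

LABEL_COLUMN = "ES"
INDICATOR_COLUMNS = [
    "TVC", "Protein", "TS", "SNF", "Fat", "Acidity", "FP", "SCC",
    "Psychro", "Lactose", "RD", "MTemp", "Color", "AD1", "AD2",
]
INFORMATIVE_FEATURES = ["Protein", "TS", "SNF", "Fat", "Acidity", "Lactose", "RD", "MTemp"]

# prevalence regimes: curated 1:4, cleaned ~1:63, production ~0.09%
CURATED_PREVALENCE = 0.2
CLEANED_PREVALENCE = 1.0 / 64.0
PRODUCTION_PREVALENCE = 0.000928


@dataclass(frozen=True)
class FeatureProfile:
    """Marginal description of one indicator.

    For ``kind="binary"`` the means are success probabilities; ``sd`` is
    ignored for sampling but must still be positive. ``clip_zero`` truncates
    draws at zero (used for count-type indicators).
    """

    name: str
    mean_neg: float
    mean_pos: float
    sd: float
    informative: bool
    kind: str = "continuous"
    clip_zero: bool = False

    def validate(self):
        if self.sd <= 0:
            raise ValidationError(f"profile '{self.name}': sd must be > 0, got {self.sd}")
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValidationError(f"profile '{self.name}': unknown kind '{self.kind}'")
        if not self.informative and self.mean_neg != self.mean_pos:
            raise ValidationError(
                f"profile '{self.name}': uninformative features must have mean_neg == mean_pos"
            )
        if self.kind == "binary" and not (0 <= self.mean_neg <= 1 and 0 <= self.mean_pos <= 1):
            raise ValidationError(f"profile '{self.name}': binary means must lie in [0, 1]")


def default_profiles(effect_scale: float = 2.0) -> list[FeatureProfile]:
    """Calibrated default marginals in native units (composition in g/100 g).

    Negative-class means sit at typical bovine-milk values; unstable
    records are shifted on the eight informative indicators by
    ``effect_scale`` standard deviations (sign chosen per indicator:
    unstable milk runs lower in protein, solids, lactose, density and
    acidity, and arrives warmer). The default scale of 2.0 puts the
    two-class Mahalanobis separation near 5, i.e. a per-class Bayes error
    well under 1%, so a well-trained classifier can reach >90% recall.
    TS means are derived from Fat + SNF; the generator draws TS
    structurally and ignores the TS profile's moments.
    """

    def cont(name, mean, sd, shift_sds, clip_zero=False):
        return FeatureProfile(
            name=name,
            mean_neg=mean,
            mean_pos=mean + shift_sds * effect_scale * sd,
            sd=sd,
            informative=shift_sds != 0,
            clip_zero=clip_zero,
        )

    fat = cont("Fat", 3.90, 0.35, -1.0)
    snf = cont("SNF", 8.70, 0.25, -1.0)
    ts = FeatureProfile(
        name="TS",
        mean_neg=fat.mean_neg + snf.mean_neg,
        mean_pos=fat.mean_pos + snf.mean_pos,
        sd=0.43,
        informative=True,
    )
    return [
        cont("TVC", 50.0, 15.0, 0.0, clip_zero=True),        # 10^3 CFU/mL
        cont("Protein", 3.25, 0.15, -1.0),                   # g/100 g
        ts,                                                  # g/100 g, structural
        snf,                                                 # g/100 g
        fat,                                                 # g/100 g
        cont("Acidity", 13.0, 0.8, -1.0),                    # °T
        cont("FP", -0.525, 0.006, 0.0),                      # °C
        cont("SCC", 250.0, 80.0, 0.0, clip_zero=True),       # 10^3 cells/mL
        cont("Psychro", 20.0, 8.0, 0.0, clip_zero=True),     # 10^3 CFU/mL
        cont("Lactose", 4.60, 0.15, -1.0),                   # g/100 g
        cont("RD", 1.030, 0.0015, -1.0),                     # dimensionless
        cont("MTemp", 6.0, 1.2, +1.0),                       # °C
        cont("Color", 80.0, 5.0, 0.0),                       # vision score
        FeatureProfile("AD1", 0.02, 0.02, 1.0, False, kind="binary"),
        FeatureProfile("AD2", 0.02, 0.02, 1.0, False, kind="binary"),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort."""

    n_records: int
    prevalence: float
    profiles: list[FeatureProfile] = field(default_factory=default_profiles)
    fat_ts_target_r: float = 0.92
    mass_balance_sd: float = 0.05
    seed: int = 0

    def validate(self):
        if self.n_records < 1:
            raise ValidationError(f"n_records must be >= 1, got {self.n_records}")
        if not 0 < self.prevalence < 1:
            raise ValidationError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not -1 < self.fat_ts_target_r < 1:
            raise ValidationError(
                f"fat_ts_target_r must be in (-1, 1), got {self.fat_ts_target_r}"
            )
        if self.mass_balance_sd < 0:
            raise ValidationError(
                f"mass_balance_sd must be >= 0, got {self.mass_balance_sd}"
            )
        names = [p.name for p in self.profiles]
        if sorted(names) != sorted(INDICATOR_COLUMNS):
            missing = set(INDICATOR_COLUMNS) - set(names)
            raise ValidationError(f"profiles: missing or unexpected indicators ({missing or set(names) - set(INDICATOR_COLUMNS)})")
        for p in self.profiles:
            p.validate()
        if round(self.n_records * self.prevalence) < 1:
            raise ValidationError(
                "prevalence: round(n_records * prevalence) must be >= 1"
            )

    def n_positive(self) -> int:
        return int(round(self.n_records * self.prevalence))


def default_cohort_spec(
    n_records: int = 13_440,
    prevalence: float = CLEANED_PREVALENCE,
    seed: int = 0,
    effect_scale: float = 2.0,
) -> CohortSpec:
    """The calibrated default cohort (cleaned-regime prevalence 1:63)."""
    return CohortSpec(
        n_records=n_records,
        prevalence=prevalence,
        profiles=default_profiles(effect_scale),
        seed=seed,
    )


@dataclass(frozen=True)
class MessinessSpec:
    """Raw-export corruption: nulls, non-numeric junk, text labels."""

    null_rate: float = 0.0
    junk_rate: float = 0.0
    label_as_text: bool = False

    def validate(self):
        for name in ("null_rate", "junk_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.null_rate + self.junk_rate > 1:
            raise ValidationError("null_rate + junk_rate must not exceed 1")


def _solve_fat_snf_corr(fat_sd: float, snf_sd: float, mb_sd: float, target_r: float) -> float:
    """Fat–SNF correlation that yields the requested Fat–TS Pearson r."""

    def r_of(rho):
        var_ts = fat_sd ** 2 + snf_sd ** 2 + 2 * rho * fat_sd * snf_sd + mb_sd ** 2
        return (fat_sd + rho * snf_sd) / np.sqrt(var_ts)

    lo, hi = -0.999, 0.999
    if not r_of(lo) <= target_r <= r_of(hi):
        raise ValidationError(
            f"fat_ts_target_r={target_r} is unattainable with fat sd={fat_sd}, "
            f"snf sd={snf_sd}, mass_balance_sd={mb_sd}"
        )
    return brentq(lambda rho: r_of(rho) - target_r, lo, hi)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; deterministic given ``spec.seed``.

    Returns a DataFrame with the label column first, then the 15 indicators
    in their canonical intake order. Exactly ``round(n * prevalence)`` rows
    are labelled unstable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_pos = spec.n_positive()

    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_pos]] = 1
    pos = labels == 1

    prof = {p.name: p for p in spec.profiles}
    fat_p, snf_p = prof["Fat"], prof["SNF"]
    rho = _solve_fat_snf_corr(fat_p.sd, snf_p.sd, spec.mass_balance_sd, spec.fat_ts_target_r)
    cov = np.array(
        [
            [fat_p.sd ** 2, rho * fat_p.sd * snf_p.sd],
            [rho * fat_p.sd * snf_p.sd, snf_p.sd ** 2],
        ]
    )
    chol = np.linalg.cholesky(cov)

    data = {LABEL_COLUMN: labels}
    # Fat and SNF jointly, then TS structurally: one mechanism yields both
    # the mass-balance identity and the Fat-TS correlation target.
    z = rng.standard_normal((n, 2)) @ chol.T
    fat_mean = np.where(pos, fat_p.mean_pos, fat_p.mean_neg)
    snf_mean = np.where(pos, snf_p.mean_pos, snf_p.mean_neg)
    fat = fat_mean + z[:, 0]
    snf = snf_mean + z[:, 1]
    ts = fat + snf + rng.normal(0.0, spec.mass_balance_sd, size=n)

    for name in INDICATOR_COLUMNS:
        p = prof[name]
        if name == "Fat":
            data[name] = fat
        elif name == "SNF":
            data[name] = snf
        elif name == "TS":
            data[name] = ts
        elif p.kind == "binary":
            prob = np.where(pos, p.mean_pos, p.mean_neg)
            data[name] = (rng.random(n) < prob).astype(np.int64)
        else:
            mean = np.where(pos, p.mean_pos, p.mean_neg)
            x = rng.normal(mean, p.sd)
            if p.clip_zero:
                x = np.maximum(x, 0.0)
            data[name] = x

    return pd.DataFrame(data, columns=[LABEL_COLUMN] + INDICATOR_COLUMNS)


_JUNK_TOKENS = ["n/a", "ERR", "--", "<LOD", "pending", "??"]


def inject_messiness(table: pd.DataFrame, mess: MessinessSpec, seed: int = 0) -> pd.DataFrame:
    """Corrupt a clean numeric cohort the way raw intake exports arrive.

    A ``null_rate`` fraction of indicator cells is blanked, a ``junk_rate``
    fraction is replaced by syntactically non-numeric strings, and with
    ``label_as_text`` the label column is re-encoded as "positive" /
    "negative". The label itself is never nulled or junked.
    """
    mess.validate()
    rng = np.random.default_rng(seed)
    out = table.copy()
    if mess.null_rate == 0 and mess.junk_rate == 0 and not mess.label_as_text:
        return out

    out = out.astype(object)
    feat_cols = [c for c in out.columns if c != LABEL_COLUMN]
    u = rng.random((len(out), len(feat_cols)))
    for j, col in enumerate(feat_cols):
        col_vals = out[col].to_numpy(dtype=object)
        null_mask = u[:, j] < mess.null_rate
        junk_mask = (u[:, j] >= mess.null_rate) & (u[:, j] < mess.null_rate + mess.junk_rate)
        col_vals[null_mask] = np.nan
        if junk_mask.any():
            tokens = rng.integers(0, len(_JUNK_TOKENS), size=int(junk_mask.sum()))
            col_vals[junk_mask] = [_JUNK_TOKENS[k] for k in tokens]
        out[col] = col_vals
    if mess.label_as_text:
        out[LABEL_COLUMN] = np.where(
            table[LABEL_COLUMN].to_numpy() == 1, "positive", "negative"
        )
    return out
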