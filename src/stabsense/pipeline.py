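"""End-to-end orchestration: generate -> clean -> select -> augment -> train -> evaluate.

Every stage writes its artifacts (CSV/JSON) into the run directory as it
completes, and a JSON manifest records the seed, a hash of the
configuration, stage durations and library versions, so a run can be
audited and reproduced exactly. All stage seeds are derived from the
single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import tempfile
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from .cleaning import CleanTable, clean_table, write_clean_csv
from .cohort import (
    CLEANED_PREVALENCE,
    PRODUCTION_PREVALENCE,
    LABEL_COLUMN,
    CohortSpec,
    MessinessSpec,
    default_profiles,
    generate_cohort,
    inject_messiness,
)
from .diffusion import (
    AugmentationRecipe,
    ConstraintSet,
    TabularDiffusionGenerator,
    compose_augmented,
    marginal_fidelity,
)
from .errors import PipelineError, ValidationError
from .evaluation import EvalReport, evaluate
from .relevance import (
    AutoencoderConfig,
    explicit_relevance,
    fit_autoencoder,
    latent_report,
    select_features,
)
from .tabnet import TabNetClassifier, TabNetConfig

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one full soft-sensing run.

    The default cohort (13,440 records at 1:63 prevalence, effect scale
    2.0) is the package's scaled-down stand-in for the industrial
    three-year dataset; the default classifier settings are the tuned
    soft-sensor configuration.
    """

    seed: int = 0
    outdir: str | None = None
    n_records: int = 13_440
    prevalence: float = CLEANED_PREVALENCE
    effect_scale: float = 2.0
    messiness: MessinessSpec = field(
        default_factory=lambda: MessinessSpec(null_rate=0.01, junk_rate=0.003, label_as_text=True)
    )
    curated_neg_per_pos: int = 4
    latent_dims: tuple = (2, 3, 4, 5)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    diffusion_T: int = 1000
    diffusion_epochs: int = 1000
    diffusion_beta_end: float = 0.02
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    recipe: AugmentationRecipe = field(default_factory=AugmentationRecipe)
    tabnet: TabNetConfig = field(default_factory=TabNetConfig)
    production_n: int = 50_000
    production_prevalence: float = PRODUCTION_PREVALENCE
    production_reuse: bool = False

    def validate(self):
        if self.n_records < 100:
            raise ValidationError("n_records too small for a meaningful run")
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must be in (0, 1)")
        self.messiness.validate()
        self.tabnet.validate()

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "messiness" in kwargs:
            kwargs["messiness"] = MessinessSpec(**kwargs["messiness"])
        if "autoencoder" in kwargs:
            kwargs["autoencoder"] = AutoencoderConfig(**kwargs["autoencoder"])
        if "recipe" in kwargs:
            kwargs["recipe"] = AugmentationRecipe(**kwargs["recipe"])
        if "tabnet" in kwargs:
            kwargs["tabnet"] = TabNetConfig(**kwargs["tabnet"])
        if "constraints" in kwargs:
            c = kwargs["constraints"]
            c["positive_features"] = tuple(c.get("positive_features", ()))
            kwargs["constraints"] = ConstraintSet(**c)
        if "latent_dims" in kwargs:
            kwargs["latent_dims"] = tuple(kwargs["latent_dims"])
        return PipelineConfig(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["latent_dims"] = list(self.latent_dims)
        d["constraints"]["positive_features"] = list(self.constraints.positive_features)
        return d


def default_config(**overrides) -> PipelineConfig:
    return replace(PipelineConfig(), **overrides)


@dataclass
class PipelineResult:
    outdir: Path
    selected_features: list
    augmented: object
    fidelity: pd.DataFrame
    eval_test: EvalReport
    eval_production: EvalReport
    tabnet: TabNetClassifier
    diffusion: TabularDiffusionGenerator
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all six stages; deterministic given ``config.seed``.

    Raises :class:`PipelineError` naming the failing stage; artifacts of
    completed stages remain on disk.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else Path(tempfile.mkdtemp(prefix="stabsense_"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "versions": _versions(),
        "stages": {},
    }
    t_all = time.time()

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _write_manifest(outdir, manifest)
                    raise PipelineError(name, str(exc)) from exc
                manifest["stages"][name] = {"seconds": round(time.time() - self.t0, 3)}
                return False

        return _Stage()

    with stage("generate"):
        spec = CohortSpec(
            n_records=config.n_records,
            prevalence=config.prevalence,
            profiles=default_profiles(config.effect_scale),
            seed=seed,
        )
        cohort = generate_cohort(spec)
        raw = inject_messiness(cohort, config.messiness, seed=seed + 1)
        raw.to_csv(outdir / "cohort_raw.csv", index=False)

    with stage("clean"):
        clean = clean_table(raw)
        write_clean_csv(clean, outdir / "cohort_clean.csv")

    with stage("select"):
        rng = np.random.default_rng(seed + 10)
        pos_mask = clean.labels == 1
        pos_idx = np.flatnonzero(pos_mask)
        neg_idx = np.flatnonzero(~pos_mask)
        n_cur_neg = min(config.curated_neg_per_pos * len(pos_idx), len(neg_idx))
        cur_idx = np.concatenate([pos_idx, rng.choice(neg_idx, n_cur_neg, replace=False)])
        curated = CleanTable(clean.records.iloc[np.sort(cur_idx)].reset_index(drop=True))
        relevance = explicit_relevance(curated, seed=seed)
        ae = fit_autoencoder(curated, config.latent_dims, config.autoencoder, seed=seed)
        latents = latent_report(ae, curated)
        features = select_features(relevance, latents)
        relevance.table.to_csv(outdir / "relevance.csv")
        relevance.corr_matrix.to_csv(outdir / "correlations.csv")
        (outdir / "features.json").write_text(json.dumps(features, indent=2))

    with stage("augment"):
        pos_records = clean.records.loc[pos_mask, features].reset_index(drop=True)
        neg_records = clean.records.loc[~pos_mask, features].reset_index(drop=True)
        generator = TabularDiffusionGenerator(
            T=config.diffusion_T, epochs=config.diffusion_epochs,
            beta_end=config.diffusion_beta_end, random_state=seed + 2
        )
        generator.fit(pos_records)
        n_gen = config.recipe.gen_per_real * len(pos_records)
        generated = generator.sample(
            n_gen, constraints=config.constraints, random_state=seed + 3
        )
        fidelity = marginal_fidelity(generated, pos_records)
        augmented = compose_augmented(
            pos_records, generated, neg_records, replace(config.recipe, seed=seed + 4)
        )
        augmented.records.to_csv(outdir / "augmented.csv", index=False)
        fidelity.to_csv(outdir / "fidelity.csv")
        manifest["augmentation"] = {
            "n_real_pos": augmented.n_real_pos,
            "n_dup_pos": augmented.n_dup_pos,
            "n_gen_pos": augmented.n_gen_pos,
            "n_pos_total": augmented.n_pos_total,
            "n_neg": augmented.n_neg,
            "acceptance_rate": generator.acceptance_rate_,
        }

    with stage("train"):
        X = augmented.records[features].to_numpy(dtype=np.float64)
        y = augmented.records[LABEL_COLUMN].to_numpy(dtype=np.int64)
        # stratified 64/16/20 train/valid/test
        X_tmp, X_test, y_tmp, y_test = train_test_split(
            X, y, test_size=0.20, stratify=y, random_state=seed + 20
        )
        X_train, X_valid, y_train, y_valid = train_test_split(
            X_tmp, y_tmp, test_size=0.20, stratify=y_tmp, random_state=seed + 21
        )
        cfg = config.tabnet
        model = TabNetClassifier(
            n_d=cfg.n_d, n_a=cfg.n_a, n_steps=cfg.n_steps, gamma=cfg.gamma,
            reg_coef=cfg.reg_coef,
            lambda_sparse=cfg.lambda_sparse, learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
            patience=cfg.patience, random_state=seed + 22,
        )
        model.fit(X_train, y_train, X_valid=X_valid, y_valid=y_valid)
        model.save(outdir / "tabnet_checkpoint.npz")

    with stage("evaluate"):
        eval_test = evaluate(model, X_test, y_test, regime="curated_test")
        if config.production_reuse:
            # non-disjoint production-like mode: score the full cleaned
            # cohort, which shares rows with the training data
            Xp = clean.records[features].to_numpy(dtype=np.float64)
            yp = clean.labels
            eval_prod = evaluate(model, Xp, yp, regime="production_reuse")
        else:
            prod_spec = CohortSpec(
                n_records=config.production_n,
                prevalence=config.production_prevalence,
                profiles=default_profiles(config.effect_scale),
                seed=seed + 30,
            )
            prod = generate_cohort(prod_spec)
            eval_prod = evaluate(
                model,
                prod[features].to_numpy(dtype=np.float64),
                prod[LABEL_COLUMN].to_numpy(dtype=np.int64),
                regime="production",
            )
        (outdir / "eval_test.json").write_text(json.dumps(eval_test.to_dict(), indent=2))
        (outdir / "eval_production.json").write_text(json.dumps(eval_prod.to_dict(), indent=2))

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    _write_manifest(outdir, manifest)
    return PipelineResult(
        outdir=outdir,
        selected_features=features,
        augmented=augmented,
        fidelity=fidelity,
        eval_test=eval_test,
        eval_production=eval_prod,
        tabnet=model,
        diffusion=generator,
        manifest=manifest,
    )


def _versions() -> dict:
    import sklearn

    from . import __version__

    return {
        "stabsense": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
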