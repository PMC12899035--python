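"""Shared fixtures: small calibrated cohorts and a fast pipeline config."""

import numpy as np
import pandas as pd
import pytest

from stabsense.cleaning import CleanTable, clean_table
from stabsense.cohort import (
    INDICATOR_COLUMNS,
    LABEL_COLUMN,
    CohortSpec,
    default_cohort_spec,
    default_profiles,
    generate_cohort,
)
from stabsense.pipeline import PipelineConfig
from stabsense.relevance import AutoencoderConfig
from stabsense.tabnet import TabNetConfig


@pytest.fixture(scope="session")
def cohort_5k():
    """Calibrated cohort at n=5000, cleaned-regime prevalence."""
    return generate_cohort(default_cohort_spec(n_records=5000, seed=11))


@pytest.fixture(scope="session")
def curated_clean():
    """Curated-prevalence (1:4) clean table, the relevance-analysis setting."""
    spec = CohortSpec(n_records=2500, prevalence=0.2, profiles=default_profiles(), seed=7)
    return clean_table(generate_cohort(spec))


@pytest.fixture
def toy_raw_table():
    """10-row raw export: 2 rows with nulls, 1 row with junk in Fat."""
    rng = np.random.default_rng(3)
    frame = generate_cohort(default_cohort_spec(n_records=10, prevalence=0.2, seed=3)).astype(object)
    frame.loc[1, "Protein"] = np.nan
    frame.loc[4, "SCC"] = None
    frame.loc[7, "Fat"] = "n/a"
    return frame


def tiny_pipeline_config(outdir, seed=0, **overrides):
    """A scaled-down pipeline configuration that runs in a few seconds."""
    base = dict(
        seed=seed,
        outdir=str(outdir),
        n_records=3200,
        autoencoder=AutoencoderConfig(epochs=30),
        diffusion_T=200,
        diffusion_epochs=300,
        diffusion_beta_end=0.1,
        tabnet=TabNetConfig(max_epochs=15, patience=6),
        production_n=3000,
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture
def tiny_config(tmp_path):
    return tiny_pipeline_config(tmp_path / "run")
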