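import numpy as np
import pandas as pd
import pytest

from diffcorrnet import (
    PermutationConfig,
    SyntheticCohortSpec,
    classify,
    generate_cohort,
    preprocess,
)


def clean_spec(**kwargs) -> SyntheticCohortSpec:
    """Cohort spec with no censoring/missingness/outliers unless overridden."""
    defaults = dict(
        n_lod_metabolites=0,
        lod_fraction=0.0,
        missing_fraction=0.0,
        outlier_fraction=0.0,
    )
    defaults.update(kwargs)
    return SyntheticCohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_null_cohort():
    """Small clean null cohort: 30+40 samples, 8 metabolites, no planted edges."""
    spec = clean_spec(n_case=30, n_control=40, n_metabolites=8, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_null_pipeline(small_null_cohort):
    """(normalized matrix, labels) for the small null cohort."""
    matrix, _ = preprocess(small_null_cohort.concentrations)
    labels = classify(small_null_cohort.outcomes)
    return matrix, labels
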