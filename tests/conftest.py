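import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from founder_risk.data_model_io import (
    GenotypeMatrix,
    PopulationCounts,
    VariantKey,
    VariantRecord,
)
from founder_risk.synthetic_data import effect_table_from_arrays


@pytest.fixture
def keys():
    return [VariantKey("1", i + 100, "A", "G") for i in range(3)]


@pytest.fixture
def small_matrix(keys):
    """6 samples x 3 variants, one missing call, no covariates."""
    dosages = np.array([
        [0, 1, 2],
        [1, 0, 0],
        [2, 2, 1],
        [0, 0, 0],
        [1, np.nan, 0],
        [0, 1, 1],
    ], dtype=float)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(6)],
        variant_keys=keys,
        dosages=dosages,
        phenotype=np.array([1, 0, 1, 0, 1, 0]),
    )


@pytest.fixture
def counts_records():
    """5 variants spanning the AF window and reference-eligibility edge cases."""
    def rec(pos, af_study, af_ref, annotation="PRA", an_study=4000, an_ref=60000):
        return VariantRecord(
            key=VariantKey("1", pos, "A", "G"),
            annotation=annotation,
            counts={
                "AJ": PopulationCounts("AJ", round(af_study * an_study), an_study),
                "NFE": PopulationCounts("NFE", round(af_ref * an_ref), an_ref),
            },
            coverage_ok={"NFE": True},
        )

    return [
        rec(1, 0.05, 0.002),           # strongly enriched, in window
        rec(2, 0.001, 0.001),          # below window
        rec(3, 0.02, 0.02, "SYN"),     # in window, null
        rec(4, 0.15, 0.05),            # above window
        rec(5, 0.01, 0.00005),         # reference below the 1e-4 floor -> unclassifiable
    ]


@pytest.fixture
def effects_two_pop():
    rng = np.random.default_rng(7)
    m = 10
    return effect_table_from_arrays(
        betas=rng.normal(0.2, 0.1, m),
        freqs={"AJ": rng.uniform(0.1, 0.4, m), "NFE": rng.uniform(0.1, 0.4, m)},
    )
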