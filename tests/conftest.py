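import numpy as np
import pandas as pd
import pytest

from metage.containers import FeatureTable, SampleMetadata
from metage.profiling import aggregate_support, normalize_single_copy
from metage.simulate import (
    SyntheticConfig,
    generate_hierarchy,
    generate_profiles,
    universal_ko_ids,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 12 subjects per cohort, 2-month delay."""
    return SyntheticConfig(
        n_subjects_per_cohort=12,
        n_features_ko=60,
        n_universal_kos=10,
        delay_months=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    table, meta, truth = generate_profiles(small_config)
    return table, meta, truth


@pytest.fixture(scope="session")
def module_dataset(small_config, small_dataset):
    """Normalized module-level table for the small synthetic study."""
    table, meta, truth = small_dataset
    hier = generate_hierarchy(small_config)
    norm = normalize_single_copy(table, universal_ko_ids(small_config))
    mods, unmapped = aggregate_support(norm, hier, "module")
    return mods, meta, truth


def toy_table(values, level="module", sample_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"F{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return FeatureTable(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), level=level
    )


def toy_metadata(sample_ids, ages, cohorts):
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": [f"subj_{s}" for s in sample_ids],
                "age_months": ages,
                "cohort": cohorts,
            }
        )
    )
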