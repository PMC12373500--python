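import numpy as np
import pandas as pd
import pytest

from pdxmeta.io import IntensityTable, SampleAnnotation
from pdxmeta.preprocessing import preprocess
from pdxmeta.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-degenerate cohort with planted effects."""
    config = SimulationConfig(
        n_origins=5,
        n_metabolites=60,
        n_pdx_per_origin_per_passage=2,
        passages=(1, 2, 3),
        origin_sd=0.8,
        residual_sd=0.2,
        host_shift_fraction=0.2,
        sample_scale_sd=0.1,
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    table, ann, _ = small_cohort
    norm, _ = preprocess(table)
    return norm, ann


def make_annotation(rows):
    """Build a SampleAnnotation from (sample_id, origin, host, passage) rows."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "origin", "host", "passage"]
    ).set_index("sample_id")
    return SampleAnnotation(df)


def make_table(values, metabolites=None, samples=None):
    arr = np.asarray(values, dtype=float)
    metabolites = metabolites or [f"m{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return IntensityTable(pd.DataFrame(arr, index=metabolites, columns=samples))
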