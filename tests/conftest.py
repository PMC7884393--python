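import numpy as np
import pandas as pd
import pytest

from genestage import StagedCohort, build_binary_task
from genestage.synth import CohortSpec, generate_cohort


@pytest.fixture
def tiny_cohort() -> StagedCohort:
    """5 genes x 8 samples, 3 A / 2 B / 3 C, hand-set ages and values."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    samples = [f"s{i}" for i in range(8)]
    expr = pd.DataFrame(rng.normal(5, 1, size=(5, 8)), index=genes, columns=samples)
    braak = pd.Series([0, 1, 2, 3, 4, 5, 6, 6], index=samples, name="braak")
    age = pd.Series([70.0, 75.0, 80.0, 72.0, 78.0, 71.0, 76.0, 81.0], index=samples, name="age")
    return StagedCohort(expr, braak, age, dataset_id="toy", region_id="r1")


@pytest.fixture
def tiny_task(tiny_cohort):
    return build_binary_task(tiny_cohort, "A", "C")


@pytest.fixture(scope="session")
def null_cohort():
    """Medium synthetic cohort with no planted signal (effect_size = 0)."""
    cohort, _ = generate_cohort(
        CohortSpec(n_per_stage=(20, 10, 20), n_genes=500, effect_size=0.0, seed=7)
    )
    return cohort


@pytest.fixture(scope="session")
def signal_cohort():
    """Medium synthetic cohort with the default planted stage effect."""
    return generate_cohort(CohortSpec(n_per_stage=(20, 10, 20), n_genes=500, seed=7))
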