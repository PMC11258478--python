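import numpy as np
import pandas as pd
import pytest

from sleepbioage.cohorts import generate_reference_cohort, generate_target_cohort
from sleepbioage.config import SyntheticConfig
from sleepbioage.panel import Analyte, BiomarkerPanel, default_panel


@pytest.fixture(scope="session")
def panel() -> BiomarkerPanel:
    return default_panel()


@pytest.fixture(scope="session")
def config() -> SyntheticConfig:
    return SyntheticConfig(seed=20240001)


@pytest.fixture(scope="session")
def reference_cohort(config) -> pd.DataFrame:
    return generate_reference_cohort(config)


@pytest.fixture(scope="session")
def target_cohort(config) -> pd.DataFrame:
    return generate_target_cohort(config)


@pytest.fixture
def two_marker_panel() -> BiomarkerPanel:
    return BiomarkerPanel(
        analytes=(Analyte("m1", "u"), Analyte("m2", "u"))
    )


def toy_reference(n: int, seed: int, q, k, s, age_lo=40.0, age_hi=70.0) -> pd.DataFrame:
    """Reference cohort with biomarkers exactly linear in age plus noise."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(age_lo, age_hi, n)
    data = {"age": age}
    for j, (qj, kj, sj) in enumerate(zip(q, k, s)):
        data[f"m{j + 1}"] = qj + kj * age + rng.normal(0.0, sj, n)
    return pd.DataFrame(data)
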