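import pandas as pd
import pytest

from maotofu import amino_acids as aa
from maotofu import synthetic


@pytest.fixture(scope="session")
def who_fao() -> aa.ReferencePattern:
    return aa.load_reference_pattern("who_fao_1973")


@pytest.fixture(scope="session")
def egg() -> aa.ReferencePattern:
    return aa.load_reference_pattern("egg")


@pytest.fixture
def small_config() -> synthetic.SynthConfig:
    """A fast, fully deterministic generator config for unit tests."""
    return synthetic.SynthConfig(
        seed=42, n_samples_per_class=2, n_reads_per_sample=15,
        n_volatiles=6, n_taxa=3, n_corr_samples=12,
    )


def make_peak_table(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["sample_id", "compound", "chemical_class", "peak_area"]
    )
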