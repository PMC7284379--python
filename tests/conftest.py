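import numpy as np
import pandas as pd
import pytest

import maizedti as m


@pytest.fixture(scope="session")
def full_dataset() -> m.PhenotypeDataset:
    """Default 40-accession x 4-treatment x 3-replicate synthetic trial."""
    return m.simulate_dataset(m.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def full_report(full_dataset) -> m.AnalysisReport:
    return m.run_analysis(full_dataset)


@pytest.fixture
def small_dataset() -> m.PhenotypeDataset:
    return m.simulate_dataset(m.SimulationConfig(n_accessions=8, seed=11))


@pytest.fixture(scope="session")
def reference_counts() -> pd.DataFrame:
    return m.load_reference_screening_counts()


def make_dti_matrix(values: pd.DataFrame, reversed_traits=("AS",)) -> m.DTIMatrix:
    """Build a DTIMatrix from a flat frame with (trait, level) tuple columns."""
    vals = values.copy()
    vals.columns = pd.MultiIndex.from_tuples(vals.columns,
                                             names=["trait", "treatment"])
    directions = {c: c[0] not in reversed_traits for c in vals.columns}
    return m.DTIMatrix(values=vals, directions=directions)
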