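import numpy as np
import pytest

from seropanel.cohort import (
    generate_expression_fixture,
    generate_serum_cohort,
    validation_design,
)


@pytest.fixture(scope="session")
def expression_fixture():
    """Planted-truth expression matrix: 10 markers + 90 single-violation
    decoys over the tissue-cohort stage design."""
    return generate_expression_fixture(n_genes=100, seed=11)


@pytest.fixture(scope="session")
def serum_cohort():
    """Validation-design serum cohort at the published operating points."""
    return generate_serum_cohort(validation_design(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
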