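import warnings

import pytest

from scanact.synthfix import (
    SimSpec,
    gen_cohort,
    gen_ligandome,
    gen_normal_panels,
    gene_layout,
)


@pytest.fixture(scope="session")
def spec():
    return SimSpec(seed=1)


@pytest.fixture(scope="session")
def layout(spec):
    return gene_layout(spec)


@pytest.fixture(scope="session")
def cohort(spec, layout):
    return gen_cohort(spec, layout)


@pytest.fixture(scope="session")
def panels(spec, layout):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gen_normal_panels(spec, layout)


@pytest.fixture(scope="session")
def ligandome(spec, layout):
    return gen_ligandome(spec, layout)
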