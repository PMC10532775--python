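import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dapsol import build_consensus, load_dapsone_table1
from dapsol.synthetic import (
    gen_mock_backend,
    gen_solubility_profiles,
    gen_solvent_space,
    gen_truth,
)

T_GRID = tuple(288.15 + 5.0 * i for i in range(8))


@pytest.fixture(scope="session")
def table1():
    """The bundled five-solvent dapsone dataset (20 records)."""
    return load_dapsone_table1()


@pytest.fixture(scope="session")
def study():
    """The 12-solvent, 3-class synthetic study used across modules.

    Class backend biases (-1, 0, +1) kcal/mol with 0.05 kcal/mol within-class
    scatter; 8-point temperature grid; replicate noise 0.02 on ln x.
    """
    solvents = gen_solvent_space(4, (-1.0, 0.0, 1.0), seed=1, within_class_sd=0.05)
    truth = gen_truth(solvents, seed=1)
    records = gen_solubility_profiles(solvents, T_GRID, truth, seed=2)
    consensus = build_consensus({"synthetic": records})
    backend = gen_mock_backend(solvents, truth, seed=3)
    return {
        "solvents": solvents,
        "truth": truth,
        "records": records,
        "consensus": consensus,
        "backend": backend,
    }
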