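import numpy as np
import pandas as pd
import pytest

from lakejsdm.model import ModelSpec, make_model_data, run_chains
from lakejsdm.preprocess import build_design_matrix
from lakejsdm.synthetic import desk_config, generate_dataset


@pytest.fixture(scope="session")
def desk_bundle():
    """One desk-scale synthetic dataset shared across the suite."""
    return generate_dataset(desk_config(seed=42))


@pytest.fixture(scope="session")
def desk_fit(desk_bundle):
    """A short two-chain fit of the community model on the desk dataset."""
    b = desk_bundle
    dm = build_design_matrix(b["covariates"])
    data = make_model_data(
        b["community"], dm, b["design"], traits=b["traits"], phylo=b["phylo"]
    )
    chains = run_chains(
        ModelSpec(), data, n_chains=2, n_iterations=700, burn_in=300, thin=2, seed=7
    )
    return {"bundle": b, "dm": dm, "data": data, "chains": chains}


@pytest.fixture()
def simple_taxonomy():
    return pd.DataFrame(
        {
            "class": ["c1", "c1", "c1", "c2"],
            "order": ["c1o1", "c1o1", "c1o1", "c2o1"],
            "family": ["c1o1f1", "c1o1f1", "c1o1f2", "c2o1f1"],
            "genus": ["c1o1f1g1", "c1o1f1g1", "c1o1f2g1", "c2o1f1g1"],
        },
        index=["sp1", "sp2", "sp3", "sp4"],
    )
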