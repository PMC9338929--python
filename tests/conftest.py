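import numpy as np
import pandas as pd
import pytest

import spacomm as sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expr():
    """3 genes x 2 units with easy arithmetic."""
    return sp.ExpressionMatrix(
        ["G1", "G2", "G3"], ["U1", "U2"],
        np.array([[10.0, 0.0], [0.0, 5.0], [2.0, 3.0]]),
    )


@pytest.fixture(scope="session")
def small_scenario():
    return sp.SyntheticScenario(seed=7, cells_per_type=50, n_genes=120,
                                n_decoy_lri=10, n_decoy_edges=15)


@pytest.fixture(scope="session")
def small_spatial(small_scenario):
    return sp.generate_spatial(small_scenario)


@pytest.fixture(scope="session")
def small_reference(small_scenario):
    return sp.generate_reference(small_scenario)


@pytest.fixture(scope="session")
def small_prior(small_scenario):
    return sp.generate_prior(small_scenario)


@pytest.fixture
def labeled_atlas(small_spatial):
    """Atlas built directly from the synthetic single-cell truth."""
    from spacomm.mapping import ReconstructedAtlas

    st, coords, labels = small_spatial
    stn = sp.log_normalize(st)
    placements = pd.DataFrame({
        "cell": st.units,
        "type": labels.loc[st.units].to_numpy(),
        "x": coords.frame.loc[st.units, "x"].to_numpy(),
        "y": coords.frame.loc[st.units, "y"].to_numpy(),
        "source_spot": st.units,
        "source_ref_cell": "",
    })
    return ReconstructedAtlas(placements=placements, expression=stn)
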