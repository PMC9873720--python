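import numpy as np
import pytest

from wetdom import synthetic as syn
from wetdom.parafac import ParafacModel

# Coarse grids keep tensor fits fast while spanning the measurement range.
EX_COARSE = np.arange(230.0, 500.0 + 1e-9, 10.0)
EM_COARSE = np.arange(250.0, 700.0 + 1e-9, 4.0)


@pytest.fixture(scope="session")
def coarse_grids():
    return EX_COARSE, EM_COARSE


@pytest.fixture(scope="session")
def three_component_dataset():
    """Noiseless 3-component EEM collection with known loadings."""
    scen = syn.EEMScenario(components=syn.DEFAULT_COMPONENTS[:3], n_samples=20,
                           seed=11, ex_grid=EX_COARSE, em_grid=EM_COARSE)
    return syn.gen_eem_dataset(scen)


def truth_model(ds: syn.EEMDataset) -> ParafacModel:
    """Wrap a generated dataset's ground truth as a ParafacModel for matching."""
    return ParafacModel(
        scores=ds.scores, em_loadings=ds.em_loadings, ex_loadings=ds.ex_loadings,
        em=ds.eems[0].em, ex=ds.eems[0].ex,
        n_components=ds.scores.shape[1], explained_variance=1.0,
        converged=True, iterations=0,
    )
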