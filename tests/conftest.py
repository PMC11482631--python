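import pytest

from feedsid import fixtures
from feedsid import synthetic_trial as st


@pytest.fixture(scope="session")
def bundle():
    return fixtures()


@pytest.fixture(scope="session")
def diet_ids(bundle):
    return [i.sample_id for i in bundle.ingredients] + [st.NFREE_DIET_ID]


@pytest.fixture(scope="session")
def noise_free_trial(bundle, diet_ids):
    """A simulated trial whose truth is the bundled SID table, no assay noise."""
    truth = st.default_ground_truth(
        bundle.ingredients, bundle.sid, bundle.endogenous,
        noise_cv=0.0, seed=7)
    design = st.build_design(seed=7, diet_ids=diet_ids)
    return st.generate_trial(bundle.ingredients, truth, design)
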