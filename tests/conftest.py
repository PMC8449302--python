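import warnings

import pytest

import laggedsense as ls
from laggedsense.synthetic_cohort import DEFAULT_APP_CATEGORY_MAP


@pytest.fixture(scope="session")
def event_bundle():
    """Small event-level cohort with a strong forward coupling."""
    cfg = ls.SimConfig(n_participants=6, coupling_rho=-0.5, seed=11)
    return ls.generate_cohort(cfg)


@pytest.fixture(scope="session")
def event_base_windows(event_bundle):
    cfg = ls.FeatureConfig(app_category_map=DEFAULT_APP_CATEGORY_MAP)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ls.extract_feature_windows(event_bundle, cfg)


@pytest.fixture(scope="session")
def feature_cohort():
    """Fast feature-level cohort with coupling -0.3 on Locations."""
    cfg = ls.SimConfig(n_participants=150, coupling_rho=-0.3, seed=7)
    return ls.generate_feature_cohort(cfg)
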