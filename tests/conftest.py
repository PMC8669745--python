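import numpy as np
import pytest

from exokin import pipeline
from exokin import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    """Reduced factorial: 2 enzymes x 2 depths x 3 temperatures x 1 core,
    all 3 timepoints — enough structure for every pipeline stage."""
    return sd.CampaignConfig(
        enzymes=("BG", "AP"), depths=("0-10", "80-90"),
        temperatures=(4.0, 16.0, 35.0), cores=(1,),
        timepoints=(1.0, 4.0, 24.0), seed=11)


@pytest.fixture(scope="session")
def small_campaign(small_config):
    return sd.simulate_campaign(small_config, seed=11)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, contamination-free campaign for exact round trips."""
    return sd.CampaignConfig(
        enzymes=("BG",), depths=("0-10", "80-90"),
        temperatures=(16.0, 35.0), cores=(1,), timepoints=(4.0,),
        cv=0.0, negative_rate=0.0, outlier_rate=0.0, standard_cv=0.0,
        seed=3)


@pytest.fixture(scope="session")
def clean_campaign(clean_config):
    return sd.simulate_campaign(clean_config, seed=3)


@pytest.fixture(scope="session")
def full_campaign_run():
    """One full default campaign (324 fit units x 3 timepoints) run through
    the whole pipeline; shared across the end-to-end checks."""
    cfg = sd.CampaignConfig(seed=17)
    res = sd.simulate_campaign(cfg, seed=17)
    out = pipeline.run_campaign_pipeline(res["assay"], res["soil"])
    return {"config": cfg, **res, **out}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
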