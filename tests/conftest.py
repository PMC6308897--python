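import numpy as np
import pandas as pd
import pytest

import allomass as am


@pytest.fixture(scope="session")
def db():
    return am.load_default_parameters()


@pytest.fixture()
def lw_params():
    """The all-taxa length+width equation, used as a generating truth."""
    return am.ParameterSet("LW", -0.340, 1.070, 1.634)


def make_region_frame(params_by_region, n=200, seed=0, sigma=0.0, log_len_range=(0.0, 1.5)):
    """Two-region length-only community generated from LR-style truths."""
    rng = np.random.default_rng(seed)
    frames = []
    for region, p in params_by_region.items():
        log_len = rng.uniform(*log_len_range, size=n)
        log_mass = p.intercept + p.slope_length * log_len + rng.normal(0, sigma, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": [f"{region[:4]}{i}" for i in range(n)],
                    "taxon": None,
                    "family": None,
                    "region": region,
                    "length_mm": 10.0 ** log_len,
                    "width_mm": np.nan,
                    "mass_mg": 10.0 ** log_mass,
                    "is_larva": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
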