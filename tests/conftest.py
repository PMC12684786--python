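import numpy as np
import pandas as pd
import pytest

from cismr import simulate as sim


@pytest.fixture
def two_ratio_instruments() -> pd.DataFrame:
    """Two instruments with Wald ratios -0.5 (se 0.2) and -0.2 (se 0.1).

    Ratio weights are b_X^2 / se_Y^2 = 25 and 100.
    """
    return pd.DataFrame(
        {
            "variant_id": ["v1", "v2"],
            "beta_exp": [0.1, 0.1],
            "se_exp": [0.01, 0.01],
            "beta_out": [-0.05, -0.02],
            "se_out": [0.02, 0.01],
        }
    )


def equal_weight_instruments(ratios, se_out=1.0, se_exp=1e-6) -> pd.DataFrame:
    """Instruments with unit beta_exp so ratios equal beta_out and weights are equal."""
    ratios = np.asarray(ratios, dtype=float)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(ratios))],
            "beta_exp": np.ones_like(ratios),
            "se_exp": np.full_like(ratios, se_exp),
            "beta_out": ratios,
            "se_out": np.full_like(ratios, se_out),
        }
    )


@pytest.fixture
def small_study():
    """A small synthetic two-sample study with a known positive causal effect."""
    cfg = sim.SimConfig(seed=11, n_exposure_sample=20_000, n_outcome_sample=30_000,
                        theta=sim.conditional_log_odds(0.661))
    return sim.make_two_sample_study(cfg)
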