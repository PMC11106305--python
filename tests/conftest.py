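import pandas as pd
import pytest

from mixedbeam.simulate import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def demo_study():
    """One synthetic study with a 1.4x mixed-beam interaction."""
    return simulate_study(SyntheticConfig(seed=42, interaction_theta=1.4))


@pytest.fixture(scope="session")
def additive_study():
    """One synthetic study under exact additivity (theta = 1)."""
    return simulate_study(SyntheticConfig(seed=7, interaction_theta=1.0))


@pytest.fixture()
def tiny_ct_frame():
    """Two samples (control + 1 Gy X-rays), one gene + reference, duplicates."""
    rows = []
    for rad, dose, tgt, ct in [
        ("control", 0.0, "FDXR_PP1", 25.0),
        ("control", 0.0, "REF_18S", 15.0),
        ("xray", 1.0, "FDXR_PP1", 23.0),
        ("xray", 1.0, "REF_18S", 15.0),
    ]:
        for rep in (1, 2):
            rows.append(
                {
                    "donor": "d1",
                    "season": 1,
                    "week": 1,
                    "radiation": rad,
                    "dose_gy": dose,
                    "target": tgt,
                    "replicate": rep,
                    "ct": ct,
                }
            )
    return pd.DataFrame(rows)
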