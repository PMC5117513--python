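import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tssclust as tc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_block() -> tc.PromoterBlock:
    """30 uniform-background sequences, 150 columns, TSS at column 75."""
    return tc.generate_background_block(30, 150, tss_col=75, seed=11)


@pytest.fixture(scope="session")
def small_bg(small_block):
    return tc.fit_background(small_block)


@pytest.fixture(scope="session")
def sharp_matrix() -> tc.CountMatrix:
    return tc.synthetic_count_matrix(5, information=0.95, seed=7, name="TFA")


@pytest.fixture(scope="session")
def planted_study():
    """Two-member RM (widths 5, offsets +7 / +13) in 30% of 150 genes."""
    block = tc.generate_background_block(
        150, 401, tss_col=200, gene_ids=[f"g{k:04d}" for k in range(150)],
        seed=21,
    )
    members = (
        tc.RmMember(tc.synthetic_count_matrix(5, 0.95, seed=31, name="TFA"), "+", 7),
        tc.RmMember(tc.synthetic_count_matrix(5, 0.95, seed=32, name="TFB"), "+", 13),
    )
    spec = tc.RmSpec(members, carrier_fraction=0.3)
    return tc.plant_rm(block, spec, seed=41)


@pytest.fixture(scope="session")
def planted_fit(planted_study):
    matrices = [m.matrix for m in planted_study.rm_spec.members]
    model = tc.PositionalClusterModel(planted_study.block, matrices)
    return model.fit()
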