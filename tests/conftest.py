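import numpy as np
import pytest
from hypothesis import settings

from ssmr import HarmonizedTable, VariantAssociation

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_harmonized(rng, m, theta=0.2, se_x=0.013, se_y=0.02, gamma_scale=0.1):
    """Random harmonized table with exposure effects bounded away from zero."""
    gamma = rng.uniform(0.5, 1.5, m) * gamma_scale * rng.choice([-1.0, 1.0], m)
    sx = np.full(m, se_x) * rng.uniform(0.8, 1.2, m)
    sy = np.full(m, se_y) * rng.uniform(0.8, 1.2, m)
    bx = gamma + rng.normal(0, sx)
    by = theta * gamma + rng.normal(0, sy)
    return HarmonizedTable.from_arrays(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def three_snp_records():
    return [
        VariantAssociation("rs1", "A", "G", 0.10, 0.013, 1.5e-14, eaf=0.3, n=26420),
        VariantAssociation("rs2", "T", "C", -0.08, 0.012, 2.5e-11, eaf=0.6, n=26420),
        VariantAssociation("rs3", "G", "A", 0.12, 0.015, 1e-15, eaf=0.25, n=26420),
    ]
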