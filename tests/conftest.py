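import numpy as np
import pytest

from phenokin.kinetics import HaldaneParameters

# Parameter triples from the phenol-degradation batch study this package
# was built around: growth branch (mu*, Ks, Ki) and degradation branch
# (q*, Ks', Ki'), rates in h^-1 and concentrations in mg/L.
GROWTH_PD35 = HaldaneParameters(rate_star=0.574, ks=20.29, ki=268.1, branch="growth")
DEGRADATION_PD35 = HaldaneParameters(
    rate_star=1.244, ks=9.152, ki=517.5, branch="degradation"
)


@pytest.fixture
def growth_params() -> HaldaneParameters:
    return GROWTH_PD35


@pytest.fixture
def degradation_params() -> HaldaneParameters:
    return DEGRADATION_PD35


def random_valid_params(rng: np.random.Generator, branch: str = "growth") -> HaldaneParameters:
    """Log-uniform draw over ranges typical of phenol kinetics."""
    return HaldaneParameters(
        rate_star=float(10 ** rng.uniform(-1, 0.5)),
        ks=float(10 ** rng.uniform(0.5, 2.5)),
        ki=float(10 ** rng.uniform(1.5, 3.5)),
        branch=branch,
    )
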