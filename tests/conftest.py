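import numpy as np
import pytest

from phenocycle.design import (
    CONTROL,
    STRESS,
    ExperimentDesign,
    GenotypeSpec,
    WateringPhase,
    build_default_design,
)
from phenocycle.synthetic import default_growth_params


@pytest.fixture(scope="session")
def default_design():
    return build_default_design()


@pytest.fixture(scope="session")
def default_params(default_design):
    return default_growth_params(default_design)


@pytest.fixture(scope="session")
def desk_design():
    """Reduced design for rendered-image runs: two parent/NIL pairs,
    two treatments, five replicates."""
    genotypes = [
        GenotypeSpec("BarNir", "parent", "NIL-B-7A-2"),
        GenotypeSpec("NIL-B-7A-2", "nil", "BarNir"),
        GenotypeSpec("Uzan", "parent", "NIL-U-2B-3"),
        GenotypeSpec("NIL-U-2B-3", "nil", "Uzan"),
    ]
    watering = {
        CONTROL: [WateringPhase(1, 0.90)],
        STRESS: [WateringPhase(1, 0.90), WateringPhase(31, 0.30),
                 WateringPhase(64, 0.20)],
    }
    return ExperimentDesign(
        genotypes=genotypes, n_rep=5, watering=watering,
        imaging_daily_until=95, imaging_stride_after=2, last_das=121,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
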