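import pytest

from pupfpcr.io_formats import builtin_pup_assay
from pupfpcr.quant import StandardCurve
from pupfpcr.synthetic import FamilySpec, PlantedDesignSpec, simulate_family


@pytest.fixture(scope="session")
def assay():
    return builtin_pup_assay()


@pytest.fixture(scope="session")
def planted_family():
    """One synthetic ortholog family with a planted assay design."""
    return simulate_family(FamilySpec(planted_design=PlantedDesignSpec(), seed=11))


@pytest.fixture(scope="session")
def perfect_curve():
    """A 100%-efficiency standard curve (slope -1/log10(2) = -3.3219)."""
    return StandardCurve(slope_a=-3.3219, intercept_b=21.0, r_squared=1.0, n_points=4)
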