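import numpy as np
import pytest

from heterores import AssayDesign, ResistanceDistribution, load_zygo_panel


@pytest.fixture
def dist():
    """A realistic spoilage-yeast population: IC50 4 mM, spread 0.07."""
    return ResistanceDistribution(np.log10(4.0), 0.07)


@pytest.fixture
def all_clear_design():
    return AssayDesign(scoring_rule="all-clear")


@pytest.fixture(scope="session")
def panel_records():
    return load_zygo_panel()


@pytest.fixture(scope="session")
def panel_arrays(panel_records):
    import numpy as np

    return {
        "strain_id": np.array([r.strain_id for r in panel_records]),
        "species": np.array([r.species for r in panel_records]),
        "heteroresistance": np.array([r.heteroresistance for r in panel_records]),
        "ic50_mM": np.array([r.ic50_mM for r in panel_records]),
        "mic_model_mM": np.array([r.mic_model_mM for r in panel_records]),
    }


def erf_normal_quantile(p: float) -> float:
    """Standard-normal quantile by bisection on math.erf (independent of scipy)."""
    import math

    lo, hi = -12.0, 12.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if 0.5 * (1.0 + math.erf(mid / math.sqrt(2.0))) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
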