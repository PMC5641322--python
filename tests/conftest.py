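import pandas as pd
import pytest
from hypothesis import settings

from n2pair import IncubationDesign, IsotopologueSeries

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def default_design() -> IncubationDesign:
    """Triplicate 0/14/24/36/48 h design, 30 mL water / 8 mL headspace."""
    return IncubationDesign()


@pytest.fixture
def noiseless_series(default_design) -> IsotopologueSeries:
    """Exact zero-order accumulation: 29N2 at 3.5 and 30N2 at 0.7 per day."""
    rows = []
    for t in default_design.sampling_times_h:
        for rep in range(1, 4):
            rows.append(
                {
                    "time_h": t,
                    "replicate": f"T{t:g}_R{rep}",
                    "excess29_nmol_per_L": 3.5 * t / 24.0,
                    "excess30_nmol_per_L": 0.7 * t / 24.0,
                }
            )
    return IsotopologueSeries(pd.DataFrame(rows), design=default_design)
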