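import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from volatilink import CompoundTable, SampleMetadata

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def meta_6_6() -> SampleMetadata:
    """Six control + six high-light coral samples, no blanks."""
    samples = [f"C{i}" for i in range(1, 7)] + [f"H{i}" for i in range(1, 7)]
    return SampleMetadata(
        frame=pd.DataFrame(
            {
                "treatment": ["control"] * 6 + ["high_light"] * 6,
                "is_blank": False,
                "internal_standard_area": 1.0,
                "scale_factor": 1.0,
            },
            index=samples,
        )
    )


@pytest.fixture
def meta_with_blanks() -> SampleMetadata:
    """2x6 corals plus 3 blanks per treatment."""
    corals = [f"C{i}" for i in range(1, 7)] + [f"H{i}" for i in range(1, 7)]
    blanks = [f"BC{i}" for i in range(1, 4)] + [f"BH{i}" for i in range(1, 4)]
    frame = pd.DataFrame(
        {
            "treatment": ["control"] * 6 + ["high_light"] * 6 + ["control"] * 3 + ["high_light"] * 3,
            "is_blank": [False] * 12 + [True] * 6,
            "internal_standard_area": 1.0,
            "scale_factor": [1.0] * 12 + [np.nan] * 6,
        },
        index=corals + blanks,
    )
    return SampleMetadata(frame=frame)


def make_table(values, samples, compounds, kind="volatile", stage="raw") -> CompoundTable:
    return CompoundTable(
        data=pd.DataFrame(np.asarray(values, dtype=float), index=samples, columns=compounds),
        kind=kind,
        stage=stage,
    )


@pytest.fixture
def small_table(meta_6_6) -> CompoundTable:
    rng = np.random.default_rng(7)
    return make_table(
        rng.lognormal(mean=2.0, sigma=0.3, size=(12, 5)),
        meta_6_6.sample_ids,
        [f"c{i}" for i in range(5)],
    )
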