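import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tff3quant as tq

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

POSITIVE_COLOR = (140, 70, 30)
GASTRIC_COLOR = (70, 110, 180)


@pytest.fixture(scope="session")
def best2_cohort():
    """Default surveillance-like cohort (n=529, 59.5% relevant)."""
    return tq.simulate_cohort(tq.BEST2_LIKE(seed=101))


@pytest.fixture(scope="session")
def small_slide():
    """A small annotated slide with two TFF3 regions and one gastric region."""
    return tq.simulate_annotated_slide(
        tq.SlideSimParams(
            width_px=640,
            height_px=480,
            n_positive_regions=2,
            n_gastric_regions=1,
            region_size_range_px=(120, 220),
            seed=7,
        )
    )


@pytest.fixture
def tiling_cfg():
    return tq.TilingConfig(tile_edge_px=64)


def make_records(counts, labels, **kw):
    """Toy patient records from parallel count/label sequences."""
    recs = []
    for i, (c, lab) in enumerate(zip(counts, labels)):
        C, M = (2.0, 5.0) if lab == tq.RELEVANT else (0.0, 1.0)
        recs.append(
            tq.PatientRecord(patient_id=f"p{i:03d}", C_cm=C, M_cm=M, tile_count=int(c), **kw)
        )
    return recs
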