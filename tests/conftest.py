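import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirnaprog as mp

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL = dict(
    n_probesets=60,
    probes_per_set=3,
    n_background_probes=40,
    n_signature=5,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale-squared config for fast unit tests."""
    return mp.SimulationConfig(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return mp.generate_cohort(small_config, 12)


@pytest.fixture(scope="session")
def tiny_annotation():
    """Hand-built annotation: 6 probe sets x 2 probes + 8 background probes."""
    rows = []
    for s in range(6):
        for p in range(2):
            rows.append((f"PS{s}_p{p}", f"PS{s}", "human" if s < 4 else "other", "measurement"))
    for b in range(8):
        rows.append((f"BG{b}", f"BG{b}", "other", "background"))
    return mp.ProbeAnnotation(
        pd.DataFrame(rows, columns=["probe_id", "probeset_id", "species", "role"])
    )


def make_sheet(n, **overrides):
    """Minimal valid sample sheet with n default-condition arrays."""
    base = {
        "array_id": [f"A{i}" for i in range(n)],
        "sample_id": [f"S{i}" for i in range(n)],
        "rna_input_ng": [600.0] * n,
        "atp_dilution": ["1:50"] * n,
        "lot_id": ["L1"] * n,
        "extraction_kit": ["RA"] * n,
        "labeling_kit": ["FH"] * n,
        "recurrence": [float(i % 2) for i in range(n)],
        "time_months": [20.0 + i for i in range(n)],
        "event": [float(i % 2) for i in range(n)],
    }
    base.update(overrides)
    return mp.SampleSheet(pd.DataFrame(base))


@pytest.fixture
def sheet_factory():
    return make_sheet
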