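import hypothesis
import numpy as np
import pandas as pd
import pytest

from cpgsig import BetaMatrix, SampleSheet, SimulationConfig, simulate_beta_matrix

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def tiny_matrix() -> BetaMatrix:
    """3 probes x 4 samples, clean."""
    return BetaMatrix(
        pd.DataFrame(
            {
                "s1": [0.10, 0.50, 0.90],
                "s2": [0.20, 0.55, 0.85],
                "s3": [0.80, 0.45, 0.10],
                "s4": [0.90, 0.52, 0.15],
            },
            index=["cgA", "cgB", "cgC"],
        )
    )


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet.from_records(
        [
            ("s1", "N", "d1"),
            ("s2", "N", "d1"),
            ("s3", "TNBC", "d1"),
            ("s4", "TNBC", "d1"),
        ]
    )


@pytest.fixture(scope="session")
def planted_sim():
    """A 1035-probe, 20 vs 20 cohort with 35 planted DMPs (Δβ = −0.35)."""
    cfg = SimulationConfig(
        n_probes=1035,
        n_planted_dmps=35,
        class_sizes={"N": 20, "TNBC": 20},
        dmp_effect=-0.35,
        dispersion=50.0,
        seed=42,
    )
    return simulate_beta_matrix(cfg)
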