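import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ushape import (
    Dataset,
    FootRecord,
    FootSide,
    GeneratorConfig,
    RiskCurve,
    generate_dataset,
)

#: Published fixed-effect estimates of the adjusted quadratic mixed model
#: (centered scale) and the exposure sample mean they were centered at.
TABLE3_BETA1 = 0.238
TABLE3_BETA2 = 0.051
SSNDT_MEAN = 7.8


@pytest.fixture(scope="session")
def table3_curve() -> RiskCurve:
    """Risk curve reconstructed from the published quadratic coefficients."""
    return RiskCurve(beta1=TABLE3_BETA1, beta2=TABLE3_BETA2,
                     ssndt_mean=SSNDT_MEAN)


@pytest.fixture(scope="session")
def calibrated_dataset() -> Dataset:
    """One study-sized draw from the calibrated generator (137 participants)."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def no_cluster_dataset() -> Dataset:
    """Data generated with sigma_u = 0: feet are independent."""
    return generate_dataset(GeneratorConfig(seed=21, sigma_u=0.0))


def make_records(n: int, seed: int = 0) -> list[FootRecord]:
    """Small hand-rolled record list for datamodel tests."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        for side in (FootSide.LEFT, FootSide.RIGHT):
            recs.append(
                FootRecord(
                    participant_id=f"S{i:03d}",
                    foot_side=side,
                    ssndt_mm=float(rng.uniform(1, 15)),
                    injured=int(rng.random() < 0.25),
                    load_h_per_week=float(rng.uniform(6, 12)),
                    experience_years=float(rng.uniform(3, 6)),
                    cohort_year=2023 + i % 3,
                )
            )
    return recs
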