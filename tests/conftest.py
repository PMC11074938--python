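"""Shared fixtures: small cohorts and fast network configurations."""

import numpy as np
import pandas as pd
import pytest

from splxann import CohortConfig, EnsembleConfig, NetworkSpec, generate_cohort

#: A seven-hidden-layer network kept deliberately narrow so unit tests train
#: in milliseconds; the architecture contract (layer count, activation plan)
#: is identical to the default.
TINY_SPEC = NetworkSpec(
    hidden_widths=(16, 16, 12, 8, 8, 6, 4),
    epochs=120,
    patience=30,
    dropout_rate=0.1,
)

FAST_ENSEMBLE = EnsembleConfig(n_members=3, replicates=2, seed=0)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    return generate_cohort(CohortConfig(seed=7).null())


@pytest.fixture()
def tiny_spec() -> NetworkSpec:
    return TINY_SPEC


@pytest.fixture()
def separable_table() -> pd.DataFrame:
    """A two-day table whose mr_il separates the classes by ~10 SD."""
    rng = np.random.default_rng(42)
    rows = []
    for group, offset, n in (("SPLX", 10.0, 20), ("SPL-sham", 0.0, 20)):
        for i in range(n):
            for day in (2, 4):
                rows.append(
                    {
                        "animal_id": f"{group}-{i}",
                        "group": group,
                        "day": day,
                        "mass": 24 + rng.normal(),
                        "ns": int(np.clip(round(12 + rng.normal()), 3, 18)),
                        "mr_il": 228 + offset + rng.normal(),
                        "mr_cl": 225 + rng.normal(),
                        "bli_flux": 1e7 * np.exp(0.3 * rng.normal()),
                        "bli_radiance": 2e5 * np.exp(0.3 * rng.normal()),
                    }
                )
    return pd.DataFrame(rows)
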