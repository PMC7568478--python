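import numpy as np
import pandas as pd
import pytest

from quantherit import CohortConfig, generate_cohort

# compact grid used throughout the tests; includes the headline quantiles
TAUS9 = np.array([0.05, 0.10, 0.25, 0.40, 0.50, 0.60, 0.75, 0.90, 0.95])
TAUS19 = np.round(np.arange(1, 20) * 0.05, 2)


@pytest.fixture(scope="session")
def small_cohort():
    """Identity-transform cohort, 400 families."""
    cfg = CohortConfig(n_families=400, h2_latent=0.5, transform="identity", seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """5000-family identity cohort for Monte-Carlo closed-form checks."""
    cfg = CohortConfig(
        n_families=5000,
        h2_latent=0.5,
        r_spouse_target=0.0,
        c2_shared=0.0,
        transform="identity",
        seed=23,
    )
    return generate_cohort(cfg)


def toy_pedigree(rows):
    """Build a pedigree frame from (id, fam, father, mother, sex, age) tuples."""
    return pd.DataFrame(
        rows,
        columns=["individual_id", "family_id", "father_id", "mother_id", "sex", "age"],
    )


def adjusted_frame(mapping):
    return pd.DataFrame(
        {"individual_id": list(mapping), "adjusted_value": list(mapping.values())}
    )


@pytest.fixture
def nuclear_family():
    """One family: both parents plus one offspring."""
    ped = toy_pedigree(
        [
            ("dad", "fam1", None, None, "M", 60.0),
            ("mom", "fam1", None, None, "F", 58.0),
            ("kid", "fam1", "dad", "mom", "M", 30.0),
        ]
    )
    adj = adjusted_frame({"dad": 2.0, "mom": 4.0, "kid": 1.0})
    return ped, adj
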