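import numpy as np
import pandas as pd
import pytest

from methclock import BatchEffect, CohortSpec, MethylationMatrix, simulate_cohort
from methclock.core import validate_meta


def make_matrix(meth, unmeth, samples=None, sites=None):
    """Small count-matrix helper for hand-built fixtures."""
    meth = np.asarray(meth)
    samples = samples or [f"S{i}" for i in range(meth.shape[0])]
    sites = sites or [f"{1 + j}:{1000 + j}" for j in range(meth.shape[1])]
    return MethylationMatrix(
        pd.DataFrame(np.asarray(meth), index=samples, columns=sites),
        pd.DataFrame(np.asarray(unmeth), index=samples, columns=sites),
    )


def make_meta(samples, ages, **overrides):
    n = len(samples)
    base = {
        "sample_id": list(samples),
        "age_days": list(ages),
        "sex": ["male", "female"] * (n // 2 + 1),
        "strain": ["C57BL/6"] * n,
        "treatment": ["none"] * n,
        "study": ["study1"] * n,
    }
    for key, val in overrides.items():
        base[key] = list(val)
    df = pd.DataFrame({k: v[:n] if isinstance(v, list) else v for k, v in base.items()})
    return validate_meta(df)


@pytest.fixture(scope="session")
def small_cohort():
    """40 samples x 120 sites, one third with planted age drift."""
    spec = CohortSpec(n_samples=40, n_sites=120, n_age_sites=40, seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def batched_cohort():
    """Two studies with a planted location/scale batch distortion."""
    spec = CohortSpec(
        n_samples=60,
        n_sites=150,
        n_age_sites=50,
        seed=5,
        noise_sd=0.05,
        missing_rate=0.0,
        mean_depth=100,
        batches=[BatchEffect("rrbs", 0.0, 1.0), BatchEffect("wgbs", 0.08, 1.8)],
    )
    return simulate_cohort(spec)
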