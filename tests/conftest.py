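import numpy as np
import pandas as pd
import pytest

from dysregkit.cohort_io import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(
    n_ids=40,
    n_visits=3,
    p=4,
    species="spA",
    seed=0,
    sex_cycle=("female", "male"),
    age_start=5.0,
    with_mass=False,
    moments_seed=42,
) -> Cohort:
    """Small deterministic single-species cohort with MVN markers.

    ``moments_seed`` fixes the generating mean/covariance separately from the
    sampling seed, so cohorts with different ``seed`` share true moments.
    """
    rng_m = np.random.default_rng(moments_seed)
    rng = np.random.default_rng(seed)
    markers = [f"m{i + 1:02d}" for i in range(p)]
    A = rng_m.normal(size=(p, p))
    cov = A @ A.T + p * np.eye(p)
    mean = rng_m.uniform(10, 30, size=p)
    rows = []
    for i in range(n_ids):
        iid = f"{species}_{i:03d}"
        sex = sex_cycle[i % len(sex_cycle)]
        ages = age_start + rng.uniform(0, 2) + np.cumsum(
            rng.uniform(0.5, 2.0, size=n_visits))
        for age in ages:
            x = rng.multivariate_normal(mean, cov)
            row = {
                "species": species, "individual_id": iid, "sex": sex,
                "age_at_obs": float(age), "population": "pop1",
                "death_age": np.nan,
                "body_mass": float(30 + rng.normal()) if with_mass else np.nan,
            }
            row.update({m: float(v) for m, v in zip(markers, x)})
            rows.append(row)
    return Cohort(pd.DataFrame(rows), markers)


@pytest.fixture
def small_cohort():
    return make_cohort()


@pytest.fixture
def multispecies_cohorts():
    """Three single-species cohorts sharing identical generating moments."""
    return {
        sp: make_cohort(species=sp, seed=i, n_ids=60, n_visits=2)
        for i, sp in enumerate(["spA", "spB", "spC"])
    }
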