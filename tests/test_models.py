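import numpy as np
import pandas as pd
import pytest

from dysregkit._errors import InputError
from dysregkit.cohort_io import Cohort
from dysregkit.models import (
    age_slope_heterogeneity, fit_age_sex_model, fit_mass_change_model,
    fit_mass_model, mass_change_rate,
)


def _score_table(n_ids=120, visits=3, slope=0.3, sex_effect=0.0, seed=0,
                 sexes=("female", "male"), n_pops=1):
    """Generate dm_z directly from the linear model the fit should recover."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ids):
        iid = f"id{i:03d}"
        sex = sexes[i % len(sexes)]
        pop = f"pop{(i // 2) % n_pops + 1}"
        u = rng.normal(0, 0.5)
        ages = np.sort(rng.uniform(5, 25, visits))
        for a in ages:
            rows.append({"species": "spA", "individual_id": iid, "sex": sex,
                         "age_at_obs": float(a), "population": pop,
                         "age_raw": a, "u": u})
    df = pd.DataFrame(rows)
    age_z = (df["age_raw"] - df["age_raw"].mean()) / df["age_raw"].std(ddof=1)
    lin = (slope * age_z + sex_effect * (df["sex"] == "male")
           + df["u"] + rng.normal(0, 0.6, len(df)))
    df["dm"] = np.exp(lin / 4)  # positive score on an arbitrary scale
    df["dm_z"] = (lin - lin.mean()) / lin.std(ddof=1)
    return df.drop(columns=["age_raw", "u"])


class TestAgeSexModel:
    def test_recovers_age_slope(self):
        scores = _score_table(slope=0.5, seed=1)
        res = fit_age_sex_model(scores)
        c = res.coef("age_z")
        assert c["ci_low"] < 0.5 * (res.n_obs and 1)  # CI sane
        assert 0.2 < c["estimate"] < 0.8
        assert c["p"] < 0.01

    def test_null_slope_ci_covers_zero(self):
        scores = _score_table(slope=0.0, seed=2)
        c = fit_age_sex_model(scores).coef("age_z")
        assert c["ci_low"] < 0 < c["ci_high"]

    def test_single_sex_age_only(self):
        scores = _score_table(sexes=("male",), seed=3)
        res = fit_age_sex_model(scores)
        terms = set(res.coefficients["term"])
        assert "age_z" in terms
        assert not any("sex" in t for t in terms)

    def test_no_repeats_uses_ols(self):
        scores = _score_table(visits=1, seed=4)
        res = fit_age_sex_model(scores)
        assert res.random_structure.startswith("none")

    def test_population_fixed_effect_included(self):
        scores = _score_table(seed=5, n_pops=2)
        res = fit_age_sex_model(scores)
        assert any("population" in t for t in res.coefficients["term"])

    def test_scale_equivariance_of_t_stats(self):
        scores = _score_table(slope=0.4, seed=6)
        res1 = fit_age_sex_model(scores)
        scaled = scores.assign(dm_z=scores["dm_z"] * 7.3,
                               dm=scores["dm"] * 7.3)
        res2 = fit_age_sex_model(scaled)
        t1 = res1.coefficients["estimate"] / res1.coefficients["se"]
        t2 = res2.coefficients["estimate"] / res2.coefficients["se"]
        assert np.allclose(t1, t2, rtol=1e-6)

    def test_multi_species_rejected(self):
        scores = _score_table()
        scores.loc[0, "species"] = "spB"
        with pytest.raises(InputError):
            fit_age_sex_model(scores)


def _mass_cohort(n_ids=80, visits=4, quad=-0.05, seed=0, dm_link=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ids):
        iid = f"id{i:03d}"
        sex = "male" if i % 2 else "female"
        u = rng.normal(0, 1.0)
        ages = np.sort(rng.uniform(5, 25, visits))
        dmz = rng.normal(size=visits)
        mass0 = 30 + u + 0.8 * ages[0] + quad * ages[0] ** 2
        masses = [mass0]
        for j in range(1, visits):
            dt = ages[j] - ages[j - 1]
            mid = (ages[j] + ages[j - 1]) / 2
            drift = 0.8 + 2 * quad * mid + dm_link * dmz[j - 1]
            masses.append(masses[-1] + drift * dt + rng.normal(0, 0.1))
        for j in range(visits):
            rows.append({"species": "spA", "individual_id": iid, "sex": sex,
                         "age_at_obs": float(ages[j]), "population": "pop1",
                         "death_age": np.nan, "body_mass": float(masses[j]),
                         "dm_z": float(dmz[j]), "m01": 1.0})
    df = pd.DataFrame(rows)
    cohort = Cohort(df.drop(columns=["dm_z"]), ["m01"])
    scores = df[["species", "individual_id", "age_at_obs", "sex",
                 "population", "dm_z"]].copy()
    scores["dm"] = np.exp(scores["dm_z"] / 4)
    return cohort, scores


class TestMassChangeRate:
    def test_rate_arithmetic(self):
        df = pd.DataFrame({
            "species": ["s"] * 2, "individual_id": ["a"] * 2,
            "sex": ["female"] * 2, "age_at_obs": [10.0, 10.5],
            "population": ["p"] * 2, "body_mass": [10.0, 9.0], "m01": [1.0, 1.0],
        })
        rates = mass_change_rate(Cohort(df, ["m01"]))
        assert len(rates) == 1
        assert rates["mass_change_rate"].iloc[0] == pytest.approx(-2.0)

    def test_single_obs_no_rate(self):
        df = pd.DataFrame({
            "species": ["s"], "individual_id": ["a"], "sex": ["female"],
            "age_at_obs": [10.0], "population": ["p"], "body_mass": [10.0],
            "m01": [1.0],
        })
        assert mass_change_rate(Cohort(df, ["m01"])).empty

    def test_equal_masses_zero_rate(self):
        df = pd.DataFrame({
            "species": ["s"] * 2, "individual_id": ["a"] * 2,
            "sex": ["female"] * 2, "age_at_obs": [10.0, 11.0],
            "population": ["p"] * 2, "body_mass": [7.0, 7.0], "m01": [1.0] * 2,
        })
        rates = mass_change_rate(Cohort(df, ["m01"]))
        assert rates["mass_change_rate"].iloc[0] == 0.0

    def test_last_observation_has_no_rate(self):
        cohort, _ = _mass_cohort(n_ids=10, visits=3)
        rates = mass_change_rate(cohort)
        assert len(rates) == 10 * 2


class TestMassModels:
    def test_negative_quadratic_recovered(self):
        cohort, _ = _mass_cohort(n_ids=100, quad=-0.05, seed=1)
        res = fit_mass_model(cohort)
        c = res.coef("I(age_z ** 2)")
        assert c["estimate"] < 0
        assert c["ci_high"] < 0

    def test_null_dm_effect_covered(self):
        cohort, scores = _mass_cohort(n_ids=80, seed=2, dm_link=0.0)
        res = fit_mass_model(cohort, scores=scores)
        c = res.coef("dm_z")
        assert c["ci_low"] < 0 < c["ci_high"]

    def test_single_sex_drops_sex_terms(self):
        cohort, _ = _mass_cohort(n_ids=40, seed=3)
        cohort.data["sex"] = "female"
        res = fit_mass_model(cohort)
        assert not any("sex" in t for t in res.coefficients["term"])

    def test_mass_change_link_recovered(self):
        cohort, scores = _mass_cohort(n_ids=150, visits=4, seed=4, dm_link=-0.3)
        rates = mass_change_rate(cohort)
        res = fit_mass_change_model(rates, scores)
        c = res.coef("dm_z")
        assert c["ci_low"] < -0.3 < c["ci_high"]
        assert c["estimate"] < -0.1

    def test_mass_change_null(self):
        cohort, scores = _mass_cohort(n_ids=100, seed=5, dm_link=0.0)
        rates = mass_change_rate(cohort)
        c = fit_mass_change_model(rates, scores).coef("dm_z")
        assert c["ci_low"] < 0 < c["ci_high"]

    def test_empty_rates_error(self):
        _, scores = _mass_cohort(n_ids=10, seed=6)
        with pytest.raises(InputError):
            fit_mass_change_model(pd.DataFrame(), scores)


def test_add_fdr_column_monotone_and_off_by_default():
    from dysregkit.models import add_fdr_column
    scores = _score_table(slope=0.4, seed=10)
    res = fit_age_sex_model(scores)
    assert "p_fdr" not in res.coefficients.columns  # unadjusted by default
    out = add_fdr_column(res.coefficients)
    assert (out["p_fdr"] >= out["p"] - 1e-12).all()


def test_forest_plot_writes_file(tmp_path):
    from dysregkit.models import forest_plot
    results = [fit_age_sex_model(_score_table(slope=s, seed=11 + i))
               for i, s in enumerate([0.2, 0.5])]
    results[1].species = "spB"
    path = tmp_path / "forest.png"
    forest_plot(results, term="age_z", path=path)
    assert path.exists()


def test_age_slope_heterogeneity_detects_differences():
    a = _score_table(slope=0.6, seed=7)
    b = _score_table(slope=-0.2, seed=8).assign(species="spB")
    out = age_slope_heterogeneity(pd.concat([a, b], ignore_index=True))
    assert out["heterogeneous"]
    same = pd.concat(
        [a, _score_table(slope=0.6, seed=9).assign(species="spB")],
        ignore_index=True)
    out2 = age_slope_heterogeneity(same)
    assert out2["p"] > 0.001  # no strong signal when slopes match
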