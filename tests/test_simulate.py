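import numpy as np
import pytest

from dysregkit._errors import ConfigurationError
from dysregkit.conservation import patristic_distance_matrix
from dysregkit.simulate import (
    SimConfig, SimTruth, regenerate_and_verify, simulate_cohort,
    simulate_species_params, simulate_tree,
)


class TestSimulateTree:
    def test_two_species_cherry(self):
        tree = simulate_tree(2, seed=0, depth=60.0)
        pdm = patristic_distance_matrix(tree, ["sp01", "sp02"])
        assert pdm.loc["sp01", "sp02"] == pytest.approx(120.0)

    def test_same_seed_identical_newick(self):
        a = simulate_tree(7, seed=42).as_string(schema="newick")
        b = simulate_tree(7, seed=42).as_string(schema="newick")
        assert a == b

    def test_ultrametric(self):
        tree = simulate_tree(11, seed=3, depth=60.0)
        depths = [leaf.distance_from_root()
                  for leaf in tree.leaf_node_iter()]
        assert len(depths) == 11
        assert np.ptp(depths) < 1e-9

    def test_ultrametric_pair_distance_is_twice_divergence(self):
        tree = simulate_tree(5, seed=1, depth=60.0)
        sp = sorted(t.label for t in tree.taxon_namespace)
        pdm = patristic_distance_matrix(tree, sp)
        assert (pdm.to_numpy().max() - 120.0) < 1e-9

    def test_min_species(self):
        with pytest.raises(ConfigurationError):
            simulate_tree(1, seed=0)


class TestSpeciesParams:
    def test_zero_divergence_limit(self):
        tree = simulate_tree(4, seed=0)
        params = simulate_species_params(tree, 5, 0.0, 0.0, seed=1)
        vals = list(params.values())
        for p in vals[1:]:
            np.testing.assert_allclose(p.mean, vals[0].mean, atol=1e-12)
            np.testing.assert_allclose(p.cov, vals[0].cov, atol=1e-12)

    def test_positive_definite_under_perturbation(self):
        tree = simulate_tree(6, seed=2)
        params = simulate_species_params(tree, 8, 0.2, 1.5, seed=3)
        for p in params.values():
            assert np.linalg.eigvalsh(p.cov).min() > 0

    def test_sisters_closer_than_distant_species(self):
        # Brownian motion: expected squared mean distance grows with
        # patristic distance; check on average over seeds
        tree = simulate_tree(6, seed=5, shape="ladder")
        sp = sorted(t.label for t in tree.taxon_namespace)
        pdm = patristic_distance_matrix(tree, sp)
        flat = pdm.where(~np.eye(len(sp), dtype=bool)).stack()
        close_pair = flat.idxmin()
        far_pair = flat.idxmax()
        closer = 0
        for seed in range(60):
            params = simulate_species_params(tree, 6, 0.3, 0.0, seed=seed)
            d_close = np.linalg.norm(params[close_pair[0]].mean
                                     - params[close_pair[1]].mean)
            d_far = np.linalg.norm(params[far_pair[0]].mean
                                   - params[far_pair[1]].mean)
            closer += d_close < d_far
        assert closer > 45  # overwhelmingly more similar


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=9, n_species=3, n_ids=20,
                        hazard_baseline=0.02, beta_dm=0.3)
        c1, t1 = simulate_cohort(cfg)
        c2, t2 = simulate_cohort(cfg)
        assert c1.data.equals(c2.data)
        assert t1.to_json() == t2.to_json()

    def test_zero_hazard_no_deaths(self):
        cfg = SimConfig(seed=1, n_species=2, n_ids=20, hazard_baseline=0.0)
        cohort, truth = simulate_cohort(cfg)
        assert cohort.data["death_age"].isna().all()
        assert all(v is None for v in truth.death_latent.values())

    def test_infeasible_ages_error(self):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, age_range=(1.0, 3.0), maturation_age=5.0)

    def test_single_sex_species_flag(self):
        cfg = SimConfig(seed=2, n_species=3, n_ids=15,
                        single_sex_species="sp01")
        cohort, _ = simulate_cohort(cfg)
        s = cohort.data.groupby("species")["sex"].nunique()
        assert s["sp01"] == 1 and s["sp02"] == 2

    def test_single_visit_species_flag(self):
        cfg = SimConfig(seed=3, n_species=3, n_ids=15,
                        single_visit_species="sp02")
        cohort, _ = simulate_cohort(cfg)
        counts = cohort.data.groupby(["species", "individual_id"]).size()
        assert (counts.loc["sp02"] == 1).all()

    def test_missingness_masks(self):
        cfg = SimConfig(seed=4, n_species=2, n_ids=10, p_markers=4,
                        missingness={"sp01": ["m01", "m02"]})
        cohort, _ = simulate_cohort(cfg)
        sub = cohort.data[cohort.data["species"] == "sp01"]
        assert sub["m03"].isna().all() and sub["m01"].notna().all()
        other = cohort.data[cohort.data["species"] == "sp02"]
        assert other["m03"].notna().all()

    def test_death_age_after_all_observations(self):
        cfg = SimConfig(seed=5, n_species=2, n_ids=50,
                        hazard_baseline=0.05, beta_dm=0.5)
        cohort, _ = simulate_cohort(cfg)
        d = cohort.data.dropna(subset=["death_age"])
        assert (d["death_age"] >= d["age_at_obs"]).all()

    def test_visit_gap_floor(self):
        cfg = SimConfig(seed=6, n_species=2, n_ids=30, mean_visits=4)
        cohort, _ = simulate_cohort(cfg)
        gaps = cohort.data.groupby("individual_id")["age_at_obs"].diff().dropna()
        assert (gaps >= 0.25 - 1e-12).all()

    def test_true_dm_increases_with_age(self):
        # dispersion inflation makes expected deviation grow with age
        cfg = SimConfig(seed=7, n_species=2, n_ids=200, mean_visits=2,
                        age_dispersion_slope=0.5)
        _, truth = simulate_cohort(cfg)
        ages = np.array(truth.visit_truth["age"])
        dm = np.array(truth.visit_truth["true_dm"])
        assert np.corrcoef(ages, dm)[0, 1] > 0.1

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=8, n_species=4, kappa_unused=None) \
            if False else SimConfig(seed=8, n_species=4)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == cfg


class TestDivergenceInvariants:
    @staticmethod
    def _median_offdiag(kappa, seed):
        from dysregkit.conservation import cross_reference_matrix

        cfg = SimConfig(seed=seed, n_species=5, n_ids=200, p_markers=6,
                        mean_visits=1.0, covariance_perturbation=kappa,
                        divergence_scale=0.0, mass=None, tree_shape="ladder")
        cohort, _ = simulate_cohort(cfg)
        crm = cross_reference_matrix(cohort.per_species(), cohort.markers)
        off = crm.values.to_numpy()[~np.eye(5, dtype=bool)]
        return float(np.median(off))

    def test_zero_divergence_offdiagonals_near_one(self):
        assert self._median_offdiag(0.0, seed=31) > 0.9

    def test_kappa_monotonically_decreases_similarity(self):
        grid = [0.0, 0.3, 0.6, 1.0]
        meds = [np.mean([self._median_offdiag(k, seed=40 + s)
                         for s in range(3)]) for k in grid]
        assert all(a > b for a, b in zip(meds, meds[1:]))


class TestRegenerateAndVerify:
    def test_untouched_truth_passes(self):
        cfg = SimConfig(seed=11, n_species=2, n_ids=10)
        _, truth = simulate_cohort(cfg)
        assert regenerate_and_verify(cfg, truth)["passed"]

    def test_perturbed_mean_fails_naming_field(self):
        cfg = SimConfig(seed=11, n_species=2, n_ids=10)
        _, truth = simulate_cohort(cfg)
        truth.species_means["sp01"][0] += 1.0
        report = regenerate_and_verify(cfg, truth)
        assert not report["passed"]
        assert "species_means" in report["first_divergence"]

    def test_wrong_seed_fails(self):
        cfg = SimConfig(seed=11, n_species=2, n_ids=10)
        _, truth = simulate_cohort(cfg)
        cfg2 = SimConfig(seed=12, n_species=2, n_ids=10)
        assert not regenerate_and_verify(cfg2, truth)["passed"]

    def test_truth_json_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=13, n_species=2, n_ids=8)
        _, truth = simulate_cohort(cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SimTruth.from_json(path)
        assert regenerate_and_verify(cfg, back)["passed"]
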