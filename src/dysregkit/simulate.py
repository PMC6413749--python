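"""Synthetic multispecies longitudinal biomarker cohorts with known truth.

Species marker means drift by Brownian motion along a (simulated or
supplied) phylogeny, and species correlation structures diverge by Brownian
motion in log-matrix space, so physiological similarity decays with
patristic distance.  Within species, individuals carry a persistent random
offset, and residual dispersion inflates with age — so the true multivariate
deviation from the species centroid grows with age, which is exactly the
signal the scoring pipeline should recover.  Mortality follows a Gompertz
hazard multiplied by exp(beta_dm * true standardized deviation); body mass
follows a quadratic age trajectory whose increments can be tied to the
deviation score.

Everything is driven by a single integer seed, and the recorded truth can be
regenerated bit-identically from the config.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError
from .cohort_io import Cohort
from .scoring import mahalanobis


# --------------------------------------------------------------------------
# configuration


@dataclass
class MassParams:
    intercept: float = 30.0     # kg at age 0 on the latent trajectory
    age_lin: float = 0.6        # kg / year
    age_quad: float = -0.02     # kg / year^2  (negative -> old-age decline)
    dm_rate_slope: float = 0.0  # kg / year per sd of true dm_z
    id_sd: float = 2.0          # individual intercept sd, kg
    rate_noise_sd: float = 0.5  # diffusion sd of mass increments, kg / sqrt(yr)


@dataclass
class SimConfig:
    seed: int
    n_species: int = 5
    tree_newick: str | None = None   # None -> simulate a tree
    tree_depth: float = 60.0
    tree_shape: str = "coalescent"   # or "ladder" (see simulate_tree)
    p_markers: int = 8
    n_ids: int = 100                 # int, or dict species -> int
    mean_visits: float = 3.0
    visit_dispersion: float = 1.0    # gamma-Poisson over-dispersion of visit counts
    visit_gap_mean: float = 1.0      # mean extra gap beyond the 0.25 y floor
    age_range: tuple[float, float] = (5.0, 30.0)
    maturation_age: float = 5.0
    divergence_scale: float = 0.1    # Brownian drift of species means (sd units)
    covariance_perturbation: float = 0.0  # log-matrix Brownian rate (kappa)
    age_dispersion_slope: float = 0.3     # gamma: dispersion inflation per age sd
    sex_offset_scale: float = 0.3    # male marker offset, in marker-sd units
    frailty_scale: float = 0.5       # individual offset sd, in marker-sd units
    hazard_baseline: float = 0.0     # h0; 0 disables mortality
    gompertz_b: float = 0.08
    beta_dm: float = 0.0             # log hazard ratio per sd of true dm_z
    follow_up: float = 3.0           # years of risk after the last visit
    prob_unknown_fate: float = 0.0   # confirmed deaths relabeled unknown
    n_populations: int = 1
    mass: MassParams | None = field(default_factory=MassParams)
    single_sex_species: str | None = None
    single_visit_species: str | None = None
    missingness: dict[str, list[str]] | None = None  # species -> available markers

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("simulation requires a seed")
        if self.n_species < 2:
            raise ConfigurationError("need at least 2 species")
        if self.mean_visits < 1:
            raise ConfigurationError("mean_visits must be >= 1")
        lo, hi = self.age_range
        if hi <= lo or hi < self.maturation_age:
            raise ConfigurationError("age_range infeasible for maturation age")
        for name in ("divergence_scale", "covariance_perturbation",
                     "age_dispersion_slope", "hazard_baseline", "frailty_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.prob_unknown_fate <= 1:
            raise ConfigurationError("prob_unknown_fate must be in [0, 1]")
        if isinstance(self.mass, dict):
            self.mass = MassParams(**self.mass)
        if isinstance(self.age_range, list):
            self.age_range = tuple(self.age_range)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        payload["age_range"] = list(self.age_range)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# --------------------------------------------------------------------------
# tree and species parameters


def simulate_tree(n_species: int, seed, depth: float = 60.0,
                  labels: list[str] | None = None,
                  shape: str = "coalescent") -> dendropy.Tree:
    """Random ultrametric tree with fixed root depth.

    ``shape='coalescent'``: lineages merge in random pairs at exponentially
    spaced times rescaled so the root sits at ``depth`` (million years by
    convention).  ``shape='ladder'``: a caterpillar topology with evenly
    spread (jittered) divergence times, giving pairwise distances that span
    the full range from shallow to deep — useful when a well-resolved
    distance gradient is wanted.
    """
    if n_species < 2:
        raise ConfigurationError("need at least 2 species for a tree")
    if shape not in ("coalescent", "ladder"):
        raise ConfigurationError(f"unknown tree shape {shape!r}")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    if shape == "ladder":
        base = np.linspace(depth / (n_species - 1), depth, n_species - 1)
        jitter = rng.uniform(0.6, 1.4, n_species - 1)
        times = np.sort(base * jitter)
        times = times * (depth / times[-1])
    else:
        times = np.cumsum(rng.exponential(1.0, n_species - 1))
        times = times * (depth / times[-1])
    active = [(lab, 0.0) for lab in labels]
    for t in times:
        if shape == "ladder":
            i, j = 0, 1  # grow a caterpillar: always extend the first clade
            if len(active) == n_species:  # first merge pairs two tips
                i, j = 0, 1
        else:
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (sa, ha), (sb, hb) = active[i], active[j]
        merged = (f"({sa}:{float(t - ha)!r},{sb}:{float(t - hb)!r})", float(t))
        active = [a for k, a in enumerate(active) if k not in (i, j)]
        active.insert(0, merged)
    newick = active[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


def _logm_spd(A: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(A)
    return (v * np.log(w)) @ v.T


def _expm_sym(A: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(A)
    return (v * np.exp(w)) @ v.T


def _cov2corr(C: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _random_correlation(p: int, rng, strength: float = 0.6) -> np.ndarray:
    A = rng.normal(size=(p, p + 3))
    R = _cov2corr(A @ A.T)
    return _cov2corr(strength * R + (1 - strength) * np.eye(p))


@dataclass
class SpeciesParams:
    mean: np.ndarray
    cov: np.ndarray


def simulate_species_params(
    tree: dendropy.Tree,
    p_markers: int,
    divergence_scale: float,
    covariance_perturbation: float,
    seed,
) -> dict[str, SpeciesParams]:
    """Evolve species marker means and covariances along the tree.

    Means: Brownian motion with per-unit-branch-length sd
    ``divergence_scale`` (in units of the marker's base sd).  Covariances:
    variances are held at the base values while the correlation matrix walks
    through log-matrix space (symmetric Brownian increments with per-entry
    per-unit-length sd ``0.05 * covariance_perturbation``), guaranteeing a
    positive-definite, correlation-valued result whose divergence grows with
    path length.  Zero scales reproduce the base parameters exactly.
    """
    rng = np.random.default_rng(seed)
    p = p_markers
    base_mean = rng.uniform(10.0, 50.0, size=p)
    base_sd = 0.15 * base_mean
    R0 = _random_correlation(p, rng)
    logR0 = _logm_spd(R0)
    mean_rate = divergence_scale * base_sd
    cov_rate = 0.05 * covariance_perturbation

    out: dict[str, SpeciesParams] = {}
    state = {id(tree.seed_node): (base_mean.copy(), np.zeros((p, p)))}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_mean, parent_E = state[id(node)]
        else:
            parent_mean, parent_E = state[id(node.parent_node)]
            length = float(node.edge.length or 0.0)
            mean = parent_mean + rng.normal(size=p) * mean_rate * math.sqrt(length)
            A = rng.normal(size=(p, p)) * cov_rate * math.sqrt(length)
            E = parent_E + (A + A.T) / 2.0
            state[id(node)] = (mean, E)
            parent_mean, parent_E = mean, E
        if node.is_leaf():
            R = _cov2corr(_expm_sym(logR0 + parent_E)) if cov_rate > 0 else R0
            cov = np.outer(base_sd, base_sd) * R
            out[node.taxon.label] = SpeciesParams(mean=parent_mean.copy(), cov=cov)
    return out


# --------------------------------------------------------------------------
# cohort generation


@dataclass
class SimTruth:
    """Ground truth recorded during generation; regenerable from the seed."""

    seed: int
    species_means: dict[str, list[float]]
    species_cov: dict[str, list[list[float]]]
    sex_offsets: dict[str, list[float]]
    gamma: float
    beta_dm: float
    frailty_scale: float
    mass: dict | None
    visit_truth: dict  # parallel lists: individual_id, species, age, true_dm, true_dm_z
    death_latent: dict[str, float | None]
    newick: str

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimTruth":
        from .transform import load_json_source

        return cls(**load_json_source(source))


def _gompertz_cumhaz(h0: float, b: float, t1: float, t2: float) -> float:
    if b == 0:
        return h0 * (t2 - t1)
    return h0 / b * (math.exp(b * t2) - math.exp(b * t1))


def _gompertz_invert(h0: float, b: float, t1: float, target: float) -> float:
    """Age t at which cumulative hazard from t1 reaches target."""
    if b == 0:
        return t1 + target / h0
    return math.log(math.exp(b * t1) + target * b / h0) / b


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Generate a longitudinal multispecies cohort plus its ground truth."""
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_params, s_cohort = ss.spawn(3)

    if config.tree_newick is not None:
        tree = dendropy.Tree.get(data=config.tree_newick, schema="newick")
    else:
        tree = simulate_tree(config.n_species, s_tree, depth=config.tree_depth,
                             shape=config.tree_shape)
    species = sorted(t.label for t in tree.taxon_namespace)
    if config.tree_newick is not None and len(species) != config.n_species:
        raise ConfigurationError("tree tip count does not match n_species")

    params = simulate_species_params(
        tree, config.p_markers, config.divergence_scale,
        config.covariance_perturbation, s_params,
    )
    markers = [f"m{i + 1:02d}" for i in range(config.p_markers)]
    rng = np.random.default_rng(s_cohort)
    lo, hi = config.age_range
    age_mid, age_sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    tau = config.frailty_scale
    gamma = config.age_dispersion_slope
    mp = config.mass

    rows: list[dict] = []
    truth_rows = {"individual_id": [], "species": [], "age": [],
                  "true_dm": [], "true_dm_z": []}
    sex_offsets: dict[str, list[float]] = {}
    death_latent: dict[str, float | None] = {}

    for sp in species:
        par = params[sp]
        L = np.linalg.cholesky(par.cov)
        base_sd = np.sqrt(np.diag(par.cov))
        sex_off = rng.normal(size=config.p_markers) * config.sex_offset_scale * base_sd
        sex_offsets[sp] = sex_off.tolist()
        cov_tot = (1.0 + tau ** 2) * par.cov
        n_ids = (config.n_ids[sp] if isinstance(config.n_ids, dict)
                 else config.n_ids)
        single_sex = sp == config.single_sex_species
        single_visit = sp == config.single_visit_species

        sp_visits: list[dict] = []  # per-individual staging
        for i in range(n_ids):
            iid = f"{sp}_{i:04d}"
            sex = "male" if single_sex else ("male" if rng.integers(2) else "female")
            pop = f"pop{1 + i % config.n_populations}"
            if single_visit:
                n_visits = 1
            elif config.visit_dispersion > 0 and config.mean_visits > 1:
                lam = rng.gamma(
                    (config.mean_visits - 1) / config.visit_dispersion,
                    config.visit_dispersion,
                )
                n_visits = 1 + int(rng.poisson(lam))
            else:
                n_visits = 1 + int(rng.poisson(max(config.mean_visits - 1, 0.0)))
            first = rng.uniform(lo, hi)
            gaps = 0.25 + rng.exponential(config.visit_gap_mean, n_visits - 1)
            ages = first + np.concatenate([[0.0], np.cumsum(gaps)])
            u = (L @ rng.normal(size=config.p_markers)) * tau
            x_rows, dms = [], []
            for age in ages:
                scale = max(1.0 + gamma * (age - age_mid) / age_sd, 0.2)
                eps = (L @ rng.normal(size=config.p_markers)) * scale
                x = par.mean + (sex_off if sex == "male" else 0.0) + u + eps
                x_rows.append(x)
                dms.append(mahalanobis(x, par.mean, cov_tot))
            sp_visits.append({
                "iid": iid, "sex": sex, "pop": pop, "ages": ages,
                "x": np.array(x_rows), "dm": np.array(dms),
            })

        # standardize true dm within species across all generated visits
        all_dm = np.concatenate([v["dm"] for v in sp_visits])
        dm_mean, dm_sd = all_dm.mean(), all_dm.std(ddof=1)
        for v in sp_visits:
            v["dm_z"] = (v["dm"] - dm_mean) / dm_sd

        for v in sp_visits:
            ages, dm_z = v["ages"], v["dm_z"]
            # mortality: piecewise Gompertz with the score as a step covariate
            death = None
            if config.hazard_baseline > 0:
                window_end = ages[-1] + config.follow_up
                bounds = list(ages) + [window_end]
                target = rng.exponential(1.0)
                acc = 0.0
                for j in range(len(ages)):
                    h0j = config.hazard_baseline * math.exp(
                        config.beta_dm * dm_z[j])
                    seg = _gompertz_cumhaz(h0j, config.gompertz_b,
                                           bounds[j], bounds[j + 1])
                    if acc + seg >= target:
                        death = _gompertz_invert(h0j, config.gompertz_b,
                                                 bounds[j], target - acc)
                        break
                    acc += seg
            death_latent[v["iid"]] = death
            confirmed = death is not None and rng.random() >= config.prob_unknown_fate
            keep = (v["ages"] < death) if death is not None else np.ones(
                len(ages), dtype=bool)
            keep_idx = np.flatnonzero(keep)
            if len(keep_idx) == 0:
                keep_idx = np.array([0])  # first visit precedes death by construction

            # body mass trajectory on the retained visits
            masses = None
            if mp is not None:
                a0 = ages[keep_idx[0]]
                m0 = (mp.intercept + mp.age_lin * a0 + mp.age_quad * a0 ** 2
                      + rng.normal() * mp.id_sd)
                masses = [m0]
                for k in range(1, len(keep_idx)):
                    a_prev, a_cur = ages[keep_idx[k - 1]], ages[keep_idx[k]]
                    dt = a_cur - a_prev
                    mid = (a_prev + a_cur) / 2.0
                    drift = (mp.age_lin + 2 * mp.age_quad * mid
                             + mp.dm_rate_slope * dm_z[keep_idx[k - 1]])
                    masses.append(masses[-1] + drift * dt
                                  + rng.normal() * mp.rate_noise_sd * math.sqrt(dt))
                masses = [max(m, 0.1) for m in masses]

            for pos, j in enumerate(keep_idx):
                row = {
                    "species": sp, "individual_id": v["iid"], "sex": v["sex"],
                    "age_at_obs": float(ages[j]), "population": v["pop"],
                    "death_age": float(death) if confirmed else np.nan,
                    "body_mass": float(masses[pos]) if masses is not None else np.nan,
                }
                for mname, val in zip(markers, v["x"][j]):
                    row[mname] = float(val)
                rows.append(row)
                truth_rows["individual_id"].append(v["iid"])
                truth_rows["species"].append(sp)
                truth_rows["age"].append(float(ages[j]))
                truth_rows["true_dm"].append(float(v["dm"][j]))
                truth_rows["true_dm_z"].append(float(dm_z[j]))

    data = pd.DataFrame(rows)
    if config.missingness:
        for sp, available in config.missingness.items():
            hidden = [m for m in markers if m not in available]
            data.loc[data["species"] == sp, hidden] = np.nan

    cohort = Cohort(data, markers)
    truth = SimTruth(
        seed=config.seed,
        species_means={sp: params[sp].mean.tolist() for sp in species},
        species_cov={sp: params[sp].cov.tolist() for sp in species},
        sex_offsets=sex_offsets,
        gamma=gamma,
        beta_dm=config.beta_dm,
        frailty_scale=tau,
        mass=asdict(mp) if mp is not None else None,
        visit_truth=truth_rows,
        death_latent=death_latent,
        newick=tree.as_string(schema="newick"),
    )
    return cohort, truth


def regenerate_and_verify(config: SimConfig, truth: SimTruth) -> dict:
    """Regenerate from the config seed and compare against recorded truth."""
    _, fresh = simulate_cohort(config)
    checks = [
        ("seed", truth.seed, fresh.seed),
        ("newick", truth.newick, fresh.newick),
        ("species_means", truth.species_means, fresh.species_means),
        ("species_cov", truth.species_cov, fresh.species_cov),
        ("sex_offsets", truth.sex_offsets, fresh.sex_offsets),
        ("visit_truth", truth.visit_truth, fresh.visit_truth),
        ("death_latent", truth.death_latent, fresh.death_latent),
    ]
    for name, a, b in checks:
        if a != b:
            detail = name
            if isinstance(a, dict) and isinstance(b, dict):
                for key in a:
                    if a.get(key) != b.get(key):
                        detail = f"{name}[{key}]"
                        break
            return {"passed": False, "first_divergence": detail}
    return {"passed": True, "first_divergence": None}
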