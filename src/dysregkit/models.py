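"""Per-species longitudinal association models.

Mixed models of the standardized dysregulation score on age and sex, body
mass models (optionally with the score as a predictor), and models of
subsequent mass-change rate.  Model fitting is delegated to statsmodels
(REML mixed models / OLS); the bespoke content here is design-matrix
assembly, standardization, random-structure selection, and reporting.

Population (research center) enters as a fixed categorical intercept when a
species spans more than one population; individual enters as a random
intercept (plus a random age slope for mass models) whenever repeated
observations exist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from ._errors import FitError, InputError

logger = logging.getLogger(__name__)

_JOIN_KEYS = ["species", "individual_id", "age_at_obs"]


@dataclass
class ModelResult:
    species: str
    formula: str
    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p
    random_structure: str
    n_obs: int
    n_ids: int
    dep_transformed: bool = False

    def __post_init__(self) -> None:
        bad = self.coefficients["ci_low"] > self.coefficients["ci_high"]
        if bad.any():
            raise FitError("confidence interval bounds out of order")
        if self.n_obs < self.n_ids:
            raise FitError("n_obs < n_ids")

    def coef(self, term: str) -> pd.Series:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out.insert(0, "species", self.species)
        out["formula"] = self.formula
        out["random_structure"] = self.random_structure
        out["n_obs"] = self.n_obs
        out["n_ids"] = self.n_ids
        out["dep_transformed"] = self.dep_transformed
        return out


def _zscore(v: pd.Series) -> pd.Series:
    sd = v.std(ddof=1)
    if not sd > 0:
        raise FitError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def _prepare(df: pd.DataFrame, require_sex: bool) -> tuple[pd.DataFrame, bool]:
    """Shared design prep: drop unknown sex, code sex_male, standardize age.

    Returns the frame and whether sex terms are usable (>= 2 sexes present).
    """
    d = df.loc[df["sex"].isin(["female", "male"])].copy()
    if d.empty:
        raise InputError("no rows with known sex")
    d["sex_male"] = (d["sex"] == "male").astype(float)
    d["age_z"] = _zscore(d["age_at_obs"])
    two_sexes = d["sex_male"].nunique() > 1
    if require_sex and not two_sexes:
        logger.info("single-sex data: sex terms dropped")
    return d, two_sexes


def _repeated_share(d: pd.DataFrame) -> float:
    counts = d.groupby("individual_id").size()
    return float((counts >= 2).mean())


def _coef_table(params, bse, ci, pvalues) -> pd.DataFrame:
    return pd.DataFrame({
        "term": list(params.index),
        "estimate": params.to_numpy(),
        "se": bse.loc[params.index].to_numpy(),
        "ci_low": ci.loc[params.index, 0].to_numpy(),
        "ci_high": ci.loc[params.index, 1].to_numpy(),
        "p": pvalues.loc[params.index].to_numpy(),
    })


def _fit_lmm(formula: str, d: pd.DataFrame, re_formula: str | None,
             use_id_re: bool) -> tuple[pd.DataFrame, str, object]:
    """Fit a mixed model (or OLS when no ID random effect is warranted)."""
    if use_id_re:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, d, groups=d["individual_id"],
                                re_formula=re_formula)
            try:
                res = model.fit(reml=True)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"mixed model failed: {exc}") from exc
        if not getattr(res, "converged", True):
            logger.warning("mixed model did not fully converge: %s", formula)
        table = _coef_table(res.fe_params, res.bse_fe,
                            res.conf_int().loc[res.fe_params.index],
                            res.pvalues.loc[res.fe_params.index])
        structure = f"ID random intercept ({re_formula or '1'})"
    else:
        res = smf.ols(formula, d).fit()
        table = _coef_table(res.params, res.bse, res.conf_int(), res.pvalues)
        structure = "none (no repeated observations)"
    return table, structure, res


def _maybe_log_dep(d: pd.DataFrame, ycol: str, res, skew_threshold: float):
    """Check residual skewness; return a log-transformed dependent or None."""
    resid = np.asarray(res.resid, dtype=float)
    if abs(stats.skew(resid)) <= skew_threshold:
        return None
    y = d[ycol]
    if (y <= 0).any():
        logger.warning("residual skew high but %s has nonpositive values; "
                       "log transform skipped", ycol)
        return None
    return np.log(y)


def fit_age_sex_model(scores: pd.DataFrame, skew_threshold: float = 1.0,
                      repeat_floor: float = 0.01) -> ModelResult:
    """Mixed model of dm_z on standardized age, sex and their interaction.

    Single-sex species get an age-only model.  The ID random intercept is
    omitted when repeated observations are absent for >= 99% of individuals;
    a multi-population species gets fixed population intercepts.  If model
    residuals are strongly skewed the dependent is refit as the standardized
    log score (transform applied before re-scaling), and flagged.
    """
    sp_all = scores["species"].unique()
    if len(sp_all) != 1:
        raise InputError("fit one species at a time")
    d, two_sexes = _prepare(scores, require_sex=True)
    d = d.copy()
    d["y"] = _zscore(d["dm_z"])  # re-standardize after any row drops

    rhs = "age_z * sex_male" if two_sexes else "age_z"
    if d["population"].nunique() > 1:
        rhs += " + C(population)"
    formula = f"y ~ {rhs}"
    use_id_re = _repeated_share(d) > repeat_floor

    table, structure, res = _fit_lmm(formula, d, None, use_id_re)
    dep_transformed = False
    logged = _maybe_log_dep(d, "dm", res, skew_threshold)
    if logged is not None:
        d["y"] = _zscore(logged)
        table, structure, res = _fit_lmm(formula, d, None, use_id_re)
        dep_transformed = True

    return ModelResult(
        species=str(sp_all[0]), formula=formula, coefficients=table,
        random_structure=structure, n_obs=len(d),
        n_ids=d["individual_id"].nunique(), dep_transformed=dep_transformed,
    )


def mass_change_rate(cohort) -> pd.DataFrame:
    """Subsequent mass-change rate (kg/year) per observation.

    For consecutive observations of an individual, the rate attached to the
    earlier one is (next mass - current mass) / (age gap).  The last
    observation per individual gets no rate; nonpositive age gaps are
    skipped.
    """
    d = cohort.data.loc[cohort.data["body_mass"].notna()].copy()
    d = d.sort_values(["individual_id", "age_at_obs"], kind="stable")
    rows = []
    for _id, grp in d.groupby("individual_id", sort=False):
        ages = grp["age_at_obs"].to_numpy()
        mass = grp["body_mass"].to_numpy()
        for i in range(len(grp) - 1):
            gap = ages[i + 1] - ages[i]
            if gap <= 0:
                logger.warning("nonpositive age gap for %s at age %s; skipped",
                               _id, ages[i])
                continue
            row = grp.iloc[i][["species", "individual_id", "sex", "age_at_obs",
                               "population", "body_mass"]].to_dict()
            row["mass_change_rate"] = (mass[i + 1] - mass[i]) / gap
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["species", "individual_id", "sex", "age_at_obs",
                       "population", "body_mass", "mass_change_rate"],
    )


def fit_mass_model(cohort, scores: pd.DataFrame | None = None,
                   skew_threshold: float = 1.0,
                   repeat_floor: float = 0.01) -> ModelResult:
    """Body mass on age + age^2 + sex + age:sex (+ dm_z when supplied).

    Random intercept and random age slope per individual; fixed population
    intercepts when applicable.  Mass is log-transformed (and flagged) if
    residuals are strongly skewed.
    """
    d = cohort.data.loc[cohort.data["body_mass"].notna()].copy()
    if d.empty:
        raise InputError("no body-mass observations")
    if scores is not None:
        d = d.merge(scores[_JOIN_KEYS + ["dm_z"]], on=_JOIN_KEYS)
        if d.empty:
            raise InputError("no rows with both mass and scores")
    d, two_sexes = _prepare(d, require_sex=True)
    d["y"] = d["body_mass"]

    terms = ["age_z", "I(age_z ** 2)"]
    if two_sexes:
        terms += ["sex_male", "age_z:sex_male"]
    if scores is not None:
        terms.append("dm_z")
    if d["population"].nunique() > 1:
        terms.append("C(population)")
    formula = "y ~ " + " + ".join(terms)
    use_id_re = _repeated_share(d) > repeat_floor
    re_formula = "1 + age_z" if use_id_re else None

    table, structure, res = _fit_lmm(formula, d, re_formula, use_id_re)
    dep_transformed = False
    logged = _maybe_log_dep(d, "body_mass", res, skew_threshold)
    if logged is not None:
        d["y"] = logged
        table, structure, res = _fit_lmm(formula, d, re_formula, use_id_re)
        dep_transformed = True

    return ModelResult(
        species=str(d["species"].iloc[0]), formula=formula, coefficients=table,
        random_structure=structure, n_obs=len(d),
        n_ids=d["individual_id"].nunique(), dep_transformed=dep_transformed,
    )


def fit_mass_change_model(rates: pd.DataFrame, scores: pd.DataFrame,
                          repeat_floor: float = 0.01) -> ModelResult:
    """Mass-change rate on sex, age, dm_z and their pairwise interactions."""
    if rates.empty:
        raise InputError("empty rate table")
    d = rates.merge(scores[_JOIN_KEYS + ["dm_z"]], on=_JOIN_KEYS)
    if d.empty:
        raise InputError("no matched rate/score rows")
    d, two_sexes = _prepare(d, require_sex=True)
    d["y"] = d["mass_change_rate"]

    terms = ["age_z", "dm_z", "age_z:dm_z"]
    if two_sexes:
        terms += ["sex_male", "sex_male:age_z", "sex_male:dm_z"]
    if d["population"].nunique() > 1:
        terms.append("C(population)")
    formula = "y ~ " + " + ".join(terms)
    use_id_re = _repeated_share(d) > repeat_floor
    table, structure, _res = _fit_lmm(formula, d, None, use_id_re)

    return ModelResult(
        species=str(d["species"].iloc[0]), formula=formula, coefficients=table,
        random_structure=structure, n_obs=len(d),
        n_ids=d["individual_id"].nunique(),
    )


def age_slope_heterogeneity(scores: pd.DataFrame) -> dict:
    """Diagnostic: do species differ in the dm_z ~ age slope?

    Pooled OLS with species x age interaction, F-test on the interaction
    block.  A significant result supports fitting species separately (the
    default throughout this package).
    """
    d = scores.copy()
    d["age_z"] = d.groupby("species")["age_at_obs"].transform(_zscore)
    full = smf.ols("dm_z ~ age_z * C(species)", d).fit()
    reduced = smf.ols("dm_z ~ age_z + C(species)", d).fit()
    f, p, df = full.compare_f_test(reduced)
    return {"f_stat": float(f), "p": float(p), "df_diff": float(df),
            "heterogeneous": bool(p < 0.05)}


def add_fdr_column(tables: pd.DataFrame, p_col: str = "p",
                   out_col: str = "p_fdr") -> pd.DataFrame:
    """Optional Benjamini–Hochberg column across a stacked coefficient table.

    Off by default everywhere: headline outputs carry unadjusted p-values,
    with the usual one-in-twenty caveat left to the reader.
    """
    from statsmodels.stats.multitest import multipletests

    out = tables.copy()
    mask = out[p_col].notna()
    out[out_col] = np.nan
    if mask.any():
        out.loc[mask, out_col] = multipletests(
            out.loc[mask, p_col], method="fdr_bh")[1]
    return out


def forest_plot(results: list[ModelResult], term: str = "age_z", path=None):
    """Minimal forest plot of one coefficient across species (95% CI bars)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = []
    for r in results:
        try:
            c = r.coef(term)
        except KeyError:
            continue
        rows.append((r.species, c["estimate"], c["ci_low"], c["ci_high"]))
    fig, ax = plt.subplots(figsize=(5, 0.4 * max(len(rows), 4) + 1))
    for i, (sp, est, lo, hi) in enumerate(rows):
        ax.plot([lo, hi], [i, i], "-", color="0.3")
        ax.plot(est, i, "o", color="C0")
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r[0] for r in rows])
    ax.set_xlabel(f"effect of {term} (95% CI)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
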