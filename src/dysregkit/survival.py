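"""Counting-process coding of longitudinal scores and Cox mortality models.

Each observation becomes a risk interval starting at the observation age and
ending at the next observation age if one exists, else at the confirmed
death age, else 0.25 years later (the minimum inter-observation time in the
source registry).  The event indicator is 1 only on the final observation of
an individual with a confirmed death.  Models use age as the timescale and
treat the score as a time-dependent covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter

from ._errors import DataError, FitError, InputError

logger = logging.getLogger(__name__)

DEFAULT_GAP = 0.25

INTERVAL_COLUMNS = ["individual_id", "start_age", "stop_age", "event",
                    "dm_z", "sex", "population"]


def code_intervals(
    scores: pd.DataFrame,
    death_ages: dict[str, float] | pd.Series | None = None,
    gap: float = DEFAULT_GAP,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Convert per-observation scores into (start, stop, event] risk intervals.

    Stop-age precedence per observation: next observation age, then confirmed
    death age, then ``start + gap``.  Duplicate ages within an individual are
    shifted forward by 1e-6 years with a warning; a death age before the last
    observation is a data error.
    """
    if scores.empty:
        raise InputError("empty score table")
    if death_ages is None:
        death_ages = {}
    elif isinstance(death_ages, pd.Series):
        death_ages = death_ages.to_dict()
    else:
        death_ages = dict(death_ages)
    covariates = covariates if covariates is not None else ["dm_z", "sex"]
    d = scores.sort_values(["individual_id", "age_at_obs"], kind="stable")

    rows = []
    for _id, grp in d.groupby("individual_id", sort=False):
        ages = grp["age_at_obs"].to_numpy(dtype=float).copy()
        for i in range(1, len(ages)):
            if ages[i] <= ages[i - 1]:
                logger.warning("duplicate age for %s at %.6g; shifted by 1e-6",
                               _id, ages[i])
                ages[i] = ages[i - 1] + 1e-6
        death = death_ages.get(_id)
        if death is not None and np.isnan(death):
            death = None
        if death is not None and death < ages[-1]:
            raise DataError(
                f"death age {death} before last observation {ages[-1]} "
                f"for individual {_id!r}"
            )
        for i in range(len(ages)):
            start = ages[i]
            last = i == len(ages) - 1
            if not last:
                stop, event = ages[i + 1], 0
            elif death is not None:
                stop = death if death > start else start + 1e-6
                event = 1
            else:
                stop, event = start + gap, 0
            row = {"individual_id": _id, "start_age": start, "stop_age": stop,
                   "event": event, "population": grp.iloc[i].get("population")}
            for cov in covariates:
                row[cov] = grp.iloc[i][cov]
            rows.append(row)
    out = pd.DataFrame(rows)
    return out[["individual_id", "start_age", "stop_age", "event",
                *covariates, "population"]]


@dataclass
class CoxResult:
    hr_table: pd.DataFrame  # term, hr, ci_low, ci_high, p, coef, se
    n_ids: int
    n_intervals: int
    n_events: int
    interaction_dropped: bool = False
    strata: str | None = None

    def hr(self, term: str) -> pd.Series:
        row = self.hr_table.loc[self.hr_table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def _design(intervals: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    d = intervals.copy()
    if "sex" in terms:
        d = d.loc[d["sex"].isin(["female", "male"])].copy()
        d["sex_male"] = (d["sex"] == "male").astype(float)
    return d


def fit_cox(
    intervals: pd.DataFrame,
    terms: tuple[str, ...] = ("dm_z", "sex"),
    center_effect: str = "none",
    interaction_screen: bool = True,
    screen_alpha: float = 0.05,
) -> CoxResult:
    """Cox proportional-hazards fit on counting-process intervals.

    Partial likelihood with Efron tie handling (lifelines default).  When
    both the score and sex are present, their interaction is screened first
    and dropped if non-significant (the prespecified rule); with
    ``center_effect='random'`` and more than one population, the baseline
    hazard is stratified by population as the available stand-in for a shared
    frailty term.
    """
    n_events = int(intervals["event"].sum())
    if n_events == 0:
        raise FitError("no events: cannot fit a Cox model")
    d = _design(intervals, list(terms))
    cols = [t if t != "sex" else "sex_male" for t in terms]
    single_sex = "sex_male" in cols and d["sex_male"].nunique() < 2
    if single_sex:
        cols = [c for c in cols if c != "sex_male"]
        logger.info("single-sex data: sex term dropped from Cox model")
    if not cols:
        raise FitError("no usable covariates")

    strata = None
    if center_effect == "random" and d["population"].nunique() > 1:
        strata = "population"

    interaction_dropped = False
    use_cols = list(cols)
    if interaction_screen and "dm_z" in cols and "sex_male" in cols:
        d["dm_z_x_sex_male"] = d["dm_z"] * d["sex_male"]
        res_full = _fit_ctv(d, cols + ["dm_z_x_sex_male"], strata)
        p_int = float(res_full.summary.loc["dm_z_x_sex_male", "p"])
        if p_int >= screen_alpha:
            interaction_dropped = True
        else:
            use_cols = cols + ["dm_z_x_sex_male"]

    res = _fit_ctv(d, use_cols, strata)
    summ = res.summary
    table = pd.DataFrame({
        "term": summ.index,
        "coef": summ["coef"].to_numpy(),
        "se": summ["se(coef)"].to_numpy(),
        "hr": summ["exp(coef)"].to_numpy(),
        "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
        "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    return CoxResult(
        hr_table=table,
        n_ids=d["individual_id"].nunique(),
        n_intervals=len(d),
        n_events=int(d["event"].sum()),
        interaction_dropped=interaction_dropped,
        strata=strata,
    )


def _fit_ctv(d: pd.DataFrame, cols: list[str], strata: str | None):
    keep = ["individual_id", "start_age", "stop_age", "event", *cols]
    if strata:
        keep.append(strata)
    frame = d[keep].dropna()
    if frame["event"].sum() == 0:
        raise FitError("no events after row drops")
    ctv = CoxTimeVaryingFitter()
    try:
        ctv.fit(
            frame,
            id_col="individual_id",
            start_col="start_age",
            stop_col="stop_age",
            event_col="event",
            strata=strata,
            show_progress=False,
        )
    except Exception as exc:
        raise FitError(f"Cox fit failed: {exc}") from exc
    return ctv


def check_interval_partition(intervals: pd.DataFrame, tol: float = 1e-9) -> None:
    """Validate the per-individual interval invariants; raise on violation."""
    for _id, grp in intervals.groupby("individual_id"):
        g = grp.sort_values("start_age")
        if not (g["stop_age"].to_numpy() > g["start_age"].to_numpy()).all():
            raise DataError(f"non-positive interval for {_id!r}")
        starts = g["start_age"].to_numpy()[1:]
        stops = g["stop_age"].to_numpy()[:-1]
        if not np.allclose(starts, stops, atol=tol):
            raise DataError(f"gap or overlap in intervals for {_id!r}")
        ev = g["event"].to_numpy()
        if ev.sum() > 1 or (ev.sum() == 1 and ev[-1] != 1):
            raise DataError(f"event coding invalid for {_id!r}")
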