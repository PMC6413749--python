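"""Mahalanobis dysregulation scores against a reference population.

The score of an observation x is sqrt((x - mu)' S^-1 (x - mu)) where mu and S
are the mean vector and covariance matrix of the reference population on the
transformed, standardized scale.  S is inverted implicitly through a Cholesky
solve; ill-conditioned S is repaired by minimal diagonal shrinkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from ._errors import ConditioningError, DataError, InputError
from .transform import apply_spec

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "species", "individual_id", "sex", "age_at_obs", "population",
    "dm", "dm_z", "reference_id",
]


@dataclass
class Moments:
    mu: np.ndarray
    S: np.ndarray
    condition_number: float
    shrinkage: float  # lambda actually applied (0 when none needed)

    def __iter__(self):  # allow ``mu, S = estimate_moments(...)``
        return iter((self.mu, self.S))


def _shrink(S: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * S + lam * np.diag(np.diag(S))


def estimate_moments(
    reference: np.ndarray | pd.DataFrame,
    cond_threshold: float = 1e8,
) -> Moments:
    """Column means and n-1 sample covariance of a standardized reference.

    If the covariance condition number exceeds ``cond_threshold``, the minimal
    diagonal shrinkage ``S <- (1-lam) S + lam diag(S)`` restoring it is found
    by bisection.  Fully shrunk-but-still-singular matrices raise.
    """
    Z = np.asarray(reference, dtype=float)
    if Z.ndim != 2:
        raise DataError("reference must be a 2-D matrix")
    n, p = Z.shape
    if n <= p:
        raise ConditioningError(
            f"reference has {n} rows for {p} markers; need n > p "
            "(use fewer markers or a larger reference)"
        )
    if not np.isfinite(Z).all():
        raise DataError("reference matrix contains missing values")
    if np.unique(Z, axis=0).shape[0] <= p:
        raise ConditioningError(
            "reference has no more distinct rows than markers; covariance is "
            "structurally singular"
        )
    mu = Z.mean(axis=0)
    S = np.cov(Z, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    cond = float(np.linalg.cond(S))
    lam = 0.0
    if not np.isfinite(cond) or cond > cond_threshold:
        full = _shrink(S, 1.0)
        cond_full = float(np.linalg.cond(full))
        if not np.isfinite(cond_full) or cond_full > cond_threshold:
            raise ConditioningError(
                "covariance singular even after maximal diagonal shrinkage"
            )
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            c = float(np.linalg.cond(_shrink(S, mid)))
            if np.isfinite(c) and c <= cond_threshold:
                hi = mid
            else:
                lo = mid
        lam = hi
        S = _shrink(S, lam)
        cond = float(np.linalg.cond(S))
        logger.info("applied diagonal shrinkage lambda=%.3g (cond=%.3g)", lam, cond)
    return Moments(mu=mu, S=S, condition_number=cond, shrinkage=lam)


def mahalanobis(x, mu, S) -> float | np.ndarray:
    """Mahalanobis distance of x (vector or row matrix) from (mu, S).

    Computed via Cholesky factorization of S; no explicit inverse is formed.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    p = mu.shape[0]
    if S.shape != (p, p):
        raise DataError(f"dimension mismatch: mu has {p}, S is {S.shape}")
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != p:
        raise DataError(f"dimension mismatch: x has {X.shape[1]} columns, mu has {p}")
    try:
        factor = linalg.cho_factor(S, lower=True)
    except linalg.LinAlgError as exc:
        raise ConditioningError(f"covariance not positive definite: {exc}") from exc
    diff = (X - mu).T  # p x n
    solved = linalg.cho_solve(factor, diff)
    d2 = np.einsum("ij,ij->j", diff, solved)
    d = np.sqrt(np.maximum(d2, 0.0))
    return float(d[0]) if single else d


def score_cohort(cohort, reference, domain_violation: str = "drop_row") -> pd.DataFrame:
    """Score every observation of a cohort against a reference population.

    Applies the reference's transform spec (dropping domain-violating rows by
    default), computes the distance per row, and standardizes it within
    species (mean 0, sd 1) into ``dm_z`` for cross-species model
    comparability.  The reference's provenance key is recorded per row.
    """
    data = cohort.data
    markers = reference.markers
    missing = [m for m in markers if m not in data.columns]
    if missing:
        raise DataError(f"cohort lacks reference markers: {missing}")

    values = data[markers]
    if getattr(reference, "pre_standardize", None):
        values = _apply_pre_standardize(values, data["species"], reference)
    Z, log = apply_spec(values, reference.spec, domain_violation=domain_violation)
    Z = Z.dropna()
    if Z.empty:
        raise InputError("no scoreable observations after domain handling")
    dm = mahalanobis(Z.to_numpy(), reference.mu, reference.S)

    out = data.loc[Z.index, ["species", "individual_id", "sex", "age_at_obs",
                             "population"]].copy()
    out["dm"] = dm
    out["dm_z"] = out.groupby("species")["dm"].transform(
        lambda v: (v - v.mean()) / v.std(ddof=1)
    )
    out["reference_id"] = reference.reference_id
    out.attrs["apply_log"] = log
    return out.reset_index(drop=True)


def _apply_pre_standardize(values: pd.DataFrame, species: pd.Series, reference):
    """Within-species z-scoring with moments recorded at reference build time."""
    table = reference.pre_standardize
    out = values.astype(float).copy()
    for sp, grp_idx in species.groupby(species).groups.items():
        if sp not in table:
            raise DataError(
                f"species {sp!r} lacks pre-standardization moments in reference"
            )
        means, sds = table[sp]
        out.loc[grp_idx] = (out.loc[grp_idx] - pd.Series(means)) / pd.Series(sds)
    return out


def marker_score_correlations(
    scores: pd.DataFrame,
    standardized_markers: pd.DataFrame,
    flag_threshold: float = 0.3,
) -> dict:
    """Diagnostic: Pearson r between the score and each standardized marker.

    A score dominated by one marker is not an emergent multivariate signal;
    the report flags any |r| above ``flag_threshold``.  Constant markers have
    undefined r and are reported as missing.
    """
    if len(scores) != len(standardized_markers):
        raise DataError("scores and marker matrix must align row-wise")
    dm = np.asarray(scores["dm"], dtype=float)
    rs: dict[str, float | None] = {}
    for m in standardized_markers.columns:
        v = np.asarray(standardized_markers[m], dtype=float)
        if np.std(v) == 0 or np.std(dm) == 0:
            rs[m] = None
            continue
        rs[m] = float(np.corrcoef(dm, v)[0, 1])
    finite = [abs(r) for r in rs.values() if r is not None]
    max_abs = max(finite) if finite else None
    return {
        "per_marker_r": rs,
        "max_abs_r": max_abs,
        "share_below_0.1": (
            sum(1 for r in finite if r < 0.1) / len(finite) if finite else None
        ),
        "non_emergent": bool(max_abs is not None and max_abs > flag_threshold),
        "flag_threshold": flag_threshold,
    }
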