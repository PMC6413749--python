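"""Construction of reference populations defining the homeostatic signature.

Three schemes are supported: each species as its own reference (``self``),
one species as a reference for others (``cross``), and a balanced pooled
multispecies subsample (``combined``).  Every scheme builds its reference
from first observations — each individual's youngest visit — to approximate
a younger, presumably healthier state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .cohort_io import Cohort
from .scoring import estimate_moments
from .transform import (
    TransformSpec, apply_spec, fit_transform_spec, load_json_source,
)

logger = logging.getLogger(__name__)


@dataclass
class ReferencePopulation:
    """Transform spec plus reference moments (mu, S) with full provenance."""

    scheme: str  # {"self", "cross", "combined"}
    source_species: str  # species label or "combined"
    markers: list[str]
    spec: TransformSpec
    mu: np.ndarray
    S: np.ndarray
    n_ref: int
    seed: int | None = None
    member_keys: list[tuple[str, str]] = field(default_factory=list)
    pre_standardize: dict | None = None  # species -> (means, sds) dicts
    shrinkage: float = 0.0
    condition_number: float | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        p = len(self.markers)
        if self.mu.shape != (p,) or self.S.shape != (p, p):
            raise DataError("mu/S dimensions do not match marker count")
        if not np.allclose(self.S, self.S.T):
            raise DataError("covariance matrix not symmetric")
        if self.n_ref <= p:
            raise DataError("reference must have more rows than markers")

    @property
    def reference_id(self) -> str:
        return f"{self.scheme}:{self.source_species}"

    def to_json(self, path=None) -> str:
        payload = {
            "scheme": self.scheme,
            "source_species": self.source_species,
            "markers": self.markers,
            "spec": json.loads(self.spec.to_json()),
            "mu": self.mu.tolist(),
            "S": self.S.tolist(),
            "n_ref": self.n_ref,
            "seed": self.seed,
            "member_keys": [list(k) for k in self.member_keys],
            "pre_standardize": self.pre_standardize,
            "shrinkage": self.shrinkage,
            "condition_number": self.condition_number,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReferencePopulation":
        payload = load_json_source(source)
        spec = TransformSpec.from_json(json.dumps(payload["spec"]))
        pre = payload.get("pre_standardize")
        if pre is not None:
            pre = {sp: (ms[0], ms[1]) for sp, ms in pre.items()}
        return cls(
            scheme=payload["scheme"],
            source_species=payload["source_species"],
            markers=payload["markers"],
            spec=spec,
            mu=np.array(payload["mu"]),
            S=np.array(payload["S"]),
            n_ref=payload["n_ref"],
            seed=payload.get("seed"),
            member_keys=[tuple(k) for k in payload.get("member_keys", [])],
            pre_standardize=pre,
            shrinkage=payload.get("shrinkage", 0.0),
            condition_number=payload.get("condition_number"),
        )


def first_observations(cohort: Cohort) -> Cohort:
    """One row per individual: its youngest visit (stable tie-break)."""
    data = cohort.data
    idx = data.groupby("individual_id", sort=False)["age_at_obs"].idxmin()
    kept = data.loc[sorted(idx)].reset_index(drop=True)
    return Cohort(kept, list(cohort.markers))


def _build_from_rows(rows: pd.DataFrame, markers: list[str], scheme: str,
                     source: str, seed=None, pre=None,
                     cond_threshold: float = 1e8) -> ReferencePopulation:
    spec = fit_transform_spec(rows, markers)
    Z, _ = apply_spec(rows[markers], spec, domain_violation="drop_row")
    moments = estimate_moments(Z.to_numpy(), cond_threshold=cond_threshold)
    return ReferencePopulation(
        scheme=scheme,
        source_species=source,
        markers=list(markers),
        spec=spec,
        mu=moments.mu,
        S=moments.S,
        n_ref=len(Z),
        seed=seed,
        member_keys=list(zip(rows["species"], rows["individual_id"])),
        pre_standardize=pre,
        shrinkage=moments.shrinkage,
        condition_number=moments.condition_number,
    )


def build_self_reference(species_cohort: Cohort, markers: list[str],
                         cond_threshold: float = 1e8) -> ReferencePopulation:
    """Species-as-own-reference: first observations of a single-species cohort."""
    species = species_cohort.species
    if len(species) != 1:
        raise ConfigurationError(
            f"self reference requires a single-species cohort, got {species}"
        )
    ref = first_observations(species_cohort)
    if ref.data[markers].isna().any().any():
        raise DataError("reference rows not complete on markers")
    return _build_from_rows(ref.data, markers, "self", species[0],
                            cond_threshold=cond_threshold)


def build_cross_reference(reference_species_cohort: Cohort, markers: list[str],
                          cond_threshold: float = 1e8) -> ReferencePopulation:
    """Same construction as the self scheme, tagged for cross-species use."""
    ref = build_self_reference(reference_species_cohort, markers,
                               cond_threshold=cond_threshold)
    ref.scheme = "cross"
    return ref


def build_combined_reference(
    cohorts: dict[str, Cohort],
    markers: list[str],
    seed: int,
    standardize_within_species: bool = False,
    cond_threshold: float = 1e8,
) -> ReferencePopulation:
    """Balanced multispecies pool: m first-observation rows per species.

    m is the smallest per-species count of first observations; each species
    is subsampled to m without replacement (seeded), so the best-sampled
    species cannot dominate the pooled moments.  With
    ``standardize_within_species`` each species' marker columns are z-scored
    on its own first observations before pooling, and the same per-species
    moments are replayed at scoring time.
    """
    if not markers:
        raise ConfigurationError("shared marker set is empty")
    if seed is None:
        raise ConfigurationError("combined reference requires a seed")
    rng = np.random.default_rng(seed)
    firsts = {sp: first_observations(c).data for sp, c in sorted(cohorts.items())}
    for sp, rows in firsts.items():
        missing = [m for m in markers if m not in rows.columns]
        if missing:
            raise ConfigurationError(f"species {sp!r} lacks markers {missing}")
        if rows[markers].isna().any().any():
            raise DataError(f"species {sp!r} first observations incomplete on markers")
    m = min(len(rows) for rows in firsts.values())

    sampled = []
    pre: dict[str, tuple[dict, dict]] = {}
    for sp, rows in firsts.items():
        take = rng.choice(len(rows), size=m, replace=False)
        sub = rows.iloc[np.sort(take)].copy()
        if standardize_within_species:
            means = rows[markers].mean()
            sds = rows[markers].std(ddof=1)
            if (sds <= 0).any():
                raise DataError(f"zero within-species variance for {sp!r}")
            sub[markers] = (sub[markers] - means) / sds
            pre[sp] = (means.to_dict(), sds.to_dict())
        sampled.append(sub)
    pooled = pd.concat(sampled, ignore_index=True)
    logger.info("combined reference: %d species x %d rows = %d pooled rows",
                len(firsts), m, len(pooled))
    return _build_from_rows(
        pooled, markers, "combined", "combined", seed=seed,
        pre=pre if standardize_within_species else None,
        cond_threshold=cond_threshold,
    )
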