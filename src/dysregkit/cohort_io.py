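"""Reading, validation and filtering of longitudinal biomarker cohorts.

A cohort is a long-format table: one row per individual-visit, identified by
(species, individual_id, age_at_obs), with a sex label, optional population
(research center), optional death age and body mass, and one column per
biomarker.  All functions operate on :class:`Cohort`, a thin wrapper around a
:class:`pandas.DataFrame` that tracks which columns are biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._errors import ConfigurationError, FormatError, InputError, SchemaError

logger = logging.getLogger(__name__)

#: Non-marker columns in canonical order.
STANDARD_COLUMNS = [
    "species",
    "individual_id",
    "sex",
    "age_at_obs",
    "population",
    "death_age",
    "body_mass",
]
REQUIRED_COLUMNS = ["species", "individual_id", "sex", "age_at_obs"]

_SEX_ALIASES = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
    "u": "unknown", "unknown": "unknown", "": "unknown", "nan": "unknown",
}


@dataclass
class Cohort:
    """Longitudinal biomarker observations plus the list of marker columns."""

    data: pd.DataFrame
    markers: list[str]
    validation_report: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort missing required columns: {missing}")
        for col in STANDARD_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan if col != "population" else "pop1"

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_ids(self) -> int:
        return self.data["individual_id"].nunique()

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def per_species(self) -> dict[str, "Cohort"]:
        return {
            sp: Cohort(grp.reset_index(drop=True), list(self.markers))
            for sp, grp in self.data.groupby("species", sort=True)
        }

    def subset(self, mask) -> "Cohort":
        return Cohort(self.data.loc[mask].reset_index(drop=True), list(self.markers))

    def marker_matrix(self) -> pd.DataFrame:
        return self.data[self.markers]


@dataclass
class SpeciesMeta:
    """Per-species metadata: maturation age and marker plausibility bounds."""

    species: str
    maturation_age: float
    plausibility_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    expected_max_lifespan: float | None = None

    def __post_init__(self) -> None:
        if not self.maturation_age > 0:
            raise ConfigurationError(
                f"maturation_age must be > 0 for {self.species!r}"
            )
        for marker, (low, high) in self.plausibility_bounds.items():
            if not low < high:
                raise ConfigurationError(
                    f"bound low >= high for marker {marker!r} in {self.species!r}"
                )


def read_cohort(path, schema: dict[str, str] | None = None,
                markers: list[str] | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    schema : dict, optional
        Mapping from canonical column name (``species``, ``individual_id``,
        ``sex``, ``age_at_obs``, ``population``, ``death_age``, ``body_mass``)
        to the column name used in the file.  Identity by default.
    markers : list of str, optional
        Columns to treat as biomarkers.  Defaults to every non-standard column.

    Invalid rows (unparseable or nonpositive age) are rejected and logged in
    ``cohort.validation_report``.  An individual appearing under more than one
    species or sex keeps its first-encountered assignment; conflicting rows
    are rejected.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {src: canon for canon, src in schema.items() if src in raw.columns}
    raw = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if raw.empty:
        raise InputError("cohort table is empty")

    if markers is None:
        markers = [c for c in raw.columns if c not in STANDARD_COLUMNS]

    report: dict = {"rejected_rows": [], "warnings": [], "all_missing_markers": []}

    for col in ["age_at_obs", "death_age", "body_mass", *markers]:
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")

    raw["sex"] = (
        raw["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
        .fillna("unknown")
    )
    raw["species"] = raw["species"].astype(str)
    raw["individual_id"] = raw["individual_id"].astype(str)

    bad_age = raw["age_at_obs"].isna() | (raw["age_at_obs"] <= 0)
    for idx in raw.index[bad_age]:
        report["rejected_rows"].append(
            {"row": int(idx), "reason": "invalid age_at_obs"}
        )
    data = raw.loc[~bad_age].copy()

    # First-encountered species/sex assignment wins per individual.
    first = data.groupby("individual_id", sort=False).agg(
        _species=("species", "first"), _sex=("sex", "first")
    )
    joined = data.join(first, on="individual_id")
    conflict = (joined["species"] != joined["_species"]) | (
        joined["sex"] != joined["_sex"]
    )
    for idx in data.index[conflict.to_numpy()]:
        report["rejected_rows"].append(
            {"row": int(idx), "reason": "conflicting species/sex for individual"}
        )
    data = data.loc[~conflict.to_numpy()].copy()

    if data.empty:
        raise InputError("no valid rows after validation")

    # death_age must cover every observation of the individual.
    if "death_age" in data.columns and data["death_age"].notna().any():
        max_age = data.groupby("individual_id")["age_at_obs"].transform("max")
        invalid = data["death_age"].notna() & (data["death_age"] < max_age)
        bad_ids = sorted(data.loc[invalid, "individual_id"].unique())
        if bad_ids:
            report["warnings"].append(
                f"death_age before last observation for {bad_ids}; death cleared"
            )
            data.loc[data["individual_id"].isin(bad_ids), "death_age"] = np.nan

    for m in markers:
        if m not in data.columns:
            data[m] = np.nan
        if data[m].isna().all():
            report["all_missing_markers"].append(m)
        data.loc[~np.isfinite(data[m].astype(float)), m] = np.nan

    for entry in report["rejected_rows"]:
        logger.warning("rejected row %d: %s", entry["row"], entry["reason"])

    cohort = Cohort(data.reset_index(drop=True), markers)
    cohort.validation_report = report
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (standard columns first, then markers)."""
    cols = [c for c in STANDARD_COLUMNS if c in cohort.data.columns] + cohort.markers
    cohort.data[cols].to_csv(path, index=False)


def read_species_meta(path, bounds_path=None) -> dict[str, SpeciesMeta]:
    """Read species metadata.

    ``path`` is a CSV with columns ``species``, ``maturation_age`` and
    optionally ``expected_max_lifespan``; ``bounds_path`` an optional long CSV
    with columns ``species``, ``marker``, ``low``, ``high``.
    """
    tab = pd.read_csv(path)
    for col in ("species", "maturation_age"):
        if col not in tab.columns:
            raise SchemaError(f"species metadata missing column {col!r}")
    bounds: dict[str, dict[str, tuple[float, float]]] = {}
    if bounds_path is not None:
        btab = pd.read_csv(bounds_path)
        for col in ("species", "marker", "low", "high"):
            if col not in btab.columns:
                raise SchemaError(f"bounds table missing column {col!r}")
        for row in btab.itertuples(index=False):
            bounds.setdefault(str(row.species), {})[str(row.marker)] = (
                float(row.low), float(row.high)
            )
    meta = {}
    for row in tab.itertuples(index=False):
        sp = str(row.species)
        meta[sp] = SpeciesMeta(
            species=sp,
            maturation_age=float(row.maturation_age),
            plausibility_bounds=bounds.get(sp, {}),
            expected_max_lifespan=float(getattr(row, "expected_max_lifespan", np.nan))
            if hasattr(row, "expected_max_lifespan") else None,
        )
    return meta


def filter_adults(cohort: Cohort, meta: dict[str, SpeciesMeta]) -> tuple[Cohort, int]:
    """Keep rows at or past the species maturation age.

    Returns the filtered cohort and the number of removed rows.  The boundary
    is inclusive: ``age_at_obs >= maturation_age`` counts as adult.
    """
    missing = [sp for sp in cohort.species if sp not in meta]
    if missing:
        raise ConfigurationError(f"species missing from metadata: {missing}")
    thresholds = cohort.data["species"].map({sp: m.maturation_age for sp, m in meta.items()})
    keep = cohort.data["age_at_obs"] >= thresholds
    n_removed = int((~keep).sum())
    out = cohort.subset(keep)
    if out.n_obs == 0:
        logger.warning("filter_adults removed every row")
    return out, n_removed


def filter_implausible(
    cohort: Cohort, meta: dict[str, SpeciesMeta]
) -> tuple[Cohort, dict[str, int]]:
    """Blank marker cells outside their species plausibility bounds.

    Cell-level screening: values outside the open interval ``(low, high)``
    are set to missing; the bounds themselves are retained.  Returns the
    screened cohort and removal counts per marker.
    """
    data = cohort.data.copy()
    counts: dict[str, int] = {}
    for sp, m in meta.items():
        rows = data["species"] == sp
        for marker, (low, high) in m.plausibility_bounds.items():
            if marker not in cohort.markers:
                continue
            vals = data.loc[rows, marker]
            bad = vals.notna() & ((vals < low) | (vals > high))
            if bad.any():
                data.loc[bad[bad].index, marker] = np.nan
                counts[marker] = counts.get(marker, 0) + int(bad.sum())
    return Cohort(data, list(cohort.markers)), counts


def select_marker_set(
    cohort: Cohort,
    mode: str,
    fixed_panel: list[str] | None = None,
    min_markers: int = 10,
    availability: float = 0.7,
) -> dict[str, Cohort]:
    """Select per-species marker panels and keep complete cases.

    ``mode='variable'``: per species, keep markers observed in at least
    ``availability`` of that species' rows; drop the species if fewer than
    ``min_markers`` survive.  ``mode='fixed'``: keep exactly ``fixed_panel``
    for every species; species entirely missing a panel marker are dropped.
    In both modes only rows complete on the selected markers are retained.
    """
    if mode not in ("variable", "fixed"):
        raise ConfigurationError(f"unknown marker-set mode {mode!r}")
    if mode == "fixed" and not fixed_panel:
        raise ConfigurationError("fixed mode requires fixed_panel")

    out: dict[str, Cohort] = {}
    for sp, sub in cohort.per_species().items():
        if mode == "fixed":
            panel = list(fixed_panel)
            absent = [m for m in panel
                      if m not in sub.data.columns or sub.data[m].isna().all()]
            if absent:
                logger.warning(
                    "species %s dropped: panel markers absent: %s", sp, absent
                )
                continue
        else:
            frac = sub.data[cohort.markers].notna().mean()
            panel = [m for m in cohort.markers if frac[m] >= availability]
            if len(panel) < min_markers:
                logger.warning(
                    "species %s dropped: %d markers < min_markers=%d",
                    sp, len(panel), min_markers,
                )
                continue
        complete = sub.data[panel].notna().all(axis=1)
        kept = Cohort(sub.data.loc[complete].reset_index(drop=True), panel)
        if kept.n_obs == 0:
            logger.warning("species %s dropped: no complete cases on panel", sp)
            continue
        out[sp] = kept
    return out


def read_tree(path, species: list[str] | None = None) -> dendropy.Tree:
    """Parse a Newick phylogeny and validate tips against cohort species.

    Branch lengths are required on every non-root edge.  Tips absent from
    ``species`` are allowed (logged); species absent from the tree raise.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises various parse errors
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    return validate_tree(tree, species)


def validate_tree(tree: dendropy.Tree, species: list[str] | None = None) -> dendropy.Tree:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("tree has edges without branch lengths")
        if edge.length < 0:
            raise FormatError("tree has negative branch lengths")
    if species is not None:
        tips = {t.label for t in tree.taxon_namespace}
        missing = sorted(set(species) - tips)
        if missing:
            raise ConfigurationError(
                f"species missing from tree: {missing}"
            )
        extra = sorted(tips - set(species))
        if extra:
            logger.info("tree has extra tips not in cohort (ignored): %s", extra)
    return tree
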