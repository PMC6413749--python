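"""Cross-species conservation of the homeostatic signature.

Scores each species against its own reference and against every other
species' reference, assembles the species x species correlation matrix, and
tests whether reference interchangeability tracks phylogenetic proximity via
a Spearman matrix correlation with Mantel-style permutation significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, DataError, InputError
from .cohort_io import Cohort
from .references import build_self_reference
from .scoring import score_cohort

logger = logging.getLogger(__name__)

_JOIN_KEYS = ["species", "individual_id", "age_at_obs"]


def self_vs_combined_correlation(
    scores_self: pd.DataFrame, scores_combined: pd.DataFrame, min_obs: int = 3
) -> pd.Series:
    """Per-species Pearson r between two score tables on matched observations."""
    merged = scores_self.merge(
        scores_combined, on=_JOIN_KEYS, suffixes=("_a", "_b")
    )
    out = {}
    for sp, grp in merged.groupby("species", sort=True):
        if len(grp) < min_obs:
            logger.warning("species %s skipped: %d matched obs < %d",
                           sp, len(grp), min_obs)
            continue
        out[sp] = float(np.corrcoef(grp["dm_a"], grp["dm_b"])[0, 1])
    return pd.Series(out, name="r")


@dataclass
class CrossRefMatrix:
    """r[target, reference]: agreement between self- and foreign-referenced scores."""

    values: pd.DataFrame  # rows = target species, columns = reference species
    n_pairs: pd.DataFrame  # observation counts behind each cell

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def cross_reference_matrix(
    cohorts: dict[str, Cohort],
    markers: list[str],
    min_obs: int = 3,
    domain_violation: str = "drop_row",
    cond_threshold: float = 1e8,
    references: dict | None = None,
) -> CrossRefMatrix:
    """Correlate self-referenced with cross-referenced scores for every pair.

    For an ordered pair (A, B), A's observations are scored against A's own
    first-observation reference and against B's reference; the cell is the
    Pearson correlation over A's observations scoreable under both.  Rows
    dropped by foreign-transform domain violations are excluded pairwise.
    Diagonal cells are exactly 1; pairs with too few joint observations are
    set missing.
    """
    species = sorted(cohorts)
    if len(species) < 2:
        raise ConfigurationError("need at least two species")
    refs = references or {
        sp: build_self_reference(cohorts[sp], markers, cond_threshold=cond_threshold)
        for sp in species
    }
    self_scores = {
        sp: score_cohort(cohorts[sp], refs[sp], domain_violation=domain_violation)
        for sp in species
    }

    r = pd.DataFrame(np.nan, index=species, columns=species)
    n = pd.DataFrame(0, index=species, columns=species)
    for a in species:
        for b in species:
            if a == b:
                r.loc[a, b] = 1.0
                n.loc[a, b] = len(self_scores[a])
                continue
            try:
                cross = score_cohort(cohorts[a], refs[b],
                                     domain_violation=domain_violation)
            except InputError:
                logger.warning("pair (%s, %s): no scoreable observations", a, b)
                continue
            merged = self_scores[a].merge(cross, on=_JOIN_KEYS,
                                          suffixes=("_self", "_cross"))
            n.loc[a, b] = len(merged)
            if len(merged) < min_obs:
                logger.warning("pair (%s, %s): %d joint obs < %d — cell missing",
                               a, b, len(merged), min_obs)
                continue
            r.loc[a, b] = float(
                np.corrcoef(merged["dm_self"], merged["dm_cross"])[0, 1]
            )
    return CrossRefMatrix(values=r, n_pairs=n)


def patristic_distance_matrix(
    tree: dendropy.Tree, species: list[str]
) -> pd.DataFrame:
    """Tip-to-tip path-length matrix (sum of branch lengths), ordered as given."""
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [sp for sp in species if sp not in taxa]
    if missing:
        raise ConfigurationError(f"species missing from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    out = pd.DataFrame(0.0, index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            d = float(pdm.patristic_distance(taxa[a], taxa[b]))
            out.loc[a, b] = d
            out.loc[b, a] = d
    return out


def _offdiag_cells(crm: np.ndarray, prox: np.ndarray, halves: str):
    k = crm.shape[0]
    if halves == "full":
        mask = ~np.eye(k, dtype=bool)
    elif halves == "upper":
        mask = np.triu(np.ones((k, k), dtype=bool), 1)
    elif halves == "lower":
        mask = np.tril(np.ones((k, k), dtype=bool), -1)
    else:
        raise ConfigurationError(f"unknown halves option {halves!r}")
    return crm[mask], prox[mask]


@dataclass
class ConservationResult:
    rho: float
    p_permutation: float
    p_naive: float
    halves: str
    n_cells: int
    n_permutations: int
    seed: int | None


def phylo_conservation_test(
    crm: CrossRefMatrix | pd.DataFrame,
    pdm: pd.DataFrame,
    halves: str = "full",
    n_permutations: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
    max_missing: float = 0.2,
) -> ConservationResult:
    """Spearman correlation between cross-reference r and phylogenetic proximity.

    Proximity is the negative patristic distance (any strictly monotone
    choice gives the same rank correlation).  Diagonals are excluded; any
    combined row/column must be dropped by the caller before this test.
    Because matrix cells sharing a species are dependent, the headline
    p-value comes from Mantel-style permutations of species labels; the naive
    cell-independence p-value is also reported.
    """
    rmat = crm.values if isinstance(crm, CrossRefMatrix) else crm
    sp = list(rmat.index)
    if list(pdm.index) != sp or list(pdm.columns) != sp or list(rmat.columns) != sp:
        pdm = pdm.loc[sp, sp]
        if list(rmat.columns) != sp:
            raise ConfigurationError("cross-reference matrix must be square on species")
    R = rmat.to_numpy(dtype=float)
    P = -pdm.to_numpy(dtype=float)
    k = len(sp)

    r_cells, p_cells = _offdiag_cells(R, P, halves)
    missing = np.isnan(r_cells)
    if missing.mean() > max_missing:
        raise DataError(
            f"{missing.mean():.0%} of cells missing exceeds {max_missing:.0%}"
        )
    valid = ~missing
    rho, p_naive = stats.spearmanr(r_cells[valid], p_cells[valid],
                                   alternative=alternative)
    rho = float(rho)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        pr_cells = _offdiag_cells(R, P[np.ix_(perm, perm)], halves)[1]
        rp = stats.spearmanr(r_cells[valid], pr_cells[valid]).statistic
        if alternative == "greater":
            extreme = rp >= rho
        elif alternative == "less":
            extreme = rp <= rho
        else:
            extreme = abs(rp) >= abs(rho)
        count += bool(extreme)
    p_perm = (1 + count) / (1 + n_permutations)
    return ConservationResult(
        rho=rho,
        p_permutation=float(p_perm),
        p_naive=float(p_naive),
        halves=halves,
        n_cells=int(valid.sum()),
        n_permutations=n_permutations,
        seed=seed,
    )
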