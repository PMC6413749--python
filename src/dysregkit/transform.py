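"""Per-marker normality-approximating transforms and reference standardization.

Each reference population gets its own :class:`TransformSpec`: for every
marker, a transform choice (identity, natural log, or square root), picked to
maximize normality of the transformed reference values, plus the mean and
standard deviation on the transformed scale used for z-scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError, InputError

logger = logging.getLogger(__name__)


def load_json_source(source) -> dict:
    """Parse JSON from a path, a JSON string, or an open file object."""
    if hasattr(source, "read"):
        return json.load(source)
    text = source.decode() if isinstance(source, bytes) else str(source)
    if text.lstrip().startswith("{"):
        return json.loads(text)
    with open(text) as fh:
        return json.load(fh)

TRANSFORMS = ("identity", "sqrt", "log")  # preference order on ties

_FUNCS = {
    "identity": lambda v: v,
    "sqrt": np.sqrt,
    "log": np.log,
}


def _admissible(values: np.ndarray) -> list[str]:
    out = ["identity"]
    if np.all(values >= 0):
        out.append("sqrt")
    if np.all(values > 0):
        out.append("log")
    return out


def _normality(values: np.ndarray, large_n: int = 5000) -> float:
    """Goodness-of-normality statistic, higher is better.

    Shapiro–Wilk W for n <= large_n; above that W is unreliable, so fall back
    to negative absolute skewness (same maximization convention).
    """
    if len(values) <= large_n:
        return float(stats.shapiro(values).statistic)
    return -abs(float(stats.skew(values)))


def select_transform(values, floor: int = 10, large_n: int = 5000) -> str:
    """Pick the admissible transform maximizing normality of the values.

    Ties break by preference order identity > sqrt > log.  Raises for fewer
    than ``floor`` finite values (caller should fall back to identity
    explicitly if that is acceptable).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < floor:
        raise InputError(
            f"only {len(v)} finite values (< {floor}); pass transform='identity' "
            "explicitly if intended"
        )
    best, best_score = None, -np.inf
    for name in TRANSFORMS:
        if name not in _admissible(v):
            continue
        score = _normality(_FUNCS[name](v), large_n=large_n)
        if score > best_score:  # strict: earlier (preferred) wins ties
            best, best_score = name, score
    return best


@dataclass
class MarkerTransform:
    choice: str
    ref_mean: float
    ref_sd: float
    normality_score: float

    def __post_init__(self) -> None:
        if not self.ref_sd > 0:
            raise DataError("ref_sd must be positive")


@dataclass
class TransformSpec:
    """Per-marker transform choices and reference moments."""

    markers: dict[str, MarkerTransform] = field(default_factory=dict)

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers)

    def to_json(self, path=None) -> str:
        payload = {
            m: {
                "choice": t.choice,
                "ref_mean": t.ref_mean,
                "ref_sd": t.ref_sd,
                "normality_score": t.normality_score,
            }
            for m, t in self.markers.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TransformSpec":
        payload = load_json_source(source)
        return cls(markers={m: MarkerTransform(**t) for m, t in payload.items()})


def fit_transform_spec(reference: pd.DataFrame, markers: list[str],
                       floor: int = 10, large_n: int = 5000) -> TransformSpec:
    """Fit a TransformSpec on a reference sample (complete on ``markers``).

    Transform selection and moments are reference-specific by construction;
    a marker with zero variance on the transformed scale is an error.
    """
    spec = TransformSpec()
    for m in markers:
        vals = np.asarray(reference[m], dtype=float)
        if not np.isfinite(vals).all():
            raise DataError(f"reference not complete on marker {m!r}")
        choice = select_transform(vals, floor=floor, large_n=large_n)
        t = _FUNCS[choice](vals)
        sd = float(np.std(t, ddof=1))
        if not sd > 0:
            raise DataError(f"zero variance in reference for marker {m!r}")
        spec.markers[m] = MarkerTransform(
            choice=choice,
            ref_mean=float(np.mean(t)),
            ref_sd=sd,
            normality_score=_normality(t, large_n=large_n),
        )
    return spec


def apply_spec(
    values: pd.DataFrame,
    spec: TransformSpec,
    domain_violation: str = "drop_row",
) -> tuple[pd.DataFrame, dict]:
    """Transform and z-score marker columns using a reference's spec.

    Cells violating the transform domain (nonpositive under log, negative
    under sqrt) — typical when a foreign species' spec is applied — are
    handled per ``domain_violation``: ``drop_row`` (default; the score needs
    a complete vector) or ``set_missing``.  Returns the standardized frame
    (original index preserved for dropped-row traceability) and an exclusion
    log with per-marker violation counts.
    """
    if domain_violation not in ("drop_row", "set_missing"):
        raise ValueError(f"unknown policy {domain_violation!r}")
    missing = [m for m in spec.marker_names if m not in values.columns]
    if missing:
        raise DataError(f"spec markers absent from values: {missing}")

    out = {}
    violations: dict[str, int] = {}
    viol_mask = pd.Series(False, index=values.index)
    for m, t in spec.markers.items():
        col = values[m].astype(float)
        if t.choice == "log":
            bad = ~(col > 0)
        elif t.choice == "sqrt":
            bad = ~(col >= 0)
        else:
            bad = pd.Series(False, index=values.index)
        bad &= col.notna()
        if bad.any():
            violations[m] = int(bad.sum())
            viol_mask |= bad
        safe = col.where(~bad)
        z = (_FUNCS[t.choice](safe) - t.ref_mean) / t.ref_sd
        out[m] = z
    frame = pd.DataFrame(out, index=values.index)[spec.marker_names]
    log = {"policy": domain_violation, "violations_per_marker": violations,
           "n_rows_affected": int(viol_mask.sum())}
    if domain_violation == "drop_row" and viol_mask.any():
        frame = frame.loc[~viol_mask]
        log["dropped_rows"] = [int(i) for i in values.index[viol_mask]]
        logger.info("apply_spec dropped %d row(s) for domain violations",
                    int(viol_mask.sum()))
    return frame, log
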