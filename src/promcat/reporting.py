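"""Score interpretation against a demographically matched reference table.

A raw 0-100 score means little on its own; the clinically useful question
is where it sits among people like the respondent.  This module filters a
reference population (one row per person-scale, with age, gender, cleft
type, laterality and country), expresses a score as a percentile of the
filtered scores, and computes matched-median profiles — the payload behind
a density/radar score-checker display.  Higher scores are clinically
better by convention; the payload says so explicitly.

Percentiles use the mid-rank convention,
``100 * (#{ref < s} + 0.5 * #{ref == s}) / n``: symmetric (a score and
its mirror average to 100), bounded in [0, 100], and well defined with
ties.  Small filtered subsets (n < 20) are flagged rather than hidden,
because percentiles from a handful of reference scores are unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cat_engine import CatTrace
from .exceptions import InvalidInputError

__all__ = [
    "REFERENCE_COLUMNS",
    "FilterSpec",
    "load_reference",
    "filter_reference",
    "percentile_of_score",
    "median_profile",
    "build_report",
]

REFERENCE_COLUMNS = (
    "person_id", "scale_id", "score", "age", "gender", "cleft_type",
    "laterality", "country",
)

SMALL_SUBSET_N = 20


@dataclass(frozen=True)
class FilterSpec:
    """Demographic filter; ``None`` fields are pass-through (empty spec =
    no filtering).  Age bounds are a closed interval in integer years;
    category fields are sets of accepted values."""

    age_range: tuple[int, int] | None = None
    gender: frozenset[str] | None = None
    cleft_type: frozenset[str] | None = None
    laterality: frozenset[str] | None = None
    country: frozenset[str] | None = None

    @classmethod
    def from_dict(cls, raw: Mapping) -> "FilterSpec":
        def as_set(key):
            v = raw.get(key)
            return frozenset(map(str, v)) if v is not None else None

        age = raw.get("age_range")
        return cls(
            age_range=(int(age[0]), int(age[1])) if age is not None else None,
            gender=as_set("gender"),
            cleft_type=as_set("cleft_type"),
            laterality=as_set("laterality"),
            country=as_set("country"),
        )


def load_reference(path: str | Path) -> pd.DataFrame:
    """Read and validate a reference score table CSV."""
    table = pd.read_csv(path)
    return validate_reference(table)


def validate_reference(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REFERENCE_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"reference table lacks columns: {sorted(missing)}")
    scores = pd.to_numeric(table["score"], errors="coerce")
    bad = table.index[scores.isna() | (scores < 0) | (scores > 100)]
    if len(bad):
        raise InvalidInputError(
            f"reference row {bad[0]}: score must be a number in [0, 100]"
        )
    if table.duplicated(["person_id", "scale_id"]).any():
        raise InvalidInputError("reference table has duplicate (person_id, scale_id) rows")
    return table


def filter_reference(
    table: pd.DataFrame, filter_spec: FilterSpec | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Rows matching every supplied criterion (conjunctive), plus the
    per-scale sample sizes of the result."""
    f = filter_spec or FilterSpec()
    mask = pd.Series(True, index=table.index)
    if f.age_range is not None:
        lo, hi = f.age_range
        mask &= (table["age"] >= lo) & (table["age"] <= hi)
    for column in ("gender", "cleft_type", "laterality", "country"):
        allowed = getattr(f, column)
        if allowed is not None:
            mask &= table[column].astype(str).isin(allowed)
    subset = table[mask]
    if subset.empty:
        warnings.warn("reference filter matched no rows", stacklevel=2)
    n_per_scale = subset.groupby("scale_id").size()
    return subset, n_per_scale


def percentile_of_score(score: float, reference_scores) -> float:
    """Mid-rank percentile of ``score`` within the reference scores."""
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size == 0:
        raise InvalidInputError(
            "empty reference population; relax the demographic filter"
        )
    below = float(np.sum(ref < score))
    equal = float(np.sum(ref == score))
    return 100.0 * (below + 0.5 * equal) / ref.size


def median_profile(
    table: pd.DataFrame,
    filter_spec: FilterSpec | None,
    scales: Sequence[str],
) -> dict[str, float]:
    """Median filtered reference score per requested scale.

    Scales with no matching reference rows are omitted from the result
    (absent, not zero); callers surface them separately.
    """
    subset, _ = filter_reference(table, filter_spec)
    out: dict[str, float] = {}
    for scale_id in scales:
        scores = subset.loc[subset["scale_id"] == scale_id, "score"]
        if len(scores):
            out[scale_id] = float(scores.median())
    return out


def build_report(
    traces: Mapping[str, CatTrace],
    table: pd.DataFrame,
    filter_spec: FilterSpec | None = None,
) -> dict:
    """Assemble the machine-readable score-checker payload.

    For each assessed scale: the 0-100 score, its percentile in the
    filtered reference, the matched median, the reference n (with a
    small-subset warning below n = 20), and the assessment length.  The
    payload also records the filter applied and the score direction
    convention (higher = clinically better).
    """
    subset, n_per_scale = filter_reference(table, filter_spec)
    medians = {}
    scales_payload = {}
    for scale_id, trace in traces.items():
        if trace.score is None:
            raise InvalidInputError(
                f"scale {scale_id!r}: trace has no 0-100 score (unanchored bank)"
            )
        ref_scores = subset.loc[subset["scale_id"] == scale_id, "score"].to_numpy()
        n_ref = int(ref_scores.size)
        entry: dict = {
            "score": float(trace.score),
            "n_items_administered": len(trace),
            "theta": trace.estimate.theta,
            "se": trace.estimate.se,
            "n_reference": n_ref,
            "small_reference_subset": bool(0 < n_ref < SMALL_SUBSET_N),
        }
        if n_ref:
            entry["percentile"] = percentile_of_score(trace.score, ref_scores)
            entry["matched_median"] = float(np.median(ref_scores))
        else:
            entry["percentile"] = None
            entry["matched_median"] = None
        scales_payload[scale_id] = entry

    f = filter_spec or FilterSpec()
    return {
        "convention": "higher score = clinically better",
        "difference_convention": "cat - full",
        "filter": {
            "age_range": list(f.age_range) if f.age_range else None,
            "gender": sorted(f.gender) if f.gender else None,
            "cleft_type": sorted(f.cleft_type) if f.cleft_type else None,
            "laterality": sorted(f.laterality) if f.laterality else None,
            "country": sorted(f.country) if f.country else None,
        },
        "n_reference_per_scale": {str(k): int(v) for k, v in n_per_scale.items()},
        "scales": scales_payload,
    }
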