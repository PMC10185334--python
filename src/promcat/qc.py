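"""Pre-replay data hygiene: missingness handling and outlier screening.

The validation pipeline's sensitivity arms are built from three simple,
auditable operations:

* :func:`listwise_exclude` — drop every person with any missing response
  among the scale's items;
* :func:`mahalanobis_outliers` — flag persons whose response vector lies
  far from the sample centroid under the sample covariance, against a
  chi-squared cut-off (distances are computed on the raw category codes,
  because outlier screening precedes scoring in the pipeline);
* :func:`impute_missing` — deterministic single imputation, either the
  item's modal category (default; ties to the lower category) or the
  person's rounded within-scale mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .calibration import ResponseMatrix
from .exceptions import InvalidInputError
from .irt_core import ItemBank

__all__ = ["QcReport", "listwise_exclude", "mahalanobis_outliers", "impute_missing"]

IMPUTATION_METHODS = ("item_mode", "person_scale_mean")


@dataclass
class QcReport:
    """Audit record for one QC operation."""

    n_input: int
    n_after: int
    excluded_persons: tuple[str, ...] = ()
    outliers: pd.DataFrame | None = None  # person_id index, columns dist2/flagged
    imputation_log: tuple[dict, ...] = ()
    method: str | None = None

    def __post_init__(self) -> None:
        if self.n_after > self.n_input:
            raise InvalidInputError("QcReport: n_after cannot exceed n_input")


def listwise_exclude(
    responses: ResponseMatrix, scale_items: Sequence[str] | None = None
) -> tuple[ResponseMatrix, QcReport]:
    """Drop persons with any missing response among ``scale_items``.

    Missingness in columns outside ``scale_items`` is ignored.  Defaults
    to all items.  An empty result is allowed (with a warning), not fatal.
    """
    items = list(scale_items) if scale_items is not None else responses.item_ids
    unknown = set(items) - set(responses.item_ids)
    if unknown:
        raise InvalidInputError(f"scale_items not in matrix: {sorted(unknown)}")
    complete = ~responses.data[items].isna().any(axis=1)
    kept = responses.select_persons(responses.data.index[complete])
    excluded = tuple(responses.data.index[~complete].astype(str))
    if kept.n_persons == 0:
        warnings.warn("listwise exclusion removed every person", stacklevel=2)
    return kept, QcReport(
        n_input=responses.n_persons,
        n_after=kept.n_persons,
        excluded_persons=excluded,
        method="listwise_exclude",
    )


def mahalanobis_outliers(
    responses: ResponseMatrix, alpha: float = 0.001
) -> pd.DataFrame:
    """Squared Mahalanobis distance of each person from the column means.

    A person is flagged when ``d^2`` exceeds the chi-squared quantile
    ``1 - alpha`` with ``n_items`` degrees of freedom.  Requires complete
    data.  A singular sample covariance is ridge-regularized
    (``lambda = 1e-6 * trace / p``) with a warning.  ``alpha = 0`` flags
    nothing.

    Returns a DataFrame indexed by person_id with columns ``dist2`` and
    ``flagged``.
    """
    if not 0 <= alpha < 1:
        raise InvalidInputError("alpha must be in [0, 1)")
    X = responses.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise InvalidInputError(
            "mahalanobis_outliers requires complete data; impute or listwise-exclude first"
        )
    n, p = X.shape
    if n < 2:
        raise InvalidInputError("need at least 2 persons for a covariance estimate")
    centered = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    try:
        # raises for exactly singular; near-singular is caught via cond check
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
        solved = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError:
        lam = 1e-6 * np.trace(cov) / p
        if lam <= 0:
            lam = 1e-6
        warnings.warn(
            f"singular covariance; ridge-regularized with lambda={lam:.3g}",
            stacklevel=2,
        )
        solved = np.linalg.solve(cov + lam * np.eye(p), centered.T)
    dist2 = np.einsum("ij,ji->i", centered, solved)
    threshold = np.inf if alpha == 0 else chi2.ppf(1 - alpha, df=p)
    return pd.DataFrame(
        {"dist2": dist2, "flagged": dist2 > threshold}, index=responses.data.index
    )


def _mode_lowest(values: np.ndarray) -> int:
    """Modal value; ties broken toward the lower category."""
    counts = np.bincount(values.astype(int))
    return int(np.argmax(counts))  # argmax returns the first (lowest) maximum


def impute_missing(
    responses: ResponseMatrix,
    method: str = "item_mode",
    bank: ItemBank | None = None,
) -> tuple[ResponseMatrix, QcReport]:
    """Fill missing cells deterministically.

    ``item_mode`` fills with the item's most frequent observed category;
    ``person_scale_mean`` with the person's mean observed response rounded
    half-up.  Imputed values are clipped to the item's legal range (from
    ``bank`` if given, else the observed column maximum).  Every imputed
    cell is logged.
    """
    if method not in IMPUTATION_METHODS:
        raise InvalidInputError(f"unknown imputation method {method!r}")
    data = responses.data.copy()
    log: list[dict] = []
    col_max: dict[str, int] = {}
    for item_id in data.columns:
        if bank is not None:
            col_max[item_id] = bank.item(str(item_id)).max_category
        else:
            obs = data[item_id].dropna()
            col_max[item_id] = int(obs.max()) if len(obs) else 0

    for item_id in data.columns:
        col = data[item_id]
        missing = col.index[col.isna()]
        if len(missing) == 0:
            continue
        if method == "item_mode":
            obs = col.dropna().to_numpy()
            if obs.size == 0:
                raise InvalidInputError(
                    f"item {item_id!r}: no observed values; cannot impute by mode"
                )
            fill = {pid: _mode_lowest(obs) for pid in missing}
        else:  # person_scale_mean
            fill = {}
            for pid in missing:
                row = data.loc[pid].dropna()
                if row.empty:
                    raise InvalidInputError(
                        f"person {pid!r}: no observed responses; cannot impute by "
                        "person mean"
                    )
                fill[pid] = int(np.floor(float(row.mean()) + 0.5))  # round half up
        for pid, value in fill.items():
            value = int(np.clip(value, 0, col_max[item_id]))
            data.loc[pid, item_id] = value
            log.append({"person_id": str(pid), "item_id": str(item_id), "value": value})

    out = ResponseMatrix(data, responses.metadata)
    return out, QcReport(
        n_input=responses.n_persons,
        n_after=out.n_persons,
        imputation_log=tuple(log),
        method=method,
    )
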