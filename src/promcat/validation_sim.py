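"""Replay validation: agreement between adaptive and full-length scores.

The validation design replays each respondent's recorded full-length
responses through the CAT at a grid of fixed assessment lengths, scores
both administrations on the 0-100 scale, and summarizes concordance per
length with three statistics:

* Pearson correlation between CAT and full-length scores;
* RMSE, ``sqrt(mean((cat - full)^2))``, in 0-100 points;
* Bland-Altman 95% limits of agreement, ``mean(d) +/- 1.96 * sd(d)`` with
  ``d = cat - full`` and the sample (n-1) standard deviation.  The limits
  bracket about 95% of individual score differences when differences are
  roughly normal.

Sensitivity arms repeat the computation under the four combinations of
outlier removal (Mahalanobis screening) and missing-data handling
(listwise exclusion vs deterministic imputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import qc
from .calibration import ResponseMatrix
from .cat_engine import CatConfig, eap_estimate, run_cat_replay
from .exceptions import InvalidInputError
from .irt_core import ItemBank, theta_to_score

__all__ = [
    "AgreementReport",
    "agreement_stats",
    "full_length_scores",
    "run_validation",
    "run_sensitivity_grid",
    "select_lengths_table",
    "SENSITIVITY_ARMS",
]

SENSITIVITY_ARMS = ("raw", "outliers_removed", "imputed", "outliers_removed+imputed")

LOA_MULTIPLIER = 1.96  # classical Bland-Altman 95% limits


@dataclass
class AgreementReport:
    """Per-length agreement table for one scale.

    ``table`` columns: cat_length, pearson_r, rmse, loa_lower, loa_upper,
    n_persons.  ``n_items_full`` is the full scale length.
    """

    scale_id: str
    n_items_full: int
    table: pd.DataFrame

    def row(self, cat_length: int) -> pd.Series:
        match = self.table[self.table["cat_length"] == cat_length]
        if match.empty:
            raise InvalidInputError(
                f"scale {self.scale_id!r}: length {cat_length} not in report grid"
            )
        return match.iloc[0]


def agreement_stats(full_scores, cat_scores) -> dict[str, float]:
    """Concordance between paired CAT and full-length scores.

    Returns ``pearson_r`` (NaN with a warning if the full-length scores
    are constant), ``rmse``, and ``loa_lower``/``loa_upper``.  The
    difference convention is ``d = cat - full`` throughout.
    """
    full = np.asarray(full_scores, dtype=float)
    cat = np.asarray(cat_scores, dtype=float)
    if full.shape != cat.shape or full.ndim != 1:
        raise InvalidInputError("full and CAT score vectors must be equal-length 1-D")
    n = len(full)
    if n < 3:
        raise InvalidInputError("agreement requires at least 3 paired scores")
    d = cat - full
    rmse = float(np.sqrt(np.mean(d**2)))
    if np.allclose(d, 0.0):
        # perfect agreement: zero spread, degenerate limits
        mean_d, sd_d = 0.0, 0.0
    else:
        mean_d = float(np.mean(d))
        sd_d = float(np.std(d, ddof=1))
    if np.ptp(full) == 0 or np.ptp(cat) == 0:
        warnings.warn(
            "constant score vector: Pearson r undefined, reported as NaN",
            stacklevel=2,
        )
        r = float("nan")
    else:
        r = float(pearsonr(full, cat).statistic)
    return {
        "pearson_r": r,
        "rmse": rmse,
        "loa_lower": mean_d - LOA_MULTIPLIER * sd_d,
        "loa_upper": mean_d + LOA_MULTIPLIER * sd_d,
    }


def _complete_or_raise(responses: ResponseMatrix, bank: ItemBank) -> pd.DataFrame:
    missing_items = set(bank.item_ids) - set(responses.item_ids)
    if missing_items:
        raise InvalidInputError(f"responses lack bank items: {sorted(missing_items)}")
    data = responses.data[list(bank.item_ids)]
    if data.isna().any().any():
        raise InvalidInputError(
            "replay requires complete responses; run QC (listwise/imputation) first"
        )
    return data


def full_length_scores(
    responses: ResponseMatrix, bank: ItemBank, config: CatConfig
) -> pd.Series:
    """Full-length EAP scores on the 0-100 scale, one per person."""
    data = _complete_or_raise(responses, bank)
    scores = {}
    for pid, row in data.iterrows():
        est = eap_estimate({k: int(v) for k, v in row.items()}, bank, config)
        scores[pid] = theta_to_score(est.theta, bank)
    return pd.Series(scores, name="full_score")


def run_validation(
    responses: ResponseMatrix,
    bank: ItemBank,
    lengths: Sequence[int],
    config: CatConfig,
) -> AgreementReport:
    """Replay every person at every length on the grid and tabulate
    agreement with the full-length score.

    Deterministic given the configuration, and invariant to person row
    order (each person is replayed independently).
    """
    if bank.score_anchors is None:
        raise InvalidInputError(
            f"scale {bank.scale_id!r}: bank must be anchored before validation"
        )
    lengths = [int(l) for l in lengths]
    for l in lengths:
        if not 1 <= l <= len(bank):
            raise InvalidInputError(
                f"length {l} outside [1, {len(bank)}] for scale {bank.scale_id!r}"
            )
    data = _complete_or_raise(responses, bank)
    full = full_length_scores(responses, bank, config)

    rows = []
    for length in lengths:
        cfg = replace(config, stopping_length=length)
        cat_scores = np.empty(len(data))
        for i, (pid, row) in enumerate(data.iterrows()):
            trace = run_cat_replay({k: int(v) for k, v in row.items()}, bank, cfg)
            cat_scores[i] = trace.score
        stats = agreement_stats(full.to_numpy(), cat_scores)
        rows.append({"cat_length": length, **stats, "n_persons": len(data)})
    table = pd.DataFrame(rows)
    return AgreementReport(scale_id=bank.scale_id, n_items_full=len(bank), table=table)


def run_sensitivity_grid(
    responses: ResponseMatrix,
    bank: ItemBank,
    lengths: Sequence[int],
    config: CatConfig,
    alpha: float = 0.001,
    imputation_method: str = "item_mode",
) -> dict[str, AgreementReport]:
    """The four sensitivity arms of the replay study.

    raw                       listwise exclusion of incomplete persons;
    outliers_removed          listwise, then Mahalanobis-flagged persons dropped;
    imputed                   missing responses imputed, everyone retained;
    outliers_removed+imputed  imputed, then Mahalanobis-flagged persons dropped.

    Arms that end up empty are skipped with a warning.  The length grid is
    identical across arms.
    """
    scale_items = list(bank.item_ids)
    arms: dict[str, ResponseMatrix] = {}

    listwise, _ = qc.listwise_exclude(responses, scale_items)
    arms["raw"] = listwise
    if listwise.n_persons >= 2:
        flags = qc.mahalanobis_outliers(
            ResponseMatrix(listwise.data[scale_items], listwise.metadata), alpha
        )
        keep = flags.index[~flags["flagged"]]
        arms["outliers_removed"] = listwise.select_persons(keep)
    imputed, _ = qc.impute_missing(responses, imputation_method, bank=bank)
    arms["imputed"] = imputed
    if imputed.n_persons >= 2:
        flags = qc.mahalanobis_outliers(
            ResponseMatrix(imputed.data[scale_items], imputed.metadata), alpha
        )
        keep = flags.index[~flags["flagged"]]
        arms["outliers_removed+imputed"] = imputed.select_persons(keep)

    reports: dict[str, AgreementReport] = {}
    for arm in SENSITIVITY_ARMS:
        subset = arms.get(arm)
        if subset is None or subset.n_persons < 3:
            warnings.warn(f"sensitivity arm {arm!r} has too few persons; skipped",
                          stacklevel=2)
            continue
        reports[arm] = run_validation(subset, bank, lengths, config)
    return reports


def select_lengths_table(
    reports: Mapping[str, AgreementReport], chosen: Mapping[str, int]
) -> pd.DataFrame:
    """Summary of the chosen assessment length per scale, with totals.

    One row per scale (full length, chosen length, agreement statistics at
    the chosen length) plus a ``TOTAL`` row summing full and chosen item
    counts — the item-burden arithmetic behind reducing a multi-scale
    battery's length.
    """
    rows = []
    for scale_id, report in reports.items():
        if scale_id not in chosen:
            raise InvalidInputError(f"no chosen length for scale {scale_id!r}")
        row = report.row(int(chosen[scale_id]))  # raises if absent from grid
        rows.append(
            {
                "scale_id": scale_id,
                "full_length": report.n_items_full,
                "chosen_length": int(chosen[scale_id]),
                "pearson_r": row["pearson_r"],
                "rmse": row["rmse"],
                "loa_lower": row["loa_lower"],
                "loa_upper": row["loa_upper"],
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "scale_id": "TOTAL",
        "full_length": int(df["full_length"].sum()),
        "chosen_length": int(df["chosen_length"].sum()),
        "pearson_r": np.nan,
        "rmse": np.nan,
        "loa_lower": np.nan,
        "loa_upper": np.nan,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
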