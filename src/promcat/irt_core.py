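"""Polytomous Rasch (partial credit) model primitives.

This module holds the measurement model everything else is built on: the
partial credit model (PCM) in Masters' parameterization,

    P(X = x | theta) ∝ exp( x * theta - sum_{k<=x} delta_k ),   x = 0..m,

where ``theta`` is the person's latent trait on the logit scale and
``delta_k`` are the item's category-step thresholds (``delta_0`` is fixed
at 0 by convention, so an item with ``m + 1`` response categories carries
``m`` free thresholds).  Thresholds are not required to be ordered:
threshold reversals are legal PCM solutions and calibration may produce
them.

All probability arithmetic is done in log space with max subtraction so
that trait values as extreme as ``|theta| = 30`` neither overflow nor
collapse to exact zeros.

The module also provides the linear logit -> 0-100 score transform used
for reporting.  Its anchors (the trait values mapped to 0 and 100) are a
property of the item bank; by convention they are the Bayesian (EAP)
estimates for the all-minimum and all-maximum response vectors, which ties
the score range to the extreme raw scores of the scale (see
:func:`promcat.cat_engine.calibrate_score_anchors`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import log_softmax

from .exceptions import ConfigurationError, InvalidInputError

BANK_FORMAT = "promcat-bank-v1"

__all__ = [
    "BANK_FORMAT",
    "ItemParameters",
    "ItemBank",
    "ThetaEstimate",
    "pcm_category_probabilities",
    "pcm_log_probabilities",
    "expected_score",
    "item_information",
    "response_log_likelihood",
    "theta_to_score",
    "bank_to_dict",
    "bank_from_dict",
    "save_bank",
    "load_bank",
]


@dataclass(frozen=True)
class ItemParameters:
    """One item's PCM parameters.

    Parameters
    ----------
    item_id:
        Unique identifier within a scale.
    thresholds:
        Category-step thresholds ``delta_1 .. delta_m`` (logits).  An item
        with ``m`` thresholds has ``m + 1`` response categories ``0..m``.
    """

    item_id: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        if len(thr) < 1:
            raise InvalidInputError(
                f"item {self.item_id!r}: needs at least one threshold (>= 2 categories)"
            )
        if not all(math.isfinite(t) for t in thr):
            raise InvalidInputError(f"item {self.item_id!r}: thresholds must be finite")
        object.__setattr__(self, "thresholds", thr)

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def max_category(self) -> int:
        return len(self.thresholds)

    @property
    def cumulative_thresholds(self) -> np.ndarray:
        """``sum_{k<=x} delta_k`` for x = 0..m (first entry 0)."""
        return np.concatenate(([0.0], np.cumsum(self.thresholds)))

    @property
    def location(self) -> float:
        """Item location: the mean of its step thresholds (logits)."""
        return float(np.mean(self.thresholds))


@dataclass(frozen=True)
class ItemBank:
    """An ordered, calibrated set of items constituting one scale.

    ``score_anchors = (theta_lo, theta_hi)`` are the trait values mapped to
    0 and 100 by :func:`theta_to_score`; ``None`` until anchoring has been
    performed.
    """

    scale_id: str
    items: tuple[ItemParameters, ...]
    score_anchors: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        items = tuple(self.items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise InvalidInputError(f"scale {self.scale_id!r}: duplicate item_ids")
        object.__setattr__(self, "items", items)
        if self.score_anchors is not None:
            lo, hi = (float(a) for a in self.score_anchors)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise InvalidInputError(
                    f"scale {self.scale_id!r}: score_anchors must satisfy lo < hi"
                )
            object.__setattr__(self, "score_anchors", (lo, hi))

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise InvalidInputError(f"scale {self.scale_id!r}: unknown item {item_id!r}")

    def with_anchors(self, theta_lo: float, theta_hi: float) -> "ItemBank":
        return replace(self, score_anchors=(float(theta_lo), float(theta_hi)))


@dataclass(frozen=True)
class ThetaEstimate:
    """A trait estimate with its posterior standard error (both logits)."""

    theta: float
    se: float
    n_items_used: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta) or not (self.se > 0):
            raise InvalidInputError("ThetaEstimate requires finite theta and se > 0")


def _check_theta(theta) -> np.ndarray:
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("theta must be finite")
    return arr


def pcm_log_probabilities(theta, item: ItemParameters) -> np.ndarray:
    """Log category probabilities, vectorized over ``theta``.

    Returns an array of shape ``theta.shape + (n_categories,)``.
    """
    th = _check_theta(theta)
    x = np.arange(item.n_categories, dtype=float)
    logits = th[..., None] * x - item.cumulative_thresholds
    return log_softmax(logits, axis=-1)


def pcm_category_probabilities(theta: float, item: ItemParameters) -> np.ndarray:
    """Probability of each response category ``0..m`` at trait level ``theta``.

    Numerically stable for ``|theta| <= 30``; entries are positive and sum
    to 1 within 1e-12.
    """
    return np.exp(pcm_log_probabilities(theta, item))


def expected_score(theta, item: ItemParameters) -> np.ndarray | float:
    """Expected response ``E(X | theta)``; vectorized over ``theta``."""
    p = np.exp(pcm_log_probabilities(theta, item))
    x = np.arange(item.n_categories, dtype=float)
    out = p @ x
    return float(out) if np.isscalar(theta) or np.ndim(theta) == 0 else out


def item_information(theta, item: ItemParameters) -> np.ndarray | float:
    """Fisher information of the item response at ``theta``.

    For the PCM this equals the category variance ``Var(X | theta)`` (and
    also the derivative of the expected score).  Vectorized over ``theta``.
    """
    p = np.exp(pcm_log_probabilities(theta, item))
    x = np.arange(item.n_categories, dtype=float)
    mean = p @ x
    var = p @ (x**2) - mean**2
    var = np.maximum(var, 0.0)  # guard tiny negative round-off
    return float(var) if np.isscalar(theta) or np.ndim(theta) == 0 else var


def scale_information(theta, bank: ItemBank) -> np.ndarray | float:
    """Total Fisher information of the bank at ``theta`` (sum over items)."""
    total = sum(item_information(theta, it) for it in bank.items)
    return total


def _validate_response(item: ItemParameters, response: int, scale_id: str) -> int:
    r = response
    if isinstance(r, float):
        if not float(r).is_integer():
            raise InvalidInputError(
                f"scale {scale_id!r}, item {item.item_id!r}: non-integer response {r!r}"
            )
        r = int(r)
    if not isinstance(r, (int, np.integer)):
        raise InvalidInputError(
            f"scale {scale_id!r}, item {item.item_id!r}: non-integer response {r!r}"
        )
    if not (0 <= r <= item.max_category):
        raise InvalidInputError(
            f"scale {scale_id!r}, item {item.item_id!r}: response {r} outside "
            f"[0, {item.max_category}]"
        )
    return int(r)


def response_log_likelihood(
    theta, responses: Mapping[str, int], bank: ItemBank
) -> np.ndarray | float:
    """Log likelihood of a (possibly partial) response pattern at ``theta``.

    ``responses`` maps item_id -> observed category; items absent from the
    mapping are skipped.  Returns 0.0 for an empty pattern.  Vectorized
    over ``theta``.
    """
    th = _check_theta(theta)
    total = np.zeros(th.shape)
    for it in bank.items:  # bank order fixes the floating-point summation order
        if it.item_id not in responses:
            continue
        r = _validate_response(it, responses[it.item_id], bank.scale_id)
        total = total + pcm_log_probabilities(th, it)[..., r]
    if np.ndim(theta) == 0:
        return float(total)
    return total


def theta_to_score(theta, bank: ItemBank) -> np.ndarray | float:
    """Map a trait value to the 0-100 reporting scale.

    Linear between the bank's anchors (theta_lo -> 0, theta_hi -> 100),
    clipped outside.  Vectorized over ``theta``.
    """
    if bank.score_anchors is None:
        raise ConfigurationError(
            f"scale {bank.scale_id!r}: score_anchors unset; anchor the bank first "
            "(see promcat.cat_engine.calibrate_score_anchors)"
        )
    lo, hi = bank.score_anchors
    th = _check_theta(theta)
    score = np.clip(100.0 * (th - lo) / (hi - lo), 0.0, 100.0)
    return float(score) if np.ndim(theta) == 0 else score


# ---------------------------------------------------------------------------
# Bank JSON serialization ("promcat-bank-v1")
# ---------------------------------------------------------------------------

def bank_to_dict(bank: ItemBank) -> dict:
    return {
        "format": BANK_FORMAT,
        "scale_id": bank.scale_id,
        "score_anchors": list(bank.score_anchors) if bank.score_anchors else None,
        "items": [
            {
                "item_id": it.item_id,
                "n_categories": it.n_categories,
                "thresholds": list(it.thresholds),
            }
            for it in bank.items
        ],
    }


def bank_from_dict(payload: Mapping) -> ItemBank:
    fmt = payload.get("format")
    if fmt != BANK_FORMAT:
        raise InvalidInputError(f"unsupported bank format {fmt!r} (expected {BANK_FORMAT!r})")
    items = []
    for raw in payload["items"]:
        item = ItemParameters(str(raw["item_id"]), tuple(raw["thresholds"]))
        declared = raw.get("n_categories")
        if declared is not None and int(declared) != item.n_categories:
            raise InvalidInputError(
                f"item {item.item_id!r}: n_categories={declared} inconsistent with "
                f"{len(item.thresholds)} thresholds"
            )
        items.append(item)
    anchors = payload.get("score_anchors")
    return ItemBank(
        scale_id=str(payload["scale_id"]),
        items=tuple(items),
        score_anchors=tuple(anchors) if anchors is not None else None,
    )


def save_bank(bank: ItemBank, path: str | Path) -> None:
    Path(path).write_text(json.dumps(bank_to_dict(bank), indent=2) + "\n")


def load_bank(path: str | Path) -> ItemBank:
    return bank_from_dict(json.loads(Path(path).read_text()))
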