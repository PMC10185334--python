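"""The adaptive assessment engine: score estimation, item selection, stopping.

A basic computerized adaptive test (CAT) has three components:

* a **score estimator** — here expected-a-posteriori (EAP): the posterior
  mean of theta under a Normal prior, evaluated by fixed quadrature on an
  evenly spaced grid weighted by the prior density (61 points over
  prior_mean +/- 6 logits by default);
* an **item selection criterion** — by default the item with maximum
  Fisher information at the current EAP; alternatively information
  averaged over the current posterior (``posterior_weighted_info``);
* a **stopping rule** — a fixed number of items per scale.

Two administration modes share the identical algorithm:
:func:`run_cat_replay` answers each selected item from a recorded
full-length response vector (the post-hoc simulation used for validation),
and :func:`run_cat_live` obtains answers from a callback.  Replay at full
length reproduces the full-length EAP bitwise because every estimate is
recomputed from scratch on the same quadrature grid with the same
summation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping

import numpy as np
from scipy.special import softmax

from .exceptions import AssessmentComplete, ConfigurationError, InvalidInputError
from .irt_core import (
    ItemBank,
    ItemParameters,
    ThetaEstimate,
    _validate_response,
    item_information,
    pcm_log_probabilities,
    theta_to_score,
)

__all__ = [
    "CatConfig",
    "CatState",
    "CatStep",
    "CatTrace",
    "eap_estimate",
    "select_next_item",
    "run_cat_replay",
    "run_cat_live",
    "calibrate_score_anchors",
]

SELECTION_RULES = ("max_info_at_eap", "posterior_weighted_info")


@dataclass(frozen=True)
class CatConfig:
    """Settings for one adaptive administration.

    Parameters
    ----------
    prior_mean, prior_sd:
        Normal prior on theta (logits).  Defaults N(0, 1).
    n_quadrature, quadrature_range:
        Number of evenly spaced quadrature nodes and their half-width
        around ``prior_mean`` (logits).
    stopping_length:
        Fixed number of items to administer; ``None`` means the full bank.
    selection_rule:
        ``max_info_at_eap`` (default) or ``posterior_weighted_info``.
    tie_break_seed:
        If set, exact criterion ties are broken by a seeded random
        preference order over bank positions; otherwise by lowest bank
        position.
    """

    prior_mean: float = 0.0
    prior_sd: float = 1.0
    n_quadrature: int = 61
    quadrature_range: float = 6.0
    stopping_length: int | None = None
    selection_rule: str = "max_info_at_eap"
    tie_break_seed: int | None = None

    def __post_init__(self) -> None:
        if not self.prior_sd > 0:
            raise ConfigurationError("prior_sd must be > 0")
        if self.n_quadrature < 21:
            raise ConfigurationError("n_quadrature must be >= 21")
        if not self.quadrature_range > 0:
            raise ConfigurationError("quadrature_range must be > 0")
        if self.selection_rule not in SELECTION_RULES:
            raise ConfigurationError(
                f"selection_rule must be one of {SELECTION_RULES}, got {self.selection_rule!r}"
            )
        if self.stopping_length is not None and self.stopping_length < 1:
            raise ConfigurationError("stopping_length must be >= 1")


@lru_cache(maxsize=128)
def _bank_tables(bank: ItemBank, config: CatConfig):
    """Per-(bank, config) quadrature tables: nodes, log-prior, per-item
    log-probability matrices (n_categories x n_nodes) and information
    curves on the grid.  Cached; arrays are read-only."""
    nodes = config.prior_mean + np.linspace(
        -config.quadrature_range, config.quadrature_range, config.n_quadrature
    )
    log_prior = -0.5 * ((nodes - config.prior_mean) / config.prior_sd) ** 2
    logp = {}
    info = {}
    for it in bank.items:
        m = pcm_log_probabilities(nodes, it).T  # (n_cat, n_nodes)
        m.flags.writeable = False
        logp[it.item_id] = m
        g = np.asarray(item_information(nodes, it))
        g.flags.writeable = False
        info[it.item_id] = g
    nodes.flags.writeable = False
    log_prior.flags.writeable = False
    return nodes, log_prior, logp, info


def _posterior(responses: Mapping[str, int], bank: ItemBank, config: CatConfig):
    """Posterior weights over the quadrature nodes (normalized)."""
    nodes, log_prior, logp, _ = _bank_tables(bank, config)
    lp = log_prior.copy()
    n_used = 0
    for it in bank.items:  # bank order fixes the summation order
        if it.item_id in responses:
            r = _validate_response(it, responses[it.item_id], bank.scale_id)
            lp += logp[it.item_id][r]
            n_used += 1
    return nodes, softmax(lp), n_used


def eap_estimate(
    responses: Mapping[str, int], bank: ItemBank, config: CatConfig
) -> ThetaEstimate:
    """Expected-a-posteriori trait estimate from a partial response pattern.

    With no observed responses the posterior equals the prior, so the
    estimate returns the prior mean and prior SD (up to quadrature error).
    Deterministic for a fixed configuration.
    """
    nodes, w, n_used = _posterior(responses, bank, config)
    theta = float(w @ nodes)
    var = float(w @ (nodes - theta) ** 2)
    return ThetaEstimate(theta=theta, se=float(np.sqrt(var)), n_items_used=n_used)


@dataclass(frozen=True)
class CatState:
    """The evolving state of one administration."""

    responses: Mapping[str, int]
    estimate: ThetaEstimate

    @property
    def administered(self) -> frozenset[str]:
        return frozenset(self.responses)


def _tie_preference(bank: ItemBank, config: CatConfig) -> np.ndarray:
    """Preference rank per bank position for breaking exact ties: identity
    (lowest position wins) unless a tie_break_seed configures a seeded
    permutation."""
    n = len(bank)
    if config.tie_break_seed is None:
        return np.arange(n)
    rng = np.random.default_rng(config.tie_break_seed)
    perm = rng.permutation(n)
    rank = np.empty(n, dtype=int)
    rank[perm] = np.arange(n)
    return rank


def select_next_item(state: CatState, bank: ItemBank, config: CatConfig) -> str:
    """The item the selection rule poses next.

    ``max_info_at_eap``: argmax of Fisher information at the current EAP.
    ``posterior_weighted_info``: argmax of information averaged over the
    current posterior.  Exact ties go to the lowest bank position (or to a
    seed-determined order when configured).
    """
    remaining = [
        (pos, it) for pos, it in enumerate(bank.items) if it.item_id not in state.responses
    ]
    if not remaining:
        raise AssessmentComplete(f"scale {bank.scale_id!r}: no items remain")

    if config.selection_rule == "max_info_at_eap":
        crit = np.array(
            [item_information(state.estimate.theta, it) for _, it in remaining]
        )
    else:  # posterior_weighted_info
        _, w, _ = _posterior(state.responses, bank, config)
        _, _, _, info = _bank_tables(bank, config)
        crit = np.array([float(w @ info[it.item_id]) for _, it in remaining])

    best = crit.max()
    tied = [i for i, c in enumerate(crit) if c == best]
    if len(tied) == 1:
        return remaining[tied[0]][1].item_id
    pref = _tie_preference(bank, config)
    winner = min(tied, key=lambda i: pref[remaining[i][0]])
    return remaining[winner][1].item_id


@dataclass(frozen=True)
class CatStep:
    item_id: str
    response: int
    theta: float
    se: float


@dataclass(frozen=True)
class CatTrace:
    """Record of one adaptive administration: items posed in order, each
    with the response used and the running estimate after it, plus the
    final estimate and 0-100 score (``None`` if the bank is unanchored)."""

    scale_id: str
    steps: tuple[CatStep, ...]
    estimate: ThetaEstimate
    score: float | None

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(s.item_id for s in self.steps)


def _resolve_length(bank: ItemBank, config: CatConfig) -> int:
    length = config.stopping_length if config.stopping_length is not None else len(bank)
    if not 1 <= length <= len(bank):
        raise ConfigurationError(
            f"stopping_length {length} outside [1, {len(bank)}] for scale {bank.scale_id!r}"
        )
    return length


def _run(
    answer: Callable[[ItemParameters], int],
    bank: ItemBank,
    config: CatConfig,
) -> CatTrace:
    length = _resolve_length(bank, config)
    responses: dict[str, int] = {}
    estimate = eap_estimate(responses, bank, config)
    steps: list[CatStep] = []
    for _ in range(length):
        item_id = select_next_item(CatState(responses, estimate), bank, config)
        item = bank.item(item_id)
        resp = answer(item)
        responses[item_id] = resp
        estimate = eap_estimate(responses, bank, config)
        steps.append(CatStep(item_id, resp, estimate.theta, estimate.se))
    score = theta_to_score(estimate.theta, bank) if bank.score_anchors else None
    return CatTrace(bank.scale_id, tuple(steps), estimate, score)


def run_cat_replay(
    full_responses: Mapping[str, int], bank: ItemBank, config: CatConfig
) -> CatTrace:
    """Replay the CAT against a recorded complete response vector.

    Every selected item is answered from ``full_responses``, which must
    contain a valid category for each bank item (quality control happens
    upstream).  Deterministic: identical inputs give identical traces.
    """
    for it in bank.items:
        if it.item_id not in full_responses:
            raise InvalidInputError(
                f"scale {bank.scale_id!r}: replay requires a complete vector; "
                f"item {it.item_id!r} missing"
            )
        _validate_response(it, full_responses[it.item_id], bank.scale_id)
    return _run(lambda item: int(full_responses[item.item_id]), bank, config)


def run_cat_live(
    response_callback: Callable[[ItemParameters], object],
    bank: ItemBank,
    config: CatConfig,
    max_retries: int = 3,
) -> CatTrace:
    """Administer the CAT interactively.

    ``response_callback(item)`` is called for each posed item and must
    return a category in ``[0, m_i]``.  An invalid return is re-prompted up
    to ``max_retries`` times, then the assessment aborts.
    """

    def answer(item: ItemParameters) -> int:
        for _ in range(1 + max_retries):
            raw = response_callback(item)
            try:
                return _validate_response(item, raw, bank.scale_id)
            except InvalidInputError:
                continue
        raise InvalidInputError(
            f"scale {bank.scale_id!r}, item {item.item_id!r}: no valid response "
            f"after {1 + max_retries} prompts"
        )

    return _run(answer, bank, config)


def calibrate_score_anchors(bank: ItemBank, config: CatConfig | None = None) -> ItemBank:
    """Anchor the 0-100 transform to the estimator's own extremes.

    ``theta_lo`` / ``theta_hi`` are the EAP estimates for the all-minimum
    and all-maximum full-length response vectors, so a respondent at an
    extreme raw score maps exactly to 0 or 100 and the transform is
    consistent with the scale's estimator.
    """
    config = config or CatConfig()
    lo = eap_estimate({it.item_id: 0 for it in bank.items}, bank, config).theta
    hi = eap_estimate(
        {it.item_id: it.max_category for it in bank.items}, bank, config
    ).theta
    return bank.with_anchors(lo, hi)
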