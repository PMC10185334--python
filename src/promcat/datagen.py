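"""Seeded synthetic data emulating a multi-scale PROM field test.

No patient-level response data are publicly available for the instrument
this engine targets, so every other module is exercised on synthetic
fixtures generated here.  The default :class:`SimulationSpec` mirrors the
structure of the real field test: eight scales with item counts
(9, 7, 8, 10, 10, 10, 12, 10), items with 3-5 ordered response
categories, respondents drawn from a continuous latent trait
``theta ~ N(0, 1)``, and a demographic mix (ages 8-29, a slight male
preponderance, cleft types dominated by CLAP) that matches the field-test
marginals qualitatively.

All randomness flows through :func:`numpy.random.default_rng` (PCG64)
seeded from the spec, so any seed reproduces the identical dataset
bit-for-bit.  True trait values are returned alongside the responses;
they exist only so tests can use them as oracles and must never feed the
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ResponseMatrix
from .exceptions import InvalidInputError
from .irt_core import ItemBank, ItemParameters, pcm_log_probabilities

__all__ = [
    "SimulationSpec",
    "generate_bank",
    "simulate_responses",
    "inject_artifacts",
    "generate_dataset",
]

DEFAULT_SCALES: tuple[tuple[str, int], ...] = (
    ("face", 9),
    ("jaw", 7),
    ("teeth", 8),
    ("school", 10),
    ("psychological", 10),
    ("speech_distress", 10),
    ("speech_function", 12),
    ("social", 10),
)

_CLEFT_TYPES = ("CL", "CP", "CLA", "CLAP")
_CLEFT_WEIGHTS = (0.11, 0.24, 0.08, 0.57)  # CLAP-dominated, as in cleft cohorts
_LATERALITY = ("left", "right", "bilateral", "not_applicable")
_LATERALITY_WEIGHTS = (0.40, 0.20, 0.15, 0.25)
_COUNTRIES = (
    "Canada", "United States", "England", "The Netherlands", "India", "Colombia",
    "Ireland", "Sweden", "Chile", "Spain", "Turkey", "Australia",
)
_COUNTRY_WEIGHTS = (0.20, 0.15, 0.13, 0.08, 0.10, 0.08, 0.04, 0.04, 0.04, 0.04, 0.02, 0.08)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one synthetic field test.

    ``scales`` lists (scale_id, n_items).  ``n_categories_range`` bounds
    the per-item category count (inclusive).  ``missing_rate`` and
    ``outlier_rate`` are 0 by default: artifacts are injected explicitly
    with :func:`inject_artifacts`.
    """

    scales: tuple[tuple[str, int], ...] = DEFAULT_SCALES
    n_categories_range: tuple[int, int] = (3, 5)
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    n_persons: int = 500
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    age_range: tuple[int, int] = (8, 29)
    male_fraction: float = 0.55
    seed: int = 20230427

    def __post_init__(self) -> None:
        for name, rate in (("missing_rate", self.missing_rate),
                           ("outlier_rate", self.outlier_rate)):
            if not 0 <= rate <= 1:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        if self.n_persons < 1 or any(n < 1 for _, n in self.scales):
            raise InvalidInputError("counts must be positive")
        lo, hi = self.n_categories_range
        if not 2 <= lo <= hi:
            raise InvalidInputError("n_categories_range must satisfy 2 <= lo <= hi")
        if not self.theta_sd > 0:
            raise InvalidInputError("theta_sd must be > 0")


def _scale_rng(spec: SimulationSpec, scale_index: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, scale, purpose)."""
    return np.random.default_rng([spec.seed, scale_index, stream])


def generate_bank(spec: SimulationSpec, scale_index: int) -> ItemBank:
    """Draw one scale's item bank.

    Item locations are drawn N(0, 1) and each item's steps are spread
    evenly around its location with half-spacing U(0.2, 1), giving banks
    whose information covers the bulk of the trait distribution.  The
    thresholds of the whole scale are then centered to mean zero, matching
    the calibration identification constraint.
    """
    if not 0 <= scale_index < len(spec.scales):
        raise InvalidInputError(f"scale_index {scale_index} out of range")
    scale_id, n_items = spec.scales[scale_index]
    rng = _scale_rng(spec, scale_index, stream=0)
    lo_cat, hi_cat = spec.n_categories_range
    items = []
    for i in range(n_items):
        n_cat = int(rng.integers(lo_cat, hi_cat + 1))
        location = rng.normal(0.0, 1.0)
        spread = rng.uniform(0.2, 1.0)
        m = n_cat - 1
        offsets = (np.arange(m) - (m - 1) / 2.0) * spread
        items.append(ItemParameters(f"{scale_id}_{i + 1:02d}", tuple(location + offsets)))
    all_thr = np.concatenate([np.asarray(it.thresholds) for it in items])
    center = float(all_thr.mean())
    items = [
        ItemParameters(it.item_id, tuple(np.asarray(it.thresholds) - center))
        for it in items
    ]
    return ItemBank(scale_id=scale_id, items=tuple(items))


def _sample_categories(
    rng: np.random.Generator, thetas: np.ndarray, item: ItemParameters
) -> np.ndarray:
    p = np.exp(pcm_log_probabilities(thetas, item))
    cum = np.cumsum(p, axis=1)
    u = rng.uniform(size=(len(thetas), 1))
    return (u > cum[:, :-1]).sum(axis=1)


def _sample_demographics(rng: np.random.Generator, n: int, spec: SimulationSpec) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n),
            "gender": rng.choice(
                ["male", "female"], size=n,
                p=[spec.male_fraction, 1 - spec.male_fraction],
            ),
            "cleft_type": rng.choice(_CLEFT_TYPES, size=n, p=_CLEFT_WEIGHTS),
            "laterality": rng.choice(_LATERALITY, size=n, p=_LATERALITY_WEIGHTS),
            "country": rng.choice(_COUNTRIES, size=n, p=_COUNTRY_WEIGHTS),
        }
    )


def simulate_responses(
    bank: ItemBank, spec: SimulationSpec, scale_index: int = 0
) -> tuple[ResponseMatrix, pd.Series]:
    """Simulate a complete response matrix from the PCM.

    Each person's trait is drawn from ``N(theta_mean, theta_sd^2)`` and
    every response from the model's category distribution at that trait.
    Returns the matrix and the true traits (oracle-only; never feed them
    to estimators).
    """
    rng = _scale_rng(spec, scale_index, stream=1)
    n = spec.n_persons
    thetas = rng.normal(spec.theta_mean, spec.theta_sd, size=n)
    person_ids = [f"P{idx + 1:05d}" for idx in range(n)]
    data = {}
    for item in bank.items:
        data[item.item_id] = _sample_categories(rng, thetas, item)
    df = pd.DataFrame(data, index=pd.Index(person_ids, name="person_id"), dtype=float)
    meta = _sample_demographics(rng, n, spec)
    meta.index = df.index
    truth = pd.Series(thetas, index=df.index, name="true_theta")
    return ResponseMatrix(df, meta), truth


def inject_artifacts(
    responses: ResponseMatrix,
    spec: SimulationSpec,
    bank: ItemBank,
    scale_index: int = 0,
    outlier_positions: Sequence[int] | None = None,
) -> tuple[ResponseMatrix, dict]:
    """Inject ground-truth artifacts into a complete matrix.

    Cells are set missing independently at ``missing_rate``.  A fraction
    ``outlier_rate`` of persons are overwritten with anti-model response
    patterns: on every item, independently, the bottom or the top category
    at random.  No single trait level can generate such a pattern — a
    model-consistent respondent's responses all track one theta — so these
    rows break the inter-item correlation structure and are genuine
    multivariate outliers rather than merely extreme scorers.  Randomizing
    the extreme per item also spreads the outliers across many directions,
    so they do not mask one another in the sample covariance.

    ``outlier_positions`` overrides the random choice of which persons to
    overwrite; :func:`generate_dataset` uses it to corrupt the same
    persons on every scale, emulating careless or adversarial responders
    across a battery (multivariate screening is most powerful on the
    combined battery).

    Returns the modified matrix and an injection log with the ground-truth
    outlier ids and missing cells.
    """
    if responses.data.isna().any().any():
        raise InvalidInputError("inject_artifacts requires a complete matrix")
    rng = _scale_rng(spec, scale_index, stream=2)
    data = responses.data.copy()
    n = responses.n_persons

    outlier_ids: list[str] = []
    if spec.outlier_rate > 0 or outlier_positions is not None:
        if outlier_positions is None:
            n_out = int(round(spec.outlier_rate * n))
            outlier_positions = rng.choice(n, size=n_out, replace=False)
        for pos in sorted(int(p) for p in outlier_positions):
            pid = data.index[pos]
            for item in bank.items:
                extreme_high = rng.uniform() < 0.5
                data.loc[pid, item.item_id] = item.max_category if extreme_high else 0
            outlier_ids.append(str(pid))

    missing_cells: list[tuple[str, str]] = []
    if spec.missing_rate > 0:
        mask = rng.uniform(size=data.shape) < spec.missing_rate
        rows, cols = np.nonzero(mask)
        arr = data.to_numpy()
        arr[rows, cols] = np.nan
        data = pd.DataFrame(arr, index=data.index, columns=data.columns)
        missing_cells = [
            (str(data.index[r]), str(data.columns[c])) for r, c in zip(rows, cols)
        ]

    log = {
        "outlier_ids": tuple(outlier_ids),
        "missing_cells": tuple(missing_cells),
        "missing_rate": spec.missing_rate,
        "outlier_rate": spec.outlier_rate,
    }
    return ResponseMatrix(data, responses.metadata), log


def generate_dataset(
    spec: SimulationSpec,
) -> dict[str, dict]:
    """All scales at once: ``{scale_id: {bank, responses, truth, injection}}``.

    Artifacts are injected only when the spec's rates are nonzero, so the
    default spec yields complete, outlier-free matrices.
    """
    out: dict[str, dict] = {}
    outlier_positions = None
    if spec.outlier_rate > 0:
        # one battery-wide draw: the same persons are corrupted on every scale
        rng = np.random.default_rng([spec.seed, len(spec.scales), 3])
        n_out = int(round(spec.outlier_rate * spec.n_persons))
        outlier_positions = rng.choice(spec.n_persons, size=n_out, replace=False)
    for idx, (scale_id, _) in enumerate(spec.scales):
        bank = generate_bank(spec, idx)
        responses, truth = simulate_responses(bank, spec, scale_index=idx)
        injection = None
        if spec.missing_rate > 0 or spec.outlier_rate > 0:
            responses, injection = inject_artifacts(
                responses, spec, bank, scale_index=idx,
                outlier_positions=outlier_positions,
            )
        out[scale_id] = {
            "bank": bank,
            "responses": responses,
            "truth": truth,
            "injection": injection,
        }
    return out
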