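"""Partial credit model calibration from full-length response matrices.

Estimation is marginal maximum likelihood (MML): the latent trait is
integrated out against a fixed standard-normal density on a quadrature
grid (EM), and each item's step thresholds are updated with damped Newton
steps on the expected complete-data log likelihood until the largest
threshold update falls below tolerance.  Unlike joint (person-by-item)
maximum likelihood, MML is consistent at a fixed test length — joint
estimation inflates the threshold spread by a factor near L/(L-1) for an
L-item scale, which is material at the 7-12 item scales this engine
targets.  The scale is identified by recentering all thresholds of the
scale to mean zero at convergence (shifting the latent origin
accordingly).

Person trait estimates reported alongside the bank are per-person maximum
likelihood at the calibrated thresholds; persons with an extreme raw
score (all-minimum or all-maximum over their observed items) have no
finite trait MLE and are reported as excluded from person estimation
(logged, not fatal) — they still inform the item thresholds through the
marginal likelihood.

Unobserved *extreme* categories are structurally collapsed (the category
coding is shifted/truncated and the collapse recorded); an unobserved
*interior* category is an error, because a step threshold between two
never-seen adjacent categories is not estimable.

Fit diagnostics are the standard Rasch mean-squares: outfit (unweighted
mean of squared standardized residuals) and infit (information-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, InvalidInputError
from .irt_core import ItemBank, ItemParameters, pcm_log_probabilities

__all__ = [
    "ResponseMatrix",
    "CalibrationConfig",
    "CalibrationResult",
    "calibrate_pcm",
    "item_fit",
]

_META_PREFIX = "meta_"


@dataclass
class ResponseMatrix:
    """Persons x items integer category codes with explicit missingness.

    ``data`` is a float DataFrame (person_id index, item_id columns) where
    NaN marks a missing response; observed entries must be non-negative
    integers.  ``metadata`` holds per-person demographics (age, gender,
    cleft_type, laterality, country, ...) on the same index.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            raise InvalidInputError("person_ids must be unique")
        if self.data.columns.has_duplicates:
            raise InvalidInputError("item_ids must be unique")
        vals = self.data.to_numpy()
        obs = vals[~np.isnan(vals)]
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            bad = np.argwhere(
                ~np.isnan(vals) & ((vals < 0) | (vals != np.round(vals)))
            )[0]
            raise InvalidInputError(
                f"response at person {self.data.index[bad[0]]!r}, item "
                f"{self.data.columns[bad[1]]!r} is not a non-negative integer"
            )
        if self.metadata is not None:
            self.metadata = self.metadata.reindex(self.data.index)

    @property
    def person_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_persons(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            self.data.copy(),
            self.metadata.copy() if self.metadata is not None else None,
        )

    def select_persons(self, person_ids: Sequence) -> "ResponseMatrix":
        return ResponseMatrix(
            self.data.loc[list(person_ids)],
            self.metadata.loc[list(person_ids)] if self.metadata is not None else None,
        )

    # -- CSV round trip ----------------------------------------------------
    # Layout: first column person_id; item columns hold integer categories
    # starting at 0 with blank = missing; demographic columns are prefixed
    # "meta_".

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        meta_cols = [c for c in df.columns if c.startswith(_META_PREFIX)]
        meta = None
        if meta_cols:
            meta = df[meta_cols].rename(
                columns={c: c[len(_META_PREFIX):] for c in meta_cols}
            )
        resp = df.drop(columns=meta_cols)
        for col in resp.columns:
            try:
                resp[col] = pd.to_numeric(resp[col])
            except (TypeError, ValueError) as exc:
                raise InvalidInputError(
                    f"column {col!r}: non-numeric response value ({exc})"
                ) from None
        return cls(resp, meta)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out = out.astype("Int64")  # nullable ints -> blank cells for NaN
        if self.metadata is not None:
            meta = self.metadata.rename(
                columns={c: _META_PREFIX + str(c) for c in self.metadata.columns}
            )
            out = pd.concat([out, meta], axis=1)
        out.index.name = "person_id"
        out.to_csv(path)


@dataclass(frozen=True)
class CalibrationConfig:
    """MML settings: quadrature for the latent density, convergence
    tolerance on the largest threshold update, iteration caps, and the
    clip bound for person trait estimates."""

    scale_id: str = "scale"
    max_iter: int = 500
    tol: float = 1e-6
    theta_clip: float = 10.0
    inner_person_iter: int = 50
    n_quadrature: int = 61
    quadrature_range: float = 6.0


@dataclass
class CalibrationResult:
    bank: ItemBank
    convergence: dict
    person_theta: pd.Series  # NaN for persons excluded from estimation
    collapse_map: dict[str, tuple[int, int]]  # item_id -> (lowest, highest) observed
    excluded_persons: tuple[str, ...]


def _collapse_categories(data: pd.DataFrame) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Shift codes so every item's observed categories are 0..m; unobserved
    extreme categories collapse away, interior gaps are fatal."""
    X = data.to_numpy(dtype=float).copy()
    collapse: dict[str, tuple[int, int]] = {}
    for j, item_id in enumerate(data.columns):
        col = X[:, j]
        obs = col[~np.isnan(col)].astype(int)
        if obs.size == 0:
            raise CalibrationError(f"item {item_id!r}: no observed responses")
        cats = np.unique(obs)
        lo, hi = int(cats[0]), int(cats[-1])
        if hi == lo:
            raise CalibrationError(
                f"item {item_id!r}: only category {lo} observed; cannot calibrate"
            )
        missing_interior = sorted(set(range(lo, hi + 1)) - set(cats.tolist()))
        if missing_interior:
            raise CalibrationError(
                f"item {item_id!r}: interior category {missing_interior[0]} has no "
                "observations"
            )
        X[:, j] = col - lo
        collapse[str(item_id)] = (lo, hi)
    return X, collapse


def _person_newton(
    theta: np.ndarray,
    X: np.ndarray,
    cum: list[np.ndarray],
    include: np.ndarray,
    cfg: CalibrationConfig,
) -> np.ndarray:
    """Newton updates of person traits given thresholds (vectorized over
    persons).  ``cum[j]`` is item j's cumulative-threshold vector."""
    theta = theta.copy()
    for _ in range(cfg.inner_person_iter):
        resid = np.zeros_like(theta)
        info = np.zeros_like(theta)
        for j, c in enumerate(cum):
            obs = include & ~np.isnan(X[:, j])
            if not obs.any():
                continue
            x = np.arange(len(c), dtype=float)
            logits = theta[obs, None] * x - c
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            mean = p @ x
            var = np.maximum(p @ (x**2) - mean**2, 1e-12)
            resid[obs] += X[obs, j] - mean
            info[obs] += var
        step = np.zeros_like(theta)
        step[include] = resid[include] / np.maximum(info[include], 1e-10)
        step = np.clip(step, -1.0, 1.0)
        theta = np.clip(theta + step, -cfg.theta_clip, cfg.theta_clip)
        if np.max(np.abs(step[include]), initial=0.0) < cfg.tol / 10:
            break
    return theta


def _item_newton_weighted(
    delta: np.ndarray, nodes: np.ndarray, n_q: np.ndarray, r_geq: np.ndarray
) -> np.ndarray:
    """One damped Newton step for one item's thresholds in the M-step.

    ``n_q`` is the expected number of responders at each quadrature node
    and ``r_geq[q, k]`` the expected count of responses ``>= k+1`` there.
    The gradient of the expected complete-data log likelihood w.r.t.
    ``delta_k`` is ``sum_q [ P_q(X >= k) * n_q - r_geq[q, k] ]`` and the
    Hessian is minus the weighted covariance of the indicators
    ``1{X >= k}``.
    """
    m = len(delta)
    cats = np.arange(m + 1, dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(delta)))
    logits = nodes[:, None] * cats - cum
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    # P(X >= k) for k = 1..m, per node
    tail = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]
    grad = (tail * n_q[:, None] - r_geq).sum(axis=0)
    kk, ll = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    tail_max = tail[:, np.maximum(kk, ll)]  # P(X >= max(k, l)) per node
    hess = ((tail[:, kk] * tail[:, ll] - tail_max) * n_q[:, None, None]).sum(axis=0)
    hess -= 1e-8 * np.eye(m)
    step = np.linalg.solve(hess, grad)
    norm = np.max(np.abs(step))
    if norm > 1.0:
        step *= 1.0 / norm
    return delta - step


def calibrate_pcm(
    responses: ResponseMatrix, config: CalibrationConfig | None = None
) -> CalibrationResult:
    """Estimate PCM thresholds for one scale by marginal maximum likelihood.

    EM over a standard-normal latent density on a fixed quadrature grid;
    each M-step applies damped Newton updates per item.  Thresholds are
    recentered to mean zero across the scale at convergence.  Raises
    :class:`CalibrationError` when fewer than two items are present or an
    interior category is unobserved.  Extreme-score persons (no finite
    trait MLE) are reported in ``excluded_persons``.
    """
    cfg = config or CalibrationConfig()
    if len(responses.item_ids) < 2:
        raise CalibrationError("calibration requires at least 2 items")
    X, collapse = _collapse_categories(responses.data)
    n, p = X.shape
    max_cat = np.array([hi - lo for lo, hi in collapse.values()], dtype=float)

    observed = ~np.isnan(X)
    raw = np.nansum(X, axis=1)
    raw_max = observed @ max_cat
    any_obs = observed.any(axis=1)
    extreme = any_obs & ((raw <= 0) | (raw >= raw_max))
    if any_obs.sum() < 2:
        raise CalibrationError("fewer than 2 persons with responses; cannot calibrate")

    # initial thresholds from adjacent-category log odds
    deltas: list[np.ndarray] = []
    for j in range(p):
        col = X[any_obs, j]
        col = col[~np.isnan(col)].astype(int)
        counts = np.bincount(col, minlength=int(max_cat[j]) + 1).astype(float)
        deltas.append(np.log(counts[:-1] / counts[1:]))

    nodes = np.linspace(-cfg.quadrature_range, cfg.quadrature_range, cfg.n_quadrature)
    log_w0 = -0.5 * nodes**2  # standard-normal latent density (unnormalized)
    # indicator tables per item: ge[j][person, k] = 1{x >= k+1}, obs rows only
    ge_tables = []
    for j in range(p):
        mask = observed[:, j]
        ge_tables.append(
            (mask, (X[mask, j][:, None] >= np.arange(1, int(max_cat[j]) + 1)).astype(float))
        )

    iterations = 0
    max_change = np.inf
    for iterations in range(1, cfg.max_iter + 1):
        # E-step: posterior weights over nodes per person
        logW = np.tile(log_w0, (n, 1))
        for j, d in enumerate(deltas):
            cats = np.arange(len(d) + 1, dtype=float)
            cum = np.concatenate(([0.0], np.cumsum(d)))
            logits = nodes[:, None] * cats - cum
            logits -= logits.max(axis=1, keepdims=True)
            logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
            mask = observed[:, j]
            logW[mask] += logp[:, X[mask, j].astype(int)].T
        logW -= logW.max(axis=1, keepdims=True)
        W = np.exp(logW)
        W /= W.sum(axis=1, keepdims=True)

        # M-step: a few damped Newton updates per item
        new_deltas = []
        for j, d in enumerate(deltas):
            mask, ge = ge_tables[j]
            W_obs = W[mask]
            n_q = W_obs.sum(axis=0)
            r_geq = W_obs.T @ ge
            new_d = d
            for _ in range(3):
                new_d = _item_newton_weighted(new_d, nodes, n_q, r_geq)
            new_deltas.append(new_d)

        max_change = max(
            float(np.max(np.abs(nd - od))) for nd, od in zip(new_deltas, deltas)
        )
        deltas = new_deltas
        if max_change < cfg.tol:
            break

    # identification: recenter thresholds to mean zero (shifts the latent
    # origin by the same amount)
    center = float(np.mean(np.concatenate(deltas)))
    deltas = [d - center for d in deltas]

    items = tuple(
        ItemParameters(str(item_id), tuple(deltas[j]))
        for j, item_id in enumerate(responses.item_ids)
    )
    bank = ItemBank(scale_id=cfg.scale_id, items=items)

    # person trait MLEs at the calibrated thresholds (extremes have none)
    include = any_obs & ~extreme
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.log((raw + 0.5) / (raw_max - raw + 0.5))
    theta = np.clip(np.nan_to_num(theta), -cfg.theta_clip, cfg.theta_clip)
    cum = [np.concatenate(([0.0], np.cumsum(d))) for d in deltas]
    theta = _person_newton(theta, X, cum, include, cfg)

    person_theta = pd.Series(
        np.where(include, theta, np.nan), index=responses.data.index, name="theta"
    )
    excluded = tuple(responses.data.index[extreme & any_obs].astype(str))
    return CalibrationResult(
        bank=bank,
        convergence={
            "iterations": iterations,
            "max_change": max_change,
            "converged": max_change < cfg.tol,
        },
        person_theta=person_theta,
        collapse_map=collapse,
        excluded_persons=excluded,
    )


def item_fit(result: CalibrationResult, responses: ResponseMatrix) -> pd.DataFrame:
    """Infit and outfit mean-squares per item.

    With residual ``z = (x - E(X|theta)) / sqrt(Var(X|theta))`` evaluated
    at each person's estimated trait: outfit is ``mean(z^2)`` and infit is
    ``sum((x - E)^2) / sum(Var)``.  Extreme persons (no trait estimate)
    are excluded.  Both statistics are near 1 when the data fit the model.
    """
    bank_ids = list(result.bank.item_ids)
    if set(bank_ids) != set(responses.item_ids):
        raise InvalidInputError("bank and response matrix cover different item sets")
    # recode with the collapse recorded at calibration time
    X = responses.data[bank_ids].to_numpy(dtype=float).copy()
    for j, item_id in enumerate(bank_ids):
        lo, hi = result.collapse_map[item_id]
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise InvalidInputError(
                f"item {item_id!r}: responses outside the calibrated category "
                f"range [{lo}, {hi}]"
            )
        X[:, j] = col - lo
    theta = result.person_theta.reindex(responses.data.index).to_numpy()
    usable = ~np.isnan(theta)

    rows = []
    for j, item in enumerate(result.bank.items):
        mask = usable & ~np.isnan(X[:, j])
        if not mask.any():
            rows.append((item.item_id, np.nan, np.nan))
            continue
        x = X[mask, j]
        cats = np.arange(item.n_categories, dtype=float)
        pmat = np.exp(pcm_log_probabilities(theta[mask], item))
        mean = pmat @ cats
        var = np.maximum(pmat @ (cats**2) - mean**2, 1e-12)
        sq = (x - mean) ** 2
        outfit = float(np.mean(sq / var))
        infit = float(np.sum(sq) / np.sum(var))
        rows.append((item.item_id, infit, outfit))
    return pd.DataFrame(rows, columns=["item_id", "infit", "outfit"]).set_index("item_id")
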