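import dataclasses
from itertools import product

import numpy as np
import pytest

from promcat import (
    AssessmentComplete,
    CatConfig,
    InvalidInputError,
    ItemBank,
    ItemParameters,
    eap_estimate,
    item_information,
    response_log_likelihood,
    run_cat_live,
    run_cat_replay,
    select_next_item,
)
from promcat.cat_engine import CatState

from conftest import random_bank


def dense_grid_eap(responses, bank, prior_sd=1.0, span=8.0, n=10001):
    """Independent posterior-mean oracle: trapezoid integration on a dense
    grid, built from the likelihood primitives only."""
    g = np.linspace(-span, span, n)
    log_post = response_log_likelihood(g, responses, bank) - 0.5 * (g / prior_sd) ** 2
    w = np.exp(log_post - log_post.max())
    return np.trapezoid(w * g, g) / np.trapezoid(w, g)


class TestEapEstimate:
    def test_no_responses_returns_prior(self, small_bank):
        # quadrature span widened so the grid still covers ~7 prior SDs
        cfg = CatConfig(prior_mean=0.4, prior_sd=1.3, quadrature_range=9.0, n_quadrature=91)
        est = eap_estimate({}, small_bank, cfg)
        assert est.theta == pytest.approx(0.4, abs=1e-6)
        assert est.se == pytest.approx(1.3, abs=1e-6)
        assert est.n_items_used == 0

    def test_matches_dense_grid_oracle(self, rng, cat_config):
        for _ in range(25):
            bank = random_bank(rng, n_items=int(rng.integers(2, 7)))
            responses = {
                it.item_id: int(rng.integers(0, it.max_category + 1))
                for it in bank.items
                if rng.uniform() < 0.8
            }
            est = eap_estimate(responses, bank, cat_config)
            assert est.theta == pytest.approx(
                dense_grid_eap(responses, bank), abs=1e-4
            )

    def test_raising_a_response_raises_the_estimate(self, rng, cat_config):
        for _ in range(10):
            bank = random_bank(rng, n_items=4)
            responses = {it.item_id: 0 for it in bank.items}
            low = eap_estimate(responses, bank, cat_config).theta
            bumped = dict(responses)
            bumped[bank.items[0].item_id] = 1
            assert eap_estimate(bumped, bank, cat_config).theta > low

    def test_se_never_exceeds_prior_sd(self, rng, cat_config):
        bank = random_bank(rng, n_items=6)
        for _ in range(20):
            responses = {
                it.item_id: int(rng.integers(0, it.max_category + 1))
                for it in bank.items
            }
            for k in range(1, len(bank.items) + 1):
                partial = {i: responses[i] for i in list(responses)[:k]}
                est = eap_estimate(partial, bank, cat_config)
                assert est.se <= cat_config.prior_sd + 1e-9

    def test_dichotomous_eap_increases_with_raw_score(self, cat_config):
        # For a dichotomous Rasch bank the raw score is sufficient for
        # theta, so EAP is constant within and strictly increasing across
        # raw-score groups.  Checked by full enumeration on 3 items.
        items = tuple(ItemParameters(f"i{k}", (b,)) for k, b in enumerate((-0.8, 0.1, 1.1)))
        bank = ItemBank("dich", items)
        by_raw = {}
        for pattern in product((0, 1), repeat=3):
            responses = {f"i{k}": pattern[k] for k in range(3)}
            theta = eap_estimate(responses, bank, cat_config).theta
            by_raw.setdefault(sum(pattern), []).append(theta)
        means = [np.mean(by_raw[r]) for r in sorted(by_raw)]
        assert np.all(np.diff(means) > 0)
        for values in by_raw.values():
            assert np.ptp(values) < 1e-12


class TestItemSelection:
    def test_single_remaining_item_is_forced(self, small_bank, cat_config):
        responses = {i: 0 for i in small_bank.item_ids[:-1]}
        state = CatState(responses, eap_estimate(responses, small_bank, cat_config))
        assert select_next_item(state, small_bank, cat_config) == small_bank.item_ids[-1]

    def test_empty_remaining_signals_completion(self, small_bank, cat_config):
        responses = {i: 0 for i in small_bank.item_ids}
        state = CatState(responses, eap_estimate(responses, small_bank, cat_config))
        with pytest.raises(AssessmentComplete):
            select_next_item(state, small_bank, cat_config)

    @pytest.mark.parametrize("rule", ["max_info_at_eap", "posterior_weighted_info"])
    def test_matches_exhaustive_argmax(self, rng, rule):
        cfg = CatConfig(selection_rule=rule)
        for _ in range(5):
            bank = random_bank(rng, n_items=6)
            responses = {}
            for _step in range(len(bank)):
                est = eap_estimate(responses, bank, cfg)
                chosen = select_next_item(CatState(responses, est), bank, cfg)
                # brute force over remaining items
                best_id, best_val = None, -np.inf
                for it in bank.items:
                    if it.item_id in responses:
                        continue
                    if rule == "max_info_at_eap":
                        val = item_information(est.theta, it)
                    else:
                        g = np.linspace(-6, 6, 61)
                        lp = response_log_likelihood(g, responses, bank) - 0.5 * g**2
                        w = np.exp(lp - lp.max())
                        w /= w.sum()
                        val = float(w @ item_information(g, it))
                    if val > best_val:
                        best_id, best_val = it.item_id, val
                assert chosen == best_id
                responses[chosen] = int(rng.integers(0, bank.item(chosen).max_category + 1))

    def test_duplicate_parameters_tie_break_to_lower_index(self, cat_config):
        twin = (0.3, 0.9)
        bank = ItemBank(
            "tie",
            (ItemParameters("first", twin), ItemParameters("second", twin)),
        )
        state = CatState({}, eap_estimate({}, bank, cat_config))
        assert select_next_item(state, bank, cat_config) == "first"


class TestReplay:
    def test_full_length_replay_reproduces_full_estimator_bitwise(
        self, face_sim, cat_config
    ):
        bank, responses, _ = face_sim
        for pid in responses.data.index[:20]:
            vec = {k: int(v) for k, v in responses.data.loc[pid].items()}
            trace = run_cat_replay(vec, bank, cat_config)
            direct = eap_estimate(vec, bank, cat_config)
            assert trace.estimate.theta == direct.theta
            assert trace.estimate.se == direct.se

    @pytest.mark.parametrize("length", [9, 8, 7])
    def test_trace_length_equals_stopping_length(self, face_sim, cat_config, length):
        bank, responses, _ = face_sim
        cfg = dataclasses.replace(cat_config, stopping_length=length)
        vec = {k: int(v) for k, v in responses.data.iloc[0].items()}
        trace = run_cat_replay(vec, bank, cfg)
        assert len(trace) == length
        assert len(set(trace.item_ids)) == length  # no repeats
        assert set(trace.item_ids) <= set(bank.item_ids)

    def test_replay_is_deterministic(self, face_sim, cat_config):
        bank, responses, _ = face_sim
        cfg = dataclasses.replace(cat_config, stopping_length=5)
        vec = {k: int(v) for k, v in responses.data.iloc[3].items()}
        assert run_cat_replay(vec, bank, cfg) == run_cat_replay(vec, bank, cfg)

    def test_incomplete_vector_rejected(self, small_bank, cat_config):
        with pytest.raises(InvalidInputError, match="missing"):
            run_cat_replay({"a": 1}, small_bank, cat_config)

    def test_score_on_anchored_bank(self, face_sim, cat_config):
        bank, responses, _ = face_sim
        vec = {k: int(v) for k, v in responses.data.iloc[0].items()}
        trace = run_cat_replay(vec, bank, cat_config)
        assert trace.score is not None and 0 <= trace.score <= 100


class TestLiveAdministration:
    def test_scripted_callback_equals_replay(self, face_sim, cat_config):
        bank, responses, _ = face_sim
        cfg = dataclasses.replace(cat_config, stopping_length=6)
        vec = {k: int(v) for k, v in responses.data.iloc[1].items()}
        live = run_cat_live(lambda item: vec[item.item_id], bank, cfg)
        assert live == run_cat_replay(vec, bank, cfg)

    def test_top_callback_scores_at_least_bottom_callback(self, small_bank, cat_config):
        top = run_cat_live(lambda item: item.max_category, small_bank, cat_config)
        bottom = run_cat_live(lambda item: 0, small_bank, cat_config)
        assert top.score >= bottom.score
        assert top.score == 100.0 and bottom.score == 0.0  # anchor convention

    def test_single_item_stopping_prompts_once(self, small_bank, cat_config):
        calls = []

        def callback(item):
            calls.append(item.item_id)
            return 0

        cfg = dataclasses.replace(cat_config, stopping_length=1)
        trace = run_cat_live(callback, small_bank, cfg)
        assert len(calls) == 1 and len(trace) == 1

    def test_invalid_responses_reprompted_then_abort(self, small_bank, cat_config):
        attempts = []

        def bad_then_good(item):
            attempts.append(1)
            return 99 if len(attempts) < 3 else 0

        trace = run_cat_live(bad_then_good, small_bank, cat_config, max_retries=3)
        assert len(trace) == len(small_bank)

        def always_bad(item):
            return -1

        with pytest.raises(InvalidInputError, match="no valid response"):
            run_cat_live(always_bad, small_bank, cat_config, max_retries=2)
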