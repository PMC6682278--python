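import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clickchain import (
    StateSpace,
    TransitionCounts,
    count_transitions,
    estimate_initial,
    fit,
    load_model,
    normalize,
    page_view_summary,
    save_model,
    sequence_log_likelihood,
    simulate_session,
    simulate_trails,
)


class TestCounting:
    def test_smallest_trail_counts_internal_and_exit(self, abc_states):
        counts = count_transitions([["A", "B"]], abc_states)
        expected = np.zeros((4, 4))
        expected[0, 1] = 1  # A -> B
        expected[1, 3] = 1  # B -> Exit
        assert np.array_equal(counts.counts, expected)

    def test_length_one_trail_counts_only_exit(self, abc_states):
        counts = count_transitions([["A"]], abc_states)
        assert counts.total == 1
        assert counts.counts[0, abc_states.exit_index] == 1

    def test_total_counts_conserve_trail_lengths(self, abc_chain):
        trails = simulate_trails(abc_chain, 1000, rng=0)
        counts = count_transitions(trails, abc_chain.states)
        # each trail of k pages: k-1 internal transitions + 1 exit
        assert counts.total == sum(len(t) for t in trails)
        assert (counts.counts[abc_chain.states.exit_index] == 0).all()

    def test_unknown_state_is_named(self, abc_states):
        with pytest.raises(KeyError, match="Mystery"):
            count_transitions([["A", "Mystery"]], abc_states)


class TestNormalize:
    def test_rows_divide_by_their_sums(self, abc_states):
        counts = np.zeros((4, 4), dtype=int)
        counts[0] = [0, 2, 2, 0]
        P = normalize(TransitionCounts(abc_states, counts))
        assert P[0].tolist() == [0.0, 0.5, 0.5, 0.0]

    def test_zero_rows_stay_zero_and_are_flagged(self, abc_states):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 1
        model = fit([["A", "B"]], abc_states)
        assert (model.P[2] == 0).all()
        assert model.dangling == ["C"]

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4),
            min_size=4,
            max_size=4,
        )
    )
    def test_every_nonzero_row_is_stochastic(self, abc_states, rows):
        rows[3] = [0, 0, 0, 0]  # exit row convention
        P = normalize(TransitionCounts(abc_states, np.array(rows)))
        sums = P.sum(axis=1)
        for total, s in zip(np.array(rows).sum(axis=1), sums):
            assert s == pytest.approx(1.0, abs=1e-9) if total else s == 0.0


class TestInitialDistribution:
    def test_reported_coach_share(self):
        states = StateSpace(pages=("Coach", "Other"))
        sessions = [["Coach"]] * 634 + [["Other"]] * 190
        pi = estimate_initial(sessions, states)
        assert round(pi[0] * 100, 1) == 76.9
        assert round((1 - pi[0]) * 100, 1) == 23.1
        assert pi[states.exit_index] == 0.0

    def test_point_mass_when_all_start_equal(self, abc_states):
        pi = estimate_initial([["A", "B"], ["A"]], abc_states)
        assert pi.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_empty_session_list_rejected(self, abc_states):
        with pytest.raises(ValueError):
            estimate_initial([], abc_states)

    def test_sampling_recovers_known_pi(self, abc_chain):
        trails = simulate_trails(abc_chain, 10_000, rng=3)
        pi = estimate_initial(trails, abc_chain.states)
        assert np.abs(pi - abc_chain.pi).max() < 0.02


class TestFit:
    def test_single_trail_model(self, abc_states):
        model = fit([["A"]], abc_states)
        assert model.prob("A", "Exit") == 1.0
        assert model.pi.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_parameter_recovery_from_simulation(self, abc_chain):
        # >= 5,000 departures per state makes every entry accurate to < 0.02
        trails = simulate_trails(abc_chain, 20_000, rng=7)
        refit = fit(trails, abc_chain.states)
        err = np.abs(refit.P[:3] - abc_chain.P[:3]).max()
        assert err < 0.02


class TestLikelihood:
    def test_matches_brute_force_product_on_all_short_trails(self, abc_chain):
        states = abc_chain.states
        for length in range(1, 7):
            for combo in itertools.product(states.pages, repeat=length):
                trail = list(combo)
                ix = [states.index(p) for p in trail] + [states.exit_index]
                product = 1.0
                for a, b in zip(ix, ix[1:]):
                    product *= abc_chain.P[a, b]
                got = sequence_log_likelihood(abc_chain, trail)
                if product == 0.0:
                    assert got == -math.inf
                else:
                    assert got == pytest.approx(math.log(product), rel=1e-12)

    def test_worked_product_on_reference_model(self, reference_model):
        got = sequence_log_likelihood(
            reference_model, ["Coach", "Track", "Route", "Routes"]
        )
        assert got == pytest.approx(math.log(0.20 * 0.30 * 0.52 * 0.07), rel=1e-12)

    def test_zero_probability_step_gives_minus_inf(self, reference_model):
        # Coach -> Route is printed 0.00
        assert sequence_log_likelihood(reference_model, ["Coach", "Route"]) == -math.inf

    def test_deterministic_chain_scores_zero(self):
        states = StateSpace(pages=("A",))
        model = fit([["A"]], states)
        assert sequence_log_likelihood(model, ["A"]) == 0.0

    def test_initial_term_is_optional(self, abc_chain):
        base = sequence_log_likelihood(abc_chain, ["A", "B"])
        with_pi = sequence_log_likelihood(abc_chain, ["A", "B"], include_initial=True)
        assert with_pi == pytest.approx(base + math.log(abc_chain.pi[0]))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=1, max_size=8))
    def test_appending_a_state_never_increases_likelihood(self, abc_chain, trail):
        for extra in ("A", "B", "C"):
            assert sequence_log_likelihood(
                abc_chain, trail + [extra]
            ) <= sequence_log_likelihood(abc_chain, trail)


class TestSimulation:
    def test_forced_absorption(self):
        states = StateSpace(pages=("A",))
        model = fit([["A"]], states)
        for seed in range(5):
            out = simulate_session(model, rng=seed)
            assert out.trail == ["A"] and not out.truncated

    def test_start_fractions_follow_pi(self, reference_model):
        trails = simulate_trails(reference_model, 20_000, rng=11)
        frac = np.mean([t[0] == "Coach" for t in trails])
        assert abs(frac - 0.769) < 0.01

    def test_truncation_flagged_when_no_exit_mass(self):
        states = StateSpace(pages=("A", "B"))
        P = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]])
        model = fit([["A"]], states)  # placeholder for pi
        model.P = P
        out = simulate_session(model, rng=0, max_len=3)
        assert len(out.trail) == 3 and out.truncated

    def test_dangling_state_error_names_the_state(self, abc_states):
        model = fit([["A", "B"]], abc_states)
        model.pi = np.array([0.0, 0.0, 1.0, 0.0])  # start at dangling C
        with pytest.raises(ValueError, match="C"):
            simulate_session(model, rng=0)

    def test_seed_reproducibility(self, reference_model):
        a = simulate_trails(reference_model, 50, rng=5)
        b = simulate_trails(reference_model, 50, rng=5)
        assert a == b


class TestPageViewSummary:
    def test_printed_field_trial_shares(self):
        printed = {
            "Coach": 1159,
            "Competition": 578,
            "Route": 547,
            "Team": 539,
            "Routes": 529,
            "Track": 507,
            "Personal": 268,
            "Trophies": 119,
            "Bug report": 58,
        }
        trail = [p for page, n in printed.items() for p in [page] * n]
        summary = page_view_summary([trail])
        assert summary["views"].sum() == 4304
        assert summary.loc["Coach", "share"] == 26.9
        assert summary.loc["Bug report", "share"] == 1.3
        assert summary["views"].is_monotonic_decreasing

    def test_single_view_is_total(self):
        summary = page_view_summary([["A"]])
        assert summary.loc["A", "views"] == 1
        assert summary.loc["A", "share"] == 100.0

    def test_shares_sum_to_hundred(self, abc_chain):
        trails = simulate_trails(abc_chain, 500, rng=2)
        summary = page_view_summary(trails)
        assert summary["share"].sum() == pytest.approx(100.0, abs=0.1)


def test_model_json_round_trip(tmp_path, reference_model):
    path = tmp_path / "model.json"
    save_model(reference_model, path)
    back = load_model(path)
    assert back.states == reference_model.states
    assert np.array_equal(back.P, reference_model.P)
    assert np.array_equal(back.pi, reference_model.pi)
    assert back.n_sessions == reference_model.n_sessions
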