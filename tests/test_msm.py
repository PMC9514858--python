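"""MSM estimation, spectral analysis, PCCA+, CK test, MFPT, VAMP-2."""

import numpy as np
import pytest

from vnarens.msm import (
    TransitionMatrix,
    ck_test,
    cluster_microstates,
    count_transitions,
    estimate_transition_matrix,
    implied_timescales,
    mfpt,
    n_macrostates_by_spectral_gap,
    pcca,
    vamp2_score,
)
from vnarens.synthetic import sample_markov_chain

T_2STATE = np.array([[0.9, 0.1], [0.2, 0.8]])


class TestMicrostates:
    def test_distinct_points_each_form_a_cluster(self):
        pts = np.array([[0.0, 0], [5.0, 0], [0, 5.0], [5.0, 5.0]])
        micro = cluster_microstates(pts, k=4, seed=0)
        assert micro.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(micro.labels[0])) == 4

    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(24)
        a = rng.normal(size=(500, 2))
        b = rng.normal(size=(500, 2)) + 20.0  # 10 sigma+ separation
        micro = cluster_microstates(np.vstack([a, b]), k=2, seed=1)
        labels = micro.labels[0]
        assert len(set(labels[:500])) == 1
        assert len(set(labels[500:])) == 1
        assert labels[0] != labels[500]

    def test_k_one_labels_everything_zero(self):
        micro = cluster_microstates(np.random.default_rng(0).normal(size=(50, 2)), k=1, seed=0)
        assert np.all(micro.labels[0] == 0)

    def test_too_few_frames_suggests_smaller_k(self):
        with pytest.raises(ValueError, match="reduce k"):
            cluster_microstates(np.zeros((5, 2)), k=10, seed=0)

    def test_deterministic_for_fixed_seed(self):
        x = np.random.default_rng(25).normal(size=(300, 2))
        a = cluster_microstates(x, k=5, seed=3)
        b = cluster_microstates(x, k=5, seed=3)
        assert np.array_equal(a.labels[0], b.labels[0])


class TestTransitionMatrix:
    def test_alternating_chain_closed_form(self):
        seq = np.tile([0, 1], 500)
        tm = estimate_transition_matrix(seq, lag=1)
        assert np.allclose(tm.matrix, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)
        assert np.allclose(tm.stationary, [0.5, 0.5], atol=1e-10)

    def test_recovers_generating_matrix_and_stationary_vector(self):
        seq = sample_markov_chain(T_2STATE, 100_000, seed=26)
        tm = estimate_transition_matrix(seq, lag=1)
        assert np.abs(tm.matrix - T_2STATE).max() < 0.01
        assert np.abs(tm.stationary - [2.0 / 3.0, 1.0 / 3.0]).max() < 0.01

    def test_reversible_estimator_satisfies_detailed_balance(self):
        seq = sample_markov_chain(T_2STATE, 20_000, seed=27)
        tm = estimate_transition_matrix(seq, lag=2)
        flux = tm.stationary[:, None] * tm.matrix
        assert np.abs(flux - flux.T).max() < 1e-8
        assert np.allclose(tm.stationary @ tm.matrix, tm.stationary, atol=1e-8)

    def test_constant_sequence_yields_one_state_model(self):
        tm = estimate_transition_matrix(np.zeros(100, dtype=int), lag=1)
        assert tm.n_states == 1
        assert tm.stationary[0] == pytest.approx(1.0)

    def test_disconnected_states_restricted_with_report(self):
        # two blocks never exchanging; the larger (by counts) is kept
        seq_a = np.tile([0, 1], 400)
        seq_b = np.tile([2, 3], 100)
        with pytest.warns(UserWarning, match="connected"):
            tm = estimate_transition_matrix([seq_a, seq_b], lag=1, n_states=4)
        assert tm.fraction_of_states == pytest.approx(0.5)
        assert set(tm.active_set) == {0, 1}

    def test_no_transitions_at_lag_is_an_error(self):
        with pytest.raises(ValueError, match="no transitions"):
            estimate_transition_matrix(np.array([0, 1]), lag=5)

    def test_sliding_window_counts(self):
        counts = count_transitions(np.array([0, 1, 0, 1, 1]), lag=2)
        # pairs: (0,0),(1,1),(0,1)
        assert counts[0, 0] == 1 and counts[1, 1] == 1 and counts[0, 1] == 1

    def test_symmetrized_fallback_estimator(self):
        seq = sample_markov_chain(T_2STATE, 5000, seed=28)
        tm = estimate_transition_matrix(seq, lag=1, estimator="symmetrized")
        flux = tm.stationary[:, None] * tm.matrix
        assert np.abs(flux - flux.T).max() < 1e-12


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        tm = TransitionMatrix(matrix=T_2STATE, lag=1)
        ts, flagged = implied_timescales(tm, n=1)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.7), abs=1e-10)
        assert not flagged.any()

    def test_identity_matrix_reports_infinite_timescale(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # identity chain is reducible
            tm = TransitionMatrix(matrix=np.eye(2), lag=1, stationary=np.array([0.5, 0.5]))
            ts, _ = implied_timescales(tm, n=1)
        assert np.isinf(ts[0])

    def test_markov_self_consistency_across_lags(self):
        # for an exactly Markovian T, timescales from T at tau and from T^2
        # at 2 tau coincide
        tm1 = TransitionMatrix(matrix=T_2STATE, lag=1)
        tm2 = TransitionMatrix(matrix=np.linalg.matrix_power(T_2STATE, 2), lag=2)
        ts1, _ = implied_timescales(tm1, n=1)
        ts2, _ = implied_timescales(tm2, n=1)
        assert ts1[0] == pytest.approx(ts2[0], rel=1e-10)

    def test_negative_eigenvalues_flagged(self):
        t = np.array([[0.1, 0.9], [0.9, 0.1]])
        tm = TransitionMatrix(matrix=t, lag=1)
        with pytest.warns(UserWarning, match="negative"):
            ts, flagged = implied_timescales(tm, n=1)
        assert flagged[0]
        assert ts[0] == pytest.approx(-1.0 / np.log(0.8), abs=1e-10)


class TestPcca:
    def test_metastable_blocks_recovered_crisply(self):
        # two blocks, intra-block 0.98, inter 0.02
        t = np.full((4, 4), 0.01)
        t[:2, :2] = 0.49
        t[2:, 2:] = 0.49
        t = t / t.sum(axis=1, keepdims=True)
        tm = TransitionMatrix(matrix=t, lag=1)
        macro = pcca(tm, 2)
        assert len(set(macro.crisp[:2])) == 1
        assert len(set(macro.crisp[2:])) == 1
        assert macro.crisp[0] != macro.crisp[2]
        block_pi = tm.stationary[:2].sum()
        assert sorted(macro.probabilities) == pytest.approx(
            sorted([block_pi, 1 - block_pi]), abs=1e-6
        )

    def test_m_equals_k_keeps_every_microstate(self):
        seq = sample_markov_chain(T_2STATE, 10_000, seed=29)
        tm = estimate_transition_matrix(seq, lag=1)
        macro = pcca(tm, 2)
        assert macro.n_macrostates == 2
        assert set(macro.crisp) == {0, 1}

    def test_memberships_are_a_stochastic_matrix(self):
        t = np.full((5, 5), 0.02)
        np.fill_diagonal(t, 0.92)
        t = t / t.sum(axis=1, keepdims=True)
        tm = TransitionMatrix(matrix=t, lag=1)
        macro = pcca(tm, 3)
        assert np.all(macro.memberships >= 0)
        assert np.allclose(macro.memberships.sum(axis=1), 1.0, atol=1e-10)
        assert macro.probabilities.sum() == pytest.approx(1.0, abs=1e-10)

    def test_permutation_equivariance_under_microstate_relabeling(self):
        rng = np.random.default_rng(30)
        t = np.full((6, 6), 0.01)
        t[:3, :3] = 0.3
        t[3:, 3:] = 0.3
        t += rng.uniform(0, 0.02, size=(6, 6))
        t = t / t.sum(axis=1, keepdims=True)
        tm = TransitionMatrix(matrix=t, lag=1)
        macro = pcca(tm, 2)
        perm = np.array([3, 0, 4, 1, 5, 2])
        t_p = t[np.ix_(perm, perm)]
        tm_p = TransitionMatrix(matrix=t_p, lag=1)
        macro_p = pcca(tm_p, 2)
        # partitions agree up to macrostate relabeling
        ref = macro.crisp[perm]
        agreement = (macro_p.crisp == ref).mean()
        assert agreement in (0.0, 1.0)  # either identical or fully swapped

    def test_spectral_gap_choice_finds_block_count(self):
        t = np.full((6, 6), 0.004)
        t[:2, :2] = 0.3
        t[2:4, 2:4] = 0.3
        t[4:, 4:] = 0.3
        t = t / t.sum(axis=1, keepdims=True)
        tm = TransitionMatrix(matrix=t, lag=1)
        assert n_macrostates_by_spectral_gap(tm) == 3


class TestMfpt:
    def test_two_state_geometric_closed_forms(self):
        tm = TransitionMatrix(matrix=T_2STATE, lag=1)
        assert mfpt(tm, [0], [1]) == pytest.approx(10.0, abs=1e-8)
        assert mfpt(tm, [1], [0]) == pytest.approx(5.0, abs=1e-8)

    def test_three_state_chain_matches_monte_carlo_oracle(self):
        t = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.25, 0.7]])
        tm = TransitionMatrix(matrix=t, lag=1)
        analytic = mfpt(tm, [0], [2])

        # vectorized first-passage simulation, 1e6 walkers from state 0
        rng = np.random.default_rng(31)
        n_walkers = 1_000_000
        state = np.zeros(n_walkers, dtype=np.int8)
        steps = np.zeros(n_walkers, dtype=np.int32)
        alive = np.ones(n_walkers, dtype=bool)
        cum = np.cumsum(t, axis=1)
        for _ in range(2000):
            if not alive.any():
                break
            u = rng.random(alive.sum())
            cur = state[alive]
            nxt = (u[:, None] > cum[cur]).sum(axis=1)
            state[alive] = nxt
            steps[alive] += 1
            still = nxt != 2
            idx = np.flatnonzero(alive)
            alive[idx[~still]] = False
        assert not alive.any()
        mc = steps.mean()
        assert analytic == pytest.approx(mc, rel=0.01)

    def test_unreachable_target_is_infinite(self):
        import warnings

        t = np.array([[1.0, 0.0], [0.5, 0.5]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # reducible chain
            tm = TransitionMatrix(matrix=t, lag=1, stationary=np.array([1.0, 0.0]))
            assert np.isinf(mfpt(tm, [0], [1]))

    def test_overlapping_sets_rejected(self):
        tm = TransitionMatrix(matrix=T_2STATE, lag=1)
        with pytest.raises(ValueError):
            mfpt(tm, [0, 1], [1])


class TestCkTest:
    def test_exact_markov_chain_passes(self):
        seq = sample_markov_chain(T_2STATE, 200_000, seed=32)
        result = ck_test(seq, lag=1, macrostate_sets=[[0], [1]], seed=0)
        assert result.passes(n_se=3.0)

    def test_identity_chain_curves_are_constant_one(self):
        seq = np.zeros(1000, dtype=int)
        result = ck_test(seq, lag=1, macrostate_sets=[[0]], seed=0)
        assert np.allclose(result.predicted, 1.0)
        assert np.allclose(result.estimated, 1.0)

    def test_lumped_hidden_states_flagged_as_non_markovian(self):
        # hidden 3-state chain observed as 2 states: a fast and a very
        # sticky hidden state share one label, breaking Markovianity
        t_hidden = np.array(
            [[0.5, 0.5, 0.0], [0.45, 0.5, 0.05], [0.0, 0.01, 0.99]]
        )
        hidden = sample_markov_chain(t_hidden, 200_000, seed=33)
        lumped = np.where(hidden == 0, 0, 1)
        result = ck_test(lumped, lag=1, macrostate_sets=[[0], [1]], seed=0)
        assert not result.passes(n_se=3.0)

    def test_unsupported_factors_omitted(self):
        seq = sample_markov_chain(T_2STATE, 40, seed=34)
        with pytest.warns(UserWarning, match="omitted"):
            result = ck_test(seq, lag=4, macrostate_sets=[[0], [1]],
                             factors=(1, 2, 50), seed=0)
        assert 50 not in result.factors


class TestVamp2:
    def test_iid_labels_score_one(self):
        rng = np.random.default_rng(35)
        seq = rng.integers(0, 4, size=100_000)
        assert vamp2_score(seq, lag=1) == pytest.approx(1.0, abs=0.01)

    def test_metastable_two_block_chain_scores_two(self):
        t = np.array([[0.999, 0.001], [0.001, 0.999]])
        seq = sample_markov_chain(t, 100_000, seed=36)
        assert vamp2_score(seq, lag=1, n_components=2) == pytest.approx(2.0, abs=0.05)

    def test_merging_slow_states_never_increases_score(self):
        t = np.full((3, 3), 0.005)
        np.fill_diagonal(t, 0.99)
        t = t / t.sum(axis=1, keepdims=True)
        seq = sample_markov_chain(t, 100_000, seed=37)
        full = vamp2_score(seq, lag=1, n_components=3)
        merged = vamp2_score(np.where(seq == 2, 1, seq), lag=1, n_components=3)
        assert merged <= full + 1e-6

    def test_rank_deficiency_reduces_components(self):
        with pytest.warns(UserWarning, match="rank"):
            score = vamp2_score(np.zeros(1000, dtype=int), lag=1, n_components=3)
        assert score == pytest.approx(1.0, abs=1e-10)
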