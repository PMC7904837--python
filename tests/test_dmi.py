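"""Entropies, dMI composition, simplex maximization, permutation, baseline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajdmi import (
    ConditionScores,
    DiscreteEnsemble,
    HiddenMarkovModel,
    StimulusWeights,
    conditional_entropy,
    dmi,
    dmi_curve,
    maximize_dmi,
    permute_timepoints,
    sample_model,
    score_conditions,
    timepoint_mi,
    trajectory_entropy,
    unconditional_entropy,
)
from trajdmi.dmi import DMIError, _maximize_on_simplex, _project_simplex
from trajdmi.models import fit_hmm

from conftest import random_hmm
from test_markov_models import enumerate_path_log2_prob


def make_scores(per_condition_logs):
    """Build ConditionScores from nested lists: [cond][traj][model] at 1 timepoint."""
    arrays = tuple(np.asarray(c, dtype=float)[:, :, None] for c in per_condition_logs)
    labels = tuple(f"c{i}" for i in range(len(arrays)))
    return ConditionScores(labels=labels, scores=arrays)


class TestTrajectoryEntropy:
    @pytest.mark.parametrize("log2p,bits", [(0.0, 0.0), (-1.0, 1.0), (-10.0, 10.0)])
    def test_values(self, log2p, bits):
        assert trajectory_entropy(log2p) == bits

    def test_positive_rejected(self):
        with pytest.raises(DMIError):
            trajectory_entropy(0.5)


class TestEntropies:
    def test_uniform_binary_diagonal(self):
        # every diagonal log-prob = -n (here n = 1) -> H(R|S) = 1 bit for any q
        scores = make_scores([[[-1.0, -3.0]], [[-2.0, -1.0]]])
        for q in ([0.5, 0.5], [0.2, 0.8]):
            got = conditional_entropy(scores, StimulusWeights(np.array(q)), 1)
            assert got == pytest.approx(1.0)

    def test_concentrated_q_reduces_to_one_condition(self):
        scores = make_scores([[[-2.0, -5.0], [-4.0, -5.0]], [[-9.0, -7.0]]])
        q = StimulusWeights(np.array([1.0, 0.0]))
        assert conditional_entropy(scores, q, 1) == pytest.approx(3.0)  # mean(2,4)
        assert unconditional_entropy(scores, q, 1) == pytest.approx(3.0)

    def test_hand_evaluated_double_sum(self):
        """2 conditions x 2 trajectories with hand-set log-probs."""
        S0 = [[-1.0, -4.0], [-2.0, -6.0]]
        S1 = [[-5.0, -2.0], [-3.0, -1.0]]
        scores = make_scores([S0, S1])
        q = StimulusWeights(np.array([0.3, 0.7]))
        # conditional: -sum_i q_i mean_j S_i[j, i]; diagonals are (-1,-2) and (-2,-1)
        expected_cond = -(0.3 * (-1 - 2) / 2 + 0.7 * (-2 - 1) / 2)
        assert conditional_entropy(scores, q, 1) == pytest.approx(expected_cond)
        # unconditional: mixture inside the log
        def mix(row):
            return np.log2(0.3 * 2.0 ** row[0] + 0.7 * 2.0 ** row[1])
        expected_unc = -(
            0.3 * (mix(S0[0]) + mix(S0[1])) / 2 + 0.7 * (mix(S1[0]) + mix(S1[1])) / 2
        )
        assert unconditional_entropy(scores, q, 1) == pytest.approx(expected_unc)
        assert dmi(scores, q, 1) == pytest.approx(expected_unc - expected_cond)

    def test_identical_models_zero_dmi(self):
        row = [-2.5, -2.5]
        scores = make_scores([[row, row], [row, row]])
        q = StimulusWeights(np.array([0.4, 0.6]))
        assert unconditional_entropy(scores, q, 1) == pytest.approx(
            conditional_entropy(scores, q, 1)
        )
        assert dmi(scores, q, 1) == 0.0

    def test_disjoint_deterministic_sequences_one_bit(self):
        # each condition's trajectories have p=1 under own model, ~0 under other
        low = -60.0
        scores = make_scores([[[0.0, low]], [[low, 0.0]]])
        assert dmi(scores, StimulusWeights(np.array([0.5, 0.5])), 1) == pytest.approx(
            1.0, abs=1e-9
        )


class TestScoreConditions:
    def test_entries_match_enumeration(self, rng):
        models = [random_hmm(2, 3, seed=s) for s in (1, 2)]
        ensembles = [
            DiscreteEnsemble(f"c{i}", rng.integers(0, 3, (4, 3)), 3, scheme_id="s")
            for i in range(2)
        ]
        scores = score_conditions(models, ensembles)
        for i, ens in enumerate(ensembles):
            for j, traj in enumerate(ens.states):
                for k, model in enumerate(models):
                    for n in range(1, 4):
                        oracle = enumerate_path_log2_prob(model, traj[:n])
                        assert scores.scores[i][j, k, n - 1] == pytest.approx(
                            oracle, abs=1e-10
                        )

    def test_scheme_mismatch_rejected(self, rng):
        models = [random_hmm(2, 3, seed=s) for s in (1, 2)]
        a = DiscreteEnsemble("a", rng.integers(0, 3, (4, 3)), 3, scheme_id="s1")
        b = DiscreteEnsemble("b", rng.integers(0, 3, (4, 3)), 3, scheme_id="s2")
        with pytest.raises(DMIError):
            score_conditions(models, [a, b])

    def test_family_mixing_rejected(self, rng):
        from trajdmi import fit_time_inhomogeneous

        a = DiscreteEnsemble("a", rng.integers(0, 3, (4, 3)), 3, scheme_id="s")
        b = DiscreteEnsemble("b", rng.integers(0, 3, (4, 3)), 3, scheme_id="s")
        with pytest.raises(DMIError):
            score_conditions([random_hmm(2, 3, 1), fit_time_inhomogeneous(b)], [a, b])


class TestPipelineOracle:
    def test_full_composition_vs_brute_force(self, rng):
        """scores -> entropies -> dMI equals a from-scratch reimplementation."""
        M = 3
        models = [random_hmm(2, 3, seed=10 + k) for k in range(M)]
        ensembles = [
            DiscreteEnsemble(f"c{i}", rng.integers(0, 3, (5, 5)), 3, scheme_id="s")
            for i in range(M)
        ]
        scores = score_conditions(models, ensembles)
        q = np.array([0.2, 0.5, 0.3])
        for n in (1, 3, 5):
            # oracle: enumeration-based probabilities composed by hand
            cond = 0.0
            unc = 0.0
            for i, ens in enumerate(ensembles):
                m_i = ens.n_cells
                for traj in ens.states:
                    probs = [
                        2.0 ** enumerate_path_log2_prob(mod, traj[:n])
                        for mod in models
                    ]
                    cond -= q[i] / m_i * np.log2(probs[i])
                    unc -= q[i] / m_i * np.log2(np.dot(q, probs))
            got = dmi(scores, StimulusWeights(q), n)
            assert got == pytest.approx(max(unc - cond, 0.0), abs=1e-8)


class TestSimplexMaximization:
    def test_projection_properties(self):
        for v in ([0.2, 0.9], [-1.0, 2.0, 0.5], [5.0, 5.0, 5.0, 5.0]):
            p = _project_simplex(np.array(v))
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6))
    def test_projection_is_nearest_simplex_point(self, v):
        v = np.array(v)
        p = _project_simplex(v)
        # KKT: active coordinates share one shift; inactive ones would go negative
        active = p > 0
        shift = (v[active] - p[active])
        assert np.allclose(shift, shift[0], atol=1e-9)
        assert np.all(v[~active] - shift[0] <= 1e-9) if (~active).any() else True

    def test_symmetric_instance_uniform_optimum(self):
        low = -40.0
        scores = make_scores([[[0.0, low]], [[low, 0.0]]])
        I, q = maximize_dmi(scores, 1)
        assert I == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(q.q, [0.5, 0.5], atol=1e-4)

    def test_z_channel_capacity(self):
        """p(y|1)=(1,0), p(y|2)=(0.5,0.5): capacity log2(5/4) ~ 0.3219 bits."""
        logP = np.log2(np.array([[1.0, 0.5], [1e-300, 0.5]]))
        S_list = [logP, logP]
        w_list = [np.array([1.0, 0.0]), np.array([0.5, 0.5])]
        I, q = _maximize_on_simplex(S_list, w_list)
        grid = np.linspace(0, 1, 1001)
        def mi(t):
            qv = np.array([t, 1 - t])
            val = 0.0
            for i in range(2):
                for y in range(2):
                    p = 2.0 ** logP[y, i]
                    if p > 0 and qv[i] > 0:
                        mix = qv @ 2.0 ** logP[y]
                        val += qv[i] * p * np.log2(p / mix)
            return val
        best = max(mi(t) for t in grid)
        assert best == pytest.approx(0.3219, abs=1e-3)
        assert abs(I - best) < 1e-3

    def test_matches_grid_oracle_on_random_instances(self, rng):
        for trial in range(5):
            S0 = -rng.exponential(2.0, size=(6, 2))
            S1 = -rng.exponential(2.0, size=(6, 2))
            scores = make_scores([S0, S1])
            I, q = maximize_dmi(scores, 1)
            grid = np.linspace(0.0, 1.0, 1001)
            vals = [
                dmi(scores, StimulusWeights(np.array([t, 1 - t])), 1) for t in grid
            ]
            assert I >= max(vals) - 1e-3
            assert I <= np.log2(2) + 1e-9

    def test_optimum_beats_random_simplex_points(self, rng):
        M = 3
        S_rows = [-rng.exponential(3.0, size=(8, M)) for _ in range(M)]
        scores = make_scores(S_rows)
        I, qstar = maximize_dmi(scores, 1)
        draws = rng.dirichlet(np.ones(M), size=1000)
        for qv in draws:
            assert I >= dmi(scores, StimulusWeights(qv), 1) - 1e-6

    def test_bound_log2_m(self, rng):
        M = 5
        scores = make_scores([-rng.exponential(1.0, size=(4, M)) for _ in range(M)])
        I, qstar = maximize_dmi(scores, 1)
        assert 0.0 <= I <= np.log2(M) + 1e-9
        assert I <= -np.sum(qstar.q[qstar.q > 0] * np.log2(qstar.q[qstar.q > 0])) + 1e-6


class TestDMICurveProperties:
    def test_relabeling_invariance(self, rng):
        """dMI is invariant under a common permutation of emission symbols."""
        models = [random_hmm(2, 4, seed=s) for s in (3, 4)]
        ensembles = [
            DiscreteEnsemble(f"c{i}", rng.integers(0, 4, (10, 6)), 4, scheme_id="s")
            for i in range(2)
        ]
        curve = dmi_curve(models, ensembles)
        perm = np.array([2, 3, 1, 0])
        inv = np.argsort(perm)
        models_p = [
            HiddenMarkovModel(pi=m.pi, T=m.T, E=m.E[inv, :]) for m in models
        ]
        ensembles_p = [
            DiscreteEnsemble(e.condition_label, perm[e.states], 4, scheme_id="s")
            for e in ensembles
        ]
        curve_p = dmi_curve(models_p, ensembles_p)
        np.testing.assert_allclose(curve.max_dmi, curve_p.max_dmi, atol=1e-8)

    def test_identical_models_flat_zero(self, rng):
        m = random_hmm(2, 3, seed=5)
        ensembles = [
            DiscreteEnsemble(f"c{i}", rng.integers(0, 3, (10, 5)), 3, scheme_id="s")
            for i in range(2)
        ]
        curve = dmi_curve([m, m], ensembles)
        np.testing.assert_allclose(curve.max_dmi, 0.0, atol=1e-9)

    def test_single_timepoint_curve_equals_timepoint_method(self, rng):
        """With N=1 and matched (empirical, pseudocounted) models, the trajectory
        and single-timepoint estimators describe the same discrete channel."""
        K_E = 3
        cols = [rng.integers(0, K_E, size=60) for _ in range(2)]
        ensembles = [
            DiscreteEnsemble(f"c{i}", np.tile(c[:, None], (1, 2)), K_E, scheme_id="s")
            for i, c in enumerate(cols)
        ]
        # one-hidden-state HMM whose emissions equal the pseudocounted column marginal
        models = []
        for c in cols:
            counts = np.bincount(c, minlength=K_E) + 0.5
            E = (counts / counts.sum())[:, None]
            models.append(HiddenMarkovModel(
                pi=np.array([1.0]), T=np.array([[1.0]]), E=E
            ))
        scores = score_conditions(models, ensembles)
        I_traj, _ = maximize_dmi(scores, 1)
        I_tp, _ = timepoint_mi(ensembles, 1, pseudocount=0.5)
        # same channel law; sample-weighted vs channel-weighted outer average
        assert I_traj == pytest.approx(I_tp, abs=0.05)


class TestPermuteTimepoints:
    def test_same_seed_same_permutation(self, rng):
        ens = [
            DiscreteEnsemble("a", rng.integers(0, 2, (5, 8)), 2, scheme_id="s"),
            DiscreteEnsemble("b", rng.integers(0, 2, (5, 8)), 2, scheme_id="s"),
        ]
        out1, perm1 = permute_timepoints(ens, seed=7)
        out2, perm2 = permute_timepoints(ens, seed=7)
        np.testing.assert_array_equal(perm1, perm2)
        np.testing.assert_array_equal(out1[0].states, out2[0].states)
        # identical permutation applied to every ensemble
        np.testing.assert_array_equal(out1[1].states, ens[1].states[:, perm1])

    def test_mismatched_lengths_rejected(self, rng):
        ens = [
            DiscreteEnsemble("a", rng.integers(0, 2, (5, 8)), 2),
            DiscreteEnsemble("b", rng.integers(0, 2, (5, 9)), 2),
        ]
        with pytest.raises(DMIError):
            permute_timepoints(ens, seed=0)


class TestTimepointMI:
    def test_identical_distributions_zero(self, rng):
        col = rng.integers(0, 3, size=50)
        ens = [
            DiscreteEnsemble(l, np.tile(col[:, None], (1, 3)), 3, scheme_id="s")
            for l in ("a", "b")
        ]
        I, _ = timepoint_mi(ens, 2)
        assert I == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_one_bit(self):
        a = DiscreteEnsemble("a", np.zeros((200, 2), dtype=int), 2, scheme_id="s")
        b = DiscreteEnsemble("b", np.ones((200, 2), dtype=int), 2, scheme_id="s")
        I, q = timepoint_mi([a, b], 1)
        assert I == pytest.approx(1.0, abs=0.05)

    def test_matches_blahut_arimoto(self, rng):
        """Independent oracle: Blahut-Arimoto capacity of the empirical channel."""
        K_E = 4
        ens = [
            DiscreteEnsemble(f"c{i}", rng.integers(0, K_E, (80, 3)), K_E, scheme_id="s")
            for i in range(2)
        ]
        n = 2
        P = np.empty((K_E, 2))
        for k, e in enumerate(ens):
            c = np.bincount(e.states[:, n - 1], minlength=K_E) + 0.5
            P[:, k] = c / c.sum()
        # Blahut-Arimoto iterations
        q = np.full(2, 0.5)
        for _ in range(2000):
            mix = P @ q
            D = (P * np.log2(P / mix[:, None])).sum(axis=0)
            w = q * 2.0 ** D
            q = w / w.sum()
        capacity = float((q * D).sum())
        I, _ = timepoint_mi(ens, n)
        assert I == pytest.approx(capacity, abs=1e-3)
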