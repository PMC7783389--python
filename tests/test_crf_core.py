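"""Native CRF scoring against brute-force enumeration and finite differences."""

import itertools
import math

import numpy as np
import pytest

from crfner.crf_core import (
    CRFConfig,
    CRFModel,
    fit,
    log_likelihood_and_gradient,
    log_partition,
    sequence_score,
    tune_hyperparameters,
    viterbi_decode,
)

# ---------------------------------------------------------------------------
# Oracles: exhaustive enumeration over all label sequences, and central
# finite differences of the likelihood.  Both use only sequence_score /
# log_partition-independent arithmetic.


def brute_force(model, feats):
    """(best labeling, log partition) by enumerating every label sequence.

    Tie-break mirrors the documented rule: earliest label in alphabet order at
    the latest differing position, i.e. minimal reversed index tuple.
    """
    L = len(model.label_alphabet)
    best = None
    scores = []
    for assignment in itertools.product(range(L), repeat=len(feats)):
        labels = [model.label_alphabet[i] for i in assignment]
        s = sequence_score(model, feats, labels)
        scores.append(s)
        key = (-s, tuple(reversed(assignment)))
        if best is None or key < best[0]:
            best = (key, labels)
    m = max(scores)
    logz = m + math.log(sum(math.exp(s - m) for s in scores))
    return best[1], logz


def random_instance(rng, T, L, n_atoms=6):
    alphabet = tuple(f"L{i}" for i in range(L))
    index = {f"a{i}": i for i in range(n_atoms)}
    model = CRFModel(
        label_alphabet=alphabet,
        feature_index=index,
        state_weights=rng.normal(scale=1.5, size=(n_atoms, L)),
        transition_weights=rng.normal(scale=1.5, size=(L, L)),
        config=CRFConfig(c1=0.0, c2=0.0),
    )
    feats = []
    for _ in range(T):
        active = rng.choice(n_atoms, size=rng.integers(1, 4), replace=False)
        feats.append({f"a{i}": True for i in active})
    # featmap_atoms produces "a3=True" atoms; index must match
    model.feature_index = {f"a{i}=True": i for i in range(n_atoms)}
    return model, feats


class TestSequenceScore:
    def test_zero_weights_score_zero(self):
        model, feats = random_instance(np.random.default_rng(0), T=4, L=3)
        model.state_weights[:] = 0
        model.transition_weights[:] = 0
        for labels in itertools.product(model.label_alphabet, repeat=2):
            assert sequence_score(model, feats[:2], list(labels)) == 0.0

    def test_single_weight_hits_single_label(self):
        model = CRFModel(
            label_alphabet=("O", "S"),
            feature_index={"lower=atp": 0},
            state_weights=np.array([[0.0, 2.5]]),
            transition_weights=np.zeros((2, 2)),
        )
        feats = [{"lower": "atp"}]
        assert sequence_score(model, feats, ["S"]) == 2.5
        assert sequence_score(model, feats, ["O"]) == 0.0

    def test_score_difference_decomposes(self):
        rng = np.random.default_rng(1)
        model, feats = random_instance(rng, T=3, L=3)
        a = ["L0", "L1", "L2"]
        b = ["L0", "L2", "L2"]
        # labelings differ only at t=1: state term plus both adjacent transitions
        S = [
            model.state_weights[[model.feature_index[k + "=True"] for k in fm]].sum(axis=0)
            for fm in feats
        ]
        Wt = model.transition_weights
        expected = (S[1][1] - S[1][2]) + (Wt[0, 1] - Wt[0, 2]) + (Wt[1, 2] - Wt[2, 2])
        got = sequence_score(model, feats, a) - sequence_score(model, feats, b)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unknown_label_rejected(self):
        model, feats = random_instance(np.random.default_rng(2), T=2, L=2)
        with pytest.raises(ValueError, match="unknown label"):
            sequence_score(model, feats, ["L0", "nope"])


class TestLogPartition:
    def test_uniform_model(self):
        model, feats = random_instance(np.random.default_rng(3), T=3, L=5)
        model.state_weights[:] = 0
        model.transition_weights[:] = 0
        assert log_partition(model, feats) == pytest.approx(3 * math.log(5), abs=1e-12)

    def test_constant_state_shift(self):
        rng = np.random.default_rng(4)
        model, feats = random_instance(rng, T=4, L=3)
        z0 = log_partition(model, feats)
        shifted = CRFModel(
            model.label_alphabet,
            model.feature_index,
            model.state_weights,
            model.transition_weights,
            model.config,
        )
        # add constant c to every state weight of one position's active atoms:
        # equivalently score every labeling +c => logZ shifts by exactly c
        c = 0.7
        feats2 = [dict(fm) for fm in feats]
        shifted.feature_index = dict(model.feature_index)
        shifted.feature_index["extra=True"] = len(model.feature_index)
        shifted.state_weights = np.vstack([model.state_weights, np.full((1, 3), c)])
        feats2[2]["extra"] = True
        assert log_partition(shifted, feats2) == pytest.approx(z0 + c, abs=1e-10)

    def test_empty_sequence_rejected(self):
        model, _ = random_instance(np.random.default_rng(5), T=2, L=2)
        with pytest.raises(ValueError, match="empty"):
            log_partition(model, [])

    def test_matches_enumeration_T4_L3(self):
        model, feats = random_instance(np.random.default_rng(6), T=4, L=3)
        _, logz = brute_force(model, feats)
        assert log_partition(model, feats) == pytest.approx(logz, abs=1e-10)


class TestViterbi:
    def test_zero_weights_tie_break_first_label(self):
        model, feats = random_instance(np.random.default_rng(7), T=5, L=4)
        model.state_weights[:] = 0
        model.transition_weights[:] = 0
        assert viterbi_decode(model, feats) == ["L0"] * 5

    def test_strong_state_preference(self):
        model, feats = random_instance(np.random.default_rng(8), T=4, L=3)
        model.state_weights[:] = 0
        model.transition_weights[:] = 0
        model.state_weights[:, 1] = 10.0  # every atom votes L1
        assert viterbi_decode(model, feats) == ["L1"] * 4

    def test_matches_enumeration_T5_L4(self):
        model, feats = random_instance(np.random.default_rng(9), T=5, L=4)
        path, _ = brute_force(model, feats)
        assert viterbi_decode(model, feats) == path


class TestDistributionalInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 5))
        L = int(rng.integers(2, 5))
        model, feats = random_instance(rng, T=T, L=L)
        logz = log_partition(model, feats)
        total = sum(
            math.exp(sequence_score(model, feats, list(labels)) - logz)
            for labels in itertools.product(model.label_alphabet, repeat=T)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def _toy_data(rng, n_seq=3, T=4, L=3, n_atoms=6):
    model, _ = random_instance(rng, T=2, L=L, n_atoms=n_atoms)
    data = []
    for _ in range(n_seq):
        feats = []
        for _ in range(T):
            active = rng.choice(n_atoms, size=int(rng.integers(1, 4)), replace=False)
            feats.append({f"a{i}": True for i in active})
        labels = [model.label_alphabet[i] for i in rng.integers(0, L, T)]
        data.append((feats, labels))
    return model, data


def _pack(model):
    return np.concatenate(
        [model.state_weights.ravel(), model.transition_weights.ravel()]
    )


def _with_weights(model, w):
    L = len(model.label_alphabet)
    nA = len(model.feature_index)
    return CRFModel(
        model.label_alphabet,
        model.feature_index,
        w[: nA * L].reshape(nA, L),
        w[nA * L :].reshape(L, L),
        model.config,
    )


class TestLikelihoodAndGradient:
    def test_unregularized_log_likelihood_nonpositive(self):
        rng = np.random.default_rng(10)
        model, data = _toy_data(rng)
        ll, _ = log_likelihood_and_gradient(model, data)
        assert ll <= 0.0

    def test_gradient_at_zero_is_observed_minus_uniform(self):
        rng = np.random.default_rng(11)
        model, data = _toy_data(rng, n_seq=2, T=3, L=3)
        model.state_weights[:] = 0
        model.transition_weights[:] = 0
        _, g = log_likelihood_and_gradient(model, data)
        L = 3
        nA = len(model.feature_index)
        g_state = g[: nA * L].reshape(nA, L)
        g_trans = g[nA * L :].reshape(L, L)
        # closed form at the uniform model: observed counts minus count/L
        obs_state = np.zeros((nA, L))
        atom_totals = np.zeros(nA)
        obs_trans = np.zeros((L, L))
        lab = {l: i for i, l in enumerate(model.label_alphabet)}
        n_pairs = 0
        for feats, labels in data:
            for fm, y in zip(feats, labels):
                for k in fm:
                    obs_state[model.feature_index[f"{k}=True"], lab[y]] += 1
                    atom_totals[model.feature_index[f"{k}=True"]] += 1
            for a, b in zip(labels, labels[1:]):
                obs_trans[lab[a], lab[b]] += 1
                n_pairs += 1
        np.testing.assert_allclose(g_state, obs_state - atom_totals[:, None] / L, atol=1e-10)
        np.testing.assert_allclose(g_trans, obs_trans - n_pairs / (L * L), atol=1e-10)

    @pytest.mark.parametrize("c1,c2,at_zero", [(0.0, 0.0, True), (0.0, 0.3, False), (0.2, 0.1, False)])
    def test_gradient_matches_central_finite_differences(self, c1, c2, at_zero):
        rng = np.random.default_rng(12)
        model, data = _toy_data(rng, n_seq=2, T=3, L=3, n_atoms=5)
        model.config = CRFConfig(c1=c1, c2=c2)
        if at_zero:
            w = np.zeros_like(_pack(model))
        else:
            # keep all |w| well away from 0 so the L1 term is differentiable
            w = rng.normal(size=_pack(model).shape)
            w = np.sign(w) * (np.abs(w) + 0.5)
        model = _with_weights(model, w)
        model.config = CRFConfig(c1=c1, c2=c2)
        f0, g = log_likelihood_and_gradient(model, data)
        eps = 1e-5
        for j in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[j] += eps
            wm[j] -= eps
            fp, _ = log_likelihood_and_gradient(_with_weights(model, wp), data)
            fm, _ = log_likelihood_and_gradient(_with_weights(model, wm), data)
            fd = (fp - fm) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def _separable_corpus():
    """Cue word uniquely identifies the label."""
    data = []
    for cue, lab in [("atp", "S"), ("binds", "O"), ("cell", "O"), ("nadh", "S")]:
        for _ in range(3):
            data.append(([{"lower": cue}, {"lower": "x"}], [lab, "O"]))
    return data


class TestFit:
    def test_separable_corpus_reproduced_exactly(self):
        data = _separable_corpus()
        model = fit(data, CRFConfig(c1=0.0, c2=0.01, max_iterations=200))
        for feats, labels in data:
            assert viterbi_decode(model, feats) == labels

    def test_deterministic(self):
        data = _separable_corpus()
        m1 = fit(data, CRFConfig(max_iterations=30))
        m2 = fit(data, CRFConfig(max_iterations=30))
        np.testing.assert_array_equal(m1.state_weights, m2.state_weights)
        np.testing.assert_array_equal(m1.transition_weights, m2.transition_weights)
        assert m1.label_alphabet == m2.label_alphabet
        assert m1.feature_index == m2.feature_index

    def test_objective_nonincreasing_neg_loglik(self):
        data = _separable_corpus()
        vals = []

        def cb(intermediate):
            x = getattr(intermediate, "x", intermediate)
            m = _with_weights(probe, np.asarray(x, dtype=float))
            m.config = CRFConfig(c1=0.0, c2=0.1)
            vals.append(log_likelihood_and_gradient(m, data)[0])

        probe = fit(data, CRFConfig(c1=0.0, c2=0.1, max_iterations=1))
        fit(data, CRFConfig(c1=0.0, c2=0.1, max_iterations=60), callback=cb)
        assert all(b >= a - 1e-8 for a, b in zip(vals, vals[1:]))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit([], CRFConfig())


class TestTuneHyperparameters:
    def test_single_config_returned(self):
        cfg = CRFConfig(c1=0.0, c2=0.5, max_iterations=10)
        data = _separable_corpus()
        assert tune_hyperparameters(data, [cfg], k=2, seed=0) == cfg

    def test_duplicates_equivalent_to_dedup(self):
        a = CRFConfig(c1=0.0, c2=0.5, max_iterations=10)
        b = CRFConfig(c1=0.0, c2=0.05, max_iterations=10)
        data = _separable_corpus()
        assert tune_hyperparameters(data, [a, b, a, b], k=2, seed=1) == tune_hyperparameters(
            data, [a, b], k=2, seed=1
        )

    def test_heavy_l2_loses_to_light_l2(self):
        data = _separable_corpus() * 3
        light = CRFConfig(c1=0.0, c2=0.01, max_iterations=50)
        heavy = CRFConfig(c1=0.0, c2=10000.0, max_iterations=50)
        assert tune_hyperparameters(data, [heavy, light], k=3, seed=0) == light

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(_separable_corpus(), [], k=2, seed=0)
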