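"""Bernoulli-emission HMM: exact small-case oracles, EM guarantees,
parameter recovery, labeling and transitions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from verncre.chromstate import (
    BinarizedMatrix, HMMModel, binarize_coverage, binarize_peaks,
    decode_states, gene_state, label_states, posterior, sequence_loglik,
    state_transitions, train_hmm, viterbi,
)
from verncre.intervals import GeneModel, Interval


def brute_force_loglik(model: HMMModel, X: np.ndarray) -> float:
    """Total likelihood by enumerating every state path."""
    K, T = model.n_states, X.shape[0]
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.initial[path[0]]
        for t in range(1, T):
            p *= model.transitions[path[t - 1], path[t]]
        for t, k in enumerate(path):
            e = model.emissions[k]
            p *= np.prod(np.where(X[t] == 1, e, 1 - e))
        total += p
    return float(np.log(total))


def brute_force_best_path(model: HMMModel, X: np.ndarray):
    K, T = model.n_states, X.shape[0]
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.initial[path[0]])
        for t in range(1, T):
            lp += np.log(model.transitions[path[t - 1], path[t]])
        for t, k in enumerate(path):
            e = model.emissions[k]
            lp += float(np.sum(np.where(X[t] == 1, np.log(e), np.log(1 - e))))
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


def random_model(rng, K, M):
    em = rng.uniform(0.05, 0.95, (K, M))
    A = rng.uniform(0.2, 1.0, (K, K))
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(K))
    return HMMModel(em, A, pi, tuple(f"m{i}" for i in range(M)))


def sample_from(model, rng, T):
    K = model.n_states
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(K, p=model.initial)
    for t in range(1, T):
        states[t] = rng.choice(K, p=model.transitions[states[t - 1]])
    X = (rng.random((T, model.emissions.shape[1]))
         < model.emissions[states]).astype(np.uint8)
    return states, X


class TestExactSmallCases:
    @pytest.mark.parametrize("K,T,M,seed", [(2, 8, 3, 0), (3, 6, 2, 1),
                                            (2, 12, 2, 2), (3, 5, 4, 3)])
    def test_forward_backward_matches_enumeration(self, K, T, M, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, K, M)
        _, X = sample_from(model, rng, T)
        ll = sequence_loglik(model, X)
        assert abs(ll - brute_force_loglik(model, X)) < 1e-9

    @pytest.mark.parametrize("K,T,M,seed", [(2, 8, 3, 0), (3, 6, 2, 1),
                                            (2, 10, 2, 4)])
    def test_viterbi_matches_enumeration(self, K, T, M, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, K, M)
        _, X = sample_from(model, rng, T)
        path, lp = viterbi(model, X)
        bpath, blp = brute_force_best_path(model, X)
        assert abs(lp - blp) < 1e-9
        np.testing.assert_array_equal(path, bpath)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, 3, 4)
        _, X = sample_from(model, rng, 50)
        gamma = posterior(model, X)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


def _binarized(data_by_chrom, marks=("ATAC", "H3K4me3", "H3K36me3",
                                     "H3K27me3", "H3K27ac")):
    return BinarizedMatrix(200, tuple(marks), data_by_chrom)


class TestTraining:
    def test_loglik_monotone_and_deterministic(self):
        rng = np.random.default_rng(0)
        model_true = random_model(rng, 3, 5)
        _, X = sample_from(model_true, rng, 2000)
        binz = _binarized({"c": X})
        m1 = train_hmm(binz, n_states=3, max_iter=50, restarts=2, seed=7)
        m2 = train_hmm(binz, n_states=3, max_iter=50, restarts=2, seed=7)
        trace = np.array(m1.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()
        np.testing.assert_array_equal(m1.emissions, m2.emissions)

    def test_emission_recovery_four_states(self):
        """0.9/0.1 emissions on a 4-state chain recovered within 0.05."""
        rng = np.random.default_rng(1)
        em = np.where(np.eye(4, 5, dtype=bool) | np.eye(4, 5, k=1, dtype=bool),
                      0.9, 0.1)
        A = np.full((4, 4), 0.05)
        np.fill_diagonal(A, 0.85)
        true = HMMModel(em, A, np.full(4, 0.25),
                        ("ATAC", "H3K4me3", "H3K36me3", "H3K27me3", "H3K27ac"))
        _, X = sample_from(true, rng, 30_000)
        model = train_hmm(_binarized({"c": X}), n_states=4, seed=0)
        # match states by best permutation
        best_err = np.inf
        for perm in itertools.permutations(range(4)):
            err = np.abs(model.emissions[list(perm)] - em).max()
            best_err = min(best_err, err)
        assert best_err <= 0.05

    def test_k1_closed_form(self):
        rng = np.random.default_rng(2)
        X = (rng.random((500, 5)) < 0.3).astype(np.uint8)
        model = train_hmm(_binarized({"c": X}), n_states=1)
        np.testing.assert_allclose(model.emissions[0], X.mean(axis=0), atol=1e-12)

    def test_too_few_bins_rejected(self):
        X = np.zeros((100, 5), dtype=np.uint8)
        with pytest.raises(ValueError, match="bins"):
            train_hmm(_binarized({"c": X}), n_states=9)


class TestDecoding:
    def test_decode_accuracy_on_separated_states(self):
        rng = np.random.default_rng(3)
        em = np.array([[0.95, 0.9, 0.9, 0.05, 0.9],
                       [0.05, 0.05, 0.1, 0.95, 0.05]])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        true = HMMModel(em, A, np.array([0.5, 0.5]),
                        ("ATAC", "H3K4me3", "H3K36me3", "H3K27me3", "H3K27ac"))
        states, X = sample_from(true, rng, 10_000)
        binz = _binarized({"c": X})
        model = train_hmm(binz, n_states=2, seed=1)
        segs, per_bin = decode_states(model, binz)
        # align decoded states to truth by best of the two mappings
        acc = max(
            (per_bin["c"] == states).mean(),
            (per_bin["c"] == 1 - states).mean(),
        )
        assert acc >= 0.95
        # segments partition the chromosome
        assert segs[0].interval.start == 0
        for a, b in zip(segs, segs[1:]):
            assert a.interval.end == b.interval.start

    def test_track_set_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        model = random_model(rng, 2, 3)
        binz = _binarized({"c": np.zeros((10, 5), dtype=np.uint8)})
        with pytest.raises(ValueError, match="track sets"):
            decode_states(model, binz)


class TestBinarize:
    def test_peaks_mode_one_bp_overlap(self):
        got = binarize_peaks([Interval("c", 399, 401)], {"c": 1000}, 200)
        np.testing.assert_array_equal(got["c"], [0, 1, 1, 0, 0])

    def test_coverage_mode_poisson_tail(self):
        # genome-wide mean 1 per bin; a bin with 10 has p ~ 1.1e-7 < 1e-4
        arr = np.zeros(2000)
        arr[:1999] = 0.005  # mean per 200bp bin ~ 1
        track = {"c": np.repeat(1.0 / 200, 2000)}
        track["c"][400:410] = 1.0  # bin 2 holds ~10 extra
        got = binarize_coverage(track, 200, 1e-4)
        assert got["c"][2] == 1
        assert got["c"][0] == 0

    def test_zero_bin_never_called(self):
        track = {"c": np.zeros(1000)}
        got = binarize_coverage(track, 200)
        assert got["c"].sum() == 0


class TestLabeling:
    def _model(self, **em):
        marks = ("ATAC", "H3K4me3", "H3K36me3", "H3K27me3", "H3K27ac")
        row = np.array([[em.get(m, 0.1) for m in marks]])
        return HMMModel(row, np.ones((1, 1)), np.ones(1), marks)

    def test_active_only_is_activated(self):
        m = self._model(H3K4me3=0.9, H3K27me3=0.05)
        assert label_states(m)[0] == "activated"

    def test_both_kinds_is_mixed(self):
        m = self._model(H3K27ac=0.7, H3K27me3=0.8)
        assert label_states(m)[0] == "mixed"

    def test_repressive_only_is_repressed(self):
        m = self._model(H3K27me3=0.8)
        assert label_states(m)[0] == "repressed"

    def test_all_low_is_unmodified(self):
        m = self._model()
        assert label_states(m)[0] == "unmodified"

    def test_pure_function_of_emissions(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            em = rng.uniform(0, 1, (1, 5))
            marks = ("ATAC", "H3K4me3", "H3K36me3", "H3K27me3", "H3K27ac")
            m = HMMModel(np.clip(em, 1e-3, 1 - 1e-3), np.ones((1, 1)),
                         np.ones(1), marks)
            lab = label_states(m)[0]
            active = (m.emissions[0, [0, 1, 2, 4]] > 0.5).any()
            rep = m.emissions[0, 3] > 0.5
            expected = ("mixed" if active and rep else "activated" if active
                        else "repressed" if rep else "unmodified")
            assert lab == expected


class TestGeneState:
    LM = {0: "activated", 1: "repressed", 2: "mixed", 3: "unmodified"}

    def test_majority_label(self):
        # assessed span = gene body [2000, 4000) plus 2 kb upstream ->
        # bins 0..19 at 200 bp; 60% repressed / 40% activated coverage
        states = np.array([1] * 12 + [0] * 8)
        g = GeneModel("g", Interval("c", 2000, 4000, strand="+"))
        lab = gene_state({"c": states}, self.LM, [g])
        assert lab["g"] == "repressed"

    def test_exact_tie_precedence(self):
        # exact 50/50 activated/repressed: precedence gives activated
        states = np.array([0] * 10 + [1] * 10)
        g = GeneModel("g", Interval("c", 2000, 4000, strand="+"))
        lab = gene_state({"c": states}, self.LM, [g])
        assert lab["g"] == "activated"

    def test_unassigned_off_decoded_chromosomes(self):
        g = GeneModel("g", Interval("chrZ", 0, 100, strand="+"))
        lab = gene_state({"c": np.zeros(5, dtype=int)}, self.LM, [g])
        assert lab["g"] == "unassigned"


class TestTransitions:
    def test_identical_maps_diagonal(self):
        labels = pd.Series({"g1": "activated", "g2": "repressed", "g3": "mixed"})
        table, maintained = state_transitions(labels, labels)
        assert maintained == 1.0
        off = table.to_numpy().sum() - np.trace(table.to_numpy())
        assert off == 0

    def test_planted_flip_fraction_recovered(self):
        rng = np.random.default_rng(0)
        n = 2000
        before = pd.Series(["activated"] * n, index=[f"g{i}" for i in range(n)])
        flip = rng.random(n) < 0.10
        after = pd.Series(np.where(flip, "unmodified", "activated"),
                          index=before.index)
        table, maintained = state_transitions(before, after)
        assert abs(maintained - 0.9) <= 0.03
        # row sums conserve before-counts
        assert table.loc["activated"].sum() == n

    def test_universe_mismatch_rejected(self):
        a = pd.Series({"g1": "activated"})
        b = pd.Series({"g2": "activated"})
        with pytest.raises(ValueError, match="mismatch"):
            state_transitions(a, b)
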