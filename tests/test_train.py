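"""Alignment encoding, homopolymer rearrangement, EM and FIC training."""

from collections import Counter

import numpy as np
import pytest

from longsim.model import ErrorHMM, ModelSet
from longsim.train import (
    TrainingSequence,
    baum_welch,
    encode_alignment,
    fic_select,
    implied_sequences,
    match_states,
    rearrange_homopolymer_indels,
    train_model_set,
)

TRUE_EMIT = np.array([[0.95, 0.01, 0.02, 0.02], [0.55, 0.05, 0.25, 0.15]])
TRUE_TRANS = np.array([[0.99, 0.01], [0.01, 0.99]])


def gen_two_state(n_seq, T, rng):
    """Synthetic sequences from the known 2-state generator (the oracle)."""
    out = []
    for _ in range(n_seq):
        states = np.empty(T, dtype=np.int64)
        s = int(rng.integers(0, 2))
        u = rng.random(T)
        for t in range(T):
            states[t] = s
            row = TRUE_TRANS[s]
            s = int(np.searchsorted(np.cumsum(row), u[t]))
        sym = np.empty(T, dtype=np.int64)
        for st in (0, 1):
            mask = states == st
            sym[mask] = rng.choice(4, size=int(mask.sum()), p=TRUE_EMIT[st])
        out.append(TrainingSequence(sym))
    return out


def gen_one_state(n_seq, T, rng, p=(0.85, 0.05, 0.05, 0.05)):
    return [
        TrainingSequence(rng.choice(4, size=T, p=list(p))) for _ in range(n_seq)
    ]


class TestEncoding:
    @pytest.mark.parametrize(
        "ref,read,expected",
        [
            ("ACGT", "ACGT", [0, 0, 0, 0]),
            ("AC-T", "ACGT", [0, 0, 2, 0]),
            ("ACGT", "AC-T", [0, 0, 3, 0]),
            ("ACGT", "AGGT", [0, 1, 0, 0]),
        ],
    )
    def test_column_codes(self, ref, read, expected):
        assert encode_alignment(ref, read).symbols.tolist() == expected

    def test_double_gap_rejected(self):
        with pytest.raises(ValueError):
            encode_alignment("A-G", "A-G")

    def test_accuracy_annotation(self):
        ts = encode_alignment("ACGT" * 25, "ACGT" * 25)
        assert ts.accuracy == 1.0


class TestRearrangement:
    def test_deletion_uniform_over_run(self, rng):
        pos = Counter()
        for _ in range(10_000):
            ref2, read2 = rearrange_homopolymer_indels("AAAA", "-AAA", rng)
            pos[read2.index("-")] += 1
        freqs = np.array([pos[i] for i in range(4)]) / 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freqs - 0.25) < 3 * se)

    def test_no_homopolymer_unchanged(self, rng):
        assert rearrange_homopolymer_indels("ACGTACGT", "ACGTACGT", rng) == (
            "ACGTACGT",
            "ACGTACGT",
        )

    def test_implied_sequences_invariant(self, rng):
        # random alignments with runs, insertions, deletions, mismatches
        for seed in range(50):
            r2 = np.random.default_rng(seed)
            bases = "ACGT"
            ref_parts, read_parts = [], []
            for _ in range(30):
                b = bases[r2.integers(0, 4)]
                run = b * int(r2.integers(1, 6))
                ref_parts.append(run)
                read_parts.append(run)
                kind = r2.integers(0, 4)
                if kind == 1:
                    ref_parts.append("-")
                    read_parts.append(b)
                elif kind == 2:
                    ref_parts.append(b)
                    read_parts.append("-")
                elif kind == 3:
                    ref_parts.append(b)
                    read_parts.append(bases[(bases.index(b) + 1) % 4])
            ref_g, read_g = "".join(ref_parts), "".join(read_parts)
            ref_o, read_o = rearrange_homopolymer_indels(ref_g, read_g, rng)
            assert implied_sequences(ref_o, read_o) == implied_sequences(ref_g, read_g)


class TestBaumWelch:
    def test_k1_closed_form(self, rng):
        seqs = gen_one_state(5, 400, rng)
        fit, ll = baum_welch(seqs, 1, rng, max_iter=5)
        obs = np.concatenate([s.symbols for s in seqs])
        freq = np.bincount(obs, minlength=4) / len(obs)
        np.testing.assert_allclose(fit.emit[0], freq, atol=1e-9)
        ll_multinomial = float(
            np.sum(np.bincount(obs, minlength=4) * np.log(np.maximum(freq, 1e-300)))
        )
        assert ll == pytest.approx(ll_multinomial, abs=1e-6)

    def test_nested_models_ll(self, rng):
        seqs = gen_two_state(10, 500, rng)
        _, ll1 = baum_welch(seqs, 1, rng, max_iter=50)
        best_ll2 = max(
            baum_welch(seqs, 2, np.random.default_rng(s), max_iter=50)[1]
            for s in range(3)
        )
        assert best_ll2 >= ll1 - 1e-6

    def test_two_state_parameter_recovery(self, rng):
        seqs = gen_two_state(50, 2000, rng)
        fit, _ = baum_welch(seqs, 2, rng, max_iter=150, tol=1e-7)
        _, perm = match_states(TRUE_EMIT, fit.emit)
        assert np.abs(fit.emit[perm] - TRUE_EMIT).max() < 0.03

    def test_agrees_with_hmmlearn_oracle(self, rng):
        # independent EM implementation on identical data and identical init
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        seqs = gen_two_state(10, 500, rng)
        init = np.array([0.6, 0.4])
        trans = np.array([[0.9, 0.1], [0.2, 0.8]])
        emit = np.array([[0.7, 0.1, 0.1, 0.1], [0.4, 0.2, 0.2, 0.2]])
        fit, ll = baum_welch(
            seqs, 2, rng, max_iter=10, tol=0, init_params=(init, trans, emit)
        )
        m = hmmlearn.CategoricalHMM(
            n_components=2, n_features=4, init_params="", params="ste", n_iter=10,
            tol=0, implementation="scaling",
        )
        m.startprob_ = init.copy()
        m.transmat_ = trans.copy()
        m.emissionprob_ = emit.copy()
        X = np.concatenate([s.symbols for s in seqs]).reshape(-1, 1)
        lengths = [len(s.symbols) for s in seqs]
        m.fit(X, lengths)
        np.testing.assert_allclose(fit.emit, m.emissionprob_, atol=2e-3)
        np.testing.assert_allclose(fit.trans, m.transmat_, atol=2e-3)

    def test_empty_training_set_rejected(self, rng):
        with pytest.raises(ValueError):
            baum_welch([], 2, rng)


class TestFICSelection:
    def test_recovers_one_state(self, rng):
        hits = 0
        for rep in range(5):
            seqs = gen_one_state(30, 1000, np.random.default_rng(100 + rep))
            best = fic_select(seqs, K_candidates=(1, 2, 3), n_trials=3, rng=rng)
            hits += best.n_states == 1
        assert hits >= 4

    def test_recovers_two_states(self, rng):
        hits = 0
        for rep in range(5):
            seqs = gen_two_state(30, 1500, np.random.default_rng(200 + rep))
            best = fic_select(seqs, K_candidates=(1, 2, 3), n_trials=3, rng=rng)
            hits += best.n_states == 2
        assert hits >= 4

    def test_selection_deterministic_given_seed(self):
        seqs = gen_two_state(10, 500, np.random.default_rng(7))
        a = fic_select(seqs, K_candidates=(1, 2), n_trials=5, rng=np.random.default_rng(3))
        b = fic_select(seqs, K_candidates=(1, 2), n_trials=5, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.emit, b.emit)
        assert a.fic == b.fic


class TestTrainModelSet:
    def test_bins_by_accuracy(self, rng):
        def seq_with_acc(acc, T=4000):
            p_err = (1 - acc) / 3
            return TrainingSequence(
                rng.choice(4, size=T, p=[acc, p_err, p_err, p_err]), accuracy=acc
            )

        data = [seq_with_acc(a) for a in (0.795, 0.801, 0.804)] + [
            seq_with_acc(0.9) for _ in range(3)
        ]
        ms = train_model_set(
            data, kind="errhmm", rng=rng, min_symbols=10_000,
            K_candidates=(1,), n_trials=1,
        )
        assert set(ms.bins) == {80, 90}

    def test_insufficient_bin_falls_back(self, rng):
        data = [
            TrainingSequence(rng.choice(4, size=50_000, p=[0.85, 0.05, 0.05, 0.05]), accuracy=0.85),
            TrainingSequence(rng.choice(4, size=100, p=[0.7, 0.1, 0.1, 0.1]), accuracy=0.7),
        ]
        ms = train_model_set(
            data, kind="errhmm", rng=rng, min_symbols=10_000,
            K_candidates=(1,), n_trials=1,
        )
        assert 85 in ms.bins and 70 in ms.fallback_bins

    def test_simulate_retrain_closure(self, rng, small_genome):
        """Train on simulated ground truth; recover the generating emissions."""
        from longsim.model import SimConfig
        from longsim.wgs import simulate_wgs

        gen = ModelSet(
            "errhmm",
            {85: ErrorHMM(85, np.ones(1), np.ones((1, 1)),
                          np.array([[0.85, 0.04, 0.06, 0.05]]))},
        )
        cfg = SimConfig(method="errhmm", depth=10, length_mean=2000, length_sd=0,
                        accuracy_mean=0.85, accuracy_sd=0.0, seed=41)
        data = [
            TrainingSequence(r.ops.codes.astype(np.int64), accuracy=r.ops.accuracy)
            for r in simulate_wgs(small_genome, cfg, gen, max_reads=60)
        ]
        ms = train_model_set(
            data, kind="errhmm", rng=rng, min_symbols=50_000,
            K_candidates=(1,), n_trials=1,
        )
        got = [b for b in ms.bins if abs(b - 85) <= 1]
        assert got, f"no bin near 85 trained (bins {sorted(ms.bins)})"
        emit = ms.bins[got[0]].emit[0]
        assert np.abs(emit - np.array([0.85, 0.04, 0.06, 0.05])).max() < 0.05
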