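"""Edit-script generation, homopolymer deletion bias, script realization."""

import numpy as np
import pytest
from scipy import stats

from longsim.errors import (
    OP_D,
    OP_I,
    OP_M,
    OP_S,
    OpString,
    dna_to_codes,
    gen_ops_errhmm,
    gen_ops_qshmm,
    gen_ops_random,
    gen_quality_track,
    hp_weight,
    place_ops,
    qualities_for_errhmm,
    site_hp_lengths,
)
from longsim.model import ErrorHMM, QualityHMM


def _sid_shares(ops: OpString):
    c = ops.counts()
    errs = c[1:].sum()
    return c[1:] / errs, int(errs)


class TestOpString:
    def test_counts_and_spans(self):
        ops = OpString("MMSIDM")
        assert ops.read_len == 5  # M+S+I
        assert ops.template_span == 5  # M+S+D
        assert ops.accuracy == pytest.approx(3 / 6)

    def test_string_roundtrip(self):
        assert str(OpString("MSIDM")) == "MSIDM"

    def test_empty_accuracy_undefined(self):
        with pytest.raises(ValueError):
            OpString("").accuracy


class TestRandomEngine:
    def test_error_free(self, rng):
        ops = gen_ops_random(0.0, (1, 1, 1), 500, rng)
        assert ops.read_len == 500
        assert np.all(ops.codes == OP_M)

    @pytest.mark.parametrize("ratio", [(6, 55, 39), (22, 45, 33), (39, 24, 36)])
    def test_printed_ratios_recovered(self, rng, ratio):
        ops = gen_ops_random(0.15, ratio, 700_000, rng)
        shares, n_err = _sid_shares(ops)
        assert n_err > 100_000
        expect = np.asarray(ratio) / sum(ratio)
        se = np.sqrt(expect * (1 - expect) / n_err)
        assert np.all(np.abs(shares - expect) < 3 * se)

    def test_per_base_substitution_rate_closed_form(self, rng):
        # multinomial expectation: P(S per op) = rate * ratio_S
        ops = gen_ops_random(0.15, (22, 45, 33), 200_000, rng)
        p = 0.15 * 0.22
        n = len(ops)
        obs = (ops.codes == OP_S).mean()
        assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_read_budget_exact_and_no_trailing_deletion(self, rng):
        ops = gen_ops_random(0.3, (1, 1, 2), 10_000, rng)
        assert ops.read_len == 10_000
        assert ops.codes[-1] != OP_D


class TestErrHMMEngine:
    def test_one_state_pure_match(self, rng):
        m = ErrorHMM(100, np.ones(1), np.ones((1, 1)), np.array([[1.0, 0, 0, 0]]))
        ops = gen_ops_errhmm(m, 300, rng)
        assert str(ops) == "M" * 300

    def test_one_state_frequencies(self, rng):
        m = ErrorHMM(85, np.ones(1), np.ones((1, 1)), np.array([[0.85, 0.05, 0.05, 0.05]]))
        ops = gen_ops_errhmm(m, 500_000, rng)
        freqs = ops.counts() / len(ops)
        expect = np.array([0.85, 0.05, 0.05, 0.05])
        se = np.sqrt(expect * (1 - expect) / len(ops))
        assert np.all(np.abs(freqs - expect) < 3 * se)

    def test_two_state_stationary_mixture(self, rng):
        trans = np.array([[0.95, 0.05], [0.10, 0.90]])
        emit = np.array([[0.95, 0.01, 0.02, 0.02], [0.55, 0.15, 0.15, 0.15]])
        m = ErrorHMM(85, np.array([0.5, 0.5]), trans, emit)
        # brute-force power-iteration oracle
        pi = np.ones(2) / 2
        for _ in range(10_000):
            pi = pi @ trans
        expect = pi @ emit
        ops = gen_ops_errhmm(m, 800_000, rng)
        freqs = ops.counts() / len(ops)
        se = np.sqrt(expect * (1 - expect) / len(ops))
        assert np.all(np.abs(freqs - expect) < 4 * se)

    def test_template_budget_stops_at_span(self, rng):
        m = ErrorHMM(85, np.ones(1), np.ones((1, 1)), np.array([[0.8, 0.05, 0.1, 0.05]]))
        ops = gen_ops_errhmm(m, None, rng, max_template=2000)
        assert ops.template_span == 2000


class TestQualityTrack:
    def test_constant_model(self, rng):
        emit = np.zeros((1, 94))
        emit[0, 12] = 1.0
        m = QualityHMM(90, np.ones(1), np.ones((1, 1)), emit)
        track = gen_quality_track(m, 50, rng)
        assert np.all(track == 12)

    def test_zero_length(self, rng):
        emit = np.zeros((1, 94))
        emit[0, 12] = 1.0
        m = QualityHMM(90, np.ones(1), np.ones((1, 1)), emit)
        assert len(gen_quality_track(m, 0, rng)) == 0

    def test_mixture_histogram_matches_stationary(self, rng):
        trans = np.array([[0.9, 0.1], [0.3, 0.7]])
        emit = np.zeros((2, 94))
        emit[0, 20] = 1.0
        emit[1, 5] = 1.0
        m = QualityHMM(90, np.array([0.5, 0.5]), trans, emit)
        pi = np.ones(2) / 2
        for _ in range(10_000):
            pi = pi @ trans
        track = gen_quality_track(m, 200_000, rng)
        share_q20 = np.mean(track == 20)
        se = np.sqrt(pi[0] * (1 - pi[0]) / len(track))
        assert abs(share_q20 - pi[0]) < 4 * se


class TestQSHMMEngine:
    def test_high_quality_near_zero_errors(self, rng):
        ops = gen_ops_qshmm(np.full(100_000, 93), (1, 1, 1), rng)
        p = 10 ** -9.3
        n_err = int((ops.codes != OP_M).sum())
        assert n_err <= 3 * np.sqrt(100_000 * p * (1 - p)) + 1

    def test_deletion_share_printed_ratio(self, rng):
        ops = gen_ops_qshmm(np.full(1_000_000, 10), (39, 24, 36), rng)
        shares, n_err = _sid_shares(ops)
        se = np.sqrt(0.36 * 0.64 / n_err)
        assert abs(shares[2] - 0.36) < 3 * se

    def test_total_error_rate_closed_form(self, rng):
        # each emitted op errs with p = 10^(-Q/10)
        ops = gen_ops_qshmm(np.full(500_000, 7), (1, 1, 1), rng)
        p = 10 ** -0.7
        obs = (ops.codes != OP_M).mean()
        assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / len(ops))

    def test_deletions_requeue_read_positions(self, rng):
        ops = gen_ops_qshmm(np.full(10_000, 3), (0, 0, 1), rng)
        assert ops.read_len == 10_000  # all qualities consumed despite deletions
        assert (ops.codes == OP_D).sum() > 0


class TestHpWeight:
    @pytest.mark.parametrize(
        "hp_len,bias,expected",
        [(1, 6.0, 1.0), (10, 6.0, 6.0), (4, 6.0, 1 + 5 * 3 / 9), (15, 6.0, 6.0), (1, 1.0, 1.0)],
    )
    def test_linear_interpolation(self, hp_len, bias, expected):
        assert hp_weight(hp_len, bias) == pytest.approx(expected)

    def test_bias_below_one_rejected(self):
        with pytest.raises(ValueError):
            hp_weight(5, 0.5)


class TestSiteLengths:
    def test_run_labeling(self):
        labels = site_hp_lengths(dna_to_codes("AACGGGT"))
        assert labels.tolist() == [2, 2, 1, 3, 3, 3, 1]


class TestPlaceOps:
    def test_all_match_copies_template(self, rng):
        template = "ACGTACGTACGT"
        seq, ops = place_ops(template, 2, OpString("M" * 8), 1.0, rng)
        assert seq == template[2:10]

    def test_substitution_never_equals_template(self, rng):
        template = "A" * 2000
        ops = OpString(np.full(2000, OP_S, dtype=np.uint8))
        seq, _ = place_ops(template, 0, ops, 1.0, rng)
        assert "A" not in seq

    def test_script_conservation_under_bias(self, rng):
        template = "".join(rng.choice(list("ACGT"), 5000))
        ops = gen_ops_random(0.2, (1, 1, 2), 3000, rng)
        seq, placed = place_ops(template, 0, ops, 6.0, rng)
        assert np.array_equal(np.sort(placed.counts()), np.sort(ops.counts()))
        assert placed.counts()[OP_D] == ops.counts()[OP_D]
        assert len(seq) == ops.read_len

    def test_unbiased_deletions_uniform(self, rng):
        # bias=1: deletion sites uniform across the window (chi-square GOF)
        template = "".join(rng.choice(list("ACGT"), 200))
        counts = np.zeros(200)
        for _ in range(500):
            # fixed 200-site span so every site is covered equally
            ops = gen_ops_random(0.1, (0, 0, 1), 10**9, rng, max_template=200)
            _, placed = place_ops(template, 0, ops, 1.0, rng)
            tpos = np.cumsum(placed.codes != OP_I) - 1
            dmask = placed.codes == OP_D
            np.add.at(counts, tpos[dmask], 1)
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_bias_six_fold_on_balanced_template(self, rng):
        from longsim.io import make_synthetic_genome

        _, seq = make_synthetic_genome(homopolymer_spec={1: 400, 10: 40}, seed=9)
        codes = dna_to_codes(seq)
        labels = site_hp_lengths(codes)
        span = len(seq)
        d1 = d10 = 0
        for _ in range(300):
            ops = gen_ops_random(0.12, (0, 0, 1), int(span * 0.8), rng, max_template=span)
            _, placed = place_ops(codes, 0, ops, 6.0, rng, site_lengths=labels)
            tpos = np.cumsum(placed.codes != OP_I) - 1
            lab = labels[tpos[placed.codes == OP_D]]
            d1 += int((lab == 1).sum())
            d10 += int((lab == 10).sum())
        # equal site counts for 1-mers and 10-mers -> rate ratio = count ratio
        fold = d10 / d1
        se = 6.0 * np.sqrt(1 / d1 + 1 / d10)
        assert abs(fold - 6.0) < 3 * se

    def test_overrun_rejected(self, rng):
        with pytest.raises(ValueError):
            place_ops("ACGT", 2, OpString("MMMM"), 1.0, rng)


class TestErrHMMQualities:
    @pytest.mark.parametrize("p_match,expected_q", [(0.9, 10), (0.99, 20), (1.0, 93)])
    def test_quality_from_state_error_rate(self, p_match, expected_q):
        rest = (1 - p_match) / 3
        m = ErrorHMM(90, np.ones(1), np.ones((1, 1)), np.array([[p_match, rest, rest, rest]]))
        ops = OpString("MMMM")
        q = qualities_for_errhmm(ops, m, np.zeros(4, dtype=int))
        assert np.all(q == expected_q)

    def test_deletions_carry_no_quality(self):
        m = ErrorHMM(90, np.ones(1), np.ones((1, 1)), np.array([[0.9, 0.04, 0.03, 0.03]]))
        ops = OpString("MDDM")
        q = qualities_for_errhmm(ops, m, np.zeros(4, dtype=int))
        assert len(q) == 2
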