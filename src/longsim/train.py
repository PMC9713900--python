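"""Model training: alignment encoding, homopolymer INDEL rearrangement, and
EM / FIC-based HMM fitting.

Training data are alignments between reads and their reference; each
alignment column is encoded as match=0, substitution=1, insertion=2,
deletion=3 (for quality-score models the symbols are the Phred values of the
read instead).  Because aligners place INDELs within homopolymers according
to their own tie-breaking habits, INDEL columns inside a homopolymer run are
first re-placed uniformly at random within the run — a transformation that
leaves both the read and the reference sequence implied by the alignment
unchanged.

Fitting uses Baum-Welch EM with per-sequence scaling.  The number of hidden
states is selected with a factorized information criterion: EM runs with
state-shrinkage (responsibilities of under-used states are exponentially
discounted and near-empty states pruned), and the model maximizing

    FIC = log-likelihood - sum_k (D_k / 2) * ln(N_k)

over candidate state counts and five random restarts is kept, where D_k
counts state k's free emission plus transition parameters and N_k is its
expected visit count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .model import ErrorHMM, ModelSet, QualityHMM, QUAL_SUPPORT

logger = logging.getLogger(__name__)


@dataclass
class TrainingSequence:
    """One encoded training sequence plus its source-read accuracy."""

    symbols: np.ndarray
    accuracy: Optional[float] = None

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if len(self.symbols) == 0:
            raise ValueError("empty training sequence")
        if self.symbols.min() < 0:
            raise ValueError("negative symbol")


# ---------------------------------------------------------------------------
# Alignment encoding
# ---------------------------------------------------------------------------


def _gapped_arrays(ref_gapped: str, read_gapped: str) -> Tuple[np.ndarray, np.ndarray]:
    if len(ref_gapped) != len(read_gapped):
        raise ValueError("gapped strings must have equal length")
    ref = np.frombuffer(ref_gapped.upper().encode(), dtype=np.uint8)
    read = np.frombuffer(read_gapped.upper().encode(), dtype=np.uint8)
    gap = ord("-")
    if np.any((ref == gap) & (read == gap)):
        raise ValueError("column with a gap in both sequences")
    return ref, read


def encode_alignment(ref_gapped: str, read_gapped: str) -> TrainingSequence:
    """Encode one alignment: match->0, mismatch->1, ins->2 (gap in ref),
    del->3 (gap in read)."""
    ref, read = _gapped_arrays(ref_gapped, read_gapped)
    gap = ord("-")
    sym = np.empty(len(ref), dtype=np.int64)
    sym[(ref != gap) & (read != gap) & (ref == read)] = 0
    sym[(ref != gap) & (read != gap) & (ref != read)] = 1
    sym[ref == gap] = 2
    sym[read == gap] = 3
    acc = float(np.mean(sym == 0))
    return TrainingSequence(symbols=sym, accuracy=acc)


def implied_sequences(ref_gapped: str, read_gapped: str) -> Tuple[str, str]:
    """(reference, read) with gaps stripped — the rearrangement invariant."""
    return ref_gapped.replace("-", ""), read_gapped.replace("-", "")


def rearrange_homopolymer_indels(
    ref_gapped: str, read_gapped: str, rng: np.random.Generator
) -> Tuple[str, str]:
    """Uniformly re-place INDEL columns within reference homopolymer runs.

    For every maximal run (length >= 2) of an identical reference base, the
    alignment columns whose characters are all either the run base or a gap
    (including adjacent insertion columns of the run base) are shuffled
    uniformly.  Mismatch columns split the shuffled stretches and stay fixed,
    so the implied read and reference sequences never change.
    """
    ref, read = _gapped_arrays(ref_gapped, read_gapped)
    gap = ord("-")
    ref_pos = np.flatnonzero(ref != gap)
    ref_seq = ref[ref_pos]
    n = len(ref_seq)
    out_ref = ref.copy()
    out_read = read.copy()
    i = 0
    while i < n:
        j = i
        while j < n and ref_seq[j] == ref_seq[i]:
            j += 1
        run_len = j - i
        if run_len >= 2:
            base = ref_seq[i]
            lo = int(ref_pos[i])
            hi = int(ref_pos[j - 1])
            while lo > 0 and out_ref[lo - 1] == gap and out_read[lo - 1] == base:
                lo -= 1
            while hi + 1 < len(out_ref) and out_ref[hi + 1] == gap and out_read[hi + 1] == base:
                hi += 1
            cols = np.arange(lo, hi + 1)
            valid = ((out_ref[cols] == base) | (out_ref[cols] == gap)) & (
                (out_read[cols] == base) | (out_read[cols] == gap)
            )
            # shuffle each maximal stretch of valid columns that has an indel
            start = None
            for k in range(len(cols) + 1):
                if k < len(cols) and valid[k]:
                    if start is None:
                        start = k
                    continue
                if start is not None:
                    seg = cols[start:k]
                    if len(seg) >= 2 and np.any(
                        (out_ref[seg] == gap) | (out_read[seg] == gap)
                    ):
                        perm = seg[rng.permutation(len(seg))]
                        out_ref[seg] = out_ref[perm]
                        out_read[seg] = out_read[perm]
                    start = None
        i = j
    return out_ref.tobytes().decode(), out_read.tobytes().decode()


# ---------------------------------------------------------------------------
# Scaled forward-backward (numba kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fb_accumulate(obs, starts, ends, init, trans, emit, shrink):
    """One E-step over all sequences with state shrinkage.

    Returns (log-likelihood, init accumulator, transition accumulator,
    emission accumulator, expected visit counts).
    """
    K = init.shape[0]
    A = emit.shape[1]
    ll = 0.0
    init_acc = np.zeros(K)
    trans_acc = np.zeros((K, K))
    emit_acc = np.zeros((K, A))
    visit_acc = np.zeros(K)
    for s in range(starts.shape[0]):
        o = obs[starts[s] : ends[s]]
        T = o.shape[0]
        alpha = np.empty((T, K))
        c = np.empty(T)
        for k in range(K):
            alpha[0, k] = init[k] * emit[k, o[0]]
        c[0] = alpha[0].sum()
        if c[0] <= 0.0:
            c[0] = 1e-300
        alpha[0] /= c[0]
        for t in range(1, T):
            for k in range(K):
                acc = 0.0
                for j in range(K):
                    acc += alpha[t - 1, j] * trans[j, k]
                alpha[t, k] = acc * emit[k, o[t]]
            c[t] = alpha[t].sum()
            if c[t] <= 0.0:
                c[t] = 1e-300
            alpha[t] /= c[t]
            ll += np.log(c[t])
        ll += np.log(c[0])
        beta = np.ones(K)
        g = np.empty(K)
        for t in range(T - 1, -1, -1):
            tot = 0.0
            for k in range(K):
                g[k] = alpha[t, k] * beta[k] * shrink[k]
                tot += g[k]
            if tot <= 0.0:
                tot = 1e-300
            for k in range(K):
                g[k] /= tot
                emit_acc[k, o[t]] += g[k]
                visit_acc[k] += g[k]
            if t == 0:
                for k in range(K):
                    init_acc[k] += g[k]
            if t > 0:
                # xi for the transition t-1 -> t
                xi = np.empty((K, K))
                tot_xi = 0.0
                for j in range(K):
                    for k in range(K):
                        v = (
                            alpha[t - 1, j]
                            * trans[j, k]
                            * emit[k, o[t]]
                            * beta[k]
                            * shrink[k]
                        )
                        xi[j, k] = v
                        tot_xi += v
                if tot_xi <= 0.0:
                    tot_xi = 1e-300
                for j in range(K):
                    for k in range(K):
                        trans_acc[j, k] += xi[j, k] / tot_xi
                # update beta to time t-1
                newbeta = np.empty(K)
                for j in range(K):
                    acc = 0.0
                    for k in range(K):
                        acc += trans[j, k] * emit[k, o[t]] * beta[k]
                    newbeta[j] = acc / c[t]
                beta = newbeta
    return ll, init_acc, trans_acc, emit_acc, visit_acc


def _pack(seqs: Sequence[TrainingSequence]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = np.concatenate([s.symbols for s in seqs])
    lens = np.array([len(s.symbols) for s in seqs], dtype=np.int64)
    ends = np.cumsum(lens)
    starts = ends - lens
    return obs, starts, ends


@dataclass
class FittedHMM:
    init: np.ndarray
    trans: np.ndarray
    emit: np.ndarray
    log_likelihood: float
    visits: np.ndarray
    fic: Optional[float] = None

    @property
    def n_states(self) -> int:
        return len(self.init)


def _random_params(
    K: int, A: int, pooled: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    init = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K) * 0.2 + np.eye(K) * 0.8
    trans /= trans.sum(axis=1, keepdims=True)
    emit = rng.dirichlet(pooled * 20.0 + 0.5, size=K)
    return init, trans, emit


def _free_params_per_state(K: int, A: int, support: int) -> float:
    """D_k: free emission parameters plus K-1 transition parameters."""
    return (support - 1) + (K - 1)


def baum_welch(
    seqs: Sequence[TrainingSequence],
    K: int,
    rng: np.random.Generator,
    max_iter: int = 200,
    tol: float = 1e-6,
    alphabet_size: int = 4,
    _fab: bool = False,
    _prune_threshold: float = 1.0,
    init_params: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> Tuple[FittedHMM, float]:
    """Fit a K-state categorical HMM by scaled-EM.

    Plain EM (the default) has a monotonically non-decreasing log-likelihood,
    asserted each iteration.  With ``_fab=True`` the E-step shrinks
    responsibilities of underpopulated states and prunes states whose
    expected visit count falls below the threshold (the FIC training path).
    Returns (fitted model, final log-likelihood).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not seqs:
        raise ValueError("empty training set")
    obs, starts, ends = _pack(seqs)
    A = alphabet_size
    if obs.max() >= A:
        raise ValueError(f"symbol {obs.max()} outside alphabet of size {A}")
    support = len(np.unique(obs))
    pooled = np.bincount(obs, minlength=A).astype(float)
    pooled /= pooled.sum()
    if init_params is None:
        init, trans, emit = _random_params(K, A, pooled, rng)
    else:
        init, trans, emit = (np.array(p, dtype=float) for p in init_params)
    n_total = float(len(obs))
    prev_ll = -np.inf
    visits = np.full(K, n_total / K)
    ll = -np.inf
    for it in range(max_iter):
        Kc = len(init)
        if _fab:
            d_k = _free_params_per_state(Kc, A, support)
            shrink = np.exp(-d_k / (2.0 * np.maximum(visits, 1e-3)))
        else:
            shrink = np.ones(Kc)
        ll, init_acc, trans_acc, emit_acc, visits = _fb_accumulate(
            obs, starts, ends, init, trans, emit, shrink
        )
        if not _fab:
            assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), (
                f"EM log-likelihood decreased: {prev_ll} -> {ll}"
            )
        converged = np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(
            1.0, abs(ll)
        )
        prev_ll = ll
        if _fab and Kc > 1:
            keep = visits >= _prune_threshold
            if not np.all(keep):
                init = init[keep]
                init /= init.sum()
                trans = trans[np.ix_(keep, keep)]
                trans /= trans.sum(axis=1, keepdims=True)
                emit = emit[keep]
                visits = visits[keep]
                prev_ll = -np.inf
                continue
        # M-step
        init = init_acc / init_acc.sum()
        trans = trans_acc + 1e-10
        trans /= trans.sum(axis=1, keepdims=True)
        emit = emit_acc + 1e-10
        emit /= emit.sum(axis=1, keepdims=True)
        if converged:
            break
    # final E-pass statistics under the last parameters
    ll, _, _, _, visits = _fb_accumulate(
        obs, starts, ends, init, trans, emit, np.ones(len(init))
    )
    return FittedHMM(init, trans, emit, float(ll), visits), float(ll)


def fic_score(fit: FittedHMM, alphabet_size: int, support: int) -> float:
    """FIC lower bound: LL - sum_k (D_k/2) ln N_k."""
    K = fit.n_states
    d_k = _free_params_per_state(K, alphabet_size, support)
    n_k = np.maximum(fit.visits, 1e-3)
    return fit.log_likelihood - float(np.sum(d_k / 2.0 * np.log(n_k)))


def fic_select(
    seqs: Sequence[TrainingSequence],
    K_candidates: Iterable[int] = (1, 2, 3, 4, 5),
    n_trials: int = 5,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 100,
    tol: float = 1e-5,
    alphabet_size: int = 4,
) -> FittedHMM:
    """Best model over candidate state counts and random restarts.

    Each (K, trial) pair runs shrinkage EM; the fit whose FIC lower bound is
    maximal is returned (its state count may be below the candidate K when
    states were pruned).  Deterministic given the generator's seed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    obs = np.concatenate([s.symbols for s in seqs])
    support = len(np.unique(obs))
    best: Optional[FittedHMM] = None
    for K in K_candidates:
        for trial in range(n_trials):
            fit, _ = baum_welch(
                seqs,
                K,
                rng,
                max_iter=max_iter,
                tol=tol,
                alphabet_size=alphabet_size,
                _fab=True,
            )
            fit.fic = fic_score(fit, alphabet_size, support)
            if best is None or fit.fic > best.fic:
                best = fit
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Per-accuracy-bin training
# ---------------------------------------------------------------------------

AlignmentLike = Union[TrainingSequence, Tuple[str, str]]


def train_model_set(
    data: Sequence[AlignmentLike],
    kind: str = "errhmm",
    rng: Optional[np.random.Generator] = None,
    min_symbols: int = 100_000,
    K_candidates: Iterable[int] = (1, 2, 3, 4, 5),
    n_trials: int = 5,
    rearrange: bool = True,
    max_iter: int = 100,
) -> ModelSet:
    """Train one model per accuracy bin with enough data; note fallbacks.

    ``data`` holds either (ref_gapped, read_gapped) alignments (errhmm) or
    pre-encoded TrainingSequences.  Alignments are optionally homopolymer-
    rearranged before encoding.  A bin whose pooled training data is shorter
    than ``min_symbols`` symbols is recorded as a fallback bin: simulation
    will use constant-quality scores matching that accuracy.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if kind not in ("errhmm", "qshmm"):
        raise ValueError(f"unknown kind {kind!r}")
    alphabet = 4 if kind == "errhmm" else QUAL_SUPPORT
    by_bin: Dict[int, List[TrainingSequence]] = {}
    for item in data:
        if isinstance(item, TrainingSequence):
            ts = item
        else:
            ref_g, read_g = item
            if rearrange:
                ref_g, read_g = rearrange_homopolymer_indels(ref_g, read_g, rng)
            ts = encode_alignment(ref_g, read_g)
        if ts.accuracy is None:
            raise ValueError("training sequence lacks a source-read accuracy")
        from .model import accuracy_to_bin

        by_bin.setdefault(accuracy_to_bin(ts.accuracy), []).append(ts)

    bins: Dict[int, Union[ErrorHMM, QualityHMM]] = {}
    fallback: List[int] = []
    cls = ErrorHMM if kind == "errhmm" else QualityHMM
    for b in sorted(by_bin):
        group = by_bin[b]
        n_sym = sum(len(t.symbols) for t in group)
        if n_sym < min_symbols:
            logger.info("bin %d: %d symbols < %d, falling back", b, n_sym, min_symbols)
            fallback.append(b)
            continue
        fit = fic_select(
            group,
            K_candidates=K_candidates,
            n_trials=n_trials,
            rng=rng,
            max_iter=max_iter,
            alphabet_size=alphabet,
        )
        bins[b] = cls(accuracy_bin=b, init=fit.init, trans=fit.trans, emit=fit.emit)
        logger.info("bin %d: K=%d, FIC=%.1f", b, fit.n_states, fit.fic)
    if not bins:
        raise ValueError(
            "no accuracy bin reached the minimum training size; nothing to train"
        )
    return ModelSet(kind=kind, bins=bins, fallback_bins=fallback)


def match_states(
    emit_a: np.ndarray, emit_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Pair states of two emission matrices by minimal total-variation
    distance (label-switching repair for recovery comparisons)."""
    from itertools import permutations

    ka, kb = len(emit_a), len(emit_b)
    if ka != kb:
        raise ValueError("state counts differ")
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(kb)):
        cost = sum(
            0.5 * np.abs(emit_a[i] - emit_b[p]).sum() for i, p in enumerate(perm)
        )
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return np.arange(ka), np.array(best_perm)
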