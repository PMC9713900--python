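"""Per-read edit-script generation and realization.

Three engines produce an ``OpString`` — a sequence over {M, S, I, D} that is
the read's ground-truth edit script against its template:

* random:  i.i.d. ops; each emitted op is an error with a fixed probability,
  the error type drawn from a user S:I:D ratio.
* qshmm:   a quality track is generated first (Markov model over Phred
  scores); position i is an error with probability 10^(-Q_i/10), typed by the
  ratio.  A deletion consumes no read position (the position is re-queued).
* errhmm:  a hidden Markov model emits M/S/I/D directly; the error ratio is a
  property of the model.

``place_ops`` realizes a script on a template window: substituted bases are
uniform over the three alternatives, inserted bases uniform over four.  A
homopolymer deletion bias >= 1 repositions the script's deletions among
template sites with weight rising linearly from 1 (1-mer) to the bias value
(10-mer), conserving the per-read deletion count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import ErrorHMM, QualityHMM, OPS, OP_M, OP_S, OP_I, OP_D

_B2C = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _B2C[b] = i
    _B2C[ord(chr(b).lower())] = i
_C2B = np.frombuffer(b"ACGT", dtype=np.uint8)

_OP2C = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"MSID"):
    _OP2C[b] = i
_C2OP = np.frombuffer(b"MSID", dtype=np.uint8)


def dna_to_codes(seq: str) -> np.ndarray:
    codes = _B2C[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def codes_to_dna(codes: np.ndarray) -> str:
    return _C2B[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return codes_to_dna(3 - dna_to_codes(seq)[::-1])


@dataclass
class OpString:
    """Edit script over {M, S, I, D}, stored as uint8 codes 0..3.

    The encoding matches the training alphabet: match=0, substitution=1,
    insertion=2, deletion=3.
    """

    codes: np.ndarray

    def __init__(self, codes):
        if isinstance(codes, OpString):
            codes = codes.codes
        elif isinstance(codes, str):
            codes = _OP2C[np.frombuffer(codes.encode(), dtype=np.uint8)]
            if len(codes) and codes.max() > 3:
                raise ValueError("op string may only contain M, S, I, D")
        self.codes = np.asarray(codes, dtype=np.uint8)

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return _C2OP[self.codes].tobytes().decode()

    def __eq__(self, other) -> bool:
        return isinstance(other, OpString) and np.array_equal(self.codes, other.codes)

    def counts(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=4)

    @property
    def read_len(self) -> int:
        """Read-consuming ops: M + S + I."""
        return int(np.count_nonzero(self.codes != OP_D))

    @property
    def template_span(self) -> int:
        """Template-consuming ops: M + S + D."""
        return int(np.count_nonzero(self.codes != OP_I))

    @property
    def accuracy(self) -> float:
        if len(self.codes) == 0:
            raise ValueError("accuracy of an empty op string is undefined")
        return float(np.count_nonzero(self.codes == OP_M)) / len(self.codes)


def _cut(codes: np.ndarray, max_read: Optional[int], max_template: Optional[int]) -> Tuple[np.ndarray, bool]:
    """Truncate a raw op stream at whichever limit is hit first.

    The cut is inclusive of the op that reaches the limit, so a read-limited
    script never ends in trailing deletions.  Returns (codes, reached) where
    reached is False if neither limit was attained.
    """
    end = len(codes)
    reached = False
    if (max_read is not None and max_read <= 0) or (
        max_template is not None and max_template <= 0
    ):
        return codes[:0], True
    if max_read is not None:
        rcum = np.cumsum(codes != OP_D)
        idx = int(np.searchsorted(rcum, max_read))
        if idx < len(codes):
            end = min(end, idx + 1)
            reached = True
        elif len(rcum) and rcum[-1] >= max_read:
            reached = True
    if max_template is not None:
        tcum = np.cumsum(codes != OP_I)
        idx = int(np.searchsorted(tcum, max_template))
        if idx < len(codes):
            if idx + 1 <= end:
                end = idx + 1
                reached = True
        elif len(tcum) and tcum[-1] >= max_template:
            reached = True
    return codes[:end], reached


def gen_ops_random(
    error_rate: float,
    ratio,
    read_len: int,
    rng: np.random.Generator,
    max_template: Optional[int] = None,
) -> OpString:
    """i.i.d. op stream: error with prob ``error_rate``, typed by S:I:D ratio.

    Generation stops once ``read_len`` read-consuming ops were emitted (or the
    template budget is exhausted).
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    r = np.asarray(ratio, dtype=float)
    r = r / r.sum()
    probs = np.array(
        [1.0 - error_rate, error_rate * r[0], error_rate * r[1], error_rate * r[2]]
    )
    cum = np.cumsum(probs)
    chunks = []
    got_read = 0
    got_template = 0
    while True:
        need = read_len - got_read
        if max_template is not None:
            need = min(need, max_template - got_template)
        if need <= 0:
            break
        m = int(need / max(1.0 - error_rate * r[2], 0.5) * 1.05) + 16
        codes = np.searchsorted(cum, rng.random(m)).astype(np.uint8)
        mr = read_len - got_read
        mt = None if max_template is None else max_template - got_template
        codes, reached = _cut(codes, mr, mt)
        chunks.append(codes)
        got_read += int(np.count_nonzero(codes != OP_D))
        got_template += int(np.count_nonzero(codes != OP_I))
        if reached:
            break
    return OpString(np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8))


def _markov_path(
    init: np.ndarray, trans: np.ndarray, n: int, rng: np.random.Generator,
    start_state: Optional[int] = None,
) -> np.ndarray:
    """Sample a state path of length n (plain loop; K is small)."""
    k = len(init)
    if k == 1:
        return np.zeros(n, dtype=np.int64)
    cum_t = np.cumsum(trans, axis=1)
    u = rng.random(n)
    states = np.empty(n, dtype=np.int64)
    if start_state is None:
        s = int(np.searchsorted(np.cumsum(init), rng.random()))
    else:
        s = int(np.searchsorted(cum_t[start_state], rng.random()))
    rows = [cum_t[i] for i in range(k)]
    for t in range(n):
        states[t] = s
        s = int(np.searchsorted(rows[s], u[t]))
    return states


def gen_quality_track(
    model: QualityHMM,
    read_len: int,
    rng: np.random.Generator,
    start_state: Optional[int] = None,
    return_states: bool = False,
):
    """Quality scores of length ``read_len`` sampled from the quality HMM."""
    states = _markov_path(model.init, model.trans, read_len, rng, start_state)
    quals = np.empty(read_len, dtype=np.int64)
    for s in np.unique(states):
        mask = states == s
        cum_e = np.cumsum(model.emit[s])
        quals[mask] = np.searchsorted(cum_e, rng.random(int(mask.sum())))
    if return_states:
        return quals, states
    return quals


def gen_ops_qshmm(
    qualities: np.ndarray,
    ratio,
    rng: np.random.Generator,
    max_template: Optional[int] = None,
) -> OpString:
    """Ops from a quality track: position i errs with prob 10^(-Q_i/10).

    Each emitted op at position i is independently an error with that
    probability and typed by the S:I:D ratio; a D op consumes the template
    only and re-queues the read position, so insertions/substitutions consume
    the position's quality while deletions do not.
    """
    q = np.asarray(qualities, dtype=float)
    r = np.asarray(ratio, dtype=float)
    r = r / r.sum()
    p = 10.0 ** (-q / 10.0)
    pd = p * r[2]
    # deletions emitted before position i is consumed ~ Geometric
    n_del = rng.geometric(1.0 - pd) - 1 if len(q) else np.zeros(0, dtype=np.int64)
    # type of the consuming op, conditional on not-D
    u = rng.random(len(q))
    p_m = (1.0 - p) / (1.0 - pd)
    p_s = p * r[0] / (1.0 - pd)
    consumed = np.where(u < p_m, OP_M, np.where(u < p_m + p_s, OP_S, OP_I)).astype(
        np.uint8
    )
    total = int(n_del.sum()) + len(q)
    codes = np.full(total, OP_D, dtype=np.uint8)
    codes[np.cumsum(n_del + 1) - 1] = consumed
    codes, _ = _cut(codes, None, max_template)
    return OpString(codes)


def gen_ops_errhmm(
    model: ErrorHMM,
    read_len: Optional[int],
    rng: np.random.Generator,
    max_template: Optional[int] = None,
    return_states: bool = False,
):
    """Ops emitted by the error HMM until a read/template budget is reached.

    Trailing deletions after the last read-consuming op are dropped when the
    read budget terminates generation.
    """
    if read_len is None and max_template is None:
        raise ValueError("need a read or template budget")
    k = model.n_states
    exp_ops = 0
    if read_len is not None:
        exp_ops = max(exp_ops, int(read_len * 1.2) + 32)
    if max_template is not None:
        exp_ops = max(exp_ops, int(max_template * 1.2) + 32)
    all_codes = []
    all_states = []
    got_read = 0
    got_template = 0
    last_state: Optional[int] = None
    while True:
        states = _markov_path(model.init, model.trans, exp_ops, rng, last_state)
        codes = np.empty(exp_ops, dtype=np.uint8)
        for s in range(k):
            mask = states == s
            nm = int(mask.sum())
            if nm:
                cum_e = np.cumsum(model.emit[s])
                codes[mask] = np.searchsorted(cum_e, rng.random(nm))
        mr = None if read_len is None else read_len - got_read
        mt = None if max_template is None else max_template - got_template
        codes, reached = _cut(codes, mr, mt)
        states = states[: len(codes)]
        all_codes.append(codes)
        all_states.append(states)
        got_read += int(np.count_nonzero(codes != OP_D))
        got_template += int(np.count_nonzero(codes != OP_I))
        if reached:
            break
        last_state = int(states[-1]) if len(states) else last_state
        exp_ops = max(exp_ops // 2, 64)
    ops = OpString(np.concatenate(all_codes))
    if return_states:
        return ops, np.concatenate(all_states)
    return ops


def qualities_for_errhmm(
    ops: OpString, model: ErrorHMM, state_path: np.ndarray
) -> np.ndarray:
    """Phred track for an errhmm script: Q = -10 log10(1 - P(M | state)).

    One value per read-consuming op, clamped to [0, 93]; a state that never
    errs gets Q = 93.
    """
    p_err = 1.0 - model.emit[:, OP_M]
    with np.errstate(divide="ignore"):
        q_state = np.where(p_err > 0, -10.0 * np.log10(np.maximum(p_err, 1e-300)), 93.0)
    q_state = np.clip(np.rint(q_state), 0, 93).astype(np.int64)
    mask = ops.codes != OP_D
    return q_state[np.asarray(state_path)[mask]]


def hp_weight(hp_len, bias: float):
    """Deletion-rate multiplier for a homopolymer site.

    Rises linearly from 1 at 1-mers to ``bias`` at 10-mers and saturates
    beyond; hp_weight(4, 6) = 1 + 5*3/9 = 2.667.
    """
    if bias < 1.0:
        raise ValueError("hp_del_bias must be >= 1")
    L = np.minimum(np.asarray(hp_len), 10)
    if np.any(L < 1):
        raise ValueError("homopolymer length must be >= 1")
    w = 1.0 + (bias - 1.0) * (L - 1) / 9.0
    return float(w) if np.isscalar(hp_len) else w


def site_hp_lengths(seq_codes: np.ndarray) -> np.ndarray:
    """Length of the maximal identical-base run containing each site."""
    n = len(seq_codes)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.flatnonzero(seq_codes[1:] != seq_codes[:-1]) + 1
    bounds = np.concatenate(([0], change, [n]))
    lens = np.diff(bounds)
    return np.repeat(lens, lens)


def _reposition_deletions(
    codes: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Re-place D ops among template sites with the given acceptance weights.

    The op multiset is conserved (same #M, #S, #I, #D) and the relative order
    of read-consuming ops is preserved; only which template slots carry a
    deletion changes.
    """
    span = int(np.count_nonzero(codes != OP_I))
    n_del = int(np.count_nonzero(codes == OP_D))
    if n_del == 0 or span == 0:
        return codes
    # Randomized systematic PPS sampling: inclusion probability of slot i is
    # exactly n_del * w_i / sum(w) (plain without-replacement draws would
    # systematically under-select heavy slots).
    perm = rng.permutation(span)
    cw = np.cumsum(weights[perm])
    total = cw[-1]
    if n_del * weights.max() < total:
        points = (rng.random() + np.arange(n_del)) * (total / n_del)
        del_slots = perm[np.searchsorted(cw, points, side="right")]
    else:  # degenerate: deletion budget too large for proportional inclusion
        del_slots = rng.choice(span, size=n_del, replace=False, p=weights / total)
    dind = np.zeros(span, dtype=bool)
    dind[del_slots] = True

    read_ops = codes[codes != OP_D]  # M, S, I in original order
    ms_ops = read_ops[read_ops != OP_I]
    events = np.full(span, OP_D, dtype=np.uint8)
    nondel = np.flatnonzero(~dind)
    events[nondel] = ms_ops

    i_idx = np.flatnonzero(read_ops == OP_I)
    if len(i_idx) == 0:
        return events
    # anchor: number of M/S read ops preceding each I
    ms_cum = np.cumsum(read_ops != OP_I)
    anchors = ms_cum[i_idx]  # insert I after the anchor-th M/S
    ins_pos = np.where(anchors > 0, nondel[np.maximum(anchors - 1, 0)] + 1, 0)
    return np.insert(events, ins_pos, OP_I)


def place_ops(
    template: str | np.ndarray,
    start: int,
    ops: OpString,
    hp_del_bias: float,
    rng: np.random.Generator,
    site_lengths: Optional[np.ndarray] = None,
) -> Tuple[str, OpString]:
    """Realize an edit script on ``template`` from offset ``start``.

    Returns (read sequence, final ops).  M copies the template base, S
    substitutes uniformly among the other three, I inserts a uniform base, D
    skips a template base.  With hp_del_bias > 1, deletions are repositioned
    within the window proportionally to the homopolymer weight of each site.
    """
    tcodes = template if isinstance(template, np.ndarray) else dna_to_codes(template)
    span = ops.template_span
    if start < 0 or start + span > len(tcodes):
        raise ValueError(
            f"ops span {span} from start {start} overruns template of {len(tcodes)}"
        )
    window = tcodes[start : start + span]
    codes = ops.codes
    if hp_del_bias > 1.0 and span > 0:
        if site_lengths is None:
            site_lengths = site_hp_lengths(tcodes)
        w = hp_weight(site_lengths[start : start + span], hp_del_bias)
        codes = _reposition_deletions(codes, w, rng)

    tcons = codes != OP_I
    tpos = np.cumsum(tcons) - 1
    rmask = codes != OP_D
    rcodes = codes[rmask]
    t_of_r = tpos[rmask]
    out = np.empty(len(rcodes), dtype=np.uint8)
    mmask = rcodes == OP_M
    out[mmask] = window[t_of_r[mmask]]
    smask = rcodes == OP_S
    ns = int(smask.sum())
    if ns:
        out[smask] = (window[t_of_r[smask]] + rng.integers(1, 4, size=ns)) % 4
    imask = rcodes == OP_I
    ni = int(imask.sum())
    if ni:
        out[imask] = rng.integers(0, 4, size=ni)
    return codes_to_dna(out), OpString(codes)


def quals_to_phred33(quals: np.ndarray) -> str:
    return (np.asarray(quals, dtype=np.uint8) + 33).tobytes().decode()


def phred33_to_quals(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int64) - 33
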