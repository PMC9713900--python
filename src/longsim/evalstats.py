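"""Evaluation statistics computed from ground-truth edit scripts.

These are the quantities used to judge how faithfully simulated reads mimic
real ones: per-read and per-window accuracy (error nonuniformity), the KL
divergence between window-accuracy distributions, per-homopolymer-length
error rates, and INDEL run-length spectra.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import OP_D, OP_I, OP_M, OP_S, OpString, dna_to_codes, site_hp_lengths
from .model import ReadRecord, accuracy_to_bin

DEFAULT_INTERVAL = 800


def read_accuracy(ops: OpString) -> float:
    """#M / (#M + #S + #I + #D) over one edit script."""
    if isinstance(ops, ReadRecord):
        ops = ops.ops
    return ops.accuracy


def interval_accuracy_hist(
    reads: Iterable[ReadRecord],
    interval: int = DEFAULT_INTERVAL,
    acc_bin_width: float = 0.01,
) -> Dict[int, np.ndarray]:
    """Window-accuracy distributions per whole-percent read-accuracy group.

    Each read's ops are split into disjoint windows of ``interval`` read
    bases (M+S+I ops); the final partial window is dropped.  Windows'
    accuracies are histogrammed with the given bin width and normalized to a
    probability distribution per read group.

    Returns {read accuracy bin (int percent): histogram over accuracy bins},
    where histogram index i covers accuracy [i*w, (i+1)*w).
    """
    n_bins = int(round(1.0 / acc_bin_width)) + 1
    counts: Dict[int, np.ndarray] = {}
    for rec in reads:
        ops = rec.ops if isinstance(rec, ReadRecord) else OpString(rec)
        codes = ops.codes
        group = accuracy_to_bin(ops.accuracy)
        rcum = np.cumsum(codes != OP_D)
        n_windows = int(rcum[-1]) // interval if len(rcum) else 0
        if n_windows == 0:
            continue
        # op index where each window of `interval` read bases ends
        ends = np.searchsorted(rcum, np.arange(1, n_windows + 1) * interval) + 1
        starts = np.concatenate(([0], ends[:-1]))
        m_cum = np.concatenate(([0], np.cumsum(codes == OP_M)))
        acc = (m_cum[ends] - m_cum[starts]) / (ends - starts)
        idx = np.minimum((acc / acc_bin_width).astype(int), n_bins - 1)
        if group not in counts:
            counts[group] = np.zeros(n_bins)
        np.add.at(counts[group], idx, 1)
    return {g: h / h.sum() for g, h in counts.items()}


def kl_divergence(
    P: np.ndarray, Q: np.ndarray, smooth: Optional[float] = None
) -> float:
    """D_KL(P || Q) = sum_i P(i) log2(P(i)/Q(i)), in bits.

    ``smooth`` adds epsilon to every Q (and P) bin and renormalizes, for
    empirical histograms with empty bins.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must share a support")
    P = P / P.sum()
    Q = Q / Q.sum()
    if smooth is not None:
        P = (P + smooth) / (P + smooth).sum()
        Q = (Q + smooth) / (Q + smooth).sum()
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise ValueError(
            "Q has zero mass where P > 0; pass smooth= to regularize the histograms"
        )
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


def homopolymer_error_profile(
    reads: Iterable[ReadRecord],
    templates: Dict[str, str],
    max_len: int = 10,
) -> "pd.DataFrame":
    """Per-homopolymer-length substitution/insertion/deletion rates.

    Every template site is labeled with the length of the identical-base run
    containing it (capped at ``max_len``; longer runs pool into the cap).
    For each length: rate = errors at sites of that length / read coverage of
    those sites.  Insertions are attributed to the template site left of the
    insertion point.
    """
    import pandas as pd

    site_cache: Dict[str, np.ndarray] = {}
    cov = np.zeros(max_len + 1)
    errs = np.zeros((max_len + 1, 3))  # S, I, D
    for rec in reads:
        tid = rec.template_id
        if tid not in site_cache:
            site_cache[tid] = np.minimum(
                site_hp_lengths(dna_to_codes(templates[tid])), max_len
            )
        labels_fwd = site_cache[tid]
        labels = labels_fwd[rec.template_start : rec.template_end]
        if rec.strand == "-":
            labels = labels[::-1]
        cov += np.bincount(labels, minlength=max_len + 1)
        codes = rec.ops.codes
        tpos = np.cumsum(codes != OP_I) - 1
        for row, op in ((0, OP_S), (2, OP_D)):
            mask = codes == op
            if mask.any():
                errs[:, row] += np.bincount(labels[tpos[mask]], minlength=max_len + 1)
        imask = codes == OP_I
        if imask.any():
            anchors = np.maximum(tpos[imask], 0)  # left-flanking site
            errs[:, 1] += np.bincount(labels[anchors], minlength=max_len + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(cov[:, None] > 0, errs / cov[:, None], 0.0)
    df = pd.DataFrame(
        {
            "hp_len": np.arange(1, max_len + 1),
            "sites_covered": cov[1:],
            "sub_rate": rates[1:, 0],
            "ins_rate": rates[1:, 1],
            "del_rate": rates[1:, 2],
        }
    )
    df["total_rate"] = df[["sub_rate", "ins_rate", "del_rate"]].sum(axis=1)
    return df


def indel_size_distribution(
    reads: Iterable[ReadRecord],
) -> Tuple[Counter, Counter]:
    """Histograms of maximal insertion-run and deletion-run lengths."""
    ins: Counter = Counter()
    dels: Counter = Counter()
    for rec in reads:
        ops = rec.ops if isinstance(rec, ReadRecord) else OpString(rec)
        codes = ops.codes
        for op, counter in ((OP_I, ins), (OP_D, dels)):
            mask = np.concatenate(([False], codes == op, [False])).astype(np.int8)
            d = np.diff(mask)
            run_starts = np.flatnonzero(d == 1)
            run_ends = np.flatnonzero(d == -1)
            for L in run_ends - run_starts:
                counter[int(L)] += 1
    return ins, dels
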