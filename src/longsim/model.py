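"""Core domain types: HMM error/quality models, model-file I/O, bin selection.

A simulated read's error process is driven by one of three engines; two of them
are hidden Markov models loaded from plain-text model files:

* ``ErrorHMM`` — emits edit operations (match / substitution / insertion /
  deletion) directly; the error ratio is implied by the model and cannot be
  overridden at run time.
* ``QualityHMM`` — emits Phred quality scores; errors are then drawn
  per-position with probability 10^(-Q/10) and typed by a user-supplied
  substitution:insertion:deletion ratio.

Models are trained per integer read-accuracy percent ("bin"): the model for
bin 80 is trained on reads whose accuracy lies in [79.5%, 80.5%).  A
``ModelSet`` holds all bins of one kind and supplies a constant-quality
surrogate for accuracies that have no trained model.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple, Union

import numpy as np

#: Emission alphabet of the error model, in file order.
OPS = "MSID"
OP_M, OP_S, OP_I, OP_D = 0, 1, 2, 3

#: Phred quality support of the quality-score model.
MAX_QUAL = 93
QUAL_SUPPORT = MAX_QUAL + 1

_ROW_TOL = 1e-6


class ModelFormatError(ValueError):
    """Raised when a model file is malformed or violates stochasticity."""


def _check_stochastic(name: str, arr: np.ndarray, tol: float = _ROW_TOL) -> None:
    a = np.asarray(arr, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ModelFormatError(f"{name}: probabilities must lie in [0, 1]")
    sums = a.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=tol, rtol=0):
        raise ModelFormatError(f"{name}: rows must sum to 1 (got {sums})")


@dataclass(frozen=True)
class _HMMBase:
    accuracy_bin: int
    init: np.ndarray
    trans: np.ndarray
    emit: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "init", np.asarray(self.init, dtype=float))
        object.__setattr__(self, "trans", np.asarray(self.trans, dtype=float))
        object.__setattr__(self, "emit", np.asarray(self.emit, dtype=float))
        k = self.init.shape[0]
        if k < 1:
            raise ModelFormatError("model must have at least one state")
        if self.trans.shape != (k, k):
            raise ModelFormatError("TRANS must be K x K")
        if self.emit.ndim != 2 or self.emit.shape[0] != k:
            raise ModelFormatError("EMIT must have one row per state")
        _check_stochastic("INIT", self.init[None, :])
        _check_stochastic("TRANS", self.trans)
        _check_stochastic("EMIT", self.emit)

    @property
    def n_states(self) -> int:
        return self.init.shape[0]

    def stationary(self, n_iter: int = 10_000, tol: float = 1e-13) -> np.ndarray:
        """Stationary distribution of the state chain by power iteration."""
        pi = np.full(self.n_states, 1.0 / self.n_states)
        for _ in range(n_iter):
            nxt = pi @ self.trans
            if np.abs(nxt - pi).max() < tol:
                pi = nxt
                break
            pi = nxt
        return pi / pi.sum()


@dataclass(frozen=True)
class ErrorHMM(_HMMBase):
    """HMM emitting edit operations (M, S, I, D) directly."""

    def __post_init__(self):
        super().__post_init__()
        if self.emit.shape[1] != 4:
            raise ModelFormatError("errhmm EMIT rows must have 4 entries (M S I D)")

    def implied_error_ratio(self) -> np.ndarray:
        """Stationary S:I:D shares (summing to 100), fixed by the model."""
        pi = self.stationary()
        sid = pi @ self.emit[:, 1:]
        total = sid.sum()
        if total <= 0:
            return np.array([0.0, 0.0, 0.0])
        return 100.0 * sid / total

    def expected_accuracy(self) -> float:
        pi = self.stationary()
        return float(pi @ self.emit[:, 0])


@dataclass(frozen=True)
class QualityHMM(_HMMBase):
    """HMM emitting Phred quality scores in 0..93."""

    def __post_init__(self):
        super().__post_init__()
        if self.emit.shape[1] != QUAL_SUPPORT:
            raise ModelFormatError(
                f"qshmm EMIT support must be 0..{MAX_QUAL} ({QUAL_SUPPORT} columns)"
            )

    def expected_error_rate(self) -> float:
        pi = self.stationary()
        p_q = pi @ self.emit
        q = np.arange(QUAL_SUPPORT)
        return float(np.sum(p_q * 10.0 ** (-q / 10.0)))


Model = Union[ErrorHMM, QualityHMM]


def accuracy_to_bin(accuracy: float) -> int:
    """Integer percent bin of a read accuracy; round half up.

    Bin b covers accuracies in [b - 0.5, b + 0.5) percent, so 79.5% and 80.4%
    both map to 80 while 80.5% maps to 81.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError(f"accuracy must be in (0, 1], got {accuracy}")
    # Guard against binary representation noise right at the x.5 breakpoints.
    return int(math.floor(round(accuracy * 100.0, 6) + 0.5))


def constant_quality_model(bin_percent: int) -> QualityHMM:
    """1-state quality model whose single Q best matches the bin's error rate.

    Used when no trained model exists for a bin: constant quality scores that
    match the requested accuracy.
    """
    err = max(1.0 - bin_percent / 100.0, 0.0)
    qs = np.arange(QUAL_SUPPORT)
    q = int(np.argmin(np.abs(10.0 ** (-qs / 10.0) - err)))
    emit = np.zeros((1, QUAL_SUPPORT))
    emit[0, q] = 1.0
    return QualityHMM(
        accuracy_bin=bin_percent, init=np.ones(1), trans=np.ones((1, 1)), emit=emit
    )


@dataclass
class ModelSet:
    """All per-accuracy-bin models of one kind, plus the fallback rule."""

    kind: str  # "errhmm" | "qshmm"
    bins: Dict[int, Model] = field(default_factory=dict)
    fallback_bins: List[int] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("errhmm", "qshmm"):
            raise ModelFormatError(f"unknown model kind {self.kind!r}")
        if not self.bins:
            raise ModelFormatError("a ModelSet needs at least one bin")
        for b, m in self.bins.items():
            if int(b) != m.accuracy_bin:
                raise ModelFormatError(
                    f"bin key {b} disagrees with model accuracy_bin {m.accuracy_bin}"
                )

    def select_bin(self, accuracy: float) -> Model:
        """Model for a read accuracy.

        Exact trained bin if present; a bin outside the trained range clamps to
        the nearest trained bin; an untrained bin inside the range falls back
        to the constant-quality surrogate matching the requested accuracy.
        """
        b = accuracy_to_bin(accuracy)
        if b in self.bins:
            return self.bins[b]
        trained = sorted(self.bins)
        if b < trained[0]:
            return self.bins[trained[0]]
        if b > trained[-1]:
            return self.bins[trained[-1]]
        return constant_quality_model(b)

    def nearest_trained(self, accuracy: float) -> Model:
        b = accuracy_to_bin(accuracy)
        key = min(self.bins, key=lambda t: abs(t - b))
        return self.bins[key]


def select_bin(ms: ModelSet, accuracy: float) -> Model:
    return ms.select_bin(accuracy)


# ---------------------------------------------------------------------------
# Model file format
#
#   MODEL errhmm|qshmm
#   ACC <int>
#   STATES <K>
#   INIT p1 .. pK
#   TRANS      (K rows of K floats)
#   EMIT       (K rows; errhmm: 4 floats M S I D; qshmm: "Q:prob" pairs)
#
# '#' starts a comment; blank lines are ignored.  Floats are written with
# repr() so that save -> load round-trips bit-identically.
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def save_model_set(ms: ModelSet, path) -> None:
    lines = [f"MODEL {ms.kind}"]
    for b in sorted(ms.bins):
        m = ms.bins[b]
        lines.append(f"ACC {b}")
        lines.append(f"STATES {m.n_states}")
        lines.append("INIT " + " ".join(_fmt(p) for p in m.init))
        lines.append("TRANS")
        for row in m.trans:
            lines.append(" ".join(_fmt(p) for p in row))
        lines.append("EMIT")
        for row in m.emit:
            if ms.kind == "errhmm":
                lines.append(" ".join(_fmt(p) for p in row))
            else:
                pairs = [f"{q}:{_fmt(p)}" for q, p in enumerate(row) if p > 0.0]
                lines.append(" ".join(pairs) if pairs else "0:0.0")
    for b in ms.fallback_bins:
        lines.append(f"# FALLBACK {b} constant-quality surrogate (insufficient training data)")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


class _LineReader:
    def __init__(self, path):
        self.path = str(path)
        with open(path, encoding="utf-8") as fh:
            self.raw = fh.read().splitlines()
        self.pos = 0
        self.fallback_bins: List[int] = []

    def next(self) -> Optional[Tuple[int, str]]:
        while self.pos < len(self.raw):
            lineno = self.pos + 1
            line = self.raw[self.pos]
            self.pos += 1
            m = re.match(r"#\s*FALLBACK\s+(\d+)", line.strip())
            if m:
                self.fallback_bins.append(int(m.group(1)))
                continue
            line = line.split("#", 1)[0].strip()
            if line:
                return lineno, line
        return None

    def require(self) -> Tuple[int, str]:
        item = self.next()
        if item is None:
            raise ModelFormatError(f"{self.path}: unexpected end of file")
        return item

    def error(self, lineno: int, msg: str):
        raise ModelFormatError(f"{self.path}:{lineno}: {msg}")


def _parse_floats(rd: _LineReader, lineno: int, line: str, n: int) -> np.ndarray:
    parts = line.split()
    if len(parts) != n:
        rd.error(lineno, f"expected {n} values, got {len(parts)}")
    try:
        return np.array([float(p) for p in parts])
    except ValueError:
        rd.error(lineno, f"non-numeric value in {line!r}")


def _parse_qual_row(rd: _LineReader, lineno: int, line: str) -> np.ndarray:
    row = np.zeros(QUAL_SUPPORT)
    for token in line.split():
        if ":" not in token:
            rd.error(lineno, f"expected Q:prob pair, got {token!r}")
        qs, ps = token.split(":", 1)
        try:
            q, p = int(qs), float(ps)
        except ValueError:
            rd.error(lineno, f"bad Q:prob pair {token!r}")
        if not 0 <= q <= MAX_QUAL:
            rd.error(lineno, f"quality {q} outside 0..{MAX_QUAL}")
        row[q] = p
    return row


def load_model_set(path) -> ModelSet:
    """Parse a model file; validates stochasticity to within {tol}.""".format(
        tol=_ROW_TOL
    )
    rd = _LineReader(path)
    lineno, header = rd.require()
    parts = header.split()
    if len(parts) != 2 or parts[0] != "MODEL" or parts[1] not in ("errhmm", "qshmm"):
        rd.error(lineno, f"expected 'MODEL errhmm|qshmm', got {header!r}")
    kind = parts[1]
    cls = ErrorHMM if kind == "errhmm" else QualityHMM
    n_emit = 4 if kind == "errhmm" else QUAL_SUPPORT

    bins: Dict[int, Model] = {}
    while True:
        item = rd.next()
        if item is None:
            break
        lineno, line = item
        if not line.startswith("ACC"):
            rd.error(lineno, f"expected 'ACC <int>', got {line!r}")
        try:
            acc = int(line.split()[1])
        except (IndexError, ValueError):
            rd.error(lineno, f"bad ACC line {line!r}")
        lineno, line = rd.require()
        if not line.startswith("STATES"):
            rd.error(lineno, f"expected 'STATES <K>', got {line!r}")
        try:
            k = int(line.split()[1])
        except (IndexError, ValueError):
            rd.error(lineno, f"bad STATES line {line!r}")
        if k < 1:
            rd.error(lineno, "STATES must be >= 1")
        lineno, line = rd.require()
        if not line.startswith("INIT"):
            rd.error(lineno, f"expected INIT line, got {line!r}")
        init = _parse_floats(rd, lineno, line[4:].strip(), k)
        lineno, line = rd.require()
        if line != "TRANS":
            rd.error(lineno, f"expected TRANS, got {line!r}")
        trans = np.vstack(
            [_parse_floats(rd, *rd.require(), k) for _ in range(k)]
        )
        lineno, line = rd.require()
        if line != "EMIT":
            rd.error(lineno, f"expected EMIT, got {line!r}")
        rows = []
        for _ in range(k):
            rl, rline = rd.require()
            if kind == "errhmm":
                rows.append(_parse_floats(rd, rl, rline, n_emit))
            else:
                rows.append(_parse_qual_row(rd, rl, rline))
        emit = np.vstack(rows)
        try:
            model = cls(accuracy_bin=acc, init=init, trans=trans, emit=emit)
        except ModelFormatError as exc:
            raise ModelFormatError(f"{rd.path}: ACC {acc}: {exc}") from exc
        bins[acc] = model

    ms = ModelSet(kind=kind, bins=bins, fallback_bins=rd.fallback_bins)
    return ms


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All knobs of one simulation run.

    Length defaults follow typical whole-genome CLR/ONT settings (gamma with
    mean = sd = 15 kb); ``error_ratio`` applies to the random and quality-score
    engines only — the error model has its ratio built in.
    """

    strategy: str = "wgs"  # "wgs" | "trans"
    method: str = "random"  # "random" | "qshmm" | "errhmm"
    depth: float = 20.0
    pass_num: int = 1
    length_mean: float = 15_000.0
    length_sd: float = 15_000.0
    length_min: int = 100
    length_max: int = 1_000_000
    accuracy_mean: float = 0.85
    accuracy_sd: float = 0.02
    error_ratio: Tuple[float, float, float] = (6.0, 55.0, 39.0)
    hp_del_bias: float = 1.0
    seed: int = 0
    prefix: str = "sim"
    # Transcriptome start-position model (Pareto + 5' atom); calibration knobs.
    start_alpha: float = 1.0
    start_scale: float = 0.05
    start_p5: float = 0.3

    def __post_init__(self):
        if self.strategy not in ("wgs", "trans"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.method not in ("random", "qshmm", "errhmm"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (self.length_min <= self.length_mean <= self.length_max):
            raise ValueError("need length_min <= length_mean <= length_max")
        if not 0.0 < self.accuracy_mean <= 1.0:
            raise ValueError("accuracy_mean must be in (0, 1]")
        if self.pass_num < 1:
            raise ValueError("pass_num must be >= 1")
        if self.hp_del_bias < 1.0:
            raise ValueError("hp_del_bias must be >= 1")
        total = float(sum(self.error_ratio))
        if total <= 0:
            raise ValueError("error_ratio must have positive sum")
        self.error_ratio = tuple(100.0 * r / total for r in self.error_ratio)

    @property
    def ratio_fractions(self) -> np.ndarray:
        """S:I:D as fractions summing to 1."""
        return np.asarray(self.error_ratio) / 100.0


# ---------------------------------------------------------------------------
# Read records
# ---------------------------------------------------------------------------


@dataclass
class ReadRecord:
    """A simulated read plus its ground-truth alignment to the template."""

    name: str
    sequence: str
    qualities: str  # Phred+33, same length as sequence
    template_id: str
    template_start: int  # 0-based inclusive, forward-strand coordinates
    template_end: int  # exclusive
    strand: str  # '+' | '-'
    ops: "np.ndarray"  # OpString codes, in sequenced-strand frame
    pass_index: int = 1

    def __post_init__(self):
        from .errors import OpString

        if not isinstance(self.ops, OpString):
            self.ops = OpString(self.ops)
        if self.ops.read_len != len(self.sequence):
            raise ValueError(
                f"{self.name}: ops imply read length {self.ops.read_len}, "
                f"sequence has {len(self.sequence)}"
            )
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.name}: quality/sequence length mismatch")
        if self.ops.template_span != self.template_end - self.template_start:
            raise ValueError(
                f"{self.name}: ops imply span {self.ops.template_span}, "
                f"coordinates give {self.template_end - self.template_start}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
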