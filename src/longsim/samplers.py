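"""Random draws other than error generation.

Read lengths follow a gamma distribution parameterized by moment matching
(shape k = mean^2/sd^2, scale theta = sd^2/mean); sd = 0 degenerates to a
constant length, which multi-pass whole-genome simulation uses.  Per-read
accuracies are truncated-normal.  Transcriptome read start offsets follow a
translated, scaled Pareto tail from the 5' end with an explicit probability
atom exactly at offset 0 (the spike of full-length / 5'-intact reads).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GammaLengthSpec:
    mean: float
    sd: float
    min: int = 100
    max: int = 1_000_000

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("mean must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.min > self.max:
            raise ValueError("length min > max")

    @property
    def shape(self) -> float:
        return self.mean**2 / self.sd**2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean


def draw_lengths(spec: GammaLengthSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """n integer lengths in [spec.min, spec.max]; out-of-range draws rejected."""
    if spec.sd == 0:
        val = int(round(spec.mean))
        if not spec.min <= val <= spec.max:
            raise ValueError("constant length outside [min, max]")
        return np.full(n, val, dtype=np.int64)
    out = np.empty(n, dtype=np.int64)
    have = 0
    while have < n:
        m = max(n - have, 16)
        draws = np.rint(rng.gamma(spec.shape, spec.scale, size=2 * m)).astype(np.int64)
        ok = draws[(draws >= spec.min) & (draws <= spec.max)]
        take = min(len(ok), n - have)
        out[have : have + take] = ok[:take]
        have += take
    return out


def draw_length(spec: GammaLengthSpec, rng: np.random.Generator) -> int:
    return int(draw_lengths(spec, 1, rng)[0])


def draw_accuracies(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n accuracies from Normal(mean, sd) truncated to (0, 1]."""
    if not 0.0 < mean <= 1.0:
        raise ValueError("accuracy mean must be in (0, 1]")
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    have = 0
    while have < n:
        m = max(n - have, 16)
        draws = rng.normal(mean, sd, size=2 * m)
        ok = draws[(draws > 0.0) & (draws <= 1.0)]
        take = min(len(ok), n - have)
        out[have : have + take] = ok[:take]
        have += take
    return out


def draw_accuracy(mean: float, sd: float, rng: np.random.Generator) -> float:
    return float(draw_accuracies(mean, sd, 1, rng)[0])


@dataclass(frozen=True)
class ParetoStartSpec:
    """Start-offset model: atom at 0 plus a bounded Pareto tail.

    ``scale`` is a fraction of the template length; defaults are calibration
    choices, not measured values.
    """

    alpha: float = 1.0
    scale: float = 0.05
    p5prime: float = 0.3

    def __post_init__(self):
        if self.alpha <= 0 or self.scale <= 0:
            raise ValueError("alpha and scale must be > 0")
        if not 0.0 <= self.p5prime <= 1.0:
            raise ValueError("p5prime must be in [0, 1]")


def draw_start_offsets(
    spec: ParetoStartSpec, template_len: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n 0-based start offsets in [0, template_len - 1].

    With probability p5prime the offset is exactly 0; otherwise a translated
    Pareto draw scale*(U^(-1/alpha) - 1) of the template length.  Tail draws
    at or beyond the 3' end are redrawn (clipping them would pile an atom on
    the last offset and break the non-increasing density).
    """
    if template_len < 1:
        raise ValueError("template_len must be >= 1")
    atom = rng.random(n) < spec.p5prime
    frac = np.empty(n)
    todo = np.arange(n)
    while len(todo):
        u = rng.random(len(todo))
        draw = spec.scale * (u ** (-1.0 / spec.alpha) - 1.0)
        ok = draw < 1.0
        frac[todo[ok]] = draw[ok]
        todo = todo[~ok]
    off = np.minimum(np.floor(template_len * frac), template_len - 1).astype(np.int64)
    off[atom] = 0
    return off


def draw_start_offset(
    spec: ParetoStartSpec, template_len: int, rng: np.random.Generator
) -> int:
    return int(draw_start_offsets(spec, template_len, 1, rng)[0])
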