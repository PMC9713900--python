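"""Single-pass whole-genome simulation.

Reads are drawn until the emitted base count reaches depth x genome length:
chromosome with probability proportional to its length, strand uniform,
length from the gamma sampler (truncated to the chromosome), start uniform
over the positions where the realized template span fits.  Minus-strand reads
are sequenced from the reverse complement; coordinates are stored 0-based
half-open on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .errors import (
    OpString,
    dna_to_codes,
    gen_ops_errhmm,
    gen_ops_qshmm,
    gen_ops_random,
    gen_quality_track,
    place_ops,
    quals_to_phred33,
    qualities_for_errhmm,
    site_hp_lengths,
)
from .model import (
    ErrorHMM,
    ModelSet,
    QualityHMM,
    ReadRecord,
    SimConfig,
    constant_quality_model,
    accuracy_to_bin,
)
from .samplers import GammaLengthSpec, draw_accuracy, draw_length

logger = logging.getLogger(__name__)


@dataclass
class GenomeIndex:
    """Ordered reference sequences with cached 2-bit codes and run lengths."""

    sequences: List[Tuple[str, str]]  # (name, ACGT string)
    _codes: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _sites: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty genome")
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names in genome")
        for n, s in self.sequences:
            if len(s) < 1:
                raise ValueError(f"sequence {n} is empty")

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.sequences]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for _, s in self.sequences], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def get(self, name: str) -> str:
        for n, s in self.sequences:
            if n == name:
                return s
        raise KeyError(name)

    def codes(self, name: str) -> np.ndarray:
        if name not in self._codes:
            self._codes[name] = dna_to_codes(self.get(name))
        return self._codes[name]

    def hp_sites(self, name: str) -> np.ndarray:
        """Homopolymer run length of each forward-strand site."""
        if name not in self._sites:
            self._sites[name] = site_hp_lengths(self.codes(name))
        return self._sites[name]


def _constant_q_for_accuracy(accuracy: float) -> int:
    err = 1.0 - accuracy
    qs = np.arange(94)
    return int(np.argmin(np.abs(10.0 ** (-qs / 10.0) - err)))


def _engine_ops(
    cfg: SimConfig,
    models: Optional[ModelSet],
    accuracy: float,
    rng: np.random.Generator,
    read_len: Optional[int] = None,
    max_template: Optional[int] = None,
) -> Tuple[OpString, np.ndarray]:
    """Generate (ops, per-read-position qualities) for one read/pass."""
    if cfg.method == "random":
        ops = gen_ops_random(
            1.0 - accuracy, cfg.ratio_fractions, read_len if read_len is not None else 10**12,
            rng, max_template=max_template,
        )
        q = _constant_q_for_accuracy(accuracy)
        return ops, np.full(ops.read_len, q, dtype=np.int64)

    if models is None:
        raise ValueError(f"method {cfg.method} requires a model set")
    model = models.select_bin(accuracy)

    if cfg.method == "errhmm" and isinstance(model, ErrorHMM):
        ops, states = gen_ops_errhmm(
            model, read_len, rng, max_template=max_template, return_states=True
        )
        return ops, qualities_for_errhmm(ops, model, states)

    # qshmm proper, or the constant-quality surrogate of either kind
    if isinstance(model, ErrorHMM):  # pragma: no cover - defensive
        model = constant_quality_model(accuracy_to_bin(accuracy))
    ratio = cfg.ratio_fractions
    if cfg.method == "errhmm":
        # error ratio is built into the error model; borrow it from the
        # nearest trained bin for the constant-quality fallback
        nearest = models.nearest_trained(accuracy)
        if isinstance(nearest, ErrorHMM):
            ratio = nearest.implied_error_ratio() / 100.0
    if read_len is not None:
        track = gen_quality_track(model, read_len, rng)
        ops = gen_ops_qshmm(track, ratio, rng, max_template=max_template)
        return ops, track[: ops.read_len]
    # template-budget generation (multi-pass): extend the track until the
    # window is consumed
    assert max_template is not None
    n = int(max_template * 1.2) + 32
    while True:
        track = gen_quality_track(model, n, rng)
        ops = gen_ops_qshmm(track, ratio, rng, max_template=max_template)
        if ops.template_span >= max_template or ops.read_len < len(track):
            return ops, track[: ops.read_len]
        n = int(n * 1.5) + 32


def simulate_wgs(
    genome: GenomeIndex,
    cfg: SimConfig,
    models: Optional[ModelSet] = None,
    max_reads: Optional[int] = None,
) -> Iterator[ReadRecord]:
    """Stream reads until total emitted bases >= depth x genome length.

    Each read gets its own generator seeded by (cfg.seed, ordinal), so output
    is reproducible and independent of chunking.
    """
    if cfg.strategy != "wgs":
        raise ValueError("simulate_wgs requires cfg.strategy == 'wgs'")
    if cfg.depth <= 0:
        raise ValueError("depth must be > 0")
    lengths = genome.lengths
    probs = lengths / lengths.sum()
    target = cfg.depth * genome.total_length
    lspec = GammaLengthSpec(cfg.length_mean, cfg.length_sd, cfg.length_min, cfg.length_max)
    emitted = 0
    ordinal = 0
    per_chrom = [0] * len(lengths)
    while emitted < target:
        if max_reads is not None and ordinal >= max_reads:
            break
        rng = np.random.default_rng((cfg.seed, ordinal))
        ci = int(rng.choice(len(lengths), p=probs))
        name = genome.names[ci]
        chrom_len = int(lengths[ci])
        strand = "+" if rng.random() < 0.5 else "-"
        read_len = min(draw_length(lspec, rng), chrom_len)
        accuracy = draw_accuracy(cfg.accuracy_mean, cfg.accuracy_sd, rng)
        ops, quals = _engine_ops(
            cfg, models, accuracy, rng, read_len=read_len, max_template=chrom_len
        )
        span = ops.template_span
        start_seq = int(rng.integers(0, chrom_len - span + 1))
        codes = genome.codes(name)
        sites = genome.hp_sites(name)
        if strand == "-":
            template = 3 - codes[::-1]
            site_lengths = sites[::-1]
        else:
            template = codes
            site_lengths = sites
        seq, ops = place_ops(
            template, start_seq, ops, cfg.hp_del_bias, rng, site_lengths=site_lengths
        )
        if strand == "-":
            t_start = chrom_len - start_seq - span
        else:
            t_start = start_seq
        per_chrom[ci] += 1
        rec = ReadRecord(
            name=f"S{ci + 1}_{per_chrom[ci]}",
            sequence=seq,
            qualities=quals_to_phred33(quals),
            template_id=name,
            template_start=t_start,
            template_end=t_start + span,
            strand=strand,
            ops=ops,
        )
        emitted += len(seq)
        ordinal += 1
        yield rec
    logger.info("simulate_wgs: %d reads, %d bases (target %.0f)", ordinal, emitted, target)


def sequenced_template(genome: GenomeIndex, rec: ReadRecord) -> str:
    """Template string the read was sequenced from (strand applied)."""
    from .errors import codes_to_dna

    codes = genome.codes(rec.template_id)[rec.template_start : rec.template_end]
    if rec.strand == "-":
        codes = 3 - codes[::-1]
    return codes_to_dna(codes)


def check_read_against_genome(rec: ReadRecord, genome: GenomeIndex) -> None:
    """Assert the ground-truth invariants of one read.

    M positions must equal the template base, S positions must differ, and
    the op counts must match the sequence length and coordinate span.
    """
    from .errors import OP_D, OP_I, OP_M, OP_S, dna_to_codes

    ops = rec.ops
    assert ops.read_len == len(rec.sequence)
    assert ops.template_span == rec.template_end - rec.template_start
    template = dna_to_codes(sequenced_template(genome, rec))
    read = dna_to_codes(rec.sequence)
    codes = ops.codes
    tpos = np.cumsum(codes != OP_I) - 1
    rpos = np.cumsum(codes != OP_D) - 1
    mmask = codes == OP_M
    assert np.array_equal(read[rpos[mmask]], template[tpos[mmask]])
    smask = codes == OP_S
    assert not np.any(read[rpos[smask]] == template[tpos[smask]])
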