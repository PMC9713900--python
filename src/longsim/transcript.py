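"""Transcriptome-sequencing (TS) simulation from an expression table.

Each template transcript yields an exact, user-specified number of reads on
the sense strand and on the antisense (reverse-complement) strand.  A read's
start offset from the sequenced strand's 5' end follows the Pareto-with-atom
model, its target length the gamma sampler; reaching the template's 3' end
truncates the read.  Multi-pass TS (Iso-seq style) reuses the multipass
machinery with a gamma-drawn window per molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .errors import place_ops, quals_to_phred33, site_hp_lengths, dna_to_codes
from .model import ModelSet, ReadRecord, SimConfig
from .multipass import Molecule
from .samplers import (
    GammaLengthSpec,
    ParetoStartSpec,
    draw_accuracy,
    draw_length,
    draw_start_offset,
)
from .wgs import _engine_ops

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptTemplate:
    """One transcript with its sense/antisense expression counts."""

    id: str
    n_sense: int
    n_antisense: int
    sequence: str

    def __post_init__(self):
        if self.n_sense < 0 or self.n_antisense < 0:
            raise ValueError(f"{self.id}: negative expression count")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")


class TranscriptTableError(ValueError):
    pass


def read_transcript_table(path) -> List[TranscriptTemplate]:
    """Parse the one-line-one-transcript tab-delimited expression table.

    Columns: transcript ID, expression count (sense), expression count
    (antisense), nucleotide sequence.
    """
    templates: List[TranscriptTemplate] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TranscriptTableError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            tid, sense_s, anti_s, seq = fields
            try:
                n_sense, n_anti = int(sense_s), int(anti_s)
            except ValueError:
                raise TranscriptTableError(
                    f"{path}:{lineno}: expression counts must be integers"
                ) from None
            if tid in seen:
                raise TranscriptTableError(f"{path}:{lineno}: duplicate transcript id {tid!r}")
            seen.add(tid)
            templates.append(TranscriptTemplate(tid, n_sense, n_anti, seq))
    if not templates:
        logger.warning("transcript table %s is empty", path)
    return templates


def _ts_specs(cfg: SimConfig) -> Tuple[GammaLengthSpec, ParetoStartSpec]:
    lspec = GammaLengthSpec(cfg.length_mean, cfg.length_sd, cfg.length_min, cfg.length_max)
    sspec = ParetoStartSpec(cfg.start_alpha, cfg.start_scale, cfg.start_p5)
    return lspec, sspec


def simulate_ts(
    templates: List[TranscriptTemplate],
    cfg: SimConfig,
    models: Optional[ModelSet] = None,
) -> Iterator[ReadRecord]:
    """Stream exactly the tabulated number of reads per template and strand.

    Coordinates in the emitted records are on the template transcript
    (forward frame); antisense reads carry strand '-'.  Templates shorter
    than the length minimum simply yield reads spanning the whole template.
    """
    if cfg.strategy != "trans":
        raise ValueError("simulate_ts requires cfg.strategy == 'trans'")
    lspec, sspec = _ts_specs(cfg)
    ordinal = 0
    for tpl in templates:
        tlen = len(tpl.sequence)
        codes_fwd = dna_to_codes(tpl.sequence)
        sites_fwd = site_hp_lengths(codes_fwd)
        for strand, count in (("+", tpl.n_sense), ("-", tpl.n_antisense)):
            if strand == "-":
                template = 3 - codes_fwd[::-1]
                site_lengths = sites_fwd[::-1]
            else:
                template = codes_fwd
                site_lengths = sites_fwd
            for i in range(count):
                rng = np.random.default_rng((cfg.seed, ordinal))
                offset = draw_start_offset(sspec, tlen, rng)
                target_len = draw_length(lspec, rng)
                avail = tlen - offset
                accuracy = draw_accuracy(cfg.accuracy_mean, cfg.accuracy_sd, rng)
                ops, quals = _engine_ops(
                    cfg, models, accuracy, rng, read_len=target_len, max_template=avail
                )
                span = ops.template_span
                seq, ops = place_ops(
                    template, offset, ops, cfg.hp_del_bias, rng, site_lengths=site_lengths
                )
                if strand == "-":
                    t_start = tlen - offset - span
                else:
                    t_start = offset
                yield ReadRecord(
                    name=f"{tpl.id}_{strand}_{i + 1}",
                    sequence=seq,
                    qualities=quals_to_phred33(quals),
                    template_id=tpl.id,
                    template_start=t_start,
                    template_end=t_start + span,
                    strand=strand,
                    ops=ops,
                )
                ordinal += 1


def simulate_ts_multipass(
    templates: List[TranscriptTemplate],
    cfg: SimConfig,
    models: Optional[ModelSet] = None,
) -> Iterator[Molecule]:
    """Iso-seq style multi-pass TS: one molecule per tabulated read.

    The molecule window is placed with the TS start model and a gamma-drawn
    length (constant across its passes, truncated at the 3' end); passes
    alternate strands as in whole-genome multi-pass simulation.
    """
    if cfg.strategy != "trans":
        raise ValueError("simulate_ts_multipass requires cfg.strategy == 'trans'")
    lspec, sspec = _ts_specs(cfg)
    zmw = 0
    for tpl in templates:
        tlen = len(tpl.sequence)
        codes_fwd = dna_to_codes(tpl.sequence)
        sites_fwd = site_hp_lengths(codes_fwd)
        for mol_strand, count in (("+", tpl.n_sense), ("-", tpl.n_antisense)):
            for _ in range(count):
                rng = np.random.default_rng((cfg.seed, zmw))
                offset = draw_start_offset(sspec, tlen, rng)
                window_len = min(draw_length(lspec, rng), tlen - offset)
                # forward-frame window coordinates
                if mol_strand == "-":
                    start_fwd = tlen - offset - window_len
                else:
                    start_fwd = offset
                subreads: List[ReadRecord] = []
                for p in range(1, cfg.pass_num + 1):
                    forward_pass = p % 2 == 1
                    strand = (
                        mol_strand
                        if forward_pass
                        else ("-" if mol_strand == "+" else "+")
                    )
                    if strand == "-":
                        template = 3 - codes_fwd[::-1]
                        site_lengths = sites_fwd[::-1]
                        start_seq = tlen - start_fwd - window_len
                    else:
                        template = codes_fwd
                        site_lengths = sites_fwd
                        start_seq = start_fwd
                    accuracy = draw_accuracy(cfg.accuracy_mean, cfg.accuracy_sd, rng)
                    ops, quals = _engine_ops(
                        cfg, models, accuracy, rng, read_len=None, max_template=window_len
                    )
                    seq, ops = place_ops(
                        template, start_seq, ops, cfg.hp_del_bias, rng,
                        site_lengths=site_lengths,
                    )
                    subreads.append(
                        ReadRecord(
                            name=f"zmw{zmw}_pass{p}",
                            sequence=seq,
                            qualities=quals_to_phred33(quals),
                            template_id=tpl.id,
                            template_start=start_fwd,
                            template_end=start_fwd + window_len,
                            strand=strand,
                            ops=ops,
                            pass_index=p,
                        )
                    )
                yield Molecule(
                    zmw=zmw,
                    template_id=tpl.id,
                    template_start=start_fwd,
                    template_end=start_fwd + window_len,
                    strand=mol_strand,
                    subreads=subreads,
                )
                zmw += 1
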