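"""Multi-pass sequencing of template molecules (HiFi precursor subreads).

One molecule is a constant-length template window; the polymerase traverses
it ``pass_num`` times, alternating strands (pass 1 on the molecule's strand,
pass 2 on its reverse complement, ...).  Every pass covers the full window
and receives independent errors, so consensus callers can be benchmarked on
the emitted subreads.  ``naive_consensus`` is a desk-scale plurality-vote
consensus that exploits the ground-truth alignments: its error rate drops
steeply with the number of passes, mirroring the real CLR -> HiFi regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

import edlib
import numpy as np

from .errors import OP_D, OP_I, OP_M, OP_S, codes_to_dna, dna_to_codes, place_ops, quals_to_phred33
from .model import ModelSet, ReadRecord, SimConfig
from .samplers import draw_accuracy
from .wgs import GenomeIndex, _engine_ops

logger = logging.getLogger(__name__)


@dataclass
class Molecule:
    """One template window plus its subread passes."""

    zmw: int
    template_id: str
    template_start: int  # forward-strand, 0-based
    template_end: int
    strand: str  # strand of pass 1
    subreads: List[ReadRecord]


def _simulate_molecule(
    genome: GenomeIndex,
    cfg: SimConfig,
    models: Optional[ModelSet],
    zmw: int,
    rng: np.random.Generator,
) -> Molecule:
    lengths = genome.lengths
    probs = lengths / lengths.sum()
    ci = int(rng.choice(len(lengths), p=probs))
    name = genome.names[ci]
    chrom_len = int(lengths[ci])
    window_len = min(int(round(cfg.length_mean)), chrom_len)
    mol_strand = "+" if rng.random() < 0.5 else "-"
    start_fwd = int(rng.integers(0, chrom_len - window_len + 1))
    codes = genome.codes(name)
    sites = genome.hp_sites(name)
    subreads: List[ReadRecord] = []
    for p in range(1, cfg.pass_num + 1):
        forward_pass = p % 2 == 1
        strand = mol_strand if forward_pass else ("-" if mol_strand == "+" else "+")
        if strand == "-":
            template = 3 - codes[::-1]
            site_lengths = sites[::-1]
            start_seq = chrom_len - start_fwd - window_len
        else:
            template = codes
            site_lengths = sites
            start_seq = start_fwd
        accuracy = draw_accuracy(cfg.accuracy_mean, cfg.accuracy_sd, rng)
        ops, quals = _engine_ops(
            cfg, models, accuracy, rng, read_len=None, max_template=window_len
        )
        # the pass must cover the window exactly
        if ops.template_span != window_len:  # pragma: no cover - defensive
            raise RuntimeError("pass did not consume its template window")
        seq, ops = place_ops(
            template, start_seq, ops, cfg.hp_del_bias, rng, site_lengths=site_lengths
        )
        subreads.append(
            ReadRecord(
                name=f"zmw{zmw}_pass{p}",
                sequence=seq,
                qualities=quals_to_phred33(quals),
                template_id=name,
                template_start=start_fwd,
                template_end=start_fwd + window_len,
                strand=strand,
                ops=ops,
                pass_index=p,
            )
        )
    return Molecule(
        zmw=zmw,
        template_id=name,
        template_start=start_fwd,
        template_end=start_fwd + window_len,
        strand=mol_strand,
        subreads=subreads,
    )


def simulate_multipass(
    genome: GenomeIndex,
    cfg: SimConfig,
    models: Optional[ModelSet] = None,
    n_molecules: Optional[int] = None,
) -> Iterator[Molecule]:
    """Stream molecules until depth is reached (or ``n_molecules`` emitted).

    Depth counts all subread bases.  Window length is the constant
    ``cfg.length_mean``; each of the ``cfg.pass_num`` passes draws its own
    accuracy and errors.
    """
    if cfg.strategy != "wgs":
        raise ValueError("simulate_multipass requires cfg.strategy == 'wgs'")
    target = cfg.depth * genome.total_length
    emitted = 0
    zmw = 0
    while True:
        if n_molecules is not None:
            if zmw >= n_molecules:
                break
        elif emitted >= target:
            break
        rng = np.random.default_rng((cfg.seed, zmw))
        mol = _simulate_molecule(genome, cfg, models, zmw, rng)
        emitted += sum(len(r.sequence) for r in mol.subreads)
        zmw += 1
        yield mol
    logger.info("simulate_multipass: %d molecules, %d subread bases", zmw, emitted)


def _forward_frame(rec: ReadRecord, mol_strand: str) -> Tuple[np.ndarray, np.ndarray]:
    """(ops codes, read base codes) of a pass in the molecule-forward frame."""
    codes = rec.ops.codes
    bases = dna_to_codes(rec.sequence)
    if rec.strand != mol_strand:
        codes = codes[::-1]
        bases = 3 - bases[::-1]
    return codes, bases


def naive_consensus(
    molecule: Molecule, genome: GenomeIndex
) -> Tuple[str, float]:
    """Plurality-vote consensus of a molecule's subreads.

    Per template position the votes are the four bases plus "absent"
    (deletion); insertion columns are emitted when present in more than half
    of the passes.  Returns (consensus sequence, edit distance to the
    template window divided by the window length).
    """
    if not molecule.subreads:
        raise ValueError("molecule has no subreads")
    win_codes = genome.codes(molecule.template_id)[
        molecule.template_start : molecule.template_end
    ]
    if molecule.strand == "-":
        win_codes = 3 - win_codes[::-1]
    span = len(win_codes)
    n_pass = len(molecule.subreads)
    votes = np.zeros((span, 5), dtype=np.int64)  # A C G T absent
    ins_votes: dict = {}  # (gap index, slot) -> np.ndarray(4)
    for rec in molecule.subreads:
        codes, bases = _forward_frame(rec, molecule.strand)
        tcons = codes != OP_I
        tpos = np.cumsum(tcons) - 1
        rpos = np.cumsum(codes != OP_D) - 1
        for op in (OP_M, OP_S):
            mask = codes == op
            np.add.at(votes, (tpos[mask], bases[rpos[mask]]), 1)
        dmask = codes == OP_D
        np.add.at(votes, (tpos[dmask], np.full(int(dmask.sum()), 4)), 1)
        imask = np.flatnonzero(codes == OP_I)
        if len(imask):
            anchors = tpos[imask]  # insertion sits after this template index
            slot = np.arange(len(imask))
            run_start = np.flatnonzero(
                np.diff(imask, prepend=imask[0] - 2) != 1
            )
            slot = slot - np.repeat(slot[run_start], np.diff(np.append(run_start, len(imask))))
            for a, s, b in zip(anchors, slot, bases[rpos[imask]]):
                key = (int(a), int(s))
                if key not in ins_votes:
                    ins_votes[key] = np.zeros(4, dtype=np.int64)
                ins_votes[key][b] += 1
    out: List[int] = []
    for t in range(span):
        if t == 0:
            for s in range(n_pass):
                key = (-1, s)
                if key in ins_votes and ins_votes[key].sum() * 2 > n_pass:
                    out.append(int(np.argmax(ins_votes[key])))
        winner = int(np.argmax(votes[t]))
        if winner != 4:
            out.append(winner)
        for s in range(n_pass):
            key = (t, s)
            if key in ins_votes and ins_votes[key].sum() * 2 > n_pass:
                out.append(int(np.argmax(ins_votes[key])))
    consensus = codes_to_dna(np.asarray(out, dtype=np.uint8))
    template = codes_to_dna(win_codes)
    dist = edlib.align(consensus, template, task="distance")["editDistance"]
    return consensus, dist / span
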