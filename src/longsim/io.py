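"""File formats and synthetic fixture generators.

FASTA/FASTQ go through Biopython, SAM through pysam.  MAF here is the
simulator's ground-truth dialect: per read an ``a`` block with a reference
``s`` line (forward strand, 0-based start, span, srcSize) and a read ``s``
line (start 0, read length, read strand, srcSize = read length), gapped per
the edit script.  The fixture generators build deterministic synthetic
genomes/transcriptomes — including genomes with an exactly balanced census
of homopolymer run lengths for deletion-bias experiments.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    OP_D,
    OP_I,
    OP_M,
    OpString,
    codes_to_dna,
    dna_to_codes,
    phred33_to_quals,
)
from .model import ReadRecord
from .multipass import Molecule
from .wgs import GenomeIndex

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path, non_acgt_seed: int = 0) -> GenomeIndex:
    """Load a FASTA into a GenomeIndex.

    Error engines are defined over ACGT, so any other character (N, IUPAC
    codes, ...) is replaced by a random base drawn with the given seed; the
    replacement count is logged.
    """
    rng = np.random.default_rng(non_acgt_seed)
    seqs: List[Tuple[str, str]] = []
    n_replaced = 0
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ValueError(f"malformed or missing FASTA {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    for rec in records:
        raw = np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8)
        bad = ~np.isin(raw, np.frombuffer(b"ACGT", dtype=np.uint8))
        if bad.any():
            n_replaced += int(bad.sum())
            raw = raw.copy()
            raw[bad] = np.frombuffer(b"ACGT", dtype=np.uint8)[
                rng.integers(0, 4, int(bad.sum()))
            ]
        seqs.append((rec.id, raw.tobytes().decode()))
    if n_replaced:
        logger.info("read_fasta: replaced %d non-ACGT bases in %s", n_replaced, path)
    return GenomeIndex(sequences=seqs)


def write_fasta(sequences: Sequence[Tuple[str, str]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for rec in reads:
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.qualities}\n")


def read_fastq(path) -> List[Tuple[str, str, str]]:
    """(name, sequence, phred+33 qualities) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), quals))
    return out


# ---------------------------------------------------------------------------
# MAF ground truth
# ---------------------------------------------------------------------------


def _gapped_pair(rec: ReadRecord, template_seq: str) -> Tuple[str, str]:
    """Gapped (reference, read) texts in forward-template frame."""
    t_codes = dna_to_codes(template_seq)[rec.template_start : rec.template_end]
    if rec.strand == "-":
        t_codes = 3 - t_codes[::-1]
    r_codes = dna_to_codes(rec.sequence)
    codes = rec.ops.codes
    gap = 4
    tpos = np.cumsum(codes != OP_I) - 1
    rpos = np.cumsum(codes != OP_D) - 1
    ref_col = np.where(codes == OP_I, gap, t_codes[tpos])
    read_col = np.where(codes == OP_D, gap, r_codes[rpos])
    alpha = np.frombuffer(b"ACGT-", dtype=np.uint8)
    ref_txt = alpha[ref_col].tobytes().decode()
    read_txt = alpha[read_col].tobytes().decode()
    if rec.strand == "-":
        # present the reference line on the forward strand
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "-": "-"}
        ref_txt = "".join(comp[c] for c in reversed(ref_txt))
        read_txt = "".join(comp[c] for c in reversed(read_txt))
    return ref_txt, read_txt


def write_maf(
    reads: Iterable[ReadRecord], templates: Dict[str, str], path
) -> None:
    with open(path, "w", encoding="ascii") as fh:
        fh.write("##maf version=1\n")
        for rec in reads:
            template_seq = templates[rec.template_id]
            ref_txt, read_txt = _gapped_pair(rec, template_seq)
            span = rec.template_end - rec.template_start
            rl = len(rec.sequence)
            fh.write("a\n")
            fh.write(
                f"s {rec.template_id} {rec.template_start} {span} + "
                f"{len(template_seq)} {ref_txt}\n"
            )
            fh.write(f"s {rec.name} 0 {rl} {rec.strand} {rl} {read_txt}\n")
            fh.write("\n")


def read_maf(path) -> List[dict]:
    """Parse the ground-truth MAF dialect back into alignment dicts."""
    out = []
    block: List[List[str]] = []
    with open(path, encoding="ascii") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("s "):
                block.append(line.split())
            elif not line.strip() and block:
                out.append(_maf_block(block))
                block = []
        if block:
            out.append(_maf_block(block))
    return out


def _maf_block(block: List[List[str]]) -> dict:
    if len(block) != 2:
        raise ValueError(f"MAF block with {len(block)} s-lines")
    ref, read = block
    return {
        "ref_name": ref[1],
        "ref_start": int(ref[2]),
        "ref_span": int(ref[3]),
        "ref_srcsize": int(ref[5]),
        "ref_text": ref[6],
        "read_name": read[1],
        "read_len": int(read[3]),
        "strand": read[4],
        "read_text": read[6],
    }


# ---------------------------------------------------------------------------
# ccs-style subread SAM
# ---------------------------------------------------------------------------


def write_sam_subreads(
    molecules: Iterable[Molecule], path, movie: str = "m00001_000000_s1"
) -> None:
    """Unaligned subread SAM, one record per pass.

    Query names follow the PacBio subread convention
    ``movie/zmw/qs_qe`` with query start/end cumulative over the molecule's
    passes; tags zm/qs/qe/np and an @RG with PL:PACBIO, DS:READTYPE=SUBREAD.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "RG": [
            {
                "ID": "rg1",
                "PL": "PACBIO",
                "PU": movie,
                "DS": "READTYPE=SUBREAD",
            }
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for mol in molecules:
            qs = 0
            for rec in mol.subreads:
                qe = qs + len(rec.sequence)
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = f"{movie}/{mol.zmw}/{qs}_{qe}"
                seg.query_sequence = rec.sequence
                seg.flag = 4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 255
                seg.query_qualities = pysam.qualitystring_to_array(rec.qualities)
                seg.set_tags(
                    [
                        ("zm", mol.zmw, "i"),
                        ("qs", qs, "i"),
                        ("qe", qe, "i"),
                        ("np", 1, "i"),
                        ("RG", "rg1", "Z"),
                    ]
                )
                out.write(seg)
                qs = qe


def read_sam_subreads(path) -> List["pysam.AlignedSegment"]:
    """Read back an unaligned subread SAM (no @SQ lines)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return list(fh.fetch(until_eof=True))


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def make_synthetic_genome(
    length: Optional[int] = None,
    gc_fraction: float = 0.5,
    homopolymer_spec: Optional[Dict[int, int]] = None,
    seed: int = 0,
    name: str = "chr1",
    path=None,
) -> Tuple[str, str]:
    """Deterministic synthetic chromosome.

    With ``homopolymer_spec`` = {run length: number of runs}, the sequence is
    exactly the concatenation of those runs in shuffled order, each run's
    base chosen to differ from its neighbor, so the homopolymer site census
    matches the spec exactly.  Otherwise i.i.d. bases at the given GC.
    """
    rng = np.random.default_rng(seed)
    if homopolymer_spec is not None:
        runs: List[int] = []
        for L, count in sorted(homopolymer_spec.items()):
            if L < 1 or count < 0:
                raise ValueError("bad homopolymer_spec")
            runs.extend([L] * count)
        order = rng.permutation(len(runs))
        pieces = []
        prev = -1
        for idx in order:
            L = runs[idx]
            choices = [b for b in range(4) if b != prev]
            b = int(choices[rng.integers(0, len(choices))])
            pieces.append(np.full(L, b, dtype=np.uint8))
            prev = b
        seq = codes_to_dna(np.concatenate(pieces))
    else:
        if length is None or length < 1:
            raise ValueError("need a positive length without a homopolymer_spec")
        p = np.array(
            [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
        )
        seq = codes_to_dna(rng.choice(4, size=length, p=p).astype(np.uint8))
    if path is not None:
        write_fasta([(name, seq)], path)
    return name, seq


def make_synthetic_transcriptome(
    n_templates: int,
    length_spec: Tuple[float, float] = (2000.0, 500.0),
    expression_spec: Tuple[int, int] = (7, 3),
    seed: int = 0,
    min_length: int = 200,
    path=None,
) -> List[Tuple[str, int, int, str]]:
    """Deterministic synthetic expression table.

    Lengths are gamma(mean, sd) via moment matching, floored at
    ``min_length``; every template gets the same (sense, antisense) counts.
    Writes the tab-delimited one-line-one-transcript table when ``path`` is
    given.
    """
    from .samplers import GammaLengthSpec, draw_lengths

    rng = np.random.default_rng(seed)
    mean, sd = length_spec
    spec = GammaLengthSpec(mean, sd, min=min_length, max=int(mean * 20) + min_length)
    lengths = draw_lengths(spec, n_templates, rng)
    n_sense, n_anti = expression_spec
    rows = []
    for i, L in enumerate(lengths, start=1):
        seq = codes_to_dna(rng.integers(0, 4, int(L)).astype(np.uint8))
        rows.append((f"T{i}", n_sense, n_anti, seq))
    if path is not None:
        with open(path, "w", encoding="ascii") as fh:
            for tid, ns, na, seq in rows:
                fh.write(f"{tid}\t{ns}\t{na}\t{seq}\n")
    return rows
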