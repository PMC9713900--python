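# longsim

A simulator for PacBio and Oxford Nanopore (ONT) long reads. It generates
whole-genome (WGS), multi-pass (HiFi-precursor subread) and transcriptome
(TS) sequencing reads together with their ground-truth alignments, trains
the underlying generative error models from alignments, and computes the
statistics used to compare simulated reads with real ones.

Developing tools for long reads — assemblers, variant callers, isoform
callers — requires reads whose errors are *known*. Real reads never come
with their true edit script; a simulator that emits each read alongside its
exact alignment to the template does. The hard part is realism: long-read
errors are bursty (local accuracy varies strongly within a read), deletions
concentrate in homopolymers on ONT, HiFi accuracy emerges from consensus
over many noisy passes, and TS reads start away from the 5' end and truncate
at the 3' end.

## The models

**Error generation.** A read's ground-truth edit script is a sequence over
{M, S, I, D} (match, substitution, insertion, deletion). Three engines
produce it:

* *random* — i.i.d. ops: each op is an error with probability *e* and typed
  by a user ratio S:I:D.
* *qshmm* (quality-score model) — a hidden Markov model emits a Phred
  quality track Q₁…Q_L; position *i* errs with probability 10^(−Qᵢ/10),
  typed by the user ratio. Nonuniformity of quality scores induces
  nonuniformity of errors.
* *errhmm* (error model) — an HMM emits M/S/I/D directly from categorical
  per-state distributions; the error ratio is a property of the model and
  cannot be overridden.

Models are trained per integer read-accuracy percent: bin *b* covers
accuracies [b−0.5, b+0.5)%. Accuracies without a trained model use constant
quality scores matching the requested accuracy.

**Homopolymer deletion bias.** With `--hp-del-bias B`, the per-site deletion
rate rises linearly from 1× at 1-mers to B× at 10-mers (saturating beyond),
by repositioning each read's deletions with inclusion probability
proportional to the site weight — the per-read deletion count is conserved.

**Multi-pass sequencing.** A molecule is a constant-length template window
read `--pass-num` times, alternating strands, each pass with independent
errors; subreads are emitted as PacBio-convention unaligned SAM
(`movie/zmw/qs_qe`, tags zm/qs/qe/np) for downstream consensus callers. A
built-in plurality-vote consensus provides a desk-scale check that consensus
error falls steeply with pass count.

**Transcriptome model.** Per transcript, an exact user-specified number of
sense and antisense reads: start offset from the sequenced strand's 5' end
follows a translated Pareto with an explicit probability atom at offset 0,
read length is gamma distributed (shape = mean²/sd², scale = sd²/mean), and
reaching the 3' end truncates the read.

**Training (FIC-HMM).** Alignments are encoded column-wise as 0/1/2/3
(match/sub/ins/del); INDELs inside reference homopolymer runs are first
re-placed uniformly at random (removing aligner placement habits without
changing either sequence). Baum–Welch EM with state shrinkage fits each
accuracy bin, and the number of hidden states is selected by maximizing a
factorized information criterion, FIC = log L − Σₖ (Dₖ/2)·ln N̄ₖ, over
candidate state counts × 5 random restarts.

## Worked example

```sh
longsim fixtures --kind genome --out ref.fa --length 50000 --seed 1
longsim simulate --strategy wgs --method random --genome ref.fa \
    --depth 2 --length-mean 3600 --length-sd 1600 --length-min 100 \
    --length-max 20000 --accuracy-mean 0.85 --error-ratio 6:55:39 \
    --seed 42 --prefix clr
longsim eval --maf clr_0001.maf --ref ref.fa --out-prefix stats
```

The simulator reports

```
INFO longsim.wgs: simulate_wgs: 25 reads, 100876 bases (target 100000)
```

— 25 reads totalling ~2× coverage of the 50 kb reference, written as
`clr_0001.fastq` (reads + qualities), `clr_0001.maf` (ground-truth gapped
alignments) and `clr_0001.ref` (the reference). Summarizing the ground
truth:

```
reads: 25   mean accuracy: 0.8544
insertion events: 7992   deletion events: 5905
```

Mean read accuracy sits at the requested 85%, and insertions outnumber
deletions roughly 55:39 — the requested PacBio RS II error ratio. The
`eval` command also writes per-window accuracy histograms (800-bp windows;
the error-nonuniformity statistic) and, with `--ref`, per-homopolymer-length
error rates.

Training closes the loop: `longsim train --maf clr_0001.maf --kind errhmm
--out model.txt` fits per-accuracy-bin HMMs that `longsim simulate --method
errhmm --errhmm model.txt` consumes.

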