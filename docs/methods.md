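# Methods

This note records the models implemented in `longsim`, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data tests
do and do not establish about real sequencing data.

## Edit-script model

A read's ground truth is an *op string* over {M, S, I, D}, stored as codes
0–3 (the same encoding used for training data). Two identities hold for
every script and are asserted throughout the test suite:

* read length = #M + #S + #I (read-consuming ops)
* template span = #M + #S + #D (template-consuming ops)

Read accuracy is #M / (#M+#S+#I+#D). Generation is budgeted either by read
length (single-pass WGS and TS: the op achieving the budget terminates the
script, so a script never ends in dangling deletions) or by template span
(multi-pass: each pass must cover its window exactly).

### Engines

**random.** Ops are i.i.d.: error with probability *e*, typed S:I:D by the
configured ratio; deletions are extra template-consuming ops, so the
realized per-op substitution rate is e·r_S exactly (closed form used as a
test oracle).

**qshmm.** A quality HMM (categorical emissions over Phred 0–93) produces a
track; each emitted op at position *i* independently errs with probability
10^(−Qᵢ/10). A deletion consumes the template but re-queues the read
position — a deleted base has no read position, so S and I consume the
position's quality while D does not. The number of deletions before a
position is consumed is geometric, which the implementation exploits to
vectorize generation. Expected per-op error rate equals the track's mean
10^(−Q/10).

**errhmm.** The HMM emits ops directly; its stationary S:I:D ratio is a
fixed property of the model (the CLI refuses `--error-ratio` with this
engine). FASTQ qualities for errhmm reads are derived per position as
Q = round(−10·log₁₀(1 − P(M | state))), clamped to [0, 93].

### Realization and homopolymer deletion bias

`place_ops` realizes a script on a template window: M copies the base, S
substitutes uniformly over the three alternatives, I inserts a uniform
base. With bias B ≥ 1, a site in a homopolymer of length ℓ gets weight
w(ℓ) = 1 + (B−1)·(min(ℓ,10)−1)/9 — linear from 1 at 1-mers to B at
10-mers, saturating beyond. The script's deletions are re-placed among the
window's template slots by randomized **systematic PPS sampling**, whose
inclusion probabilities are exactly proportional to the weights. Plain
sequential weighted sampling without replacement was tried first and
systematically under-selects heavy sites (measured ~8% deficit at the
10-mer/1-mer fold); systematic sampling removes the bias. The per-read
deletion count is conserved exactly; whether the original tool preserves
the global deletion rate under bias is unobservable from published
material, so per-read conservation was chosen and is asserted.

The homopolymer length of a site is the length of the maximal identical-base
run containing it, computed on the strand actually sequenced (run lengths
are invariant under reverse complement, so forward-strand labels are cached
and reversed).

## Whole-genome simulation

Reads are drawn until emitted bases ≥ depth × genome length (the final read
may overshoot and is emitted). Chromosome ∝ length, strand uniform, length
gamma-drawn (rejection outside [min, max] rather than clamping, which would
pile mass on the bounds) and truncated to the chromosome; the start is drawn
uniformly *after* the realized span is known, so reads are never clipped at
chromosome ends. Templates are linear; no wraparound. Non-ACGT reference
characters are replaced by seeded-random bases at load time (the engines are
defined over ACGT) and the replacement count logged.

Each read uses `numpy.random.default_rng((seed, ordinal))`, so output is
reproducible and independent of chunking or consumption order.

## Multi-pass simulation

Window length is the constant `length_mean` (single-pass WGS uses the gamma
model; multi-pass uses a constant, and TS multi-pass a gamma draw per
molecule). All passes are full passes — the published experiments specify
pass counts directly, so partial first/last passes are not modelled.
Per-pass accuracies are drawn independently (intra-molecule correlation is
unknown). Pass *p* sequences the molecule's strand if *p* is odd, its
reverse complement if even. SAM output is unaligned (FLAG 4) with
PacBio-convention names and zm/qs/qe/np tags; compatibility with external
consensus callers is best-effort and not exercised in tests.

`naive_consensus` is a plurality vote over the ground-truth-aligned passes:
per template position the candidates are the four bases plus "absent";
insertion columns (keyed by anchor site and slot within the run) are taken
when present in more than half of the passes. Ties resolve to the
lowest-indexed base, and "absent" never wins a tie. Its error rate (edit
distance to the window via edlib, divided by window length) drops from
~14% at 1 pass to ~10⁻⁴ at 10 passes at 85% per-pass accuracy — the
CLR-to-HiFi regime — and the monotone decrease over {1, 3, 5, 10} passes is
an acceptance property. This oracle deliberately uses ground truth; it is a
test instrument, not a consensus caller.

## Transcriptome model

Inputs are tab-delimited one-line-one-transcript tables (ID, sense count,
antisense count, sequence); counts are exact read counts, not rates.
Start offsets follow an atom-plus-Pareto construction: with probability
`p5prime` the read starts exactly at the sequenced strand's 5' end;
otherwise offset = floor(L · scale·(U^(−1/α) − 1)). Tail draws beyond the
template are redrawn — clipping them would create a probability atom at the
last position and break the monotone-decreasing offset density. Defaults
α = 1.0, scale = 0.05, p5prime = 0.3 are calibration knobs chosen to
reproduce the qualitative 5'-spike-plus-decay shape of real start-position
distributions, not fitted values. Antisense reads apply the identical model
on the reverse complement. Target lengths are gamma; the realized span is
min(target span, template length − offset), i.e. the 3' end terminates the
read.

## Training

Alignment columns encode to 0/1/2/3; the accuracy of a training alignment is
#M over its columns, and sequences are pooled per integer-percent bin
(round-half-up, bin b = [b−0.5, b+0.5)%).

**Homopolymer rearrangement.** Within each maximal reference run (length
≥ 2), alignment columns whose two characters both belong to {run base, gap}
— including adjacent insertion columns of the run base — are shuffled
uniformly; mismatch columns split the shuffled stretches and stay fixed.
Because every shuffled stretch contains only the run base and gaps, the
implied read and reference sequences are invariant (property-tested), while
the INDEL positions the aligner chose are forgotten.

**EM.** Scaled forward–backward (per-sequence normalization, so 10⁵-symbol
sequences do not underflow) with the inner loop numba-compiled. Plain EM
asserts monotone non-decreasing log-likelihood each iteration (slack 1e-8
relative); convergence at relative LL change ≤ tol (default 1e-6, 1e-5 in
selection runs) or max_iter. K = 1 reduces to pooled symbol frequencies and
the multinomial likelihood, used as an analytic oracle; an independent EM
implementation (hmmlearn) is a cross-check oracle at identical
initialization.

**State-count selection.** The FIC variational scheme is implemented as
factorized-asymptotic-Bayes shrinkage: after each E-step, responsibilities
of state k are discounted by exp(−Dₖ/2N̄ₖ) and renormalized, where
Dₖ = (emission support − 1) + (K − 1) free parameters and N̄ₖ the expected
visit count; states with N̄ₖ < 1 expected visit are pruned. The selected
model maximizes LL − Σₖ(Dₖ/2)·ln N̄ₖ over candidate K × 5 restarts. The
published description fixes neither the exact bound, the prune rule nor the
K range searched; these are this package's choices, validated by synthetic
recovery: the selector returns the generator's state count (1-state and
2-state generators, 50 × 2000-symbol sequences) in ≥ 80% of 20 seeded
replicates with fitted emissions within 0.03 after total-variation state
matching. Bins with fewer than 10⁵ pooled symbols (configurable) are not
trained; simulation falls back to a 1-state constant-quality model whose
single Q has 10^(−Q/10) closest to the bin's error rate. A requested bin
outside the trained range clamps to the nearest trained bin; for an errhmm
fallback the error ratio is borrowed from the nearest trained bin's
stationary ratio.

## Evaluation statistics

* Window accuracy: reads grouped by whole-percent accuracy; ops split into
  disjoint windows of 800 *read* bases (M+S+I; the final partial window is
  dropped). Read-base windows were chosen because the published figures
  segment reads, not alignments; this is a documented interpretation.
* KL divergence Σ P log₂(P/Q) in bits; optional add-ε smoothing
  (ε = 1e-6, renormalized) for empirical histograms — unsmoothed zeros in Q
  under positive P raise an error directing the caller to smoothing.
* Homopolymer profile: per-length error rates with insertions attributed to
  the left-flanking template site (the published convention is unstated).
* INDEL spectra: maximal-run lengths of I and D; for i.i.d. op processes
  run lengths are geometric, used as a test oracle.

## Problem sizes and defaults

Defaults follow the published operating points: WGS gamma mean = sd = 15 kb
(length bounds 100 bp – 1 Mb), accuracy mean 0.85 with sd 0.02 per read,
error ratios 6:55:39 (PacBio RS II), 22:45:33 (Sequel), 39:24:36 (ONT
quality model); TS settings 2.4 kb / 1 kb (ONT) and 3.6 kb / 1.6 kb with 10
passes (Iso-seq). Test and acceptance runs use 10⁵-draw samplers,
~1.2×10⁵-deletion bias experiments on a 110 kb balanced-homopolymer genome,
50-molecule consensus batches and 20-replicate training recoveries — sizes
at which every 3-SE band in the suite is decisive while the whole suite
runs on a single core in minutes.

## What synthetic tests do not show

The generators emulate the *models'* assumptions (i.i.d. or Markov error
processes, exact gamma lengths, exact Pareto starts). Passing tests
demonstrate internal correctness — parameter recovery, distributional
convergence, conservation identities — not that the models capture any
particular real dataset: context-dependent (k-mer) error profiles are
explicitly out of scope, ONT A↔G substitution enrichment is not modelled,
junk/chimera/adapter artifacts are absent, and consensus behaviour is
checked against the built-in vote oracle rather than production consensus
software. Model files shipped by the original tool are not readable; models
are trained from alignments or written in this package's text format.
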