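# motifstream

Model-based motif analysis for ChIP-Seq peak sequences: PSWM motif
scanning against a third-order Markov background, and de novo motif
discovery by collapsed Gibbs sampling with per-sequence inclusion
indicators and a student-t positional prior.

## Who this is for

Regulatory-genomics analysts who have a set of DNA sequences — typically
ChIP-enriched regions around transcription-factor binding peaks — and want
to (a) count incidences of known motifs given TRANSFAC-style weight
matrices, or (b) discover an over-represented motif de novo, exploiting
the fact that read depth and peak geometry carry information about where
binding sites sit.

## The models

**Scan.** A motif of width *w* is a position-specific weight matrix
Θ = (θ₁ … θ_w), each θᵢ a probability vector over A, C, G, T (encoded
1–4). For every window start *a* of every sequence the scanner computes
the log₂ likelihood ratio

    llr(a) = Σᵢ log₂ θᵢ(s_{a+i−1}) − log₂ P(window | background)

where the background is an order-3 Markov chain fitted to the input (each
base conditioned on its three predecessors; sequence starts fall back to
lower-order tables). A position is a *motif incidence* when llr ≥ a
significance threshold (default 6.0, i.e. likelihood ratio 64); a
two-component mixture posterior π·r/(π·r + 1−π) with per-position prior
π = 10⁻³ is reported alongside. Both strands are scanned by default.

Execution follows a concatenate-then-separate contract: all sequences are
scored as one long sequence, in "fragments" (contiguous ranges of window
starts), and results are separated back per sequence afterwards. The
output is bit-for-bit identical for every fragment size, and windows
spanning a join between two sequences are never scored.

**De novo.** The Hybrid-Motif-Sampler-style model: motif columns are
independent multinomials with conjugate Dirichlet(β) priors (β = 0.5 per
base); each sequence *j* carries one candidate start A_j with a
student-t(ν = 4) positional prior centred on the peak (scale L/4), and a
binary indicator Z_j that admits the sequence to motif search only when
the average of its per-position likelihood ratios exceeds 1. Alignments
are drawn by collapsed Gibbs sampling from leave-one-out
Dirichlet-predictive full conditionals; sweeps visit sequences in
descending read depth. The best state by joint log posterior after
burn-in is reported.

**Performance model.** Parallelizing the scan core, which occupies
fraction *f* of runtime, bounds the overall speedup by Amdahl's law,
1/(1−f). The `perf` subcommand tabulates theoretical bounds against
achieved speedups from an external profile.

## Worked example

Simulate a peak dataset with a planted motif, rediscover it, and scan
with the recovered matrix:

```bash
motifstream --seed 5 simulate --n-sequences 40 --length 120 \
    --planting-probability 1.0 \
    --out-fasta demo.fa --out-truth truth.tsv --out-matrix true.transfac
motifstream --seed 5 denovo --fasta demo.fa --width 8 \
    --iterations 150 --burn-in 50 \
    --out-matrix found.transfac --out-sites sites.bed --out-trace trace.tsv
motifstream --seed 5 scan --fasta demo.fa --matrix found.transfac \
    --threshold 2 --out-bed hits.bed --out-counts counts.tsv
```

The de novo run logs

    INFO motifstream: consensus GACTCAGT; 30/40 sequences included

`GACTCAGT` is the planted consensus `TGACTCAG` locked in one column to
the right (column-shifted solutions are near-equivalent local modes; the
scoreboard aligns shift and orientation before scoring). 30 of 40
sequences passed the inclusion rule. Scoring each sequence's best hit
from `hits.bed` against `truth.tsv` with the bundled scoreboard gives
site recall 0.80 at ±1 bp tolerance, and the recovered matrix sits at
median per-column total-variation distance 0.049 from the truth.

The performance model reproduces the published profiling table: for a
dataset whose scan core occupies 90.62 % of runtime,

```bash
$ motifstream perf --profile profile.tsv --out report.tsv
```

reports a theoretical speedup limit of 10.66 (= 1/(1−0.9062)).

## Layout

- `src/motifstream/sequence_io.py` — FASTA, TRANSFAC matrices, BED6 hits
- `src/motifstream/background.py` — order-0..3 Markov background, θ₀
- `src/motifstream/scan.py` — fragment-streamed scan core
- `src/motifstream/denovo.py` — collapsed Gibbs motif sampler
- `src/motifstream/synthetic.py` — peak-dataset generator + scoreboard
- `src/motifstream/perfmodel.py` — Amdahl's-law bounds and reports
- `src/motifstream/cli.py` — `motifstream` scan/denovo/simulate/perf
- `docs/methods.md` — modelling notes, parameter choices, limitations
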