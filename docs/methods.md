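# Methods

This note records the statistical models motifstream implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions used throughout.

## Sequence representation and coordinates

Nucleotides are carried as integer codes A=1, C=2, G=3, T=4 so probability
lookups are array indexing; the complement of code c is 5−c. Positions are
1-based inclusive internally (a window starting at *a* with width *w*
covers *a* … *a*+*w*−1); BED output converts to 0-based half-open. Bases
outside ACGT are replaced by a uniformly random base drawn from the run's
seeded generator and the replacement count is logged: the scan arithmetic
requires codes 1–4, and dropping bases would silently shift every
downstream coordinate. Matrices are read and written in TRANSFAC-style row
layout; written matrices store θ×scale with 10 significant digits so a
write→read round trip recovers θ well within 1/(2·scale).

## Background model

Non-motif sequence is modelled by an order-k Markov chain (k ∈ 0…3,
default 3). Fitting pools transition counts across all input sequences and
applies a per-cell Laplace pseudocount (default 1.0):
P(b|ctx) = (n(ctx,b) + pc) / (n(ctx) + 4·pc). The smoothing scheme is a
package choice; pc > 0 guarantees strictly positive conditionals so
likelihood ratios stay finite. Tables for every lower order are fitted
from the same data; position t of a sequence uses context length
min(k, t−1), i.e. the true left-flanking bases whenever they exist and
lower-order tables only within the first k bases of a sequence. A context
never observed with pc = 0 receives a uniform row so every table is
row-stochastic by construction. By default the background is fitted on the
scanned sequences themselves (`--background-fasta` overrides); note this
slightly inflates the background probability of the motif's own k-mers
when motif instances are dense in the input.

All probability arithmetic downstream is log₂: products over window
positions underflow in linear space.

## Scan statistic and posterior

For PSWM Θ and window start a, llr(a) = Σᵢ log₂ θᵢ(s_{a+i−1}) −
log₂ P(window|background). The per-position match posterior is the
two-component mixture π·r/(π·r + 1−π), r = 2^llr, with prior π = 10⁻³ per
position; it is computed in the log domain and is exactly 0/1 at
llr = ∓∞. A zero θ entry at an observed base yields llr = −∞, never an
exception. Incidence calling thresholds the llr (default 6.0 ≈ ratio 64,
closed bound: llr = threshold is a hit). Thresholding the ratio rather
than the posterior or a p-value is a package decision, as is scanning both
strands by default (`--forward-only` disables); the minus-strand score
evaluates the reverse-complemented window against the same matrix, with
the same forward-window background term.

### Concatenation and fragmentation

Sequences are concatenated and scored as one coordinate space; a validity
mask excludes every window that would span two source sequences, and hits
are mapped back to per-sequence coordinates afterwards. The scan is
processed in fragments — contiguous ranges of window starts (default
65536). The contract, and the property the tests quantify, is that
fragmentation is pure streaming: scores and hit sets are bit-for-bit
identical for every fragment size, and identical to a per-sequence scan.
This holds because every per-start score is assembled from the same
per-position arrays with a fixed reduction order regardless of fragment
boundaries.

## De novo sampler

The product-multinomial model: columns θᵢ carry conjugate Dirichlet(β)
priors with β = (0.5, 0.5, 0.5, 0.5); non-motif positions follow the
Markov background above. Each sequence has one candidate start A_j
(single-site model; multi-site search is out of scope) and an indicator
Z_j. The positional prior over starts is a discretized, range-truncated
student-t on the window midpoint's distance to the peak centre: probs[a] ∝
t_ν((a + (w−1)/2 − c)/σ). Defaults: ν = 4, c = the sequence midpoint,
σ = L/4 — a deliberately broad stand-in for a read-depth profile when no
per-base depth is available; all three are configurable.

Sampling is collapsed Gibbs: sequence j's site is removed from the column
counts, and a new (start, strand) is drawn from
p(a, strand) ∝ prior(a) · Πᵢ θ̃ᵢ(s) / P_bg(window), with θ̃ᵢ(k) =
(cᵢₖ + βₖ)/(n + Σβ) the leave-one-out Dirichlet predictive. Both
orientations of every window are candidates by default (2(L−w+1)
outcomes). The PSWM estimate is the posterior mean (cᵢₖ + βₖ)/(n₁ + Σβ).

The indicator rule: Z_j = 1 iff the average over all starts of the window
likelihood ratio under the current θ̂ exceeds 1 — strictly, so an average
of exactly 1 (e.g. a θ̂ that equals a 0-order background column-wise,
which gives every window ratio exactly 1) excludes the sequence. In
both-strand mode the reverse-complement orientation of θ̂ is also
averaged and the larger value decides, so a motif living on the minus
strand does not eject its sequence. Excluded sequences contribute no
counts and are skipped by the alignment sweep; they are re-tested every
sweep and re-enter when the motif estimate starts matching them.

Two scheduling choices matter and are package decisions:

- **Indicator delay.** Indicator updates begin when burn-in ends. Early in
  a run θ̂ is essentially noise, and the average-ratio rule applied to a
  noise matrix excludes roughly half the sequences at random; measured on
  synthetic data this starves the sampler badly enough that most seeds
  never converge. Holding Z = 1 through burn-in (the first sweeps see
  every sequence) removes that failure mode without touching the rule
  itself.
- **Depth-ordered sweeps.** Each sweep visits sequences in descending read
  depth so high-coverage (high-confidence) sequences shape θ̂ first. This
  is a documented approximation of prioritized sequence scheduling, not a
  reproduction of any particular scheduler.

The run keeps the maximum-joint-log-posterior state seen after burn-in
(Dirichlet-multinomial column marginals + per-included-sequence positional
prior and background terms). Before reporting, a deterministic refinement
replaces each included sequence's sampled start with the mode of its
leave-one-out full conditional: the reported site list then reflects the
chosen state rather than single-draw noise. Every random number in a run
flows from one integer seed; identical seed and inputs give byte-identical
outputs. If all indicators collapse to 0 the best pre-collapse state is
returned with a warning.

Width w is fixed per run; different widths are separate runs. No
phase/column-shift proposal moves are implemented: column-shifted
solutions are near-equivalent posterior modes, and runs may lock into a
±1–2 column shift of the planted pattern. The evaluation utilities align
shift and orientation before scoring for exactly this reason.

## Synthetic peak data

The generator emulates what the de novo model assumes: background bases
from a configurable Markov chain (default: uniform order-0); with
probability 0.9 (default) a motif instance — an independent per-column
draw from the true PSWM, uniform strand — overwrites w bases at a start
drawn from the truncated t prior (ν = 4, scale L/8, centred); per-sequence
depths are log-normal (σ = 0.5) with mean parameter 3.0 for unplanted and
4.0 for planted sequences, giving depth a genuine association with motif
presence so that depth-ordered sweeps have signal to use. The default true
motif is an 8-mer with 0.88 on the consensus base per column (≈1.28
bits/column), consensus TGACTCAG.

What the generator does *not* emulate: read-level artefacts (duplicates,
mapping bias), per-base depth profiles (depth is one number per
sequence), multiple motif occurrences per sequence, motif variants with
indels, and correlated background (repeats, CpG structure). Recovery
results on this generator therefore speak to the sampler's statistical
correctness, not to performance on real peaks.

### Observed recovery behaviour

On the reference recovery setup (200 sequences × 200 bp, w = 8, planting
probability 0.9, 500 iterations), the recovered matrix is reliably close
to the truth (best-run median per-column total variation ≈ 0.05), but the
fraction of planted sequences that end with Z = 1 and a correct site tops
out around 74 %. Two effects cap it, both intrinsic to the model rather
than to the implementation: (1) with per-column-independent instances from
a 1.28 bits/column matrix, 14–21 % of planted instances have an average
likelihood ratio below 1 *under the true matrix* — the strict indicator
rule excludes them no matter how well the sampler does; (2) the indicator
feeds back into estimation, so θ̂ is estimated from the consensus-richer
included subset and is slightly sharper than the truth (dominant ≈ 0.93 vs
0.88), which excludes a further few percent of borderline instances. Both
effects shrink for sharper or less uniform motifs; real TF matrices, whose
information is concentrated in a core of near-deterministic columns, sit
in the friendlier regime.

## Performance model

amdahl_limit(f) = 1/(1−f) for f ∈ [0, 1); the fraction f comes from an
external profiler — the module never times anything, which keeps it
deterministic and hardware-independent. Reports round to 2 decimal places
(round-half-even) for display and keep exact values internally; an
achieved speedup above its theoretical bound produces a warning, not an
error, since measured fractions carry noise.

## Problem sizes used in the test suite

Unit tests run on sequences of tens to hundreds of bases. The heavier
checks use: 50×200 bp × 3 matrix widths for fragmentation invariance;
exhaustive positions of 100 sequences ≤ 30 bp for scan-oracle
equivalence; 4×15 bp toys with 10⁵ draws for sampler-conditional
correctness; and the 200×200 bp recovery experiment above over five
seeds. These sizes were chosen so the whole suite completes in a couple
of minutes on a single core while still exercising every contract at
full fidelity.

## Known limitations

- The llr threshold is not calibrated to a p-value or FDR; incidence
  counts across matrices of different widths are not directly comparable.
- One motif per run; masking-and-rerunning for secondary motifs is left
  to the user.
- The indicator rule's strict average-ratio-greater-than-1 criterion has
  no tunable sensitivity; sequences with weak (high-divergence) instances
  are excluded by design.
- The background is strand-symmetric only if the input is; no
  strand-specific background is fitted.
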