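"""Synthetic ChIP-peak-like datasets with ground truth.

Emulates the statistical structure the de novo model assumes: Markov-chain
background sequence, a motif instance planted (with some probability) at a
start drawn from a discretized, range-truncated student-t around the peak
center, a uniform strand, and a per-sequence read depth whose distribution
is shifted upward for planted sequences (depth carries motif-presence
signal).  Planted windows overwrite background bases, keeping lengths
fixed.  Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .background import MarkovBackground, uniform_background
from .denovo import position_prior
from .sequence_io import EncodedSequence, PSWM, reverse_complement_codes


def demo_pswm(width: int = 8, dominant: float = 0.88,
              consensus: str = "TGACTCAG", name: str = "demo") -> PSWM:
    """A moderately informative test motif (~1.3 bits/column).

    Each column puts ``dominant`` mass on the consensus base and splits the
    rest evenly; with dominant = 0.88 the per-column information content is
    about 1.28 bits.
    """
    from .sequence_io import CODE_OF_BASE

    if len(consensus) < width:
        raise ValueError("consensus shorter than requested width")
    theta = np.full((width, 4), (1.0 - dominant) / 3.0)
    for i, base in enumerate(consensus[:width]):
        theta[i, CODE_OF_BASE[base] - 1] = dominant
    return PSWM(name, theta)


@dataclass
class DepthLaw:
    """Log-normal per-sequence depth; planted sequences draw a higher mu."""

    kind: str = "lognormal"
    mu: float = 3.0
    sigma: float = 0.5
    planted_mu: float = 4.0

    def draw(self, planted: bool, rng: np.random.Generator) -> float:
        if self.kind == "constant":
            return self.mu
        if self.kind == "lognormal":
            return float(rng.lognormal(
                self.planted_mu if planted else self.mu, self.sigma))
        raise ValueError(f"unknown depth law {self.kind!r}")


@dataclass
class SyntheticSpec:
    n_sequences: int = 200
    length: int | Sequence[int] = 200
    true_pswm: PSWM = field(default_factory=demo_pswm)
    planting_probability: float = 0.9
    position_df: float = 4.0
    position_scale: float | None = None  # default L/8
    background: MarkovBackground | str = "uniform"
    depth_law: DepthLaw = field(default_factory=DepthLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planting_probability <= 1.0):
            raise ValueError("planting_probability must lie in [0, 1]")
        lengths = self.lengths()
        if min(lengths) < self.true_pswm.width:
            raise ValueError("sequence length < motif width")

    def lengths(self) -> list[int]:
        if isinstance(self.length, int):
            return [self.length] * self.n_sequences
        lengths = list(self.length)
        if len(lengths) != self.n_sequences:
            raise ValueError("per-sequence length list has wrong size")
        return lengths


def _sample_markov_chain(bg: MarkovBackground, L: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw one sequence from the background chain (codes 1..4)."""
    cum = [np.cumsum(t, axis=-1) for t in bg.tables]
    out = np.empty(L, dtype=np.int8)
    ctx: list[int] = []
    for t in range(L):
        k = min(bg.order, t)
        row = cum[k][tuple(ctx[-k:])] if k else cum[0]
        out[t] = 1 + int(np.searchsorted(row, rng.random(), side="right"))
        ctx.append(int(out[t]) - 1)
    return out


def _draw_motif_instance(pswm: PSWM, rng: np.random.Generator) -> np.ndarray:
    """One per-column-independent draw from the motif model (codes 1..4)."""
    u = rng.random(pswm.width)
    cum = np.cumsum(pswm.theta, axis=1)
    return (1 + np.array([np.searchsorted(cum[i], u[i], side="right")
                          for i in range(pswm.width)])).astype(np.int8)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[EncodedSequence], pd.DataFrame]:
    """Generate sequences and a ground-truth table.

    The truth table has one row per sequence: sequence_id, planted,
    start (1-based forward-strand window start, 0 when unplanted), strand,
    depth.
    """
    rng = np.random.default_rng(spec.seed)
    bg = (uniform_background(0) if spec.background == "uniform"
          else spec.background)
    pswm = spec.true_pswm
    w = pswm.width
    sequences: list[EncodedSequence] = []
    rows = []
    for j, L in enumerate(spec.lengths()):
        codes = _sample_markov_chain(bg, L, rng)
        planted = rng.random() < spec.planting_probability
        start, strand = 0, "."
        if planted:
            scale = spec.position_scale or L / 8.0
            prior = position_prior(L, w, spec.position_df, scale)
            start = 1 + int(np.searchsorted(np.cumsum(prior.probs),
                                            rng.random(), side="right"))
            start = min(start, L - w + 1)
            instance = _draw_motif_instance(pswm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                instance = reverse_complement_codes(instance)
            codes[start - 1:start - 1 + w] = instance
        depth = spec.depth_law.draw(planted, rng)
        sid = f"peak{j:05d}"
        sequences.append(EncodedSequence(sid, codes, depth=depth))
        rows.append((sid, planted, start, strand, depth))
    truth = pd.DataFrame(
        rows, columns=["sequence_id", "planted", "start", "strand", "depth"])
    return sequences, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RecoveryMetrics:
    recall: float
    precision: float
    n_planted: int
    n_found: int
    n_matched: int
    no_predictions: bool = False


def scoreboard(truth: pd.DataFrame,
               found_sites: Sequence[tuple[str, int, str]],
               tolerance: int = 1,
               strand_agnostic: bool = True,
               shift: int = 0,
               orientation: str = "+") -> RecoveryMetrics:
    """Site-level recall and precision against the planted ground truth.

    A found site matches when it names a planted sequence and its
    (shift-corrected) start is within ``tolerance`` bases of the planted
    start (strands ignored when strand_agnostic; starts are forward-strand
    window starts on both sides).  ``shift`` and ``orientation`` — as
    reported by :func:`pswm_column_tv` — align sites of a column-shifted or
    reverse-complemented recovered motif with the true motif's frame: a
    site whose strand agrees with the orientation moves by +shift, a
    disagreeing one by -shift.  An empty prediction list reports precision
    0 with a flag.
    """
    planted = truth[truth["planted"].astype(bool)]
    planted_start = dict(zip(planted["sequence_id"], planted["start"]))
    planted_strand = dict(zip(planted["sequence_id"], planted["strand"]))
    matched_seqs: set[str] = set()
    n_good_preds = 0
    for sid, start, strand in found_sites:
        corrected = start + (shift if strand == orientation else -shift)
        ok = (sid in planted_start
              and abs(int(corrected) - int(planted_start[sid])) <= tolerance
              and (strand_agnostic or strand == planted_strand[sid]))
        if ok:
            n_good_preds += 1
            matched_seqs.add(sid)
    n_found = len(found_sites)
    n_planted = len(planted_start)
    recall = len(matched_seqs) / n_planted if n_planted else 0.0
    precision = n_good_preds / n_found if n_found else 0.0
    return RecoveryMetrics(
        recall=recall, precision=precision, n_planted=n_planted,
        n_found=n_found, n_matched=len(matched_seqs),
        no_predictions=(n_found == 0))


def pswm_column_tv(recovered: PSWM, true: PSWM,
                   max_shift: int = 2) -> tuple[float, int, str]:
    """Median per-column total-variation distance after alignment.

    Tries every column shift in [-max_shift, max_shift] and both
    orientations.  The alignment is chosen by the smallest MEAN TV over
    overlapping columns (robust against a single coincidentally matching
    stretch in a wrong alignment); the reported distance is the median
    per-column TV of the chosen alignment, as (median_tv, shift,
    orientation).
    """
    best_mean = np.inf
    best = (np.inf, 0, "+")
    for orient, cand in (("+", recovered), ("-", recovered.reverse_complement())):
        for shift in range(-max_shift, max_shift + 1):
            lo = max(0, shift)
            hi = min(cand.width, true.width + shift)
            if hi - lo < 1:
                continue
            tv = 0.5 * np.abs(cand.theta[lo:hi]
                              - true.theta[lo - shift:hi - shift]).sum(axis=1)
            mean = float(np.mean(tv))
            if mean < best_mean:
                best_mean = mean
                best = (float(np.median(tv)), shift, orient)
    return best
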