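"""PSWM motif scanning over concatenated sequences with fragment streaming.

All sequences are concatenated and scored as one long coordinate space; a
post-processing step separates hits back to their source sequences.  The
scan is processed in "fragments" — contiguous ranges of window-start
positions — and the normative contract is that the output is identical for
every fragment size: fragments are a streaming mechanism, never a change of
semantics.  Windows spanning a boundary between two original sequences are
never scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .background import MarkovBackground
from .sequence_io import EncodedSequence, HitRecord, PSWM

DEFAULT_LLR_THRESHOLD = 6.0  # log2 units: likelihood ratio 64
DEFAULT_PRIOR_PI = 1e-3  # prior probability that a position starts a motif


@dataclass
class ScanConfig:
    llr_threshold: float = DEFAULT_LLR_THRESHOLD
    scan_both_strands: bool = True
    fragment_size: int = 65536  # window starts per fragment
    prior_pi: float = DEFAULT_PRIOR_PI

    def __post_init__(self) -> None:
        if self.fragment_size < 1:
            raise ValueError("fragment_size must be >= 1")
        if not (0.0 < self.prior_pi < 1.0):
            raise ValueError("prior_pi must lie in (0, 1)")


@dataclass
class ScanResult:
    pswm_name: str
    hits: list[HitRecord]
    incidences_per_sequence: dict[str, int]
    total_incidences: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_incidences = sum(self.incidences_per_sequence.values())


def log_likelihood_ratio(pswm: PSWM, bg: MarkovBackground,
                         seq: EncodedSequence, a: int) -> float:
    """log2 P(window | motif) - log2 P(window | background) at 1-based a.

    The motif term is the sum over columns of log2 theta at the observed
    base (indicator exponents: each window base selects exactly one theta
    entry per column).  A zero theta entry at an observed base yields -inf,
    never an exception.
    """
    w = pswm.width
    L = len(seq)
    if not (1 <= a <= L - w + 1):
        raise ValueError(f"start {a} out of range for L={L}, w={w}")
    logp = bg.position_log2_probs(seq)
    window = seq.codes[a - 1:a - 1 + w].astype(np.int64) - 1
    motif = float(np.sum(pswm.log2_theta()[np.arange(w), window]))
    background = float(np.sum(logp[a - 1:a - 1 + w]))
    return motif - background


def posterior_match_probability(llr: float | np.ndarray,
                                prior_pi: float) -> float | np.ndarray:
    """Posterior P(motif starts here) in a two-component mixture.

    With per-position prior pi and likelihood ratio r = 2**llr this is
    pi*r / (pi*r + (1-pi)); monotone in llr, 0 at llr = -inf.  Computed in
    the log domain to stay finite for large |llr|.
    """
    if not (0.0 < prior_pi < 1.0):
        raise ValueError("prior_pi must lie in (0, 1)")
    llr = np.asarray(llr, dtype=float)
    # pi*r/(pi*r + 1-pi) = 1/(1 + exp2(log2((1-pi)/pi) - llr))
    log_odds = np.log2((1.0 - prior_pi) / prior_pi)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp2(log_odds - llr))
    return float(out) if out.ndim == 0 else out


class _ConcatScanSpace:
    """Concatenated coordinate space shared by all PSWMs of one scan."""

    def __init__(self, sequences: Sequence[EncodedSequence],
                 bg: MarkovBackground) -> None:
        ids = [s.id for s in sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in scan input")
        self.ids = ids
        self.lengths = np.array([len(s) for s in sequences], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        self.codes = np.concatenate([s.codes for s in sequences])
        self.bg_logp = np.concatenate(
            [bg.position_log2_probs(s) for s in sequences])
        # owner[t] = index of the sequence containing concatenated position t
        self.owner = np.repeat(np.arange(len(sequences)), self.lengths)

    def valid_starts_mask(self, w: int) -> np.ndarray:
        """True where a w-window stays inside one original sequence."""
        n_starts = self.codes.size - w + 1
        if n_starts <= 0:
            return np.zeros(0, dtype=bool)
        return self.owner[:n_starts] == self.owner[w - 1:]


def _score_fragment(windows: np.ndarray, bg_windows: np.ndarray,
                    log2_theta: np.ndarray,
                    both_strands: bool) -> tuple[np.ndarray, np.ndarray]:
    """llr arrays (forward, reverse) for a block of window rows."""
    w = log2_theta.shape[0]
    cols = np.arange(w)
    with np.errstate(invalid="ignore"):
        bg_sum = np.sum(bg_windows, axis=1)
        fwd = np.sum(log2_theta[cols, windows - 1], axis=1) - bg_sum
        if both_strands:
            rc = (5 - windows)[:, ::-1]
            rev = np.sum(log2_theta[cols, rc - 1], axis=1) - bg_sum
        else:
            rev = None
    return fwd, rev


def scan_all(pswms: Sequence[PSWM], sequences: Sequence[EncodedSequence],
             bg: MarkovBackground,
             config: ScanConfig | None = None) -> list[ScanResult]:
    """Scan every PSWM over every valid window start of every sequence.

    Sequences shorter than a PSWM contribute zero positions for it.  Hits
    are positions with llr >= the threshold (closed bound); overlapping
    hits are all reported.  Output is identical for every fragment size.
    """
    if not pswms:
        raise ValueError("no PSWMs supplied")
    if not sequences:
        raise ValueError("no sequences supplied")
    config = config or ScanConfig()
    space = _ConcatScanSpace(sequences, bg)
    results: list[ScanResult] = []
    for pswm in pswms:
        w = pswm.width
        log2_theta = pswm.log2_theta()
        hits: list[HitRecord] = []
        counts = {sid: 0 for sid in space.ids}
        n_starts = max(space.codes.size - w + 1, 0)
        if n_starts:
            windows = sliding_window_view(space.codes, w)
            bg_windows = sliding_window_view(space.bg_logp, w)
            valid = space.valid_starts_mask(w)
            for f0 in range(0, n_starts, config.fragment_size):
                f1 = min(f0 + config.fragment_size, n_starts)
                fwd, rev = _score_fragment(
                    windows[f0:f1], bg_windows[f0:f1], log2_theta,
                    config.scan_both_strands)
                strand_scores = [("+", fwd)]
                if rev is not None:
                    strand_scores.append(("-", rev))
                frag_valid = valid[f0:f1]
                by_pos: dict[int, list[tuple[str, float]]] = {}
                for strand, llrs in strand_scores:
                    ok = np.flatnonzero(
                        frag_valid & (llrs >= config.llr_threshold))
                    for k in ok:
                        by_pos.setdefault(int(k), []).append(
                            (strand, float(llrs[k])))
                for k in sorted(by_pos):
                    t = f0 + k
                    sidx = int(space.owner[t])
                    sid = space.ids[sidx]
                    local = int(t - space.offsets[sidx]) + 1
                    for strand, llr in by_pos[k]:
                        hits.append(HitRecord(
                            sequence_id=sid, start=local, width=w,
                            strand=strand, llr=llr,
                            posterior=posterior_match_probability(
                                llr, config.prior_pi),
                            pswm_name=pswm.name))
                        counts[sid] += 1
        results.append(ScanResult(pswm_name=pswm.name, hits=hits,
                                  incidences_per_sequence=counts))
    return results


def count_incidences(result: ScanResult) -> dict[str, int]:
    """Hits per sequence, both strands pooled; zero for hit-free sequences."""
    return dict(result.incidences_per_sequence)
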