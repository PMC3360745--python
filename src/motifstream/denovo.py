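"""De novo motif discovery by collapsed Gibbs sampling.

The model is the product multinomial: motif columns are independent
multinomial draws with conjugate Dirichlet priors, non-motif positions
follow the Markov background.  Each sequence j carries one candidate motif
start A_j and a binary inclusion indicator Z_j; Z_j is 1 when the average
of per-position likelihood ratios for the sequence exceeds 1, and only
included sequences take part in the alignment sweep.  Motif starts carry a
student-t positional prior centered on the ChIP peak summit, standing in
for the read-depth profile within the peak.

The sampler is collapsed: theta is integrated out and each A_j is drawn
from its leave-one-out Dirichlet posterior-predictive full conditional.
Sweeps optionally visit sequences in descending read depth so that
high-confidence sequences shape the motif estimate first (a documented
approximation of prioritized scheduling, not a reproduction of it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln
from scipy.stats import t as student_t

from .background import MarkovBackground
from .sequence_io import EncodedSequence, PSWM

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class SamplerConfig:
    """Tunables of one de novo run (motif width w is fixed per run)."""

    w: int
    beta: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    iterations: int = 500
    burn_in: int = 100
    seed: int = 0
    t_df: float = 4.0
    t_scale_factor: float = 0.25  # prior scale = factor * L_j
    depth_ordered_sweeps: bool = True
    both_strands: bool = True
    use_position_prior: bool = True  # False: flat prior over valid starts
    # Z is held at 1 while the motif estimate is still forming; indicator
    # updates start once burn-in ends.  With a near-random theta_hat the
    # average-ratio rule excludes sequences essentially at random, which
    # can starve the sampler before a motif emerges.
    indicator_delay: int | None = None  # default: burn_in

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("motif width must be >= 1")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if any(b <= 0 for b in self.beta):
            raise ValueError("all Dirichlet beta entries must be > 0")
        if self.t_df <= 0 or self.t_scale_factor <= 0:
            raise ValueError("t_df and t_scale_factor must be > 0")


@dataclass
class PositionPrior:
    """Discretized, range-truncated prior over valid motif starts."""

    center: float
    scale: float
    df: float
    probs: np.ndarray  # over starts 1..L-w+1, sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError("prior probs must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("prior probs must be strictly positive")


def position_prior(seq: EncodedSequence | int, w: int, df: float,
                   scale: float, center: float | None = None) -> PositionPrior:
    """Student-t prior over starts: window midpoints vs. the peak center.

    probs[a] is proportional to the t_df density of
    (a + (w-1)/2 - center) / scale, normalized over a in 1..L-w+1.
    ``center`` defaults to the sequence midpoint (L+1)/2.
    """
    L = seq if isinstance(seq, int) else len(seq)
    if L < w:
        raise ValueError(f"sequence length {L} < motif width {w}")
    if center is None:
        center = (L + 1) / 2.0
    starts = np.arange(1, L - w + 2, dtype=float)
    z = (starts + (w - 1) / 2.0 - center) / scale
    dens = student_t.pdf(z, df)
    return PositionPrior(center=center, scale=scale, df=df,
                         probs=dens / dens.sum())


def flat_position_prior(seq: EncodedSequence | int, w: int) -> PositionPrior:
    """Uniform prior over valid starts (no positional information)."""
    L = seq if isinstance(seq, int) else len(seq)
    if L < w:
        raise ValueError(f"sequence length {L} < motif width {w}")
    n = L - w + 1
    return PositionPrior(center=(L + 1) / 2.0, scale=1.0, df=1.0,
                         probs=np.full(n, 1.0 / n))


def update_pswm(counts: np.ndarray, beta: Sequence[float],
                n_included: int | None = None) -> np.ndarray:
    """Posterior-mean motif matrix from column counts.

    theta_hat[i, k] = (c[i, k] + beta[k]) / (n1 + sum(beta)), with n1 the
    number of included, aligned sequences.  With n1 = 0 this is the prior
    mean (a warning is logged by the sampler in that case).
    """
    counts = np.asarray(counts, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if n_included is None:
        n_included = int(round(counts[0].sum())) if counts.size else 0
    return (counts + beta) / (n_included + beta.sum())


def average_likelihood_ratio(seq: EncodedSequence, theta_hat: np.ndarray,
                             bg: MarkovBackground) -> float:
    """Mean over all starts of the per-window likelihood ratio.

    Returns (1/(L-w+1)) * sum_a 2**llr(a) with llr the log2 ratio of the
    window probability under theta_hat to its background probability.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    w = theta_hat.shape[0]
    L = len(seq)
    if L < w:
        raise ValueError(f"sequence length {L} < motif width {w}")
    with np.errstate(divide="ignore"):
        lt = np.log2(theta_hat)
    win = sliding_window_view(seq.codes, w).astype(np.int64) - 1
    logp = bg.position_log2_probs(seq)
    bgw = np.sum(sliding_window_view(logp, w), axis=1)
    llr = np.sum(lt[np.arange(w), win], axis=1) - bgw
    with np.errstate(over="ignore"):
        return float(np.mean(np.exp2(llr)))


@dataclass
class SamplerState:
    """Mutable Gibbs state: alignments, indicators, sufficient statistics."""

    A: np.ndarray        # 1-based start per sequence, -1 = unassigned
    strand: np.ndarray   # 0 = forward, 1 = reverse
    Z: np.ndarray        # inclusion indicator per sequence
    counts: np.ndarray   # (w, 4) motif-column base counts over contributors
    n_assigned: int      # sequences with Z=1 and an assigned start

    def copy(self) -> "SamplerState":
        return SamplerState(self.A.copy(), self.strand.copy(), self.Z.copy(),
                            self.counts.copy(), self.n_assigned)


@dataclass
class DenovoResult:
    """Best-posterior state of a de novo run."""

    pswm: PSWM
    sites: list[tuple[str, int, str]]  # (sequence_id, start, strand)
    Z: dict[str, int]
    trace: pd.DataFrame  # iteration, log_post, n_included
    log_post: float
    collapsed: bool = False


class GibbsMotifSampler:
    """Collapsed Gibbs sampler over motif start positions.

    Precomputes, per sequence: the (L-w+1, w) window code matrix for both
    orientations, background window log2 probabilities, and the positional
    prior.  All randomness flows from the config seed.
    """

    def __init__(self, sequences: Sequence[EncodedSequence],
                 config: SamplerConfig, bg: MarkovBackground) -> None:
        w = config.w
        usable = [s for s in sequences if len(s) >= w]
        if len(usable) < 2:
            raise ValueError("need >= 2 sequences at least w bases long")
        if len(usable) < len(sequences):
            logger.warning("%d sequence(s) shorter than w=%d excluded",
                           len(sequences) - len(usable), w)
        self.sequences = usable
        self.config = config
        self.bg = bg
        self.rng = np.random.default_rng(config.seed)
        self.beta = np.asarray(config.beta, dtype=float)
        self.n = len(usable)
        # per-sequence workspace
        self.win_fwd: list[np.ndarray] = []
        self.win_rev: list[np.ndarray] = []
        self.bgw: list[np.ndarray] = []
        self.log2_prior: list[np.ndarray] = []
        for s in usable:
            win = sliding_window_view(s.codes, w).astype(np.int64) - 1
            self.win_fwd.append(win)
            self.win_rev.append((3 - win)[:, ::-1])
            logp = bg.position_log2_probs(s)
            self.bgw.append(np.sum(sliding_window_view(logp, w), axis=1))
            if config.use_position_prior:
                prior = position_prior(
                    s, w, config.t_df, config.t_scale_factor * len(s))
            else:
                prior = flat_position_prior(s, w)
            self.log2_prior.append(np.log2(prior.probs))
        self.state = self._initial_state()

    # ------------------------------------------------------------------
    def _initial_state(self) -> SamplerState:
        w = self.config.w
        A = np.empty(self.n, dtype=np.int64)
        strand = np.zeros(self.n, dtype=np.int64)
        for j, s in enumerate(self.sequences):
            A[j] = self.rng.integers(1, len(s) - w + 2)
            if self.config.both_strands:
                strand[j] = self.rng.integers(0, 2)
        Z = np.ones(self.n, dtype=np.int64)
        state = SamplerState(A=A, strand=strand, Z=Z,
                             counts=np.zeros((w, 4), dtype=np.int64),
                             n_assigned=0)
        state.counts = self.rebuild_counts(state)
        state.n_assigned = int(((state.Z == 1) & (state.A >= 1)).sum())
        return state

    def _site_columns(self, j: int, a: int, strand: int) -> np.ndarray:
        """0-based column bases of the motif instance at (a, strand)."""
        win = self.win_rev[j] if strand else self.win_fwd[j]
        return win[a - 1]

    def rebuild_counts(self, state: SamplerState | None = None) -> np.ndarray:
        """Recompute column counts from scratch from (A, Z, strand)."""
        state = state or self.state
        counts = np.zeros((self.config.w, 4), dtype=np.int64)
        cols = np.arange(self.config.w)
        for j in range(self.n):
            if state.Z[j] == 1 and state.A[j] >= 1:
                counts[cols, self._site_columns(j, int(state.A[j]),
                                                int(state.strand[j]))] += 1
        return counts

    def _remove_site(self, j: int) -> None:
        st = self.state
        if st.A[j] >= 1:
            cols = np.arange(self.config.w)
            st.counts[cols, self._site_columns(
                j, int(st.A[j]), int(st.strand[j]))] -= 1
            st.n_assigned -= 1
            st.A[j] = -1

    def _add_site(self, j: int, a: int, strand: int) -> None:
        st = self.state
        cols = np.arange(self.config.w)
        st.counts[cols, self._site_columns(j, a, strand)] += 1
        st.A[j] = a
        st.strand[j] = strand
        st.n_assigned += 1

    # ------------------------------------------------------------------
    def alignment_conditional(self, j: int) -> np.ndarray:
        """Leave-one-out full conditional over (strand, start) for seq j.

        Returns probabilities of shape (2, n_starts) in both-strand mode
        or (1, n_starts) forward-only; sums to 1.  The state is left
        unchanged (any removed site is restored).
        """
        st = self.state
        had = int(st.A[j]) if st.A[j] >= 1 else None
        had_strand = int(st.strand[j])
        if had is not None and st.Z[j] == 1:
            self._remove_site(j)
        probs = self._conditional_probs(j)
        if had is not None and st.Z[j] == 1:
            self._add_site(j, had, had_strand)
        return probs

    def _predictive_log2_theta(self) -> np.ndarray:
        st = self.state
        with np.errstate(divide="ignore"):
            return np.log2((st.counts + self.beta)
                           / (st.n_assigned + self.beta.sum()))

    def _conditional_probs(self, j: int) -> np.ndarray:
        lt = self._predictive_log2_theta()
        cols = np.arange(self.config.w)
        lw_f = (self.log2_prior[j]
                + np.sum(lt[cols, self.win_fwd[j]], axis=1) - self.bgw[j])
        if self.config.both_strands:
            lw_r = (self.log2_prior[j]
                    + np.sum(lt[cols, self.win_rev[j]], axis=1) - self.bgw[j])
            lw = np.stack([lw_f, lw_r])
        else:
            lw = lw_f[None, :]
        lw = lw - lw.max()
        p = np.exp2(lw)
        return p / p.sum()

    def sample_alignment(self, j: int) -> int:
        """Draw a new (start, strand) for included sequence j.

        Leave-one-out: the sequence's current site is removed from the
        counts before forming the Dirichlet posterior-predictive, and the
        counts are re-incremented at the sampled site.  Returns the new
        1-based start.
        """
        st = self.state
        if st.Z[j] != 1:
            raise ValueError(f"sequence {j} is excluded (Z=0)")
        self._remove_site(j)
        probs = self._conditional_probs(j)
        flat = probs.ravel()
        idx = int(np.searchsorted(np.cumsum(flat),
                                  self.rng.random() * flat.sum(),
                                  side="right"))
        idx = min(idx, flat.size - 1)
        strand, a0 = divmod(idx, probs.shape[1])
        self._add_site(j, a0 + 1, strand)
        return a0 + 1

    def current_theta_hat(self) -> np.ndarray:
        st = self.state
        if st.n_assigned == 0:
            logger.warning("no included aligned sequences; theta_hat is the "
                           "prior mean")
            return self.beta / self.beta.sum() * np.ones((self.config.w, 1))
        return update_pswm(st.counts, self.beta, st.n_assigned)

    def update_indicator(self, j: int, theta_hat: np.ndarray) -> int:
        """Set Z_j from the average likelihood ratio under theta_hat.

        Z_j = 1 iff the average exceeds 1 (strict).  In both-strand mode
        the reverse-complement orientation of theta_hat is also considered
        and the larger average decides.  On a 1 -> 0 transition the
        sequence's counts are removed.
        """
        avg = self._average_ratio(j, theta_hat, reverse=False)
        if self.config.both_strands:
            avg = max(avg, self._average_ratio(j, theta_hat, reverse=True))
        st = self.state
        new_z = 1 if avg > 1.0 else 0
        if st.Z[j] == 1 and new_z == 0:
            self._remove_site(j)
        st.Z[j] = new_z
        return new_z

    def _average_ratio(self, j: int, theta_hat: np.ndarray,
                       reverse: bool) -> float:
        with np.errstate(divide="ignore"):
            lt = np.log2(theta_hat)
        win = self.win_rev[j] if reverse else self.win_fwd[j]
        llr = (np.sum(lt[np.arange(self.config.w), win], axis=1)
               - self.bgw[j])
        with np.errstate(over="ignore"):
            return float(np.mean(np.exp2(llr)))

    # ------------------------------------------------------------------
    def log_posterior(self) -> float:
        """Collapsed joint log posterior (natural log, up to a constant).

        Dirichlet-multinomial column marginals plus, per included aligned
        sequence, the positional prior and the background correction of
        its window.
        """
        st = self.state
        bsum = self.beta.sum()
        lp = float(np.sum(gammaln(st.counts + self.beta))
                   - self.config.w * gammaln(st.n_assigned + bsum))
        for j in range(self.n):
            if st.Z[j] == 1 and st.A[j] >= 1:
                a0 = int(st.A[j]) - 1
                lp += LN2 * (self.log2_prior[j][a0] - self.bgw[j][a0])
                if self.config.both_strands:
                    lp -= LN2  # uniform 1/2 prior over orientation
        return lp

    def sweep_order(self) -> np.ndarray:
        if self.config.depth_ordered_sweeps:
            depths = np.array([s.depth for s in self.sequences])
            return np.argsort(-depths, kind="stable")
        return np.arange(self.n)

    def _map_alignment_pass(self, st: SamplerState) -> SamplerState:
        """Deterministic refinement of the reported state.

        Each included sequence's start is replaced by the mode of its
        leave-one-out full conditional, removing the single-draw sampling
        noise from the reported site list.  Purely deterministic: the
        sampler's rng is not consumed.
        """
        saved = self.state
        self.state = st.copy()
        try:
            for j in range(self.n):
                if self.state.Z[j] == 1 and self.state.A[j] >= 1:
                    self._remove_site(j)
                    probs = self._conditional_probs(j)
                    strand, a0 = np.unravel_index(int(np.argmax(probs)),
                                                  probs.shape)
                    self._add_site(j, int(a0) + 1, int(strand))
            return self.state
        finally:
            self.state = saved

    def run(self) -> DenovoResult:
        cfg = self.config
        order = self.sweep_order()
        trace_rows = []
        best: tuple[float, SamplerState] | None = None
        last_good: tuple[float, SamplerState] | None = None
        collapsed = False
        z_from = (cfg.burn_in if cfg.indicator_delay is None
                  else cfg.indicator_delay)
        for it in range(cfg.iterations):
            for j in order:
                if self.state.Z[j] == 1:
                    self.sample_alignment(int(j))
            theta_hat = self.current_theta_hat()
            if it >= z_from:
                for j in range(self.n):
                    self.update_indicator(j, theta_hat)
            lp = self.log_posterior()
            n1 = int(self.state.Z.sum())
            trace_rows.append((it, lp, n1))
            if self.state.n_assigned > 0:
                snap = (lp, self.state.copy())
                last_good = snap
                if it >= cfg.burn_in and (best is None or lp > best[0]):
                    best = snap
            else:
                logger.warning("all sequences excluded at iteration %d; "
                               "returning best pre-collapse state", it)
                collapsed = True
                break
        chosen = best or last_good
        if chosen is None:
            raise RuntimeError("sampler never had an included sequence")
        lp, st = chosen
        st = self._map_alignment_pass(st)
        theta = update_pswm(st.counts, self.beta, st.n_assigned)
        pswm = PSWM(f"denovo_w{cfg.w}", theta)
        sites = [(self.sequences[j].id, int(st.A[j]),
                  "-" if st.strand[j] else "+")
                 for j in range(self.n) if st.Z[j] == 1 and st.A[j] >= 1]
        zmap = {self.sequences[j].id: int(st.Z[j]) for j in range(self.n)}
        trace = pd.DataFrame(trace_rows,
                             columns=["iteration", "log_post", "n_included"])
        return DenovoResult(pswm=pswm, sites=sites, Z=zmap, trace=trace,
                            log_post=lp, collapsed=collapsed)


def run_sampler(sequences: Sequence[EncodedSequence], config: SamplerConfig,
                bg: MarkovBackground) -> DenovoResult:
    """Run a full de novo motif search; reproducible given the config seed."""
    return GibbsMotifSampler(sequences, config, bg).run()
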