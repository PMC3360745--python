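"""Markov background models for non-motif sequence.

The background is an order-k Markov chain over nucleotides (k in 0..3,
default 3): each base is conditioned on the up-to-k preceding bases of the
full sequence.  The first k positions of a sequence fall back to the
lower-order tables fitted from the same data.  All downstream arithmetic is
log2; window probabilities are sums of per-position log2 conditionals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import EncodedSequence

MAX_ORDER = 3


@dataclass
class MarkovBackground:
    """Conditional probability tables for orders 0..order.

    ``tables[k]`` has shape ``(4,)*(k+1)``: the first k axes index the
    context (oldest base first), the last axis the outcome.  Every context
    row sums to 1.
    """

    order: int
    tables: list[np.ndarray]
    pseudocount: float = 1.0
    _log2_tables: list[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.order <= MAX_ORDER):
            raise ValueError(f"order must be in 0..{MAX_ORDER}")
        if len(self.tables) != self.order + 1:
            raise ValueError("need one table per order 0..order")
        for k, t in enumerate(self.tables):
            t = np.asarray(t, dtype=float)
            if t.shape != (4,) * (k + 1):
                raise ValueError(f"table {k} must have shape {(4,)*(k+1)}")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"table {k}: context rows must sum to 1")
            self.tables[k] = t
        with np.errstate(divide="ignore"):
            self._log2_tables = [np.log2(t) for t in self.tables]

    # spec-named views -----------------------------------------------------
    @property
    def marg0(self) -> np.ndarray:
        return self.tables[0]

    @property
    def cond1(self) -> np.ndarray:
        return self.tables[1] if self.order >= 1 else None

    @property
    def cond2(self) -> np.ndarray:
        return self.tables[2] if self.order >= 2 else None

    @property
    def cond3(self) -> np.ndarray:
        return self.tables[3] if self.order >= 3 else None

    # ----------------------------------------------------------------------
    def position_log2_probs(self, seq: EncodedSequence) -> np.ndarray:
        """log2 P(base_t | up to ``order`` preceding bases), all positions.

        Position t (0-based) uses context length min(order, t): the true
        left-flanking bases when available, lower-order tables otherwise.
        """
        c = seq.codes.astype(np.int64) - 1
        L = c.size
        out = np.empty(L, dtype=float)
        k = self.order
        head = min(k, L)
        for t in range(head):
            idx = tuple(c[t - t0] for t0 in range(t, 0, -1)) + (c[t],)
            out[t] = self._log2_tables[t][idx]
        if L > k:
            flat = np.zeros(L - k, dtype=np.int64)
            for j in range(k + 1):
                flat = flat * 4 + c[j:L - k + j]
            out[k:] = self._log2_tables[k].reshape(-1)[flat]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "motifstream-background",
            "version": 1,
            "order": self.order,
            "pseudocount": self.pseudocount,
            "tables": [t.tolist() for t in self.tables],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovBackground":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "motifstream-background":
            raise ValueError(f"{path}: not a motifstream background dump")
        return cls(
            order=int(payload["order"]),
            tables=[np.asarray(t, dtype=float) for t in payload["tables"]],
            pseudocount=float(payload["pseudocount"]),
        )


@dataclass
class NonMotifVector:
    """Pooled nucleotide preference theta0 for non-motif positions."""

    theta0: np.ndarray

    def __post_init__(self) -> None:
        self.theta0 = np.asarray(self.theta0, dtype=float)
        if self.theta0.shape != (4,):
            raise ValueError("theta0 must be a length-4 vector")
        if not np.isclose(self.theta0.sum(), 1.0, atol=1e-9):
            raise ValueError("theta0 must sum to 1")


def fit_markov_background(
    sequences: Sequence[EncodedSequence],
    order: int = 3,
    pseudocount: float = 1.0,
) -> MarkovBackground:
    """Fit conditional tables of every order 0..order by pooled counting.

    Each context's conditional distribution is
    ``(count + pseudocount) / (context_total + 4 * pseudocount)``.
    Contexts never observed with pseudocount 0 get a uniform row so the
    row-stochastic invariant always holds.
    """
    if not sequences:
        raise ValueError("cannot fit a background on an empty sequence set")
    if not (0 <= order <= MAX_ORDER):
        raise ValueError(f"order must be in 0..{MAX_ORDER}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if not any(len(s) > order for s in sequences):
        raise ValueError(f"need at least one sequence longer than {order}")
    tables: list[np.ndarray] = []
    for k in range(order + 1):
        counts = np.zeros(4 ** (k + 1), dtype=np.int64)
        for seq in sequences:
            c = seq.codes.astype(np.int64) - 1
            if c.size <= k:
                continue
            flat = np.zeros(c.size - k, dtype=np.int64)
            for j in range(k + 1):
                flat = flat * 4 + c[j:c.size - k + j]
            counts += np.bincount(flat, minlength=4 ** (k + 1))
        grid = counts.reshape((4,) * (k + 1)).astype(float) + pseudocount
        totals = grid.sum(axis=-1, keepdims=True)
        empty = totals[..., 0] == 0
        if empty.any():  # only possible with pseudocount 0
            grid[empty] = 0.25
            totals = grid.sum(axis=-1, keepdims=True)
        tables.append(grid / totals)
    return MarkovBackground(order=order, tables=tables,
                            pseudocount=pseudocount)


def uniform_background(order: int = 0) -> MarkovBackground:
    """A background with every conditional probability 0.25."""
    tables = [np.full((4,) * (k + 1), 0.25) for k in range(order + 1)]
    return MarkovBackground(order=order, tables=tables, pseudocount=0.0)


def window_log_prob(bg: MarkovBackground, seq: EncodedSequence,
                    a: int, w: int) -> float:
    """log2 probability of the window starting at 1-based ``a``, width w.

    Each base is conditioned on the up-to-``order`` preceding bases of the
    full sequence; the context may extend left of the window.
    """
    L = len(seq)
    if not (1 <= a <= L - w + 1):
        raise ValueError(f"start {a} out of range for L={L}, w={w}")
    logp = bg.position_log2_probs(seq)
    return float(np.sum(logp[a - 1:a - 1 + w]))


def fit_nonmotif_vector(
    sequences: Sequence[EncodedSequence],
    pseudocount: float = 1.0,
) -> NonMotifVector:
    """Pooled base frequencies with pseudocount smoothing."""
    if not sequences:
        raise ValueError("empty sequence set")
    counts = np.zeros(4, dtype=np.int64)
    for seq in sequences:
        counts += np.bincount(seq.codes.astype(np.int64) - 1, minlength=4)
    freq = counts.astype(float) + pseudocount
    return NonMotifVector(freq / freq.sum())
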