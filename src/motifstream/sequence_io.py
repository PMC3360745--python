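"""Sequence and matrix I/O: FASTA, TRANSFAC-style matrices, BED hit tables.

Nucleotides are carried as integer codes 1-4 (A=1, C=2, G=3, T=4) so that
all downstream probability lookups are plain array indexing.  Coordinates
are 1-based inclusive internally; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: nucleotide -> integer code
CODE_OF_BASE = {"A": 1, "C": 2, "G": 3, "T": 4}
#: integer code -> nucleotide (index 0 unused)
BASE_OF_CODE = np.array([".", "A", "C", "G", "T"])


@dataclass
class EncodedSequence:
    """A DNA sequence as integer codes with an id and optional read depth."""

    id: str
    codes: np.ndarray  # int8 values in {1,2,3,4}
    depth: float = 1.0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.size and not (
            (self.codes >= 1).all() and (self.codes <= 4).all()
        ):
            raise ValueError(f"sequence {self.id!r}: codes must be in 1..4")
        if self.depth < 0:
            raise ValueError(f"sequence {self.id!r}: depth must be >= 0")

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def length(self) -> int:
        return int(self.codes.size)

    def decode(self) -> str:
        """Return the sequence as an uppercase ACGT string."""
        return "".join(BASE_OF_CODE[self.codes])

    def reverse_complement(self) -> "EncodedSequence":
        return EncodedSequence(self.id, reverse_complement_codes(self.codes),
                               self.depth)


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space: A<->T, C<->G is ``5 - code``."""
    return (5 - np.asarray(codes, dtype=np.int8))[::-1]


def encode_sequence(
    s: str,
    seq_id: str = "",
    depth: float = 1.0,
    rng: np.random.Generator | None = None,
) -> EncodedSequence:
    """Encode an ACGT string (case-insensitive) to integer codes.

    Bases outside {A,C,G,T} are replaced by a uniformly random base drawn
    from ``rng`` (a fresh seed-0 generator if none is given); the number of
    replacements is logged.  Silent dropping would shift coordinates, and
    the scan arithmetic requires codes 1-4.
    """
    up = s.upper()
    codes = np.frombuffer(up.encode("ascii"), dtype=np.uint8)
    out = np.zeros(codes.size, dtype=np.int8)
    for base, code in CODE_OF_BASE.items():
        out[codes == ord(base)] = code
    bad = out == 0
    n_bad = int(bad.sum())
    if n_bad:
        if rng is None:
            rng = np.random.default_rng(0)
        out[bad] = rng.integers(1, 5, size=n_bad)
        logger.warning(
            "sequence %r: replaced %d non-ACGT base(s) with random bases",
            seq_id, n_bad,
        )
    return EncodedSequence(seq_id, out, depth)


@dataclass
class PSWM:
    """Position-specific weight matrix: one probability 4-vector per column."""

    name: str
    theta: np.ndarray  # shape (w, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != 4:
            raise ValueError("theta must have shape (w, 4)")
        if self.theta.shape[0] < 1:
            raise ValueError("motif width must be >= 1")
        if (self.theta < 0).any():
            raise ValueError("theta entries must be non-negative")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each theta row must sum to 1")

    @property
    def width(self) -> int:
        return int(self.theta.shape[0])

    def log2_theta(self) -> np.ndarray:
        """log2 of theta with -inf at zero entries (never raises)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.theta)

    def reverse_complement(self) -> "PSWM":
        """The matrix describing the same motif on the opposite strand."""
        return PSWM(self.name + "_rc", self.theta[::-1, ::-1].copy())

    def consensus(self) -> str:
        return "".join(BASE_OF_CODE[1 + np.argmax(self.theta, axis=1)])

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (0..2 for DNA)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.theta > 0,
                             self.theta * np.log2(self.theta), 0.0)
        return 2.0 + plogp.sum(axis=1)


@dataclass
class HitRecord:
    """One motif match: 1-based start, strand, log2 LLR and posterior."""

    sequence_id: str
    start: int  # 1-based inclusive
    width: int
    strand: str  # '+' or '-'
    llr: float
    posterior: float
    pswm_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.start < 1:
            raise ValueError("start is 1-based and must be >= 1")
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError("posterior must lie in [0, 1]")


def read_fasta(
    path: str | Path,
    rng: np.random.Generator | None = None,
) -> list[EncodedSequence]:
    """Read a FASTA file into encoded sequences.

    Ids are taken from the header up to the first whitespace.  Records with
    zero bases are reported and skipped.  Non-ACGT bases follow the
    replacement policy of :func:`encode_sequence`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[EncodedSequence] = []
    for rec in records:
        s = str(rec.seq)
        if not s:
            logger.warning("record %r has no bases; skipped", rec.id)
            continue
        out.append(encode_sequence(s, seq_id=rec.id, rng=rng))
    if not out:
        raise ValueError(f"no non-empty FASTA records in {path}")
    return out


def write_fasta(sequences: Iterable[EncodedSequence], path: str | Path,
                width: int = 70) -> None:
    """Write encoded sequences as plain FASTA."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            s = seq.decode()
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _split_transfac_row(tokens: list[str]) -> list[float] | None:
    """Return the 4 counts of a matrix row, or None if not a matrix row."""
    # strip trailing consensus letters (non-numeric tokens)
    nums: list[float] = []
    for tok in tokens:
        try:
            nums.append(float(tok))
        except ValueError:
            break
    if len(nums) == 5 and float(nums[0]).is_integer():
        return nums[1:]  # "01  10 0 0 0  A" style: position index + counts
    indexed = tokens and len(tokens[0]) > 1 and tokens[0][0] == "0" \
        and tokens[0].isdigit()
    if len(nums) == 4 and not indexed:
        return nums  # bare counts ("10 0 0 0")
    return None  # leading-zero index ("01") with != 4 counts is malformed


def read_transfac_matrix(path: str | Path, pseudocount: float = 0.0) -> PSWM:
    """Read a TRANSFAC-style count matrix and normalize to probabilities.

    Only the matrix block is required: per-position rows of four counts,
    optionally preceded by a position index and followed by a consensus
    letter.  ``XX`` / ``//`` delimiters and header lines (ID, NA, P0, ...)
    are tolerated.  ``pseudocount`` is added to every cell before row
    normalization.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    name = path.stem
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "//")):
                continue
            tokens = line.split()
            tag = tokens[0].upper()
            if tag in ("XX", "P0", "PO"):
                continue
            if tag in ("ID", "NA") and len(tokens) > 1:
                name = tokens[1]
                continue
            if tag in ("AC", "DE", "BF", "BA", "CC"):
                continue
            counts = _split_transfac_row(tokens)
            if counts is None:
                if tokens[0][:1].isdigit():
                    raise ValueError(
                        f"{path}:{lineno}: malformed matrix row "
                        f"(expected 4 numeric count fields): {line!r}"
                    )
                continue  # unrecognized annotation line
            rows.append(counts)
    if not rows:
        raise ValueError(f"{path}: no matrix rows found")
    counts_arr = np.asarray(rows, dtype=float) + pseudocount
    totals = counts_arr.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.argmax(totals <= 0)) + 1
        raise ValueError(
            f"{path}: position {bad} has zero total count and pseudocount 0 "
            "(degenerate matrix)"
        )
    return PSWM(name, counts_arr / totals[:, None])


def write_transfac_matrix(pswm: PSWM, path: str | Path,
                          scale: int = 1000) -> None:
    """Write a PSWM as scaled pseudo-counts in TRANSFAC row layout.

    Re-reading with pseudocount 0 recovers theta within 1/(2*scale).
    """
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    with open(path, "w") as fh:
        fh.write(f"ID {pswm.name}\nP0      A      C      G      T\n")
        for i, row in enumerate(pswm.theta, start=1):
            cells = "  ".join(format(v * scale, ".10g") for v in row)
            base = BASE_OF_CODE[1 + int(np.argmax(row))]
            fh.write(f"{i:02d}  {cells}  {base}\n")
        fh.write("//\n")


def write_hits_bed(hits: Sequence[HitRecord], path: str | Path,
                   header: str | None = None) -> None:
    """Write hits as BED6: 0-based half-open interval per hit.

    chrom=sequence_id, chromStart=start-1, chromEnd=start-1+width,
    name=motif name, score=llr (log2 units), strand.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start - 1}\t{h.start - 1 + h.width}\t"
                f"{h.pswm_name}\t{format(h.llr, '.6g')}\t{h.strand}\n"
            )
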