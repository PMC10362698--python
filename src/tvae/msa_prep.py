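"""Cleaning, weighting and encoding of aligned protein families.

The cleaning rules mirror common practice for alignment-based generative
models: drop sequences whose gap content exceeds a fraction of the
alignment length, deduplicate exact repeats, and (optionally) strip gap
characters for unaligned output.  Surviving sequences are re-weighted
with Henikoff & Henikoff (1994) position-based weights so that
over-represented subfamilies do not dominate training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DEFAULT_ALPHABET, ProteinAlphabet

logger = logging.getLogger(__name__)

GAP_CHARS = (".", "-")


@dataclass
class RawFamily:
    """Raw FASTA records: (id, sequence) pairs, possibly with gaps."""

    records: list[tuple[str, str]]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def source_length(self) -> int | None:
        """Column count if all records share one length, else None."""
        lengths = {len(s) for _, s in self.records}
        return lengths.pop() if len(lengths) == 1 else None


@dataclass
class AlignedFamily:
    """Numeric view of a cleaned alignment plus per-sequence weights."""

    ids: list[str]
    matrix: np.ndarray  # N x L, int codes 0..20
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be N x L")
        if self.weights is None:
            self.weights = np.ones(self.n, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n,):
            raise ValueError("weights must have one entry per sequence")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive and finite")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def read_aligned_fasta(path: str | Path) -> RawFamily:
    """Read an aligned FASTA file into a :class:`RawFamily`.

    '.' and '-' are both accepted as gap characters.  All entries must
    have the same column count; unequal lengths raise ``ValueError``.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        logger.warning("no FASTA records found in %s", path)
        return RawFamily([])
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError(
            f"{path}: aligned FASTA requires equal-length entries, got lengths {sorted(lengths)}"
        )
    return RawFamily(records)


def write_fasta(fam: RawFamily | AlignedFamily, path: str | Path) -> None:
    """Write a family back out as FASTA (gap token '-')."""
    if isinstance(fam, AlignedFamily):
        pairs: Iterable[tuple[str, str]] = (
            (i, DEFAULT_ALPHABET.decode(row)) for i, row in zip(fam.ids, fam.matrix)
        )
    else:
        pairs = fam.records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in pairs]
    SeqIO.write(recs, str(path), "fasta")


def gap_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    return sum(sequence.count(c) for c in GAP_CHARS) / len(sequence)


def filter_by_gap_fraction(fam: RawFamily, max_frac: float = 0.2) -> RawFamily:
    """Drop sequences whose gap fraction exceeds ``max_frac``.

    The fraction is computed on the aligned sequences (gaps still
    present); order of the survivors is preserved.
    """
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError("max_frac must lie in [0, 1]")
    kept = [(i, s) for i, s in fam.records if gap_fraction(s) <= max_frac]
    if not kept and fam.records:
        logger.warning("gap filter at %.2f removed every sequence", max_frac)
    return RawFamily(kept)


def deduplicate(fam: RawFamily) -> RawFamily:
    """Keep the first occurrence of each distinct sequence string."""
    seen: set[str] = set()
    kept = []
    for name, seq in fam.records:
        if seq not in seen:
            seen.add(seq)
            kept.append((name, seq))
    return RawFamily(kept)


def strip_gap_sites(fam: RawFamily) -> RawFamily:
    """Remove every '.' and '-' from each sequence (lengths may differ after)."""
    out = []
    for name, seq in fam.records:
        stripped = seq
        for c in GAP_CHARS:
            stripped = stripped.replace(c, "")
        if not stripped:
            logger.warning("sequence %s is all gaps; stripped to empty", name)
        out.append((name, stripped))
    return RawFamily(out)


def clean_family(
    fam: RawFamily,
    max_gap_frac: float = 0.2,
    alphabet: ProteinAlphabet = DEFAULT_ALPHABET,
) -> AlignedFamily:
    """Gap-filter, deduplicate and encode an aligned family, then weight it."""
    fam = deduplicate(filter_by_gap_fraction(fam, max_gap_frac))
    if fam.n == 0:
        raise ValueError("no sequences survived cleaning")
    matrix = np.stack([alphabet.encode(seq) for _, seq in fam.records])
    out = AlignedFamily(ids=[name for name, _ in fam.records], matrix=matrix)
    out.weights = position_weights(out)
    return out


def position_weights(fam: AlignedFamily) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights.

    In each alignment column with ``r`` distinct symbols, a sequence
    carrying a symbol observed ``m`` times contributes ``1/(r*m)``; a
    sequence's raw weight is the mean contribution over columns, and the
    vector is normalized to sum to N.  The gap counts as a 21st symbol.
    """
    mat = fam.matrix
    n, length = mat.shape
    raw = np.zeros(n, dtype=float)
    for col in mat.T:
        counts = np.bincount(col, minlength=21)
        r = int(np.count_nonzero(counts))
        raw += 1.0 / (r * counts[col])
    raw /= length
    return raw * (n / raw.sum())


def encode_onehot(row: np.ndarray, alphabet: ProteinAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Residue-index row -> 21 x L one-hot grid (each column sums to 1)."""
    row = np.asarray(row)
    if row.ndim != 1:
        raise ValueError("expected a 1-D residue-index row")
    if row.size and (row.min() < 0 or row.max() >= alphabet.size):
        raise ValueError("residue indices must lie in 0..20")
    grid = np.zeros((alphabet.size, row.size), dtype=np.float64)
    grid[row, np.arange(row.size)] = 1.0
    return grid


def decode_onehot(grid: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_onehot` (argmax per column)."""
    return np.argmax(np.asarray(grid), axis=0).astype(np.int8)


def family_onehot(fam: AlignedFamily) -> np.ndarray:
    """Whole family as an N x 21 x L stack of one-hot grids."""
    return np.stack([encode_onehot(row) for row in fam.matrix])


def write_weights_tsv(fam: AlignedFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, w in zip(fam.ids, fam.weights):
            fh.write(f"{name}\t{w:.10g}\n")
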