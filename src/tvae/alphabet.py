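"""Residue alphabet: gap plus the 20 standard amino acids.

The integer coding is gap -> 0 and the amino acids, in alphabetical
one-letter order ``ACDEFGHIKLMNPQRSTVWY``, -> 1..20.  One-hot encodings
are 21 x L with the gap channel first.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues with no slot in the 21-letter model (ambiguity/rare codes);
#: they are coerced to gap with a warning.
NONSTANDARD = set("BJOUXZ")


class ProteinAlphabet:
    """Bijection between the 21 residue tokens and integer codes 0..20."""

    def __init__(self) -> None:
        self.symbols: str = GAP + AMINO_ACIDS
        self._index = {sym: i for i, sym in enumerate(self.symbols)}

    @property
    def size(self) -> int:
        return len(self.symbols)  # 21

    def index_of(self, token: str) -> int:
        """Integer code of a residue token; '.' is an alias for the gap."""
        if token == ".":
            return 0
        try:
            return self._index[token]
        except KeyError:
            if token.upper() in NONSTANDARD:
                logger.warning("nonstandard residue %r coerced to gap", token)
                return 0
            raise ValueError(f"unknown residue token {token!r}") from None

    def token_of(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise ValueError(f"residue index {index} out of range 0..20")
        return self.symbols[index]

    def encode(self, sequence: str) -> np.ndarray:
        """Residue string -> integer row (dtype int8)."""
        return np.array([self.index_of(c) for c in sequence.upper()], dtype=np.int8)

    def decode(self, row: np.ndarray) -> str:
        return "".join(self.token_of(int(i)) for i in row)


DEFAULT_ALPHABET = ProteinAlphabet()
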