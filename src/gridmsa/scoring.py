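"""Substitution matrices and affine-gap parameters.

All dynamic-programming arithmetic in the engine is integer, on a fixed scale
of 100 DP units per score point (``SCALE``), so that grid-cache cells are exact
32-bit values and both cell codecs stay meaningful.  Floating-point scores and
penalties are rounded onto that scale once, at scheme/profile construction.

Defaults follow Clustal W 1.83: DNA match +1 / mismatch 0 with gap open 15 and
gap extend 6.66; protein BLOSUM62 with gap open 10 and gap extend 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import Alphabet

#: DP units per score point.
SCALE = 100

#: Residue category order used by profiles; DNA includes the IUPAC ambiguity
#: codes, protein the 20 amino acids plus B, Z, X.
DNA_ORDER = "ACGTURYSWKMBDHVN"
PROTEIN_ORDER = "ARNDCQEGHILKMFPSTWYVBZX"

#: Input residues normalized before encoding (RNA U -> T; selenocysteine and
#: pyrrolysine mapped to their closest standard residues).
_NORMALIZE = {
    Alphabet.DNA: {"U": "T"},
    Alphabet.PROTEIN: {"U": "C", "O": "K"},
}


def residue_order(alphabet: Alphabet) -> str:
    return DNA_ORDER if alphabet is Alphabet.DNA else PROTEIN_ORDER


def to_scaled_int(x) -> np.ndarray:
    """Round score points onto the integer DP scale."""
    return np.rint(np.asarray(x, dtype=np.float64) * SCALE).astype(np.int64)


@dataclass
class ScoringScheme:
    """Symmetric substitution matrix plus affine gap costs (score points)."""

    alphabet: Alphabet
    residues: str
    matrix: np.ndarray
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        L = len(self.residues)
        if self.matrix.shape != (L, L):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match the "
                f"{L}-residue alphabet")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        self._index = {ch: i for i, ch in enumerate(self.residues)}

    # -- constructors -------------------------------------------------------

    @classmethod
    def dna(cls, match: float = 1.0, mismatch: float = 0.0,
            gap_open: float = 15.0, gap_extend: float = 6.66) -> "ScoringScheme":
        L = len(DNA_ORDER)
        m = np.full((L, L), mismatch, dtype=np.float64)
        np.fill_diagonal(m, match)
        return cls(Alphabet.DNA, DNA_ORDER, m, gap_open, gap_extend)

    @classmethod
    def protein(cls, gap_open: float = 10.0,
                gap_extend: float = 0.1) -> "ScoringScheme":
        blosum = substitution_matrices.load("BLOSUM62")
        return cls._from_bio_matrix(blosum, Alphabet.PROTEIN,
                                    gap_open, gap_extend)

    @classmethod
    def from_matrix_file(cls, path: str | Path, alphabet: Alphabet,
                         gap_open: float, gap_extend: float) -> "ScoringScheme":
        """Load an NCBI/EMBOSS plain-text substitution matrix."""
        mat = substitution_matrices.read(str(path))
        return cls._from_bio_matrix(mat, alphabet, gap_open, gap_extend)

    @classmethod
    def _from_bio_matrix(cls, mat, alphabet: Alphabet,
                         gap_open: float, gap_extend: float) -> "ScoringScheme":
        order = residue_order(alphabet)
        L = len(order)
        m = np.zeros((L, L))
        src = {ch: i for i, ch in enumerate(mat.alphabet)}
        for i, a in enumerate(order):
            for j, b in enumerate(order):
                if a in src and b in src:
                    m[i, j] = mat[src[a], src[b]]
        return cls(alphabet, order, m, gap_open, gap_extend)

    @classmethod
    def default_for(cls, alphabet: Alphabet) -> "ScoringScheme":
        return cls.dna() if alphabet is Alphabet.DNA else cls.protein()

    # -- integer DP scale ---------------------------------------------------

    @cached_property
    def int_matrix(self) -> np.ndarray:
        return to_scaled_int(self.matrix)

    @property
    def int_gap_open(self) -> int:
        return int(to_scaled_int(self.gap_open))

    @property
    def int_gap_extend(self) -> int:
        return int(to_scaled_int(self.gap_extend))

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to category indices (int64)."""
        norm = _NORMALIZE[self.alphabet]
        try:
            return np.fromiter(
                (self._index[norm.get(ch, ch)] for ch in residues),
                dtype=np.int64, count=len(residues))
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} is not scorable under the "
                f"{self.alphabet.value} scheme") from None

    def score(self, a: str, b: str) -> float:
        norm = _NORMALIZE[self.alphabet]
        return float(self.matrix[self._index[norm.get(a, a)],
                                 self._index[norm.get(b, b)]])
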