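"""Protein scoring scheme shared by the translated search and the classifier.

The scheme bundles a BLOSUM62 substitution matrix with affine gap
penalties (BLAST-style open 11 / extend 1) and Karlin-Altschul
parameters used to convert raw local-alignment scores into E-values,

    E = K * m * n * exp(-lambda * S)

with m the query length in residues and n the effective nucleotide
search space (assembly gaps excluded).  lambda and K default to the
published gapped BLOSUM62/11,1 values; both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

#: letters with defined BLOSUM62 scores; anything else scores like X
_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


def _encoded_matrix() -> tuple[np.ndarray, np.ndarray]:
    """BLOSUM62 as a dense 128x128 int array indexed by ord(char)."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.full((128, 128), -4, dtype=np.int32)
    for a in _ALPHABET:
        for b in _ALPHABET:
            mat[ord(a), ord(b)] = int(blosum[a, b])
    codes = np.full(128, ord("X"), dtype=np.uint8)
    for a in _ALPHABET:
        codes[ord(a)] = ord(a)
    return mat, codes


_SCORE_MATRIX, _CODE_TABLE = _encoded_matrix()


def encode_protein(seq: str) -> np.ndarray:
    """uint8 codes (ord values, unknowns folded to X) for fast scoring."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def score_profile(query_codes: np.ndarray, subject_codes: np.ndarray) -> np.ndarray:
    """Elementwise substitution scores for two equal-length code arrays."""
    return _SCORE_MATRIX[query_codes, subject_codes]


def free_end_gaps(aligner: Align.PairwiseAligner) -> None:
    """Zero the terminal-gap scores (handles the biopython attribute rename)."""
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0


@dataclass
class ScoringScheme:
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    e_max: float = 1e-5
    matrix: object = field(default_factory=lambda: substitution_matrices.load("BLOSUM62"))

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def evalue(self, score: float, query_len: int, search_space: int) -> float:
        return self.K * query_len * search_space * math.exp(-self.lam * score)

    def local_aligner(self) -> Align.PairwiseAligner:
        """Smith-Waterman aligner under this scheme (affine gaps)."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def semiglobal_aligner(self) -> Align.PairwiseAligner:
        """Global aligner with free terminal gaps (for identity estimates)."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        free_end_gaps(aligner)
        return aligner
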