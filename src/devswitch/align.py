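"""Global protein alignment and the longer-sequence identity measure.

Candidate variant pairs must be plausibly substitutable proteins, so pairs
are screened by Needleman-Wunsch global alignment under BLOSUM62 with affine
gap costs of 11 for gap existence plus 1 per residue (a length-L gap costs
11 + L, the BLAST-2-Sequences convention); end gaps are penalized. Similarity
is the fraction of identically aligned residues out of the length of the
longer input sequence, so it lives in [0, 1] regardless of alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN_DEFAULT = 11.0
GAP_EXTEND_DEFAULT = 1.0


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    similarity: float


@lru_cache(maxsize=8)
def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython charges open on the first gapped position and extend on each
    # subsequent one; open+extend, extend reproduces the 11 + 1*L total cost.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def sequence_similarity(n_identical: int, len_a: int, len_b: int) -> float:
    """Identical residues over the longer raw sequence length."""
    longer = max(len_a, len_b)
    if longer == 0:
        raise ValueError("both sequences are empty")
    sim = n_identical / longer
    if not 0.0 <= sim <= 1.0:
        raise ValueError(f"similarity {sim} outside [0, 1]")
    return sim


def align_global(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = GAP_OPEN_DEFAULT,
    gap_extend: float = GAP_EXTEND_DEFAULT,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Returns the canonical (first-traceback) optimal alignment; among
    co-optimal alignments the score is invariant, and the reported identity
    count refers to this canonical alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for name, seq in (("first", seq_a), ("second", seq_b)):
        bad = sorted(set(seq) - alphabet)
        if bad:
            raise ValueError(
                f"{name} sequence contains residues not in {matrix}: {bad}"
            )
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    row_a, row_b = str(best[0]), str(best[1])
    n_identical = sum(
        1 for ca, cb in zip(row_a, row_b) if ca == cb and ca != "-"
    )
    return AlignmentResult(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(best.score),
        n_identical=n_identical,
        similarity=sequence_similarity(n_identical, len(seq_a), len(seq_b)),
    )
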