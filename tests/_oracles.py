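"""Independent test oracles, kept free of any devswitch internals.

The alignment oracle is a plain three-matrix Gotoh dynamic program for
global alignment with affine gaps (a length-L gap costs open + ext*L) and
penalized end gaps. It shares no code with the package's aligner.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_NEG = -1e9
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_global_score(
    a: str, b: str, open_cost: float = 11.0, ext: float = 1.0
) -> float:
    """Optimal global affine-gap alignment score (score only)."""
    first = open_cost + ext  # cost of a gap's first residue
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in b (a aligned to gaps)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(open_cost + ext * i)
    for j in range(1, m + 1):
        Iy[0, j] = -(open_cost + ext * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - first, Ix[i - 1, j] - ext, Iy[i - 1, j] - first)
            Iy[i, j] = max(M[i, j - 1] - first, Iy[i, j - 1] - ext, Ix[i, j - 1] - first)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def bh_adjust_reference(p):
    """Textbook Benjamini-Hochberg step-up, written directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
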