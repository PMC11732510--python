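"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive results from first principles (quadratic DP,
all-offsets character comparison) and share no code with the package paths
they check.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(
    query: str, subject: str, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Smith-Waterman score with affine gaps, cost(k) = open + k * extend.

    Plain-Python Gotoh recursion; the maximum over the match matrix is the
    local alignment score (0 when no positive-scoring alignment exists).
    """
    m, n = len(query), len(subject)
    NEG = float("-inf")
    first = gap_open + gap_extend  # cost of the first gap residue
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (along subject)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject
    best = 0.0
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[qi, subject[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def brute_motif_scan(sequence: str, motifs) -> set[tuple[int, str]]:
    """All (offset, motif_id) pairs found by naive character comparison."""
    found = set()
    for motif in motifs:
        for start in range(len(sequence) - motif.length + 1):
            if all(
                sequence[start + off] == res
                for off, res in motif.required.items()
            ):
                found.add((start, motif.motif_id))
    return found
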