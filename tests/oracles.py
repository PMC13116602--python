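"""Independent reference implementations used only to check the package.

Deliberately naive: exhaustive enumeration for the fuzzy scan, textbook
Gotoh dynamic programming for the aligners.  They share no code with the
implementations they verify.
"""

from __future__ import annotations

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# fuzzy RCL scan
# ---------------------------------------------------------------------------


def brute_force_best_match(
    sequence: str,
    queries: dict[str, str],
    window_len: int,
    max_mismatch_fraction: float,
    forbid_adjacent: bool = True,
):
    """Enumerate every (query, offset) pair; return (qid, start, count) or None.

    Tie order: fewest mismatches, then smallest offset, then sorted query id.
    """
    seq = sequence.upper()
    n = len(seq)
    win_start = max(0, n - window_len)
    best = None
    for rank, qid in enumerate(sorted(queries)):
        q = queries[qid].upper()
        m = len(q)
        if m == 0:
            continue
        for start in range(win_start, n - m + 1):
            window = seq[start : start + m]
            mism = [
                i
                for i in range(m)
                if window[i] != q[i] or window[i] == "X" or q[i] == "X"
            ]
            budget = int(max_mismatch_fraction * m)
            if len(mism) > budget:
                continue
            if forbid_adjacent and any(b - a == 1 for a, b in zip(mism, mism[1:])):
                continue
            key = (len(mism), start, rank)
            if best is None or key < best[0]:
                best = (key, (qid, start, len(mism)))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Gotoh affine-gap alignment scores
# ---------------------------------------------------------------------------


def _score(matrix, x: str, y: str) -> float:
    try:
        return matrix[x, y]
    except (KeyError, IndexError):
        return matrix[y, x]


def gotoh_global_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score; gap of length L costs open+(L-1)*extend."""
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(matrix, a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal Smith-Waterman score with affine gaps (0 if none positive)."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = _score(matrix, a[i - 1], b[j - 1])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
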