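"""Independent brute-force alignment oracle for cross-checking scores.

A plain three-state Gotoh dynamic program written directly from the recurrence,
with explicit terminal-gap handling: gaps in row 0 / column 0 (left ends) and
in the last row / column (right ends) are charged at the terminal rate, all
other gaps at the internal rate.  Quadratic space, pure Python, no shared code
with the package's alignment path.
"""

from __future__ import annotations

NEG = float("-inf")


def oracle_global_score(
    ref: str,
    query: str,
    score_fn,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    terminal_factor: float = 0.5,
) -> float:
    """Optimal global alignment score; gap of length L costs open + (L-1)*extend."""
    n, m = len(ref), len(query)
    t_open = gap_open * terminal_factor
    t_ext = gap_extend * terminal_factor

    # M[i][j]: best ending in a match/mismatch at (i, j)
    # X[i][j]: best ending with ref[i] aligned to a gap (gap in query)
    # Y[i][j]: best ending with query[j] aligned to a gap (gap in ref)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(t_open + (i - 1) * t_ext)
    for j in range(1, m + 1):
        Y[0][j] = -(t_open + (j - 1) * t_ext)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(ref[i - 1], query[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            # vertical gap (in query); terminal when the query is exhausted
            # (j == m) or untouched (j == 0, handled in init)
            go, ge = (t_open, t_ext) if j == m else (gap_open, gap_extend)
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge, Y[i - 1][j] - go)
            # horizontal gap (in ref); terminal on the ref's ends
            go, ge = (t_open, t_ext) if i == n else (gap_open, gap_extend)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge, X[i][j - 1] - go)
    return max(M[n][m], X[n][m], Y[n][m])
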