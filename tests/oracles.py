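"""Independent reference implementations used only as test oracles.

These are deliberately naive, pure-Python routines — a triple-loop Gotoh
dynamic program, an explicit enumeration of all gapped local alignment
paths, sliding ungapped window comparison, and naive substring counting —
kept entirely separate from the package's alignment engine.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, score_pair, gap_open: float,
                      gap_extend: float) -> float:
    """Textbook affine-gap Smith-Waterman score by explicit DP.

    Gap convention matches the package: a gap of length g costs
    gap_open + (g-1)*gap_extend.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            diag = H[i - 1][j - 1] + score_pair(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def enumerate_local_score(a: str, b: str, score_pair, gap_open: float,
                          gap_extend: float) -> float:
    """Best local score by brute-force enumeration of every alignment path.

    Exponential; only for very short sequences.  Every monotone path of
    match/insert/delete moves from every start cell is scored, with affine
    gap costs tracked through the previous move.
    """
    n, m = len(a), len(b)
    best = 0.0

    def extend(i: int, j: int, cur: float, prev: str | None) -> None:
        nonlocal best
        if cur > best:
            best = cur
        if i < n and j < m:
            extend(i + 1, j + 1, cur + score_pair(a[i], b[j]), "M")
        if j < m:
            pen = gap_extend if prev == "E" else gap_open
            extend(i, j + 1, cur + pen, "E")
        if i < n:
            pen = gap_extend if prev == "F" else gap_open
            extend(i + 1, j, cur + pen, "F")

    for i in range(n):
        for j in range(m):
            extend(i, j, 0.0, None)
    return best


def best_ungapped_window_identity(window: str, subject: str,
                                  ambiguity: frozenset = frozenset("XBZU"),
                                  ) -> float:
    """Best percent identity of the window over all ungapped placements.

    The window may overhang the subject; overhanging columns count in the
    denominator and never as identities.
    """
    L = len(window)
    best = 0
    for off in range(-L + 1, len(subject)):
        matches = 0
        for i, c in enumerate(window):
            j = off + i
            if 0 <= j < len(subject) and c == subject[j] \
                    and c not in ambiguity:
                matches += 1
        if matches > best:
            best = matches
    return 100.0 * best / L


def naive_shared_kmers(query: str, subject: str, k: int = 8) -> int:
    """Distinct query k-mers appearing verbatim in the subject, by brute force."""
    found = set()
    for i in range(len(query) - k + 1):
        word = query[i:i + k]
        for j in range(len(subject) - k + 1):
            if subject[j:j + k] == word:
                found.add(word)
                break
    return len(found)
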