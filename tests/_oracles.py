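"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms from the package: reversal
distances come from breadth-first search over the reversal graph, and
maximal repeats from exhaustive per-(anti-)diagonal run scanning with
numpy. They are O(exponential) / O(L^2) and only usable at toy sizes.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_ENC = {c: i for i, c in enumerate("ACGTN")}
_COMP_CODE = np.array([3, 2, 1, 0, 9], dtype=np.int8)  # A<->T, C<->G, N -> no match


def bfs_reversal_distances(n: int) -> dict[tuple[int, ...], int]:
    """Exact reversal distance to identity for every signed permutation."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    queue = deque([ident])
    revs = [(i, j) for i in range(n) for j in range(i, n)]
    while queue:
        p = queue.popleft()
        dp = dist[p]
        for i, j in revs:
            c = p[:i] + tuple(-x for x in p[i : j + 1][::-1]) + p[j + 1 :]
            if c not in dist:
                dist[c] = dp + 1
                queue.append(c)
    return dist


def _runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs (stop inclusive)."""
    if not valid.any():
        return []
    padded = np.concatenate(([False], valid, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def brute_force_maximal_repeats(seq: str, min_len: int, include_inverted: bool = True):
    """All maximal repeated pairs >= min_len on a linear sequence.

    Returns the same canonical tuples as the package finder:
    (pos1, pos2, length, orientation) with pos1 <= pos2.
    """
    from plastarch.repeats import RepeatHit

    L = len(seq)
    a = np.array([_ENC[c] for c in seq], dtype=np.int8)
    not_n = a != _ENC["N"]
    hits = set()
    for d in range(1, L):
        valid = (a[:-d] == a[d:]) & not_n[:-d]
        for u, v in _runs(valid):
            if v - u + 1 >= min_len:
                hits.add(RepeatHit(u, u + d, v - u + 1, "direct"))
    if include_inverted:
        comp = _COMP_CODE[a]
        for c in range(min_len - 1, 2 * L - min_len):
            p0, p1 = max(0, c - L + 1), min(c, L - 1)
            valid = comp[p0 : p1 + 1] == a[c - p1 : c - p0 + 1][::-1]
            for ru, rv in _runs(valid):
                u, v = ru + p0, rv + p0
                if v - u + 1 < min_len:
                    continue
                mu = c - v
                if u < mu:
                    hits.add(RepeatHit(u, mu, v - u + 1, "inverted"))
                elif u == mu:  # palindrome: report the two halves
                    half = (v - u + 1) // 2
                    if half >= min_len:
                        hits.add(RepeatHit(u, u + half, half, "inverted"))
    return sorted(hits, key=lambda h: (h.pos1, h.pos2, h.orientation, -h.length))
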