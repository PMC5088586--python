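"""Maximal exact repeat detection and repeat-mask coverage.

A repeated pair is *maximal* when neither copy can be extended by one
position on either side without breaking the exact match (for inverted
pairs the match is to the reverse complement). Degenerate bases (N) never
match anything, including other Ns.

Detection is seed-and-extend over a ``min_len``-mer index. A direct pair
with copies ``min_len`` apart lives on a *diagonal* d = pos2 - pos1 where
matching positions form contiguous runs; an inverted pair lives on an
*anti-diagonal* c = pos1 + pos2 + length - 1 where position p of one copy
pairs with position c - p of the other. Each candidate seed is extended to
the full run it sits in; seeds already covered by a reported run are
skipped, so every maximal pair is extended exactly once. A run that is its
own mirror (a perfect palindrome) is reported as its two half-copies.

Circular sequences are seeded on the sequence extended by ``min_len - 1``
wrap-around bases and extended with indices modulo the genome length;
wrapped duplicates are removed by canonicalizing start coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .genome_io import merge_intervals

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class RepeatHit:
    """One maximal repeated pair; ``pos1 <= pos2`` canonically."""

    pos1: int
    pos2: int
    length: int
    orientation: str  # "direct" | "inverted"


@dataclass
class RepeatMask:
    intervals: list[tuple[int, int]]
    coverage: float


def find_maximal_repeats(
    seq: str,
    min_len: int = 30,
    include_inverted: bool = True,
    circular: bool = False,
    include_direct: bool = True,
    seed_len: int | None = None,
) -> list[RepeatHit]:
    """All maximal exact repeated pairs of length >= ``min_len``.

    Both direct and reverse-complement (inverted) pairs are reported, each
    unordered pair once; self-overlapping tandem copies are allowed.
    ``seed_len`` caps the k-mer size used for seeding (shorter seeds find
    the same maximal pairs at the cost of more candidate checks; useful
    when ``min_len`` is in the kilobases).
    """
    L = len(seq)
    k = min_len if seed_len is None else min(min_len, seed_len)
    if L < min_len or k < 2:
        return []
    ext = seq + (seq[: k - 1] if circular else "")

    index: dict[str, list[int]] = {}
    for i in range(len(ext) - k + 1):
        kmer = ext[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    def char(i: int) -> str:
        if circular:
            return seq[i % L]
        return seq[i] if 0 <= i < L else "\0"

    hits: set[RepeatHit] = set()
    covered: dict[tuple[str, int], list[tuple[int, int]]] = {}

    def is_covered(orient: str, key: int, i: int) -> bool:
        return any(u <= i and i + k - 1 <= v for u, v in covered.get((orient, key), ()))

    def canonical(p1: int, p2: int, length: int, orient: str) -> RepeatHit:
        if circular:
            p1, p2 = p1 % L, p2 % L
        a, b = min(p1, p2), max(p1, p2)
        return RepeatHit(a, b, length, orient)

    def run_around(p0: int, p1: int, valid) -> tuple[int, int]:
        """Maximal contiguous run of ``valid`` positions containing [p0, p1]."""
        u, v = p0, p1
        while v - u + 1 < L and valid(u - 1):
            u -= 1
        while v - u + 1 < L and valid(v + 1):
            v += 1
        return u, v

    for kmer, positions in index.items():
        if include_direct and len(positions) > 1:
            for ai in range(len(positions) - 1):
                for bi in range(ai + 1, len(positions)):
                    i, j = positions[ai], positions[bi]
                    d = j - i
                    if circular and d % L == 0:
                        continue  # the same position seen across the wrap
                    if is_covered("direct", d, i):
                        continue
                    u, v = run_around(
                        i, i + k - 1, lambda p: char(p) == char(p + d) and char(p) != "\0" and char(p) != "N"
                    )
                    covered.setdefault(("direct", d), []).append((u, v))
                    hits.add(canonical(u, u + d, v - u + 1, "direct"))
        if not include_inverted:
            continue
        rc = "".join(_COMP.get(c, "N") for c in reversed(kmer))
        if "N" in rc or rc not in index:
            continue
        if rc < kmer:
            continue  # handle each kmer/revcomp class once
        for i in positions:
            for j in index[rc]:
                if rc == kmer and j < i:
                    continue
                c = i + j + k - 1  # anti-diagonal: p pairs with c - p
                if is_covered("inverted", c, min(i, j)):
                    continue

                def ivalid(p: int, c: int = c) -> bool:
                    x, y = char(p), char(c - p)
                    return _COMP.get(x) == y

                u, v = run_around(min(i, j), min(i, j) + k - 1, ivalid)
                covered.setdefault(("inverted", c), []).append((u, v))
                mu, mv = c - v, c - u  # mirror run (the partner copy)
                if (mu, mv) != (u, v):
                    covered.setdefault(("inverted", c), []).append((mu, mv))
                    hits.add(canonical(u, mu, v - u + 1, "inverted"))
                else:  # self-mirror run: an exact palindrome, report the halves
                    half = (v - u + 1) // 2
                    if half >= k:
                        hits.add(canonical(u, u + half, half, "inverted"))

    return sorted(
        (h for h in hits if h.length >= min_len),
        key=lambda h: (h.pos1, h.pos2, h.orientation, -h.length),
    )


def mask_coverage(hits: list[RepeatHit], genome_len: int) -> RepeatMask:
    """Union of every interval participating in at least one hit.

    Overlapping copies are merged, so no base is counted twice; intervals
    running past the origin of a circular genome are wrapped.
    """
    raw: list[tuple[int, int]] = []
    for h in hits:
        if h.length > genome_len:
            raise ValidationError(f"hit length {h.length} exceeds genome ({genome_len} bp)")
        for p in (h.pos1, h.pos2):
            if p < 0 or p >= genome_len:
                raise ValidationError(f"hit position {p} outside genome of {genome_len} bp")
            e = p + h.length
            if e <= genome_len:
                raw.append((p, e))
            else:  # wraps the origin
                raw.append((p, genome_len))
                raw.append((0, e - genome_len))
    merged = merge_intervals(raw)
    masked = sum(e - s for s, e in merged)
    return RepeatMask(intervals=merged, coverage=masked / genome_len if genome_len else 0.0)
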