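"""Signed gene orders, reversal distance, and rearrangement rates.

Two annotated plastomes are reduced to a signed permutation over their
shared gene set (IR duplicates collapsed, trans-spliced genes anchored at
their 5'-most exon, the circle cut before an anchor gene). The minimum
number of reversals separating the orders is then the exact
Hannenhalli–Pevzner distance for linear signed permutations,

    d = (n + 1) - c + h + f,

where ``c`` counts breakpoint-graph cycles, ``h`` hurdles, and ``f`` is 1
for a fortress. Rearrangement rates are expressed as reversals per 1,000
nucleotide substitutions, with substitutions from a pairwise raw/JC69/K80
estimator (or supplied externally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import (
    DuplicationError,
    InsufficientDataError,
    SaturationError,
    UndefinedStatisticError,
    ValidationError,
)
from .genome_io import Plastome, is_conserved_gene


@dataclass
class SignedGeneOrder:
    """A signed permutation of the shared conserved genes of two genomes."""

    genes: list[tuple[str, int]]  # (name, +1/-1) in genomic order
    anchor: str
    perm: tuple[int, ...] = ()  # signed elements relative to the partner

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class BreakpointGraphSummary:
    n: int
    c: int
    h: int
    fortress: bool
    d: int


@dataclass
class RateEstimate:
    reversals: int
    substitutions: float
    rho: float  # reversals per 1,000 substitutions


@dataclass
class Reversal:
    """Reversal of positions ``start..end`` (0-based, inclusive) of the order."""

    start: int
    end: int


# ---------------------------------------------------------------------------
# Gene-order extraction


def _in_any(pos: int, regions: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in regions)


def _gene_markers(plastome: Plastome, gene_list, ir_regions):
    """One (name, position, sign) marker per conserved gene.

    IR-duplicated genes keep the copy in the first IR region (IR-A); a gene
    present more than once outside the IR is an annotation error.
    """
    markers: dict[str, list] = {}
    for f in plastome.features:
        if not is_conserved_gene(f, gene_list):
            continue
        pos = f.five_prime_position()
        sign = 1 if f.strand == "+" else -1
        markers.setdefault(f.name, []).append((pos, sign))
    out = {}
    for name, copies in markers.items():
        if len(copies) == 1:
            out[name] = copies[0]
            continue
        in_ir = [c for c in copies if _in_any(c[0], ir_regions)]
        outside = [c for c in copies if not _in_any(c[0], ir_regions)]
        if len(outside) > 1 or not in_ir and len(copies) > 1:
            raise DuplicationError(f"gene {name} duplicated outside the IR")
        if ir_regions:
            a_start = ir_regions[0][0]
            in_a = [c for c in in_ir if ir_regions[0][0] <= c[0] < ir_regions[0][1]]
            out[name] = in_a[0] if in_a else min(in_ir)
        else:
            out[name] = copies[0]
    return out


def _ir_regions(plastome: Plastome) -> list[tuple[int, int]]:
    regs = [
        (f.start, f.end)
        for f in plastome.features
        if f.kind == "IR"
    ]
    return sorted(regs)


def extract_shared_order(
    a: Plastome,
    b: Plastome,
    gene_list: set[str] | None = None,
    anchor: str | None = None,
) -> tuple[SignedGeneOrder, SignedGeneOrder]:
    """Reduce two annotated plastomes to a pair of signed gene orders.

    Genome ``a`` is mapped to the identity 1..n; genome ``b`` becomes a
    signed permutation relative to it. The circle is linearized by cutting
    before the anchor gene (default: the first shared gene of ``a``) and
    orienting it ``+``.
    """
    ma = _gene_markers(a, gene_list, _ir_regions(a))
    mb = _gene_markers(b, gene_list, _ir_regions(b))
    shared = sorted(set(ma) & set(mb))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared genes; need at least 3"
        )
    order_a = sorted(shared, key=lambda g: ma[g][0])
    order_b = sorted(shared, key=lambda g: mb[g][0])

    def linearize(order, markers, anchor_gene):
        i = order.index(anchor_gene)
        rot = order[i:] + order[:i]
        signs = [markers[g][1] for g in rot]
        if signs[0] < 0:  # flip the whole circle so the anchor reads +
            rot = [rot[0]] + rot[:0:-1]
            signs = [-markers[g][1] for g in rot]
        return list(zip(rot, signs))

    anchor_gene = anchor if anchor is not None else order_a[0]
    if anchor_gene not in shared:
        raise ValidationError(f"anchor gene {anchor_gene!r} not in shared set")
    genes_a = linearize(order_a, ma, anchor_gene)
    genes_b = linearize(order_b, mb, anchor_gene)

    index = {name: i + 1 for i, (name, _) in enumerate(genes_a)}
    sign_a = {name: s for name, s in genes_a}
    perm_b = tuple(index[name] * s * sign_a[name] for name, s in genes_b)
    perm_a = tuple(range(1, len(genes_a) + 1))
    return (
        SignedGeneOrder(genes=genes_a, anchor=anchor_gene, perm=perm_a),
        SignedGeneOrder(genes=genes_b, anchor=anchor_gene, perm=perm_b),
    )


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner distance


def _as_perm(order) -> tuple[int, ...]:
    perm = tuple(order.perm) if isinstance(order, SignedGeneOrder) else tuple(order)
    if sorted(abs(x) for x in perm) != list(range(1, len(perm) + 1)):
        raise ValidationError(f"not a signed permutation: {perm}")
    return perm


def _breakpoint_graph(perm: tuple[int, ...]):
    """Frame with 0/n+1, return point sequence, cycles, and gray edges."""
    n = len(perm)
    seq = [0]
    for x in perm:
        seq.extend((2 * x - 1, 2 * x) if x > 0 else (-2 * x, -2 * x - 1))
    seq.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(seq)}

    # cycles alternate black edges (adjacent positions 2i,2i+1) and gray
    # edges (values 2i,2i+1)
    visited = [False] * (n + 1)  # indexed by black edge i: positions (2i, 2i+1)
    cycles = 0
    for start in range(n + 1):
        if visited[start]:
            continue
        cycles += 1
        i = start
        side = 0  # enter black edge i at its left point
        while not visited[i]:
            visited[i] = True
            v = seq[2 * i + 1 - side]  # exit point of the black edge
            w = v + 1 if v % 2 == 0 else v - 1  # gray partner value
            p = pos[w]
            i, side = divmod(p, 2)  # next black edge, entered at side p % 2
    gray = []
    for i in range(n + 1):
        p, q = pos[2 * i], pos[2 * i + 1]
        if p > q:
            p, q = q, p
        if q - p > 1:  # span-1 gray edges are adjacencies, structurally inert
            gray.append((p, q, (p % 2) == (q % 2)))  # oriented iff same parity
    return seq, cycles, gray


def _components(gray):
    """Connected components of the gray-edge interleaving graph."""
    m = len(gray)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        p1, q1, _ = gray[i]
        for j in range(i + 1, m):
            p2, q2, _ = gray[j]
            crosses = (p1 < p2 < q1 < q2) or (p2 < p1 < q2 < q1)
            if crosses:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(m):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _hurdles_of(order_positions: list[tuple[int, int]]) -> set[int]:
    """Hurdles among unoriented components given (position, comp_id) pairs.

    A component is a hurdle iff its positions are contiguous in the circular
    sequence of positions belonging to unoriented components.
    """
    labels = [c for _, c in sorted(order_positions)]
    if not labels:
        return set()
    # collapse runs, circularly
    runs = [labels[0]]
    for lab in labels[1:]:
        if lab != runs[-1]:
            runs.append(lab)
    if len(runs) > 1 and runs[0] == runs[-1]:
        runs = runs[:-1]
    from collections import Counter

    counts = Counter(runs)
    return {lab for lab, k in counts.items() if k == 1}


def breakpoint_summary(order) -> BreakpointGraphSummary:
    """Exact reversal distance via the breakpoint graph.

    ``d = n + 1 - c + h + f`` with hurdles/fortress handled in full.
    """
    perm = _as_perm(order)
    n = len(perm)
    _, cycles, gray = _breakpoint_graph(perm)
    comps = _components(gray)
    unoriented = [
        comp for comp in comps if not any(gray[i][2] for i in comp)
    ]
    # positions of every gray-edge endpoint in each unoriented component
    upos = []
    for cid, comp in enumerate(unoriented):
        for i in comp:
            p, q, _ = gray[i]
            upos.append((p, cid))
            upos.append((q, cid))
    hurdle_ids = _hurdles_of(upos)
    h = len(hurdle_ids)
    fortress = False
    if h % 2 == 1 and h >= 3:
        # fortress iff every hurdle is a super-hurdle: removing it promotes
        # a previously non-hurdle unoriented component to hurdle status
        all_super = True
        for hid in hurdle_ids:
            remaining = [(p, c) for p, c in upos if c != hid]
            new_hurdles = _hurdles_of(remaining)
            promoted = new_hurdles - hurdle_ids
            if not promoted:
                all_super = False
                break
        fortress = all_super
    d = n + 1 - cycles + h + (1 if fortress else 0)
    return BreakpointGraphSummary(n=n, c=cycles, h=h, fortress=fortress, d=d)


def reversal_distance(order) -> int:
    """Minimum number of signed reversals sorting the order to identity."""
    return breakpoint_summary(order).d


def apply_reversal(perm: tuple[int, ...], start: int, end: int) -> tuple[int, ...]:
    """Reverse (and sign-flip) positions start..end inclusive."""
    return perm[:start] + tuple(-x for x in perm[start : end + 1][::-1]) + perm[end + 1 :]


def sorting_scenario(order) -> list[Reversal]:
    """A minimum-length sequence of reversals sorting the order to identity.

    Greedy: at each step some reversal lowers the distance by one (the
    distance is realizable), so scan all O(n^2) candidates.
    """
    perm = _as_perm(order)
    scenario: list[Reversal] = []
    d = reversal_distance(perm)
    while d > 0:
        n = len(perm)
        found = False
        for i in range(n):
            for j in range(i, n):
                cand = apply_reversal(perm, i, j)
                if reversal_distance(cand) == d - 1:
                    scenario.append(Reversal(i, j))
                    perm, d = cand, d - 1
                    found = True
                    break
            if found:
                break
        if not found:  # cannot happen for a correct distance
            raise ValidationError("no distance-decreasing reversal found")
    return scenario


# ---------------------------------------------------------------------------
# Substitution estimators and rates

_PURINES = frozenset("AG")


def pairwise_substitutions(
    seq_a: str, seq_b: str, model: str = "K80"
) -> float:
    """Estimated substitution count between two aligned sequences.

    Columns containing a gap or N in either sequence are dropped. ``raw``
    counts mismatches; JC69 and K80 multiply the closed-form corrected
    per-site distance by the number of retained sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError("aligned sequences must have equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    sites = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise UndefinedStatisticError("no comparable sites after filtering")
    mismatches = transitions + transversions
    if model == "raw":
        return float(mismatches)
    if model == "JC69":
        p = mismatches / sites
        if p >= 0.75:
            raise SaturationError(f"JC69 undefined at p = {p:.3f} >= 3/4")
        return -0.75 * math.log(1 - 4 * p / 3) * sites
    if model == "K80":
        P = transitions / sites
        Q = transversions / sites
        w1 = 1 - 2 * P - Q
        w2 = 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError("K80 undefined: sequences saturated")
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
        return d * sites
    raise ValidationError(f"unknown substitution model {model!r}")


def rearrangement_rate(r: int, s: float) -> RateEstimate:
    """Reversals per 1,000 nucleotide substitutions."""
    if s <= 0:
        raise UndefinedStatisticError("substitution count must be positive")
    return RateEstimate(reversals=r, substitutions=s, rho=1000.0 * r / s)
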