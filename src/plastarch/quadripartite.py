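"""Inverted-repeat detection and quadripartite genome maps.

Most plastomes carry two identical, oppositely oriented copies of a large
inverted repeat (IR) that split the circle into a large (SC1) and a small
(SC2) single-copy region. The IR is found as the longest pair of disjoint
segments where one equals the reverse complement of the other (exact match
by default — plastid IR copies are homogenized by gene conversion), and
the single-copy arcs are labeled by size, SC1 being the larger.

Junction reports describe the "ebb and flow" of the IR: for each of the
four IR/SC junctions, the overlapping (or nearest) gene and how many bp of
it lie inside the IR.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .genome_io import Plastome
from .repeats import find_maximal_repeats


@dataclass
class QuadripartiteMap:
    """IR-A/IR-B/SC1/SC2 partition of a circular genome.

    Intervals are 0-based half-open on the circle; an interval whose end
    exceeds the genome length wraps through the origin. ``ir_a`` is the
    copy with the smaller start coordinate.
    """

    ir_a: tuple[int, int]
    ir_b: tuple[int, int]
    ir_length: int
    sc1: tuple[int, int]
    sc2: tuple[int, int]
    genome_length: int

    @property
    def junction_coords(self) -> dict[str, int]:
        L = self.genome_length
        return {
            "SC1/IRa": self.ir_a[0] % L,
            "IRa/SC2": self.ir_a[1] % L,
            "SC2/IRb": self.ir_b[0] % L,
            "IRb/SC1": self.ir_b[1] % L,
        }


@dataclass
class JunctionEntry:
    junction: str
    position: int
    gene: str | None
    overlap_bp: int  # bp of that gene inside the IR (0 if intergenic junction)
    intergenic: bool


@dataclass
class JunctionReport:
    genome_id: str
    entries: list[JunctionEntry]


def _arc_len(s: int, e: int, L: int) -> int:
    return (e - s) % L or (L if s != e else 0)


def detect_inverted_repeat(
    plastome: Plastome, min_len: int = 5000
) -> QuadripartiteMap | None:
    """Locate the large IR, or return None if no pair reaches ``min_len``.

    The longest pair of disjoint, exactly reverse-complementary segments is
    taken, handling circular wrap; ties break on the smallest start
    coordinate. The two arcs between the copies become SC1 (larger) and
    SC2 (smaller).
    """
    L = plastome.length
    if L < 2 * min_len:
        return None
    hits = find_maximal_repeats(
        plastome.sequence,
        min_len=min_len,
        include_inverted=True,
        circular=plastome.circular,
        include_direct=False,
        seed_len=64,
    )
    best = None
    for h in sorted(hits, key=lambda h: (-h.length, h.pos1, h.pos2)):
        if h.orientation != "inverted" or h.length < min_len:
            continue
        # disjoint on the circle: copy2 must start after copy1 ends and
        # copy2's wrapped end must not reach back into copy1
        if h.pos2 < h.pos1 + h.length:
            continue
        if h.pos2 + h.length > L and (h.pos2 + h.length) % L > h.pos1:
            continue
        best = h
        break
    if best is None:
        return None
    ir_a = (best.pos1, best.pos1 + best.length)
    ir_b = (best.pos2, best.pos2 + best.length)
    arc1 = (ir_a[1] % L, ir_b[0])  # between end of IR-A and start of IR-B
    arc2 = (ir_b[1] % L, ir_a[0])
    l1, l2 = _arc_len(*arc1, L), _arc_len(*arc2, L)
    sc1, sc2 = (arc1, arc2) if l1 >= l2 else (arc2, arc1)
    return QuadripartiteMap(
        ir_a=ir_a,
        ir_b=ir_b,
        ir_length=best.length,
        sc1=sc1,
        sc2=sc2,
        genome_length=L,
    )


def _ir_overlap_bp(feature_intervals, ir_regions, L: int) -> int:
    """bp of the feature inside either IR copy (circle-aware)."""
    total = 0
    for fs, fe in feature_intervals:
        for s, e in ir_regions:
            for s2, e2 in _unwrap(s, e, L):
                lo, hi = max(fs, s2), min(fe, e2)
                if hi > lo:
                    total += hi - lo
    return total


def _unwrap(s: int, e: int, L: int):
    if e <= L:
        return [(s, e)]
    return [(s, L), (0, e - L)]


def junction_report(qmap: QuadripartiteMap, plastome: Plastome) -> JunctionReport:
    """Per-junction nearest/overlapping gene and its extent inside the IR."""
    L = plastome.length
    ir_regions = [qmap.ir_a, qmap.ir_b]
    genic = [
        f
        for f in plastome.features
        if f.kind in ("gene", "tRNA", "rRNA", "CDS", "orf")
    ]
    entries = []
    for name, pos in qmap.junction_coords.items():
        over = [
            f
            for f in genic
            if any(s <= pos < e or (e > L and pos < e - L) for s, e in f.intervals)
        ]
        if over:
            f = min(over, key=lambda f: f.span_bp)
            entries.append(
                JunctionEntry(
                    junction=name,
                    position=pos,
                    gene=f.name,
                    overlap_bp=_ir_overlap_bp(f.intervals, ir_regions, L),
                    intergenic=False,
                )
            )
        else:
            def circ_dist(f):
                d = min(
                    min((pos - e) % L, (s - pos) % L) for s, e in f.intervals
                )
                return d
            nearest = min(genic, key=circ_dist, default=None)
            entries.append(
                JunctionEntry(
                    junction=name,
                    position=pos,
                    gene=nearest.name if nearest else None,
                    overlap_bp=0,
                    intergenic=True,
                )
            )
    return JunctionReport(genome_id=plastome.id, entries=entries)


def compare_junctions(
    map_a: QuadripartiteMap | None,
    plastome_a: Plastome,
    map_b: QuadripartiteMap | None,
    plastome_b: Plastome,
) -> tuple[JunctionReport, JunctionReport]:
    """IR/SC junction reports for two genomes, for side-by-side comparison."""
    if map_a is None or map_b is None:
        raise ValidationError(
            "junction comparison requires a detected IR in both genomes"
        )
    return junction_report(map_a, plastome_a), junction_report(map_b, plastome_b)
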