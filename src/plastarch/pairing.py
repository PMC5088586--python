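"""EBS/IBS complementarity and group IIA intron mobility signatures.

Group IIA introns recognize their insertion sites through antiparallel
base pairing between three short motifs in intron domain I — EBS1, EBS2
and δ — and the complementary IBS1/IBS2 windows at the 3' end of the 5'
exon plus the δ′ position(s) at the start of the 3' exon. How well each
intron copy of a family pairs with *its own* target site, versus how
divergent the motifs are *between* copies, separates two dispersal
pathways: retrohoming after EBS sequence divergence (divergent motifs,
each perfectly matched to its site) and retrotransposition through
relaxed complementarity (near-constant motifs, imperfectly matched
sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .errors import AnnotationError, InsufficientDataError, ValidationError

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}

# D = inter-copy motif divergence; C = fraction of copies whose EBS1 and
# EBS2 both pair (near-)perfectly with their own site
DIVERGENCE_THRESHOLD = 0.2
SELF_COMPAT_RETROHOMING = 0.8
SELF_COMPAT_RETROTRANSPOSITION = 0.5


@dataclass
class TargetSite:
    """Exon context of one intron copy.

    ``exon5`` holds the last 24 nt of the 5' exon (positions -24..-1) and
    ``exon3`` the first 3 nt of the 3' exon. IBS windows are given in
    positions relative to the intron boundary: IBS1 abuts the boundary
    (default -6..-1), IBS2 sits immediately 5' of it (default -13..-7),
    and δ′ is the first ``delta_len`` nt of the 3' exon.
    """

    exon5: str
    exon3: str
    ibs1_window: tuple[int, int] = (-6, -1)
    ibs2_window: tuple[int, int] = (-13, -7)
    delta_len: int = 1

    def __post_init__(self) -> None:
        self.exon5 = self.exon5.upper()
        self.exon3 = self.exon3.upper()
        if self.ibs1_window[1] != -1:
            raise ValidationError("IBS1 must abut the intron boundary (end at -1)")
        if self.ibs2_window[1] != self.ibs1_window[0] - 1:
            raise ValidationError("IBS2 must lie immediately 5' of IBS1")
        if not 1 <= self.delta_len <= 3:
            raise ValidationError("delta' length must be 1-3 nt")
        if len(self.exon5) < -self.ibs2_window[0]:
            raise ValidationError("exon5 too short for the IBS2 window")
        if len(self.exon3) < self.delta_len:
            raise ValidationError("exon3 too short for delta'")

    def _window(self, w: tuple[int, int]) -> str:
        start, end = w  # negative, inclusive
        return self.exon5[len(self.exon5) + start : len(self.exon5) + end + 1]

    @property
    def ibs1(self) -> str:
        return self._window(self.ibs1_window)

    @property
    def ibs2(self) -> str:
        return self._window(self.ibs2_window)

    @property
    def delta_prime(self) -> str:
        return self.exon3[: self.delta_len]


@dataclass
class MotifAnnotation:
    """EBS1/EBS2/δ motif sequences of one intron copy (5'->3')."""

    ebs1: str
    ebs2: str
    delta: str
    coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ebs1 = self.ebs1.upper()
        self.ebs2 = self.ebs2.upper()
        self.delta = self.delta.upper()
        for name, motif in (("EBS1", self.ebs1), ("EBS2", self.ebs2)):
            if not 3 <= len(motif) <= 8:
                raise ValidationError(f"{name} must be 3-8 nt, got {len(motif)}")
        if not 1 <= len(self.delta) <= 3:
            raise ValidationError("delta must be 1-3 nt")

    @property
    def concatenated(self) -> str:
        return self.ebs1 + self.ebs2 + self.delta


@dataclass
class ElementPairing:
    """Pairing of one motif element against one exon window."""

    element: str
    pairing: str  # one char per paired column: W (WC), G (wobble), . (mismatch)
    n_wc: int
    n_wobble: int
    n_mismatch: int
    verdict: str  # perfect | near_perfect | incompatible


def pairing_profile(
    motif: str, window: str, allow_wobble: bool = True, element: str = ""
) -> ElementPairing:
    """Antiparallel pairing of an intron motif against an exon window.

    The motif is read 5'->3' against the window 3'->5'; Watson-Crick pairs
    and (optionally) G·T wobbles count as pairing. Verdicts: perfect = no
    mismatch, near_perfect = exactly one, else incompatible.
    """
    motif, window = motif.upper(), window.upper()
    if not motif or not window:
        raise ValidationError("motif and window must be non-empty")
    if abs(len(motif) - len(window)) > 2:
        raise AnnotationError(
            f"{element or 'element'}: motif/window lengths differ by more than 2"
        )
    n = min(len(motif), len(window))
    rev = window[::-1]
    chars = []
    n_wc = n_wob = n_mm = 0
    for i in range(n):
        duo = (motif[i], rev[i])
        if duo in WC_PAIRS:
            chars.append("W")
            n_wc += 1
        elif allow_wobble and duo in WOBBLE_PAIRS:
            chars.append("G")
            n_wob += 1
        else:
            chars.append(".")
            n_mm += 1
    verdict = "perfect" if n_mm == 0 else "near_perfect" if n_mm == 1 else "incompatible"
    return ElementPairing(element or "?", "".join(chars), n_wc, n_wob, n_mm, verdict)


def profile_intron(
    motifs: MotifAnnotation, site: TargetSite, allow_wobble: bool = True
) -> dict[str, ElementPairing]:
    """EBS1·IBS1, EBS2·IBS2 and δ·δ′ profiles for one intron copy."""
    return {
        "EBS1·IBS1": pairing_profile(motifs.ebs1, site.ibs1, allow_wobble, "EBS1·IBS1"),
        "EBS2·IBS2": pairing_profile(motifs.ebs2, site.ibs2, allow_wobble, "EBS2·IBS2"),
        "δ·δ′": pairing_profile(motifs.delta, site.delta_prime, allow_wobble, "δ·δ′"),
    }


def locate_ebs(
    intron_seq: str,
    search_region: tuple[int, int],
    window: str,
    length: int,
    allow_wobble: bool = True,
):
    """Best-pairing candidate motif of ``length`` nt within a search region.

    Scans every subsequence of the region, scoring WC + wobble pairings
    against the exon window; ties break to the smallest start. Returns
    (sequence, (start, end)) or None when nothing reaches length/2
    pairings.
    """
    s, e = search_region
    if not (0 <= s < e <= len(intron_seq)):
        raise ValidationError("search region outside the intron")
    if length > e - s:
        raise ValidationError("motif length exceeds the search region")
    best, best_score, best_start = None, -1, -1
    for start in range(s, e - length + 1):
        cand = intron_seq[start : start + length]
        prof = pairing_profile(cand, window[-length:] if len(window) > length else window,
                               allow_wobble)
        score = prof.n_wc + prof.n_wobble
        if score > best_score:
            best, best_score, best_start = cand, score, start
    if best is None or best_score < length / 2:
        return None
    return best, (best_start, best_start + length)


@dataclass
class ConsensusProfile:
    n_introns: int
    length: int
    column_multiplicity: list[int]  # max residue count per column (gaps excluded)

    def f(self, k: int) -> float:
        """Fraction of columns whose most common residue occurs >= k times."""
        if self.length == 0:
            return 0.0
        return sum(m >= k for m in self.column_multiplicity) / self.length


def consensus_conservation(aligned_introns: list[str], k: int | None = None):
    """Column-wise conservation of a gapped intron alignment.

    Gaps never count as residues. Returns the profile; if ``k`` is given,
    returns (profile, f(k)).
    """
    if len(aligned_introns) < 2:
        raise ValidationError("need at least two aligned sequences")
    lengths = {len(s) for s in aligned_introns}
    if len(lengths) != 1:
        raise ValidationError("ragged alignment: unequal sequence lengths")
    (ncol,) = lengths
    mult = []
    for col in range(ncol):
        counts: dict[str, int] = {}
        for s in aligned_introns:
            c = s[col].upper()
            if c not in "-.":
                counts[c] = counts.get(c, 0) + 1
        mult.append(max(counts.values()) if counts else 0)
    profile = ConsensusProfile(len(aligned_introns), ncol, mult)
    if k is None:
        return profile
    return profile, profile.f(k)


@dataclass
class MobilitySignature:
    verdict: str  # retrohoming_like | retrotransposition_like | indeterminate
    divergence: float  # D: mean pairwise mismatch fraction of concatenated motifs
    self_compatibility: float  # C: fraction of copies with (near-)perfect EBS1+EBS2
    evidence: pd.DataFrame


def mobility_signature(
    family: list[tuple[MotifAnnotation, TargetSite]],
    allow_wobble: bool = True,
    divergence_threshold: float = DIVERGENCE_THRESHOLD,
    self_compat_high: float = SELF_COMPAT_RETROHOMING,
    self_compat_low: float = SELF_COMPAT_RETROTRANSPOSITION,
) -> MobilitySignature:
    """Classify how an intron family spread to its sites.

    D is the mean pairwise mismatch fraction across the members'
    concatenated EBS1+EBS2+δ motifs; C is the fraction of members whose
    EBS1 and EBS2 both pair perfectly or near-perfectly with their own
    site. Retrohoming-like requires divergent motifs that still fit their
    sites (D >= 0.2 and C >= 0.8); retrotransposition-like requires poor
    self-compatibility (C < 0.5); anything else is indeterminate.
    """
    if len(family) < 3:
        raise InsufficientDataError(
            f"family of {len(family)} members; need at least 3"
        )
    motifs = [m.concatenated for m, _ in family]
    pair_div = []
    for a, b in combinations(motifs, 2):
        n = min(len(a), len(b))
        pair_div.append(sum(a[i] != b[i] for i in range(n)) / n)
    D = sum(pair_div) / len(pair_div)

    rows = []
    compatible = 0
    for idx, (motif, site) in enumerate(family):
        prof = profile_intron(motif, site, allow_wobble)
        ok = all(
            prof[e].verdict in ("perfect", "near_perfect")
            for e in ("EBS1·IBS1", "EBS2·IBS2")
        )
        compatible += ok
        rows.append(
            {
                "member": idx,
                "EBS1": prof["EBS1·IBS1"].verdict,
                "EBS2": prof["EBS2·IBS2"].verdict,
                "δ": prof["δ·δ′"].verdict,
                "self_compatible": ok,
            }
        )
    C = compatible / len(family)
    if D >= divergence_threshold and C >= self_compat_high:
        verdict = "retrohoming_like"
    elif C < self_compat_low:
        verdict = "retrotransposition_like"
    else:
        verdict = "indeterminate"
    evidence = pd.DataFrame(rows).set_index("member")
    evidence.attrs["D"] = D
    evidence.attrs["C"] = C
    return MobilitySignature(verdict, D, C, evidence)
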