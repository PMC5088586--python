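"""Synthetic plastomes with known ground truth.

Everything the pipeline measures can be planted: a quadripartite genome
with an exact inverted repeat housing the rRNA operon, gene orders
scrambled by a known number of reversals, i.i.d. nucleotide substitutions
at a known per-site distance, dispersed repeats at a target mask
coverage, and group IIA intron families whose EBS1/EBS2/δ motifs either
match each copy's own target site (retrohoming mode) or keep the
ancestral motifs against mismatched sites (retrotransposition mode).

A single top-level seed drives independent per-component substreams, so
regenerating one component never perturbs another; identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .genome_io import Feature, Plastome, reverse_complement
from .pairing import MotifAnnotation, TargetSite, profile_intron
from .introns import IntronRecord

_BASES = np.array(list("ACGT"))

# named after common plastid genes so synthetic annotations read naturally
_GENE_NAMES = (
    "atpA atpB atpE atpF atpH atpI ccsA cemA chlB chlL chlN clpP ftsH petA "
    "petB petD petG petL psaA psaB psaC psaJ psbA psbB psbC psbD psbE psbF "
    "psbH psbI psbJ psbK psbL psbM psbN psbT psbZ rbcL rpl2 rpl5 rpl14 rpl16 "
    "rpl20 rpl23 rpl36 rpoA rpoBa rpoBb rpoC1 rpoC2 rps2 rps3 rps4 rps7 rps8 "
    "rps9 rps11 rps12 rps14 rps18 rps19 tufA ycf1 ycf3 ycf4 ycf12 cysA cysT "
    "minD infA"
).split()
_RRNA_OPERON = (("rrs", 1400), ("trnI", 70), ("trnA", 70), ("rrl", 2700), ("rrf", 120))

# substream tags keep the per-component RNGs independent of one another
_STREAMS = {"sequence": 1, "layout": 2, "reversals": 3, "evolve": 4, "repeats": 5, "introns": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SimConfig:
    """Parameters of one synthetic study; identical configs reproduce byte-identically."""

    seed: int = 0
    genome_length: int = 50_000
    n_genes: int = 60
    ir_length: int = 8_000
    at_fraction: float = 0.70
    k_reversals: int = 0
    subst_distance: float = 0.10
    repeat_coverage_target: float = 0.10
    repeat_length_range: tuple[int, int] = (50, 400)
    family_size: int = 6
    mobility_mode: str = "retrohoming"
    ebs_divergence: float = 0.20
    site_mismatches: int = 2

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_genes, self.ir_length, self.k_reversals) < 0:
            raise ConfigError("counts and lengths must be non-negative")
        for frac in (self.at_fraction, self.repeat_coverage_target, self.ebs_divergence):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.repeat_coverage_target >= 0.5:
            raise ConfigError("repeat coverage target must be < 0.5")
        if self.mobility_mode not in ("retrohoming", "retrotransposition"):
            raise ConfigError(f"unknown mobility mode {self.mobility_mode!r}")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-simulation."""

    ir_a: tuple[int, int] | None = None
    ir_b: tuple[int, int] | None = None
    gene_order: list[tuple[str, int]] = field(default_factory=list)
    reversals: list[tuple[int, int]] = field(default_factory=list)
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)
    repeat_coverage: float = 0.0
    subst_distance: float = 0.0
    mobility_mode: str | None = None
    motifs: list[MotifAnnotation] = field(default_factory=list)
    sites: list[TargetSite] = field(default_factory=list)


def random_sequence(rng: np.random.Generator, length: int, at_fraction: float = 0.70) -> str:
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    draws = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(_BASES[draws])


# ---------------------------------------------------------------------------
# Quadripartite plastome


def _place_genes(rng, names, region_start, region_len, pad=40, min_gap=30):
    """Lay genes head-to-tail with random intergenic gaps inside a region."""
    lengths = [int(rng.integers(200, 600)) for _ in names]
    need = sum(lengths) + pad * 2 + min_gap * (len(names) + 1)
    if need > region_len:
        raise ConfigError(
            f"cannot fit {len(names)} genes ({need} bp) in a {region_len} bp region"
        )
    slack = region_len - sum(lengths) - 2 * pad
    weights = rng.random(len(names) + 1)
    gaps = (weights / weights.sum() * (slack - min_gap * (len(names) + 1))).astype(int) + min_gap
    feats = []
    pos = region_start + pad + int(gaps[0])
    for name, ln, gap in zip(names, lengths, gaps[1:]):
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(Feature(name, "gene", strand, [(pos, pos + ln)]))
        pos += ln + int(gap)
    return feats


def simulate_plastome(config: SimConfig) -> tuple[Plastome, GroundTruth]:
    """A circular genome with named stranded genes and an exact planted IR.

    The IR copies contain the rRNA-operon block (duplicated by name, the
    IR-B copy on the minus strand); the single-copy arcs carry
    ``n_genes`` protein/tRNA-style genes; the rest is random intergenic
    sequence at the configured A+T fraction.
    """
    L, ir = config.genome_length, config.ir_length
    seq_rng = _rng(config.seed, "sequence")
    lay_rng = _rng(config.seed, "layout")
    if ir and ir < sum(ln for _, ln in _RRNA_OPERON) + 600:
        raise ConfigError(f"IR of {ir} bp cannot hold the rRNA operon block")
    if 2 * ir >= L:
        raise ConfigError("IR copies would cover the whole genome")

    names = [
        _GENE_NAMES[i] if i < len(_GENE_NAMES) else f"gen{i + 1}"
        for i in range(config.n_genes)
    ]
    sc_total = L - 2 * ir
    sc1_len = int(sc_total * 0.63)
    sc2_len = sc_total - sc1_len
    n1 = max(0, int(round(config.n_genes * sc1_len / max(sc_total, 1))))
    if config.n_genes and n1 == 0:
        n1 = config.n_genes
    sc1_start, ira_start = 0, sc1_len
    sc2_start = ira_start + ir
    irb_start = sc2_start + sc2_len

    seq = list(random_sequence(seq_rng, L, config.at_fraction))
    feats: list[Feature] = []
    truth = GroundTruth()
    feats += _place_genes(lay_rng, names[:n1], sc1_start, sc1_len) if n1 else []
    feats += _place_genes(lay_rng, names[n1:], sc2_start, sc2_len) if config.n_genes > n1 else []

    if ir:
        # rRNA operon inside IR-A, mirrored by coordinate into IR-B
        pos = ira_start + 200
        rrna_feats = []
        for name, ln in _RRNA_OPERON:
            rrna_feats.append(Feature(name, "rRNA" if name.startswith("rr") else "tRNA", "+", [(pos, pos + ln)]))
            pos += ln + 120
        ira_end, irb_end = ira_start + ir, irb_start + ir
        seq[irb_start:irb_end] = reverse_complement("".join(seq[ira_start:ira_end]))
        for f in rrna_feats:
            (s, e), = f.intervals
            ms, me = irb_start + (ira_end - e), irb_start + (ira_end - s)
            feats.append(f)
            feats.append(Feature(f.name, f.kind, "-", [(ms, me)], {"ir_copy": "B"}))
        feats.append(Feature("IR-A", "IR", "+", [(ira_start, ira_end)]))
        feats.append(Feature("IR-B", "IR", "-", [(irb_start, irb_end)]))
        truth.ir_a, truth.ir_b = (ira_start, ira_end), (irb_start, irb_end)
        # enforce maximality of the planted IR: break both one-step extensions
        if seq[ira_start - 1] == reverse_complement(seq[irb_end % L]):
            seq[ira_start - 1] = "A" if seq[ira_start - 1] != "A" else "C"
        if seq[ira_end] == reverse_complement(seq[irb_start - 1]):
            seq[ira_end] = "A" if seq[ira_end] != "A" else "C"

    plastome = Plastome("sim", "".join(seq), True, sorted(feats, key=lambda f: f.start))
    gene_like = [f for f in plastome.features if f.kind in ("gene", "tRNA", "rRNA")]
    truth.gene_order = [(f.name, 1 if f.strand == "+" else -1) for f in gene_like]
    return plastome, truth


# ---------------------------------------------------------------------------
# Gene-order reversals


def _cut_candidates(plastome: Plastome) -> list[int]:
    """Midpoints of intergenic gaps outside the IR (no wrap gap)."""
    protected = [(f.start, f.end) for f in plastome.features if f.kind == "IR"]
    genes = sorted(
        (f for f in plastome.features if f.kind in ("gene", "tRNA", "rRNA")),
        key=lambda f: f.start,
    )
    cuts = []
    for a, b in zip(genes, genes[1:]):
        if b.start <= a.end:
            continue
        mid = (a.end + b.start) // 2
        if any(s <= mid < e for s, e in protected):
            continue
        cuts.append(mid)
    return cuts


def _order_distance(original: Plastome, current: Plastome) -> int:
    """Reversal distance between positional gene orders (single-copy genes)."""
    from .rearrangement import reversal_distance

    def order(g: Plastome):
        feats = sorted(
            (f for f in g.features if f.kind in ("gene", "tRNA", "rRNA")),
            key=lambda f: f.start,
        )
        names = [f.name for f in feats]
        return [
            (f.name, 1 if f.strand == "+" else -1)
            for f in feats
            if names.count(f.name) == 1
        ]

    base = order(original)
    index = {name: i + 1 for i, (name, _) in enumerate(base)}
    sign0 = dict(base)
    perm = tuple(index[n] * s * sign0[n] for n, s in order(current))
    return reversal_distance(perm)


def apply_reversals(
    plastome: Plastome, k: int, seed: int
) -> tuple[Plastome, GroundTruth]:
    """Apply ``k`` effective random segmental reversals between gene boundaries.

    Each reversal flips a sequence segment (and the strands and order of
    the genes inside it); segments never split a gene and never leave a
    single-copy arc. A draw that fails to raise the reversal distance by
    one (e.g. a segment that undoes an earlier draw) is resampled, so the
    planted ``k`` is the true minimum distance. The truth records each
    reversal's endpoints.
    """
    rng = _rng(seed, "reversals")
    truth = GroundTruth(reversals=[])
    current = plastome
    for step in range(k):
        cuts = _cut_candidates(current)
        if len(cuts) < 2:
            raise ConfigError("not enough intergenic cut points for a reversal")
        protected = [(f.start, f.end) for f in current.features if f.kind == "IR"]
        for _attempt in range(300):
            i, j = sorted(rng.choice(len(cuts), size=2, replace=False))
            c1, c2 = cuts[i], cuts[j]
            if any(c1 <= s < c2 for s, _ in protected):
                continue  # segment must stay within one single-copy arc
            inside = [
                f
                for f in current.features
                if f.kind in ("gene", "tRNA", "rRNA") and c1 <= f.start and f.end <= c2
            ]
            if not inside:
                continue
            seq = (
                current.sequence[:c1]
                + reverse_complement(current.sequence[c1:c2])
                + current.sequence[c2:]
            )
            feats = []
            for f in current.features:
                if c1 <= f.start and f.end <= c2:
                    ivs = [(c1 + c2 - e, c1 + c2 - s) for s, e in reversed(f.intervals)]
                    strand = "-" if f.strand == "+" else "+"
                    feats.append(
                        Feature(f.name, f.kind, strand, ivs, dict(f.attributes), f.wraps)
                    )
                else:
                    feats.append(f)
            candidate = Plastome(
                current.id, seq, current.circular, sorted(feats, key=lambda f: f.start)
            )
            if _order_distance(plastome, candidate) == step + 1:
                break
        else:  # pragma: no cover
            raise ConfigError("could not sample an effective reversal")
        current = candidate
        truth.reversals.append((c1, c2))
    truth.gene_order = [
        (f.name, 1 if f.strand == "+" else -1)
        for f in current.features
        if f.kind in ("gene", "tRNA", "rRNA")
    ]
    return current, truth


# ---------------------------------------------------------------------------
# Sequence evolution


def evolve_sequence(
    seq: str, distance: float, model: str = "JC69", kappa: float = 2.0, seed: int = 0
) -> str:
    """Mutate a sequence by i.i.d. per-site substitution at a given distance.

    ``distance`` is the expected number of substitutions per site (the
    model's branch length), under JC69 or K80 with transition/transversion
    ratio ``kappa``.
    """
    if distance < 0:
        raise ConfigError("distance must be >= 0")
    rng = _rng(seed, "evolve")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        code[ord(c)] = i
    idx = code[arr]
    sites = idx >= 0
    n = int(sites.sum())
    if n == 0 or distance == 0:
        return seq
    if model == "JC69":
        p_change = 0.75 * (1 - np.exp(-4 * distance / 3))
        change = rng.random(n) < p_change
        shift = rng.integers(1, 4, size=n)
        new = (idx[sites] + np.where(change, shift, 0)) % 4
    elif model == "K80":
        e1 = np.exp(-4 * distance / (kappa + 2))
        e2 = np.exp(-2 * distance * (kappa + 1) / (kappa + 2))
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv_each = 0.25 - 0.25 * e1
        u = rng.random(n)
        # base order ACGT: transition partner = A<->G, C<->T
        ts_partner = np.array([2, 3, 0, 1])
        tv1 = np.array([1, 0, 1, 0])  # a transversion target
        tv2 = np.array([3, 2, 3, 2])  # the other transversion target
        cur = idx[sites]
        new = cur.copy()
        new = np.where(u < p_ts, ts_partner[cur], new)
        new = np.where((u >= p_ts) & (u < p_ts + p_tv_each), tv1[cur], new)
        new = np.where(
            (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each), tv2[cur], new
        )
    else:
        raise ConfigError(f"unknown evolution model {model!r}")
    out = arr.copy()
    out[sites] = np.frombuffer("ACGT".encode(), dtype=np.uint8)[new]
    return out.tobytes().decode()


# ---------------------------------------------------------------------------
# Dispersed repeats


def plant_repeats(
    plastome: Plastome,
    coverage_target: float,
    length_range: tuple[int, int] = (50, 400),
    seed: int = 0,
    orientation: str = "both",
) -> tuple[Plastome, GroundTruth]:
    """Overwrite intergenic stretches with repeated segment pairs.

    Fresh random segments are written at two free intergenic locations
    each (second copy reverse-complemented for inverted pairs) until the
    union of planted intervals reaches the coverage target. The truth
    stores the exact planted intervals.
    """
    if not 0 <= coverage_target < 0.5:
        raise ConfigError("coverage target must be in [0, 0.5)")
    if orientation not in ("both", "direct", "inverted"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    rng = _rng(seed, "repeats")
    L = plastome.length
    busy = [
        iv
        for f in plastome.features
        if f.kind in ("gene", "tRNA", "rRNA", "IR", "intron")
        for iv in f.intervals
    ]
    free: list[tuple[int, int]] = []
    prev = 0
    for s, e in sorted(busy) + [(L, L)]:
        if s - prev >= length_range[0] + 4:
            free.append((prev + 2, s - 2))
        prev = max(prev, e)
    seq = list(plastome.sequence)
    truth = GroundTruth(repeat_intervals=[])
    planted_bp = 0
    target_bp = coverage_target * L

    def take_slot(length: int) -> tuple[int, int] | None:
        fits = [i for i, (s, e) in enumerate(free) if e - s >= length + 2]
        if not fits:
            return None
        i = fits[int(rng.integers(len(fits)))]
        s, e = free.pop(i)
        off = int(rng.integers(s + 1, e - length))
        if off - s >= length_range[0] + 4:
            free.append((s, off - 1))
        if e - (off + length) >= length_range[0] + 4:
            free.append((off + length + 1, e))
        return off, off + length

    while planted_bp < target_bp:
        caps = sorted((e - s - 2 for s, e in free), reverse=True)
        if len(caps) < 2 or caps[1] < length_range[0]:
            raise ConfigError(
                f"insufficient intergenic space: planted {planted_bp / L:.3f}, "
                f"target {coverage_target:.3f}"
            )
        hi = min(length_range[1], caps[1])  # both copies must fit somewhere
        ln = int(rng.integers(length_range[0], hi + 1))
        slot1 = take_slot(ln)
        slot2 = take_slot(ln)
        if slot1 is None or slot2 is None:  # pragma: no cover
            raise ConfigError("slot bookkeeping exhausted unexpectedly")
        segment = random_sequence(rng, ln, 0.5)
        orient = orientation if orientation != "both" else ("direct", "inverted")[int(rng.integers(2))]
        seq[slot1[0] : slot1[1]] = segment
        seq[slot2[0] : slot2[1]] = (
            segment if orient == "direct" else reverse_complement(segment)
        )
        for s, e in (slot1, slot2):
            truth.repeat_intervals.append((s, e))
            planted_bp += e - s
    truth.repeat_coverage = planted_bp / L
    out = Plastome(plastome.id, "".join(seq), plastome.circular, list(plastome.features))
    return out, truth


# ---------------------------------------------------------------------------
# Group IIA intron families


def _mutate(rng, seq: str, rate: float, protect: set[int] = frozenset()) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protect or rng.random() >= rate:
            continue
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def plant_intron_family(
    config: SimConfig,
) -> tuple[Plastome, list[IntronRecord], list[tuple[MotifAnnotation, TargetSite]], GroundTruth]:
    """A family of related IIA intron copies planted at distinct sites.

    One ancestral intron core is copied into ``family_size`` host genes.
    In retrohoming mode each copy's EBS1/EBS2/δ are rewritten to the
    reverse complement of its own IBS windows (at most one residual
    mismatch), so motifs diverge between copies but fit their sites; in
    retrotransposition mode all copies keep the ancestral motifs and the
    sites are resampled until every element carries at least
    ``site_mismatches`` mismatches.
    """
    if config.family_size < 3:
        raise ConfigError("family size must be >= 3")
    rng = _rng(config.seed, "introns")
    core_len = 380
    ebs2_at, ebs1_at, delta_at = (100, 107), (150, 156), (156, 157)
    core = "GTGCG" + random_sequence(rng, core_len - 7, 0.6) + "AT"
    host_names = ["atpA", "atpI", "petB", "psaB", "psbB", "psbC"] + [
        f"hostGene{i}" for i in range(7, config.family_size + 1)
    ]
    host_names = host_names[: config.family_size]

    mode = config.mobility_mode
    motif_idx = set(range(*ebs2_at)) | set(range(*ebs1_at)) | set(range(*delta_at))
    for _attempt in range(100):
        hosts, sites, motifs, copies, offsets = [], [], [], [], []
        for _ in range(config.family_size):
            host = random_sequence(rng, 600, 0.55)
            off = int(rng.integers(100, 500))
            site = TargetSite(exon5=host[off - 24 : off], exon3=host[off : off + 3])
            intron = _mutate(rng, core, 0.02, protect=motif_idx)
            if mode == "retrohoming":
                ebs1 = reverse_complement(site.ibs1)
                ebs2 = reverse_complement(site.ibs2)
                delta = reverse_complement(site.delta_prime)
                if rng.random() < 0.3:  # at most one residual mismatch
                    which = int(rng.integers(len(ebs1)))
                    alt = [b for b in "ACGT" if b != ebs1[which]]
                    ebs1 = ebs1[:which] + alt[int(rng.integers(3))] + ebs1[which + 1 :]
            else:
                ebs1 = core[ebs1_at[0] : ebs1_at[1]]
                ebs2 = core[ebs2_at[0] : ebs2_at[1]]
                delta = core[delta_at[0] : delta_at[1]]
            intron = (
                intron[: ebs2_at[0]] + ebs2 + intron[ebs2_at[1] : ebs1_at[0]]
                + ebs1 + delta + intron[delta_at[1] :]
            )
            motif = MotifAnnotation(
                ebs1, ebs2, delta, {"EBS1": ebs1_at, "EBS2": ebs2_at, "δ": delta_at}
            )
            hosts.append(host)
            offsets.append(off)
            sites.append(site)
            motifs.append(motif)
            copies.append(intron)
        if mode == "retrohoming":
            concat = [m.concatenated for m in motifs]
            n = len(concat)
            div = [
                sum(a != b for a, b in zip(concat[i], concat[j])) / len(concat[i])
                for i in range(n)
                for j in range(i + 1, n)
            ]
            if sum(div) / len(div) >= config.ebs_divergence:
                break
        else:
            ok = True
            for motif, site in zip(motifs, sites):
                prof = profile_intron(motif, site)
                if any(
                    prof[e].n_mismatch < config.site_mismatches
                    for e in ("EBS1·IBS1", "EBS2·IBS2")
                ):
                    ok = False
                    break
            if ok:
                break
    else:  # pragma: no cover
        raise ConfigError("could not satisfy the mobility-mode constraints")

    # assemble one genome: host genes with their intron copies, spaced out
    seq_parts, feats, records = [], [], []
    pos = 0
    spacer = random_sequence(rng, 200, config.at_fraction)
    for name, host, off, intron in zip(host_names, hosts, offsets, copies):
        seq_parts.append(spacer)
        pos += len(spacer)
        exon1 = (pos, pos + off)
        intron_iv = (pos + off, pos + off + len(intron))
        exon2 = (intron_iv[1], intron_iv[1] + len(host) - off)
        feats.append(Feature(name, "gene", "+", [exon1, exon2]))
        feats.append(
            Feature(f"{name}-intron", "intron", "+", [intron_iv], {"intron_class": "IIA"})
        )
        records.append(
            IntronRecord(
                taxon="sim",
                host_gene=name,
                intron_class="IIA",
                splicing="cis",
                site=off,
                sequence=intron,
            )
        )
        seq_parts.append(host[:off] + intron + host[off:])
        pos = exon2[1]
    seq_parts.append(spacer)
    genome = Plastome("sim_introns", "".join(seq_parts), True, feats)
    truth = GroundTruth(mobility_mode=mode, motifs=list(motifs), sites=list(sites))
    return genome, records, list(zip(motifs, sites)), truth


# ---------------------------------------------------------------------------


def simulate_pair(config: SimConfig) -> tuple[Plastome, Plastome, GroundTruth]:
    """A pair of genomes separated by known reversals and substitutions."""
    ancestor, truth = simulate_plastome(config)
    derived, rev_truth = apply_reversals(ancestor, config.k_reversals, config.seed)
    mutated = evolve_sequence(
        derived.sequence, config.subst_distance, "K80", seed=config.seed
    )
    irs = sorted(
        (f.intervals[0] for f in derived.features if f.kind == "IR"),
        key=lambda iv: iv[0],
    )
    if len(irs) == 2:  # IR copies are homogenized, as by gene conversion
        (a1, a2), (b1, b2) = irs
        seq = list(mutated)
        seq[b1:b2] = reverse_complement("".join(seq[a1:a2]))
        if seq[a1 - 1] == reverse_complement(seq[b2 % len(seq)]):
            seq[a1 - 1] = "A" if seq[a1 - 1] != "A" else "C"
        if seq[a2] == reverse_complement(seq[b1 - 1]):
            seq[a2] = "A" if seq[a2] != "A" else "C"
        mutated = "".join(seq)
    derived = Plastome(ancestor.id + "_derived", mutated, True, derived.features)
    truth.reversals = rev_truth.reversals
    truth.subst_distance = config.subst_distance
    return ancestor, derived, truth
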