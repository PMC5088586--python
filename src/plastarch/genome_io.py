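"""Plastome sequences, features, and genome accounting.

The in-memory model is a :class:`Plastome` — a circular DNA sequence plus an
ordered list of typed, stranded :class:`Feature` records. Internally all
coordinates are 0-based half-open; every file format read or written here
(GenBank-style feature tables, the TSV feature dialect, GFF3) uses 1-based
inclusive coordinates, so the conversion happens at exactly one boundary.

Features that wrap the circular origin are stored unwrapped as two intervals
with ``wraps=True`` so interval arithmetic stays linear.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import CoordinateError, FormatError, UndefinedStatisticError

KNOWN_KINDS = {"gene", "CDS", "tRNA", "rRNA", "intron", "orf", "repeat_region", "IR"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U->T, collapse everything else outside ACGT to N."""
    seq = raw.upper().replace("U", "T")
    return re.sub(r"[^ACGT]", "N", seq)


@dataclass
class Feature:
    """A typed, stranded annotation on a plastome.

    ``intervals`` is an ordered list of 0-based half-open ``(start, end)``
    pairs; multi-interval features (trans-spliced genes, origin-wrapping
    features) keep their interval order. ``attributes`` holds free-form
    key/value metadata (``intron_class``, ``trans_spliced`` ...).
    """

    name: str
    kind: str
    strand: str
    intervals: list[tuple[int, int]]
    attributes: dict[str, str] = field(default_factory=dict)
    wraps: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("feature name must be non-empty")
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.name}")
        if not self.intervals:
            raise FormatError(f"feature {self.name} has no intervals")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise CoordinateError(f"bad interval ({s}, {e}) in {self.name}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def span_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def five_prime_position(self) -> int:
        """Genomic coordinate of the 5'-most base (strand-aware)."""
        if self.strand == "+":
            return self.intervals[0][0]
        return self.intervals[-1][1] - 1


@dataclass
class Plastome:
    """A circular plastid genome with its annotations."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if re.search(r"[^ACGTN]", self.sequence):
            raise FormatError(f"{self.id}: non-normalized characters in sequence")
        for f in self.features:
            if f.end > self.length:
                raise CoordinateError(
                    f"{self.id}: feature {f.name} interval exceeds length {self.length}"
                )

    def feature_sequence(self, feature: Feature) -> str:
        parts = [self.sequence[s:e] for s, e in feature.intervals]
        seq = "".join(parts)
        return reverse_complement(seq) if feature.strand == "-" else seq

    def rotated(self, offset: int) -> "Plastome":
        """Rotate the circular origin so old position ``offset`` becomes 0.

        Features are re-based; a feature that now spans the new origin is
        split into two intervals with ``wraps=True``.
        """
        n = self.length
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            ivs = []
            for s, e in f.intervals:
                s2, e2 = (s - offset) % n, (e - offset) % n or n
                if s2 < e2:
                    ivs.append([(s2, e2)])
                else:  # wraps the new origin
                    ivs.append([(s2, n), (0, e2)])
            flat = [iv for group in ivs for iv in group]
            wraps = any(len(group) > 1 for group in ivs)
            feats.append(
                Feature(f.name, f.kind, f.strand, flat, dict(f.attributes), wraps)
            )
        return Plastome(self.id, seq, self.circular, feats)


@dataclass
class GenomeStats:
    """Genome accounting in the style of a comparative-features table."""

    length: int
    at_fraction: float
    n_conserved_genes: int | None = None
    coding_fraction: float | None = None
    intron_fraction: float | None = None
    intergenic_fraction: float | None = None
    mean_intergenic_size: float | None = None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[Plastome]:
    """Read one or more plastomes from FASTA, normalizing the alphabet.

    Record ids are the first whitespace-delimited header token. A record
    whose sequence is more than 10% outside {A,C,G,T,N} (after RNA->DNA
    mapping) is rejected as non-nucleotide.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    out = []
    for rec in records:
        raw = str(rec.seq).upper().replace("U", "T")
        if not raw:
            raise FormatError(f"{rec.id}: empty sequence")
        n_bad = sum(1 for c in raw if c not in "ACGTN")
        if n_bad > 0.1 * len(raw):
            raise FormatError(f"{rec.id}: >10% non-nucleotide characters")
        out.append(Plastome(id=rec.id, sequence=normalize_sequence(raw)))
    return out


def write_fasta(plastomes: list[Plastome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for p in plastomes:
            fh.write(f">{p.id}\n")
            for i in range(0, p.length, width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables

_LOC_RE = re.compile(r"^\s*(complement|join|order)\s*\((.*)\)\s*$", re.I)


def _split_args(text: str) -> list[str]:
    args, depth, cur = [], 0, []
    for ch in text:
        if ch == "," and depth == 0:
            args.append("".join(cur))
            cur = []
        else:
            depth += ch == "("
            depth -= ch == ")"
            cur.append(ch)
    args.append("".join(cur))
    return args


def parse_location(text: str) -> tuple[list[tuple[int, int]], str]:
    """Parse a GenBank location string into 0-based intervals and a strand."""
    m = _LOC_RE.match(text)
    if m:
        op, inner = m.group(1).lower(), m.group(2)
        if op == "complement":
            ivs, strand = parse_location(inner)
            if strand == "-":
                raise FormatError(f"nested complement in {text!r}")
            return ivs, "-"
        parts = [parse_location(a) for a in _split_args(inner)]
        strands = {s for _, s in parts}
        strand = "-" if strands == {"-"} else "+"
        ivs = [iv for p, _ in parts for iv in p]
        return ivs, strand
    m = re.match(r"^\s*<?(\d+)\s*\.\.\s*>?(\d+)\s*$", text)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if a > b:
            raise FormatError(f"reversed range in location {text!r}")
        return [(a - 1, b)], "+"
    m = re.match(r"^\s*(\d+)\s*$", text)
    if m:
        a = int(m.group(1))
        return [(a - 1, a)], "+"
    raise FormatError(f"cannot parse location {text!r}")


def _finish_feature(kind, location, qualifiers, declared_length):
    intervals, strand = parse_location(location)
    if declared_length is not None:
        for s, e in intervals:
            if e > declared_length:
                raise CoordinateError(
                    f"interval ({s + 1}..{e}) outside sequence of length {declared_length}"
                )
    name = (
        qualifiers.get("gene")
        or qualifiers.get("name")
        or qualifiers.get("label")
        or qualifiers.get("locus_tag")
        or kind
    )
    attrs = {k: v for k, v in qualifiers.items()}
    if kind not in KNOWN_KINDS:
        warnings.warn(f"unknown feature kind {kind!r}; kept as attribute")
        attrs["original_kind"] = kind
        kind = "gene" if kind in ("mRNA", "exon") else "orf"
    return Feature(name=name, kind=kind, strand=strand, intervals=intervals, attributes=attrs)


def _read_genbank_ft(lines, declared_length):
    feats = []
    kind = location = None
    qualifiers: dict[str, str] = {}
    for line in lines:
        if not line.strip() or line.startswith("FEATURES"):
            continue
        stripped = line.strip()
        if stripped.startswith("/"):
            m = re.match(r"/([\w\-]+)(?:=(.*))?$", stripped)
            if m:
                qualifiers[m.group(1)] = (m.group(2) or "true").strip('"')
            continue
        cols = stripped.split(None, 1)
        if len(cols) == 2 and re.match(r"^[<>\d(cjo]", cols[1]):
            if kind is not None:
                feats.append(_finish_feature(kind, location, qualifiers, declared_length))
            kind, location, qualifiers = cols[0], cols[1], {}
        elif kind is not None and location is not None:
            location += stripped  # continuation of a long location
    if kind is not None:
        feats.append(_finish_feature(kind, location, qualifiers, declared_length))
    return feats


def _parse_attrs(text: str) -> dict[str, str]:
    attrs = {}
    for part in re.split(r"[;]", text or ""):
        part = part.strip()
        if not part or part == ".":
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
        else:
            attrs[part] = "true"
    return attrs


def _read_tsv(lines, declared_length):
    feats = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[0] == "name":
            continue  # header
        if len(cols) < 5:
            raise FormatError(f"TSV feature row needs >=5 columns: {line!r}")
        name, kind, strand = cols[0], cols[1], cols[2]
        starts = [int(x) for x in cols[3].split(",")]
        ends = [int(x) for x in cols[4].split(",")]
        if len(starts) != len(ends):
            raise FormatError(f"start/end list length mismatch in {name}")
        intervals = [(s - 1, e) for s, e in zip(starts, ends)]
        if declared_length is not None:
            for s, e in intervals:
                if e > declared_length or s < 0:
                    raise CoordinateError(f"{name}: interval outside sequence bounds")
        attrs = _parse_attrs(cols[5]) if len(cols) > 5 else {}
        if kind not in KNOWN_KINDS:
            warnings.warn(f"unknown feature kind {kind!r}; kept as attribute")
            attrs["original_kind"] = kind
            kind = "orf"
        wraps = attrs.pop("wraps", "false") == "true"
        feats.append(Feature(name, kind, strand, intervals, attrs, wraps))
    return feats


def _read_gff3(lines, declared_length):
    by_id: dict[str, Feature] = {}
    feats = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"GFF3 row needs 9 columns: {line!r}")
        kind, start, end, strand = cols[2], int(cols[3]), int(cols[4]), cols[6]
        if declared_length is not None and end > declared_length:
            raise CoordinateError(f"interval {start}..{end} outside sequence bounds")
        attrs = _parse_attrs(cols[8])
        fid = attrs.pop("ID", None)
        name = attrs.pop("Name", None) or fid or kind
        if kind not in KNOWN_KINDS:
            warnings.warn(f"unknown feature kind {kind!r}; kept as attribute")
            attrs["original_kind"] = kind
            kind = "orf"
        wraps = attrs.pop("wraps", "false") == "true"
        interval = (start - 1, end)
        if fid is not None and fid in by_id:
            by_id[fid].intervals.append(interval)
            by_id[fid].wraps = by_id[fid].wraps or wraps
        else:
            feat = Feature(name, kind, strand if strand in "+-" else "+", [interval], attrs, wraps)
            feats.append(feat)
            if fid is not None:
                by_id[fid] = feat
    return feats


def read_feature_table(path, dialect: str = "genbank_ft", declared_length: int | None = None) -> list[Feature]:
    """Read features from a GenBank feature table, the TSV dialect, or GFF3.

    All dialects use 1-based inclusive coordinates on disk; the returned
    features are 0-based half-open.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "genbank_ft":
        return _read_genbank_ft(lines, declared_length)
    if dialect == "tsv":
        return _read_tsv(lines, declared_length)
    if dialect == "gff3":
        return _read_gff3(lines, declared_length)
    raise FormatError(f"unknown feature dialect {dialect!r}")


def write_tsv(features: list[Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tkind\tstrand\tstart\tend\tattributes\n")
        for f in features:
            starts = ",".join(str(s + 1) for s, _ in f.intervals)
            ends = ",".join(str(e) for _, e in f.intervals)
            attrs = dict(f.attributes)
            if f.wraps:
                attrs["wraps"] = "true"
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(f"{f.name}\t{f.kind}\t{f.strand}\t{starts}\t{ends}\t{attr_s}\n")


def write_gff3(plastome: Plastome, path) -> None:
    """Write the plastome's features as GFF3 (1-based inclusive).

    Multi-interval features are emitted as one line per interval sharing an
    ``ID`` attribute, per the GFF3 multi-part convention.
    """
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    buf.write(f"##sequence-region {plastome.id} 1 {plastome.length}\n")
    for i, f in enumerate(plastome.features):
        fid = f"f{i:04d}"
        attrs = [f"ID={fid}", f"Name={f.name}"]
        attrs += [f"{k}={v}" for k, v in f.attributes.items()]
        if f.wraps:
            attrs.append("wraps=true")
        for s, e in f.intervals:
            buf.write(
                "\t".join(
                    [
                        plastome.id,
                        "plastarch",
                        f.kind,
                        str(s + 1),
                        str(e),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Accounting

ORF_NAME_RE = re.compile(r"^orf\d*", re.I)


def is_conserved_gene(feature: Feature, gene_list: set[str] | None = None) -> bool:
    """Conserved-gene rule used for gene counts and gene-order extraction.

    With an explicit ``gene_list``, membership decides. Otherwise any
    gene/tRNA/rRNA feature whose name is not orf-like counts; free-standing
    ORFs with no similarity to known genes are treated as intergenic.
    """
    if feature.kind not in ("gene", "tRNA", "rRNA", "CDS"):
        return False
    if gene_list is not None:
        return feature.name in gene_list
    return not ORF_NAME_RE.match(feature.name)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _union_bp(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def basic_stats(plastome: Plastome) -> GenomeStats:
    """Length and A+T fraction; Ns excluded from both sides of the ratio."""
    if not plastome.sequence:
        raise UndefinedStatisticError("empty sequence")
    counts = {c: plastome.sequence.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedStatisticError("all-N sequence: A+T fraction undefined")
    at = (counts["A"] + counts["T"]) / denom
    return GenomeStats(length=plastome.length, at_fraction=at)


def annotation_accounting(
    plastome: Plastome, gene_list: set[str] | None = None
) -> GenomeStats:
    """Genome accounting over the feature annotation.

    Conserved genes are counted once even when duplicated in the inverted
    repeat; coding space is the union of conserved-gene exons plus rRNA/tRNA
    intervals; intron space is the union of intron intervals; everything
    else — including unidentified ORFs — is intergenic. The mean intergenic
    size divides total intergenic bp by the number of maximal gaps on the
    circle.
    """
    stats = basic_stats(plastome)
    L = plastome.length
    gene_names = set()
    coding_ivs: list[tuple[int, int]] = []
    intron_ivs: list[tuple[int, int]] = []
    for f in plastome.features:
        if f.kind == "intron":
            intron_ivs.extend(f.intervals)
        elif is_conserved_gene(f, gene_list):
            gene_names.add(f.name)
            coding_ivs.extend(f.intervals)
    coding = merge_intervals(coding_ivs)
    introns = merge_intervals(intron_ivs)
    genic = merge_intervals(coding + introns)
    genic_bp = _union_bp(genic)
    intergenic_bp = L - genic_bp
    # count maximal gaps on the circle
    if not genic:
        n_gaps = 1 if L else 0
    else:
        n_gaps = 0
        for (s1, e1), (s2, _) in zip(genic, genic[1:]):
            if s2 > e1:
                n_gaps += 1
        # wrap-around gap between last end and first start
        if (L - genic[-1][1]) + genic[0][0] > 0:
            n_gaps += 1
    overlap = _union_bp(coding) + _union_bp(introns) - genic_bp
    if overlap > 0:
        warnings.warn(f"{overlap} bp of coding/intron overlap resolved by union")
    stats.n_conserved_genes = len(gene_names)
    # intron bp outside exons, so the three fractions partition the genome
    stats.intron_fraction = (genic_bp - _union_bp(coding)) / L
    stats.coding_fraction = _union_bp(coding) / L
    stats.intergenic_fraction = intergenic_bp / L
    stats.mean_intergenic_size = intergenic_bp / n_gaps if n_gaps else 0.0
    return stats
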