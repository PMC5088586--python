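"""Intron registry, positional homology, and intron statistics.

Insertion sites are expressed in the coordinates of a reference homolog
(e.g. a deeply diverging streptophyte gene for protein-coding hosts, or
the E. coli rRNAs for ribosomal hosts) as the reference position of the
host nucleotide immediately preceding the intron. Introns from different
taxa inserted at the identical reference site of a homologous host gene
are *positional homologs* and are grouped by exact (host gene, site)
equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .errors import HomologyError, ValidationError

INTRON_CLASSES = ("I", "IIA", "IIB")
ORF_DOMAINS = ("RT", "maturase", "HNH", "LAGLIDADG", "GIY-YIG")


@dataclass
class IntronRecord:
    """One intron occurrence in one taxon."""

    taxon: str
    host_gene: str
    intron_class: str  # I | IIA | IIB
    splicing: str = "cis"  # cis | trans
    site: int | None = None  # 1-based reference coordinate
    orf_domains: tuple[str, ...] = ()
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.intron_class not in INTRON_CLASSES:
            raise ValidationError(f"unknown intron class {self.intron_class!r}")
        if self.splicing not in ("cis", "trans"):
            raise ValidationError(f"unknown splicing mode {self.splicing!r}")
        if self.site is not None and self.site < 1:
            raise ValidationError("insertion site must be >= 1 (reference coords)")
        if self.splicing == "cis" and not self.sequence:
            raise ValidationError(
                f"cis intron in {self.host_gene} ({self.taxon}) needs a sequence"
            )
        bad = set(self.orf_domains) - set(ORF_DOMAINS)
        if bad:
            raise ValidationError(f"unknown ORF domains {sorted(bad)}")


@dataclass
class MappedSite:
    site: int  # 1-based reference coordinate
    is_approximate: bool = False


def _make_aligner(match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-2.0, end_gaps_free=False):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if end_gaps_free:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _alignment_columns(alignment):
    """Aligned strings (with '-') for target and query."""
    return str(alignment[0]), str(alignment[1])


def map_insertion_site(
    host_exons: str, reference_gene: str, intron_offset: int, min_identity: float = 0.40
) -> MappedSite:
    """Map an intron insertion point onto reference-gene coordinates.

    ``intron_offset`` is the 1-based position, within the concatenated host
    exons, of the nucleotide immediately preceding the intron. The host is
    globally aligned to the reference with free end gaps; the returned site
    is the reference position aligned to that host nucleotide, or the
    nearest upstream reference position (flagged approximate) if it falls
    in a deletion.
    """
    if not (1 <= intron_offset <= len(host_exons)):
        raise ValidationError("intron offset outside the host exons")
    aligner = _make_aligner(end_gaps_free=True)
    alignment = max(aligner.align(reference_gene.upper(), host_exons.upper()))
    ref_row, host_row = _alignment_columns(alignment)
    matches = sum(1 for x, y in zip(ref_row, host_row) if x == y and x != "-")
    identity = matches / len(ref_row)
    if identity < min_identity:
        raise HomologyError(
            f"host/reference identity {identity:.2f} below {min_identity:.2f}"
        )
    host_i = ref_i = 0
    for x, y in zip(ref_row, host_row):
        host_i += y != "-"
        ref_i += x != "-"
        if host_i == intron_offset and y != "-":
            if x != "-":
                return MappedSite(site=ref_i, is_approximate=False)
            return MappedSite(site=max(ref_i, 1), is_approximate=True)
    raise ValidationError("intron offset not reached in alignment")  # pragma: no cover


def positional_homologs(records: list[IntronRecord]) -> list[tuple[tuple[str, int], list[IntronRecord]]]:
    """Group records by exact (host gene, insertion site) equality."""
    groups: dict[tuple[str, int], list[IntronRecord]] = {}
    for r in records:
        key = (r.host_gene, r.site if r.site is not None else -1)
        groups.setdefault(key, []).append(r)
    return sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1]))


def distribution_matrix(records: list[IntronRecord], taxa: list[str]) -> pd.DataFrame:
    """Taxa x (host gene, site) presence matrix.

    Cells are None (absent), "ORF-less", or a "+"-joined domain list for
    ORF-containing introns; the intron class is appended in brackets.
    """
    sites = sorted({(r.host_gene, r.site if r.site is not None else -1) for r in records})
    columns = pd.MultiIndex.from_tuples(sites, names=["host_gene", "site"]) if sites else []
    mat = pd.DataFrame(None, index=pd.Index(taxa, name="taxon"), columns=columns, dtype=object)
    for r in records:
        if r.taxon not in mat.index:
            raise ValidationError(f"record taxon {r.taxon!r} not in taxa list")
        content = "+".join(r.orf_domains) if r.orf_domains else "ORF-less"
        mat.loc[r.taxon, (r.host_gene, r.site if r.site is not None else -1)] = (
            f"{content} [{r.intron_class}]"
        )
    return mat


def class_counts(records: list[IntronRecord]) -> pd.DataFrame:
    """Intron counts per taxon: group I, IIA, IIB, and group II total."""
    rows: dict[str, dict[str, int]] = {}
    for r in records:
        row = rows.setdefault(r.taxon, {"I": 0, "IIA": 0, "IIB": 0})
        row[r.intron_class] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["I", "IIA", "IIB"], dtype=int)
    df["II"] = df.get("IIA", 0) + df.get("IIB", 0)
    df.index.name = "taxon"
    return df


def pairwise_intron_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> tuple[float, int]:
    """Percent identity of two intron sequences over a global alignment.

    The denominator is the full alignment length, gap columns included, so
    the figure reads "identical over an alignment spanning their entire
    lengths". Returns (identity fraction, alignment columns).
    """
    if not a or not b:
        raise ValidationError("both sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = max(aligner.align(a.upper(), b.upper()))
    row_a, row_b = _alignment_columns(alignment)
    columns = len(row_a)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return matches / columns, columns


# ---------------------------------------------------------------------------
# Registry I/O (TSV)


def read_registry(path) -> list[IntronRecord]:
    """Read an intron registry TSV.

    Columns: taxon, host_gene, class, splicing, site, domains, sequence.
    ``domains`` is "+"-separated or "-" for none; ``site`` may be "-" when
    unmapped; ``sequence`` may be "-" for trans-spliced introns.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("taxon\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ValidationError(f"registry row needs 7 columns: {line!r}")
            taxon, gene, cls, splicing, site, domains, seq = cols[:7]
            records.append(
                IntronRecord(
                    taxon=taxon,
                    host_gene=gene,
                    intron_class=cls,
                    splicing=splicing,
                    site=None if site in ("-", "") else int(site),
                    orf_domains=tuple(d for d in domains.split("+") if d and d != "-"),
                    sequence="" if seq == "-" else seq,
                )
            )
    return records


def write_registry(records: list[IntronRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\thost_gene\tclass\tsplicing\tsite\tdomains\tsequence\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.taxon,
                        r.host_gene,
                        r.intron_class,
                        r.splicing,
                        "-" if r.site is None else str(r.site),
                        "+".join(r.orf_domains) or "-",
                        r.sequence or "-",
                    ]
                )
                + "\n"
            )
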