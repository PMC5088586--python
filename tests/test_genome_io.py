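"""Sequence/feature I/O, coordinate conventions, and genome accounting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastarch.errors import CoordinateError, FormatError, UndefinedStatisticError
from plastarch.genome_io import (
    Feature,
    Plastome,
    annotation_accounting,
    basic_stats,
    parse_location,
    read_fasta,
    read_feature_table,
    reverse_complement,
    write_gff3,
    write_tsv,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("acgt", "ACGT"),
        ("ACGU", "ACGT"),
        ("ACGTACGTACGTR", "ACGTACGTACGTN"),  # ambiguity codes collapse to N
        ("acguACGU", "ACGTACGT"),
    ],
)
def test_fasta_normalization(tmp_path, raw, expected):
    p = tmp_path / "x.fa"
    p.write_text(f">x some description\n{raw}\n")
    (rec,) = read_fasta(p)
    assert rec.id == "x"
    assert rec.sequence == expected
    assert rec.length == len(expected)


@pytest.mark.parametrize(
    "content",
    ["", ">x\nXXXXXXXXXY\n", ">x\nPROTEINSEQQQ\n"],
    ids=["empty", "non-nucleotide", "protein"],
)
def test_fasta_rejects_bad_records(tmp_path, content):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FormatError):
        read_fasta(p)


@pytest.mark.parametrize(
    "loc, intervals, strand",
    [
        ("1..1062", [(0, 1062)], "+"),
        ("complement(10..20)", [(9, 20)], "-"),
        ("join(1..10,21..30)", [(0, 10), (20, 30)], "+"),
        ("complement(join(5..8,12..15))", [(4, 8), (11, 15)], "-"),
        ("42", [(41, 42)], "+"),
    ],
)
def test_location_parsing(loc, intervals, strand):
    got_ivs, got_strand = parse_location(loc)
    assert got_ivs == intervals
    assert got_strand == strand


def test_genbank_feature_table(tmp_path):
    table = """FEATURES             Location/Qualifiers
     gene            1..1062
                     /gene="psbA"
     gene            complement(2000..2500)
                     /gene="rbcL"
     intron          join(3000..3100,3200..3300)
                     /gene="petB"
                     /intron_class="IIA"
"""
    p = tmp_path / "feat.txt"
    p.write_text(table)
    feats = read_feature_table(p, "genbank_ft")
    assert [f.name for f in feats] == ["psbA", "rbcL", "petB"]
    assert feats[0].intervals == [(0, 1062)]
    assert feats[1].strand == "-" and feats[1].intervals == [(1999, 2500)]
    assert feats[2].intervals == [(2999, 3100), (3199, 3300)]
    assert feats[2].attributes["intron_class"] == "IIA"


def test_tsv_row_coordinate_conversion(tmp_path):
    p = tmp_path / "f.tsv"
    p.write_text("name\tkind\tstrand\tstart\tend\tattributes\npsbA\tgene\t+\t1\t1062\t.\n")
    (f,) = read_feature_table(p, "tsv")
    assert f.intervals == [(0, 1062)]


def test_interval_outside_bounds_raises(tmp_path):
    p = tmp_path / "f.tsv"
    p.write_text("psbA\tgene\t+\t1\t500\t.\n")
    with pytest.raises(CoordinateError):
        read_feature_table(p, "tsv", declared_length=100)


@pytest.mark.parametrize("dialect, writer", [("tsv", "tsv"), ("gff3", "gff3")])
def test_feature_round_trip(tmp_path, dialect, writer):
    feats = [
        Feature("psbA", "gene", "+", [(0, 10)]),
        Feature("petD", "gene", "-", [(20, 30), (40, 50)], {"trans_spliced": "true"}),
        Feature("petD-intron", "intron", "+", [(30, 40)], {"intron_class": "IIB"}),
    ]
    genome = Plastome("t", "A" * 60, True, feats)
    path = tmp_path / f"out.{writer}"
    if writer == "gff3":
        write_gff3(genome, path)
        text = path.read_text()
        assert "\t1\t10\t" in text  # 1-based inclusive on disk
        assert text.count("ID=f0001") == 2  # multi-part feature shares one ID
    else:
        write_tsv(feats, path)
    back = read_feature_table(path, dialect, declared_length=60)
    assert [(f.name, f.kind, f.strand, f.intervals) for f in back] == [
        (f.name, f.kind, f.strand, f.intervals) for f in feats
    ]
    assert back[1].attributes["trans_spliced"] == "true"


@pytest.mark.parametrize(
    "seq, at",
    [("ATAT", 1.0), ("ACGT", 0.5), ("GCGC", 0.0), ("ANTN", 1.0)],
)
def test_at_fraction(seq, at):
    assert basic_stats(Plastome("x", seq)).at_fraction == pytest.approx(at)


def test_at_fraction_undefined_on_all_n():
    with pytest.raises(UndefinedStatisticError):
        basic_stats(Plastome("x", "NNNN"))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(dna)
def test_at_fraction_reverse_complement_invariant(seq):
    p, q = Plastome("a", seq), Plastome("b", reverse_complement(seq))
    assert basic_stats(p).at_fraction == pytest.approx(basic_stats(q).at_fraction)


def test_accounting_partitions_tiny_genome(tiny_plastome):
    st = annotation_accounting(tiny_plastome)
    assert st.n_conserved_genes == 2
    assert st.coding_fraction == pytest.approx(0.60)
    assert st.intron_fraction == pytest.approx(0.10)
    assert st.intergenic_fraction == pytest.approx(0.30)
    assert st.coding_fraction + st.intron_fraction + st.intergenic_fraction == pytest.approx(1.0)
    # one maximal gap on the circle: [70, 100)
    assert st.mean_intergenic_size == pytest.approx(30.0)


def test_accounting_full_coverage_has_no_intergenic():
    g = Plastome("x", "ACGT" * 25, True, [Feature("psbA", "gene", "+", [(0, 100)])])
    st = annotation_accounting(g)
    assert st.intergenic_fraction == 0.0


def test_accounting_counts_ir_duplicates_once_and_orfs_as_intergenic(sim_genome):
    genome, truth = sim_genome
    st = annotation_accounting(genome)
    names = {f.name for f in genome.features if f.kind in ("gene", "tRNA", "rRNA")}
    assert st.n_conserved_genes == len(names)  # rRNA operon present twice, counted once
    # planted intergenic fraction derivable from the generator's layout
    genic = sum(
        e - s
        for s, e in {
            iv
            for f in genome.features
            if f.kind in ("gene", "tRNA", "rRNA")
            for iv in f.intervals
        }
    )
    assert st.intergenic_fraction == pytest.approx(1 - genic / genome.length, abs=1e-9)


def test_orf_features_are_intergenic():
    g = Plastome(
        "x",
        "ACGT" * 25,
        True,
        [
            Feature("psbA", "gene", "+", [(0, 40)]),
            Feature("orf123", "gene", "+", [(50, 90)]),
        ],
    )
    st = annotation_accounting(g)
    assert st.n_conserved_genes == 1
    assert st.intergenic_fraction == pytest.approx(0.60)
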