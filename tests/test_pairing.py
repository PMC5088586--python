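"""EBS/IBS pairing, consensus conservation, and mobility signatures."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastarch.errors import AnnotationError, InsufficientDataError, ValidationError
from plastarch.genome_io import reverse_complement
from plastarch.pairing import (
    MotifAnnotation,
    TargetSite,
    consensus_conservation,
    locate_ebs,
    mobility_signature,
    pairing_profile,
    profile_intron,
)

dna = st.text(alphabet="ACGT", min_size=3, max_size=8)


def test_perfect_complement_pairs_fully():
    prof = pairing_profile("GTTCAA", reverse_complement("GTTCAA"), element="EBS1·IBS1")
    assert prof.n_wc == 6 and prof.n_mismatch == 0
    assert prof.verdict == "perfect"
    assert prof.pairing == "WWWWWW"


def test_single_substitution_is_near_perfect():
    window = list(reverse_complement("GTTCAA"))
    window[2] = "C" if window[2] != "C" else "A"
    prof = pairing_profile("GTTCAA", "".join(window))
    assert prof.n_mismatch == 1
    assert prof.verdict == "near_perfect"


def test_unpairable_delta_is_incompatible():
    # mirrors a δ motif that cannot base pair with δ' at all
    prof = pairing_profile("AAA", "AAA", allow_wobble=True)
    assert prof.verdict == "incompatible"
    assert prof.n_mismatch == 3


@settings(deadline=None, max_examples=60, derandomize=True)
@given(dna)
def test_motif_always_pairs_its_reverse_complement(motif):
    assert pairing_profile(motif, reverse_complement(motif)).verdict == "perfect"


@settings(deadline=None, max_examples=60, derandomize=True)
@given(dna, dna)
def test_disabling_wobble_never_increases_pairing(a, b):
    if abs(len(a) - len(b)) > 2:
        return
    with_w = pairing_profile(a, b, allow_wobble=True)
    without = pairing_profile(a, b, allow_wobble=False)
    assert without.n_wc + without.n_wobble <= with_w.n_wc + with_w.n_wobble
    assert without.n_wobble == 0


def test_wobble_counts_as_pairing_only_when_enabled():
    # G·T opposition: motif G against window T (antiparallel)
    assert pairing_profile("G", "T", allow_wobble=True).verdict == "perfect"
    assert pairing_profile("G", "T", allow_wobble=False).verdict == "near_perfect"


def test_length_mismatch_beyond_two_is_an_annotation_error():
    with pytest.raises(AnnotationError):
        pairing_profile("GTTCAA", "GTT")


def test_target_site_window_geometry():
    exon5 = "A" * 11 + "GTCCGGT" + "TTCAAC"
    site = TargetSite(exon5=exon5, exon3="ATG")
    assert site.ibs1 == "TTCAAC"
    assert site.ibs2 == "GTCCGGT"
    assert site.delta_prime == "A"
    with pytest.raises(ValidationError):
        TargetSite(exon5=exon5, exon3="ATG", ibs1_window=(-6, -2))


def test_locate_ebs_finds_planted_motif():
    rng = random.Random(5)
    window = "TTCAAC"
    planted = reverse_complement(window)
    intron = "".join(rng.choice("ACGT") for _ in range(120))
    intron = intron[:70] + planted + intron[76:]
    found = locate_ebs(intron, (40, 110), window, 6)
    assert found is not None
    seq, (s, e) = found
    assert (s, e) == (70, 76) and seq == planted


def test_locate_ebs_breaks_ties_leftmost():
    window = "TTCAAC"
    planted = reverse_complement(window)
    intron = "A" * 10 + planted + "C" * 10 + planted + "A" * 10
    _, (s, _) = locate_ebs(intron, (0, len(intron)), window, 6)
    assert s == 10


def test_locate_ebs_tolerates_one_mutation_among_decoys():
    rng = random.Random(6)
    window = "GTTCAA"
    planted = list(reverse_complement(window))
    planted[3] = "A" if planted[3] != "A" else "C"  # one mutation
    intron = "".join(rng.choice("ACGT") for _ in range(150))
    intron = intron[:90] + "".join(planted) + intron[96:]
    found = locate_ebs(intron, (80, 140), window, 6)
    assert found is not None and found[1][0] == 90


def test_consensus_trivial_cases():
    profile = consensus_conservation(["ACGT"] * 8)
    assert profile.f(6) == 1.0
    distinct = ["AAAA", "CCCC", "GGGG", "TTTT", "AAAA", "CCCC", "GGGG", "TTTT"]
    # every column has max multiplicity 2 < 6
    assert consensus_conservation(distinct).f(6) == 0.0


def test_consensus_planted_conserved_fraction():
    rng = random.Random(9)
    ncol, n_cons = 1000, 780
    cols = []
    for i in range(ncol):
        if i < n_cons:  # conserved in >= 6 of 8
            base = rng.choice("ACGT")
            others = [b for b in "ACGT" if b != base]
            col = [base] * 6 + [rng.choice(others), rng.choice(others)]
        else:  # max multiplicity 3 < 6
            col = ["A", "A", "A", "C", "C", "C", "G", "T"]
        cols.append(col)
    aligned = ["".join(cols[i][row] for i in range(ncol)) for row in range(8)]
    profile, f6 = consensus_conservation(aligned, 6)
    assert f6 == pytest.approx(0.78, abs=0.001)


def test_consensus_ignores_gaps_and_rejects_ragged():
    profile = consensus_conservation(["A-GT", "AC-T", "ACG-"])
    assert profile.column_multiplicity == [3, 2, 2, 2]
    with pytest.raises(ValidationError):
        consensus_conservation(["ACGT", "ACG"])


def test_consensus_f_non_increasing_and_permutation_invariant():
    rng = random.Random(10)
    aligned = ["".join(rng.choice("ACGT-") for _ in range(60)) for _ in range(8)]
    profile = consensus_conservation(aligned)
    fs = [profile.f(k) for k in range(1, 9)]
    assert fs == sorted(fs, reverse=True)
    perm = rng.sample(range(60), 60)
    shuffled = ["".join(s[i] for i in perm) for s in aligned]
    sprof = consensus_conservation(shuffled)
    assert sorted(sprof.column_multiplicity) == sorted(profile.column_multiplicity)
    assert all(sprof.f(k) == profile.f(k) for k in range(1, 9))


def _family(mode, seed=0, size=5):
    """Hand-built family: divergent-but-matched or constant-but-mismatched."""
    rng = random.Random(seed)
    fam = []
    anc_ebs1, anc_ebs2, anc_delta = "GTTCAA", "AGTTGGA", "G"
    for _ in range(size):
        exon5 = "".join(rng.choice("ACGT") for _ in range(24))
        exon3 = "".join(rng.choice("ACGT") for _ in range(3))
        site = TargetSite(exon5=exon5, exon3=exon3)
        if mode == "retrohoming":
            motif = MotifAnnotation(
                reverse_complement(site.ibs1),
                reverse_complement(site.ibs2),
                reverse_complement(site.delta_prime),
            )
        else:
            motif = MotifAnnotation(anc_ebs1, anc_ebs2, anc_delta)
        fam.append((motif, site))
    return fam


def test_identical_perfectly_pairing_family_is_indeterminate():
    site = TargetSite(exon5="A" * 11 + "GTCCGGT" + "TTCAAC", exon3="CAT")
    motif = MotifAnnotation(
        reverse_complement(site.ibs1),
        reverse_complement(site.ibs2),
        reverse_complement(site.delta_prime),
    )
    sig = mobility_signature([(motif, site)] * 4)
    assert sig.divergence == 0.0
    assert sig.self_compatibility == 1.0
    assert sig.verdict == "indeterminate"


def test_hand_built_modes_classify_correctly():
    retro = mobility_signature(_family("retrohoming", seed=1))
    assert retro.verdict == "retrohoming_like"
    trans = mobility_signature(_family("retrotransposition", seed=2))
    assert trans.verdict == "retrotransposition_like"


def test_mobility_invariant_under_member_order():
    fam = _family("retrohoming", seed=3)
    a = mobility_signature(fam)
    b = mobility_signature(list(reversed(fam)))
    assert a.verdict == b.verdict
    assert a.divergence == pytest.approx(b.divergence)
    assert a.self_compatibility == pytest.approx(b.self_compatibility)


def test_small_family_raises():
    with pytest.raises(InsufficientDataError):
        mobility_signature(_family("retrohoming", size=2))
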