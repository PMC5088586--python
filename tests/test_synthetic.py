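"""Generator determinism, feasibility checks, and truth consistency."""

import pytest

from plastarch.errors import ConfigError
from plastarch.genome_io import (
    read_fasta,
    read_feature_table,
    reverse_complement,
    write_fasta,
    write_tsv,
)
from plastarch.pairing import mobility_signature, profile_intron
from plastarch.rearrangement import (
    extract_shared_order,
    pairwise_substitutions,
    reversal_distance,
)
from plastarch.synthetic import (
    SimConfig,
    apply_reversals,
    evolve_sequence,
    plant_intron_family,
    plant_repeats,
    simulate_pair,
    simulate_plastome,
)


def test_same_config_is_byte_identical(tmp_path):
    for make in (
        lambda: simulate_plastome(SimConfig(seed=4))[0],
        lambda: plant_intron_family(SimConfig(seed=4))[0],
    ):
        a, b = make(), make()
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta([a], pa)
        write_fasta([b], pb)
        assert pa.read_bytes() == pb.read_bytes()


def test_different_seeds_differ():
    a, _ = simulate_plastome(SimConfig(seed=1))
    b, _ = simulate_plastome(SimConfig(seed=2))
    assert a.sequence != b.sequence


def test_outputs_round_trip_through_genome_io(tmp_path):
    genome, _ = simulate_plastome(SimConfig(seed=3))
    write_fasta([genome], tmp_path / "g.fa")
    write_tsv(genome.features, tmp_path / "g.tsv")
    (back,) = read_fasta(tmp_path / "g.fa")
    feats = read_feature_table(tmp_path / "g.tsv", "tsv", declared_length=back.length)
    assert back.sequence == genome.sequence
    assert [(f.name, f.strand, f.intervals) for f in feats] == [
        (f.name, f.strand, f.intervals) for f in genome.features
    ]


def test_planted_ir_is_exact_reverse_complement(sim_genome):
    genome, truth = sim_genome
    (a1, a2), (b1, b2) = truth.ir_a, truth.ir_b
    assert genome.sequence[a1:a2] == reverse_complement(genome.sequence[b1:b2])


def test_featureless_circle():
    genome, truth = simulate_plastome(SimConfig(seed=5, n_genes=0, ir_length=0))
    assert genome.features == []
    assert genome.length == 50_000


def test_infeasible_packing_raises():
    with pytest.raises(ConfigError):
        simulate_plastome(SimConfig(seed=0, genome_length=9000, n_genes=60, ir_length=0))
    with pytest.raises(ConfigError):
        simulate_plastome(SimConfig(seed=0, genome_length=15000, ir_length=8000))


def test_zero_reversals_is_identity(sim_genome):
    genome, _ = sim_genome
    same, truth = apply_reversals(genome, 0, seed=1)
    assert same.sequence == genome.sequence
    assert truth.reversals == []


def test_reversals_flip_strands_and_preserve_gene_sets(sim_genome):
    genome, _ = sim_genome
    derived, truth = apply_reversals(genome, 2, seed=8)
    assert len(truth.reversals) == 2
    names = lambda g: sorted(f.name for f in g.features)
    assert names(derived) == names(genome)
    _, order_b = extract_shared_order(genome, derived)
    assert reversal_distance(order_b) == 2


def test_evolve_distance_zero_is_identity(sim_genome):
    genome, _ = sim_genome
    assert evolve_sequence(genome.sequence, 0.0, seed=1) == genome.sequence


@pytest.mark.parametrize("model", ["JC69", "K80"])
def test_evolve_is_deterministic_per_seed(model):
    seq = "ACGT" * 2500
    a = evolve_sequence(seq, 0.05, model, seed=9)
    assert a == evolve_sequence(seq, 0.05, model, seed=9)
    assert a != evolve_sequence(seq, 0.05, model, seed=10)


def test_repeat_planting_truth_matches_target(sim_genome_no_ir):
    genome, _ = sim_genome_no_ir
    planted, truth = plant_repeats(genome, 0.10, seed=2)
    assert truth.repeat_coverage >= 0.10
    assert truth.repeat_coverage == pytest.approx(0.10, abs=0.01)
    covered = sum(e - s for s, e in truth.repeat_intervals)
    assert covered == pytest.approx(truth.repeat_coverage * genome.length)
    assert plant_repeats(genome, 0.0, seed=2)[0].sequence == genome.sequence


def test_intron_family_modes_have_promised_motif_structure():
    for mode, expected in (
        ("retrohoming", "retrohoming_like"),
        ("retrotransposition", "retrotransposition_like"),
    ):
        genome, records, table, truth = plant_intron_family(
            SimConfig(seed=11, mobility_mode=mode)
        )
        assert truth.mobility_mode == mode
        assert len(records) == len(table) == 6
        sig = mobility_signature(table)
        assert sig.verdict == expected
        # every intron sequence embeds its own annotated motifs
        for rec, (motif, _) in zip(records, table):
            assert motif.ebs1 in rec.sequence
            assert motif.ebs2 in rec.sequence


def test_retrohoming_copies_pair_with_their_own_sites():
    _, _, table, _ = plant_intron_family(SimConfig(seed=12, mobility_mode="retrohoming"))
    for motif, site in table:
        prof = profile_intron(motif, site)
        assert prof["EBS1·IBS1"].verdict in ("perfect", "near_perfect")
        assert prof["EBS2·IBS2"].verdict in ("perfect", "near_perfect")


def test_small_family_config_rejected():
    with pytest.raises(ConfigError):
        plant_intron_family(SimConfig(seed=0, family_size=2))


def test_simulated_pair_recovers_planted_distance():
    cfg = SimConfig(seed=13, k_reversals=1, subst_distance=0.08)
    a, b, truth = simulate_pair(cfg)
    _, order_b = extract_shared_order(a, b)
    assert reversal_distance(order_b) == 1
    # substitutions estimated on the colinear (non-reversed) portion
    (c1, c2) = truth.reversals[0]
    colinear_a = a.sequence[:c1] + a.sequence[c2:]
    colinear_b = b.sequence[:c1] + b.sequence[c2:]
    est = pairwise_substitutions(colinear_a, colinear_b, "K80") / len(colinear_a)
    assert est == pytest.approx(0.08, abs=0.015)
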