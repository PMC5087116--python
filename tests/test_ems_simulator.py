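import math

import numpy as np
import pytest

import crossmut as cm
from crossmut.ems_simulator import (
    make_reference,
    mutagenize_ems,
    mutagenize_natural,
    plant_causal,
    read_truth_tsv,
    simulate_pileup,
)


def rng_(seed=0):
    return np.random.default_rng(seed)


SMALL = dict(n_contigs=10, contig_length_median=3000, contig_length_sigma=0.3,
             causal_length=4000, n_mutants=3)


# ---------------------------------------------------------------------------
# reference construction


def test_reference_is_deterministic_and_seed_sensitive(tmp_path):
    config = cm.SimulationConfig(seed=5, **SMALL)
    a, causal_a = make_reference(config)
    b, causal_b = make_reference(config)
    assert causal_a == causal_b
    assert [(c.id, c.sequence) for c in a] == [(c.id, c.sequence) for c in b]
    c, _ = make_reference(cm.SimulationConfig(seed=6, **SMALL))
    assert [x.sequence for x in c] != [x.sequence for x in a]

    out1, out2 = tmp_path / "a.fa", tmp_path / "b.fa"
    cm.write_fasta(a, out1)
    cm.write_fasta(b, out2)
    assert out1.read_bytes() == out2.read_bytes()


def test_reference_respects_length_floor_and_causal_length():
    config = cm.SimulationConfig(seed=3, n_contigs=50, contig_length_median=700,
                                 contig_length_sigma=1.0, causal_length=4000, n_mutants=3)
    contigs, causal_id = make_reference(config)
    index = {c.id: c for c in contigs}
    assert index[causal_id].length == 4000
    assert all(c.length >= 500 for c in contigs if c.id != causal_id)


def test_gc_content_zero_means_no_gc():
    config = cm.SimulationConfig(seed=1, gc_content=0.0, **SMALL)
    contigs, _ = make_reference(config)
    for contig in contigs:
        assert contig.gc_unmasked == 0
        assert not set(contig.sequence.upper()) & {"G", "C"}


def test_empirical_gc_matches_configuration():
    config = cm.SimulationConfig(seed=9, n_contigs=2, contig_length_median=500_000,
                                 contig_length_sigma=0.0, masked_fraction=0.0,
                                 causal_length=10_000, n_mutants=1)
    contigs, _ = make_reference(config)
    total = sum(c.length for c in contigs)
    gc = sum(c.gc_unmasked for c in contigs)
    se = math.sqrt(0.44 * 0.56 / total)
    assert abs(gc / total - 0.44) <= 3 * se


def test_masked_fraction_is_approximately_respected():
    config = cm.SimulationConfig(seed=2, masked_fraction=0.2, **SMALL)
    contigs, _ = make_reference(config)
    total = sum(c.length for c in contigs)
    masked = sum(c.length - c.unmasked_bases for c in contigs)
    assert 0.15 <= masked / total <= 0.25


# ---------------------------------------------------------------------------
# mutagenesis


@pytest.fixture(scope="module")
def flat_reference():
    config = cm.SimulationConfig(seed=12, n_contigs=5, contig_length_median=1_000_000,
                                 contig_length_sigma=0.0, masked_fraction=0.0,
                                 causal_length=10_000, n_mutants=6)
    return make_reference(config)


def test_ems_density_zero_leaves_reference_unchanged(flat_reference):
    contigs, _ = flat_reference
    genome, entries = mutagenize_ems(contigs, 0.0, rng_(1))
    assert entries == []
    for contig in contigs:
        assert genome[contig.id].tobytes().decode() == contig.sequence


def test_ems_realized_count_is_binomial(flat_reference):
    contigs, _ = flat_reference
    unmasked = sum(c.unmasked_bases for c in contigs)
    density = 1 / 500_000
    expected = density * unmasked  # ≈ 8
    _, entries = mutagenize_ems(contigs, density, rng_(4))
    assert abs(len(entries) - expected) <= 3 * math.sqrt(expected)


def test_ems_entries_are_canonical_at_unmasked_sites(flat_reference):
    contigs, _ = flat_reference
    index = {c.id: c for c in contigs}
    _, entries = mutagenize_ems(contigs, 1 / 100_000, rng_(5))
    assert entries
    for cid, pos, ref, alt in entries:
        assert index[cid].sequence[pos - 1] == ref  # unmasked uppercase site
        assert (ref, alt) in {("G", "A"), ("C", "T")}


def test_ems_density_above_gc_budget_rejected(flat_reference):
    contigs, _ = flat_reference
    with pytest.raises(cm.ConfigError):
        mutagenize_ems(contigs, 0.9, rng_(1))


def test_plant_causal_gives_each_mutant_a_distinct_lesion(flat_reference):
    contigs, causal_id = flat_reference
    causal = next(c for c in contigs if c.id == causal_id)
    genomes = {
        f"mut{i}": {c.id: np.frombuffer(c.sequence.encode(), np.uint8).copy()
                    for c in contigs}
        for i in range(6)
    }
    hits = plant_causal(genomes, causal, rng_(6))
    positions = [pos for _, pos, _, _ in hits.values()]
    assert len(set(positions)) == 6
    for mutant_id, (cid, pos, ref, alt) in hits.items():
        assert cid == causal_id and 1 <= pos <= causal.length
        assert causal.sequence[pos - 1] == ref and (ref, alt) in {("G", "A"), ("C", "T")}
        assert chr(genomes[mutant_id][cid][pos - 1]) == alt


def test_plant_causal_needs_enough_gc_sites():
    causal = cm.ReferenceContig("c0", "ATAT" * 300 + "G")
    genomes = {f"m{i}": {"c0": np.frombuffer(causal.sequence.encode(), np.uint8).copy()}
               for i in range(3)}
    with pytest.raises(cm.ConfigError):
        plant_causal(genomes, causal, rng_(1))


def test_natural_variation_count_and_spectrum(flat_reference):
    contigs, _ = flat_reference
    genome, entries = mutagenize_natural(contigs, 0.0, rng_(1))
    assert entries == []
    density = 1 / 1580
    subset = contigs[:2]  # 2 Mb
    unmasked = sum(c.unmasked_bases for c in subset)
    _, entries = mutagenize_natural(subset, density, rng_(7))
    expected = density * unmasked
    assert abs(len(entries) - expected) <= 3 * math.sqrt(expected)
    canonical = sum(
        1 for _, _, ref, alt in entries
        if (ref, alt) in {("G", "A"), ("C", "T")}
    )
    # canonical pairs are 2 of the 12 substitution types; at GC 0.44 the
    # expected canonical fraction is gc/3 ≈ 0.147
    frac = canonical / len(entries)
    assert 0.08 <= frac <= 0.22
    assert canonical < len(entries)  # non-canonical changes present


# ---------------------------------------------------------------------------
# pileup synthesis


def test_error_free_pileup_reports_the_line_base():
    contig = cm.ReferenceContig("c1", "GGGGGGGGGG")
    mutant = "GGGGAGGGGG"  # position 5 mutated
    cols = list(simulate_pileup(contig, mutant, 30.0, 0.0, rng_(9)))
    for col in cols:
        assert sum(col.counts.values()) == col.depth
        if col.position == 5:
            assert col.counts == {"A": col.depth}
        else:
            assert col.counts == {"G": col.depth}


def test_pileup_depth_is_poisson_and_zero_depth_omitted():
    contig = cm.ReferenceContig("c1", "G" * 200_000)
    cols = list(simulate_pileup(contig, contig.sequence, 2.0, 0.0, rng_(10)))
    present = len(cols)
    # P(depth=0) = e^-2 ≈ 0.135
    expected_present = 200_000 * (1 - math.exp(-2))
    assert abs(present - expected_present) <= 3 * math.sqrt(expected_present)
    depths = np.array([c.depth for c in cols])
    assert depths.min() >= 1
    mean_depth = depths.sum() / 200_000
    assert mean_depth == pytest.approx(2.0, rel=0.02)


def test_pileup_error_rate_recovered():
    contig = cm.ReferenceContig("c1", "G" * 40_000)
    cols = list(simulate_pileup(contig, contig.sequence, 30.0, 0.01, rng_(11)))
    total = sum(c.depth for c in cols)
    miscalls = sum(c.depth - c.counts.get("G", 0) for c in cols)
    se = math.sqrt(0.01 * 0.99 * total)
    assert abs(miscalls - 0.01 * total) <= 3 * se


# ---------------------------------------------------------------------------
# whole experiments


def test_experiment_files_parse_and_round_trip(small_experiment_dir):
    config, out = small_experiment_dir
    assembly = cm.read_fasta(out / "reference.fasta")
    assert len(assembly) == config.n_contigs
    truth = read_truth_tsv(out / "truth.tsv")
    assert truth.causal_contig_id in {c.id for c in assembly}
    n_lines = config.n_mutants + 1  # contaminant enabled
    for i in range(1, n_lines + 1):
        path = out / f"mut{i:02d}.mpileup"
        assert path.exists()
    columns = list(cm.read_mpileup(out / "mut01.mpileup", assembly))
    assert columns  # parses cleanly through formats_io
    assert all(sum(c.counts.values()) == c.depth for c in columns[:200])


def test_experiment_rerun_is_byte_identical(tmp_path):
    config = cm.SimulationConfig(seed=21, **SMALL)
    out1 = cm.simulate_experiment(config, tmp_path / "a")
    out2 = cm.simulate_experiment(config, tmp_path / "b")
    for name in ["reference.fasta", "mut01.mpileup", "truth.tsv"]:
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_different_seeds_give_different_truth(tmp_path):
    t1 = cm.simulate(cm.SimulationConfig(seed=1, **SMALL)).truth
    t2 = cm.simulate(cm.SimulationConfig(seed=2, **SMALL)).truth
    assert t1.entries != t2.entries


def test_truth_table_invariants(small_experiment):
    exp = small_experiment
    truth = exp.truth
    by_mutant = truth.by_mutant()
    causal = truth.causal_contig_id
    for mutant_id in exp.ems_mutant_ids:
        entries = by_mutant[mutant_id]
        assert any(e.contig_id == causal for e in entries)
        for e in entries:
            assert (e.ref, e.alt) in {("G", "A"), ("C", "T")}


def test_config_invariants_enforced():
    with pytest.raises(cm.ConfigError):
        cm.SimulationConfig(causal_length=500)
    with pytest.raises(cm.ConfigError):
        cm.SimulationConfig(n_mutants=0)
    with pytest.raises(cm.ConfigError):
        cm.SimulationConfig(gc_content=1.5)
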