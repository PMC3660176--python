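"""Simulator: determinism, compartment structure, ploidy-driven read depth."""

import numpy as np
import pytest

from cqkit.fragmenter import fragment_masked
from cqkit.sexsim import (
    SimulationConfig,
    SimulationError,
    SimTruth,
    simulate_genome,
    simulate_reads,
    write_genome_fasta,
    write_reads_fastq,
)


def kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=5, n_autosomal_seqs=1, autosomal_length=3000,
                           x_length=3000, y_length=3000,
                           repeat_family_count=1,
                           repeat_copies_per_compartment=4, repeat_copies_y=4,
                           n_duplications=1, n_expressed_y_genes=1,
                           male_coverage=3, female_coverage=3)
    files = []
    for run in ("a", "b"):
        genome, truth = simulate_genome(cfg)
        male, female, tx = simulate_reads(genome, truth, cfg)
        fasta = tmp_path / f"{run}.fasta"
        fastq = tmp_path / f"{run}.fastq"
        write_genome_fasta(genome, fasta)
        write_reads_fastq(male, fastq)
        files.append((fasta.read_bytes(), fastq.read_bytes()))
    assert files[0] == files[1]


def test_compartments_share_no_kmers_without_repeats_or_duplications():
    cfg = SimulationConfig(seed=2, n_autosomal_seqs=2, autosomal_length=5000,
                           x_length=5000, y_length=3000,
                           repeat_family_count=0, n_duplications=0,
                           n_expressed_y_genes=1)
    genome, truth = simulate_genome(cfg)
    k = cfg.read_length
    y_kmers = kmers(next(s.residues for s in genome if s.seq_id == "Y"), k)
    for seq in genome:
        if truth.compartment_of[seq.seq_id] != "Y":
            assert not (y_kmers & kmers(seq.residues.upper(), k))


def test_perfect_identity_duplication_is_exact_copy():
    cfg = SimulationConfig(seed=9, n_autosomal_seqs=1, autosomal_length=5000,
                           x_length=5000, y_length=3000,
                           repeat_family_count=0, n_duplications=1,
                           duplication_identity_percent=100.0,
                           duplication_length=500)
    genome, truth = simulate_genome(cfg)
    seqs = {s.seq_id: s.residues.upper() for s in genome}
    (dup,) = truth.duplications
    donor = seqs[dup["donor_id"]][dup["donor_start"] : dup["donor_end"]]
    assert seqs["Y"][dup["y_start"] : dup["y_end"]] == donor
    assert len(donor) == 500


def test_diverged_duplication_identity_near_target():
    cfg = SimulationConfig(seed=9, n_autosomal_seqs=1, autosomal_length=20_000,
                           x_length=5000, y_length=10_000,
                           repeat_family_count=0, n_duplications=3,
                           duplication_identity_percent=95.0,
                           duplication_length=2000)
    genome, truth = simulate_genome(cfg)
    seqs = {s.seq_id: s.residues.upper() for s in genome}
    for dup in truth.duplications:
        donor = seqs[dup["donor_id"]][dup["donor_start"] : dup["donor_end"]]
        copy = seqs["Y"][dup["y_start"] : dup["y_end"]]
        identity = np.mean([a == b for a, b in zip(donor, copy)])
        assert identity == pytest.approx(0.95, abs=0.02)


def test_softmasking_marks_planted_repeats():
    cfg = SimulationConfig(seed=4, n_autosomal_seqs=1, autosomal_length=10_000,
                           x_length=5000, y_length=5000,
                           repeat_family_count=1, repeat_copies_per_compartment=2,
                           repeat_copies_y=3, n_duplications=0)
    genome, truth = simulate_genome(cfg)
    for seq in genome:
        lower = {i for i, ch in enumerate(seq.residues) if ch.islower()}
        planted = {
            i for s, e in truth.repeat_intervals[seq.seq_id] for i in range(s, e)
        }
        assert lower == planted
    # Y carries more repeat copies than the single autosome
    assert len(truth.repeat_intervals["Y"]) == 3
    assert len(truth.repeat_intervals["autosome_1"]) == 2


def test_no_female_reads_match_y_unique_sequence(small_sim):
    """Females carry no Y: error-free female reads never occur on unique Y."""
    _, genome, truth, male, female, _ = small_sim
    y = next(s for s in genome if s.seq_id == "Y")
    frags = fragment_masked(y, min_length=100)
    dup_spans = [(d["y_start"], d["y_end"]) for d in truth.duplications]
    from cqkit.exact_match import build_index, count_alignments

    unique_frags = [
        f for f in frags
        if not any(s < f.end and f.start < e for s, e in dup_spans)
    ]
    assert unique_frags
    index = build_index(unique_frags, k=100)
    counts = count_alignments(index, female)
    assert all(v == 0 for v in counts.counts.values())
    male_counts = count_alignments(index, male)
    assert sum(male_counts.counts.values()) > 0


def test_male_x_depth_is_half_autosomal_depth():
    """One X copy vs two autosome copies: male read density ratio ~ 0.5."""
    cfg = SimulationConfig(seed=6, n_autosomal_seqs=1, autosomal_length=100_000,
                           x_length=100_000, y_length=1000,
                           repeat_family_count=0, n_duplications=0,
                           male_coverage=20, female_coverage=20,
                           n_expressed_y_genes=1, expressed_gene_length=500)
    genome, truth = simulate_genome(cfg)
    male, female, _ = simulate_reads(genome, truth, cfg)
    # reads per sequence are drawn in genome order; recover per-seq totals
    per_seq = {
        s.seq_id: int(round(
            (20 * {"autosome": 2, "X": 1, "Y": 1}[truth.compartment_of[s.seq_id]])
            * len(s) / cfg.read_length
        ))
        for s in genome
    }
    assert per_seq["X"] / per_seq["autosome_1"] == pytest.approx(0.5, rel=0.10)
    assert len(male) == sum(per_seq.values())
    # female pool: no Y reads, X at autosomal depth
    assert len(female) == 2 * 20 * 100_000 // 100 * 2


def test_transcriptome_reads_come_from_planted_genes(small_sim):
    _, genome, truth, _, _, tx = small_sim
    y = next(s.residues.upper() for s in genome if s.seq_id == "Y")
    gene_seqs = [y[s:e] for s, e in truth.expressed_genes]
    from cqkit.exact_match import reverse_complement

    for read in tx.reads:
        assert any(
            read in g or reverse_complement(read) in g for g in gene_seqs
        )


def test_infeasible_configs_rejected():
    with pytest.raises(SimulationError):
        SimulationConfig(y_length=50)  # shorter than read length
    with pytest.raises(SimulationError):
        SimulationConfig(duplication_identity_percent=40.0)
    with pytest.raises(SimulationError):
        SimulationConfig(male_coverage=0)
    with pytest.raises(SimulationError):
        # repeats cannot fit: too many copies for the compartment
        simulate_genome(
            SimulationConfig(seed=0, n_autosomal_seqs=1, autosomal_length=1000,
                             x_length=1000, y_length=1000,
                             repeat_family_count=1, repeat_unit_length=400,
                             repeat_copies_per_compartment=3,
                             n_duplications=0, n_expressed_y_genes=0)
        )


def test_sequencing_errors_reduce_exact_matches():
    base = SimulationConfig(seed=12, n_autosomal_seqs=1, autosomal_length=5000,
                            x_length=5000, y_length=2000,
                            repeat_family_count=0, n_duplications=0,
                            male_coverage=5, female_coverage=5)
    noisy = SimulationConfig(**{**base.__dict__, "sequencing_error_rate": 0.01})
    from cqkit.pipeline import count_read_sets, fragment_genome

    totals = {}
    for cfg in (base, noisy):
        genome, truth = simulate_genome(cfg)
        male, female, _ = simulate_reads(genome, truth, cfg)
        frags = fragment_genome(genome, min_length=250)
        table = count_read_sets(frags, female, male)
        totals[cfg.sequencing_error_rate] = (
            table.table[["female_count", "male_count"]].to_numpy().sum()
        )
    assert totals[0.01] < totals[0.0]
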