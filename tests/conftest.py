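"""Shared fixtures: small simulated datasets written to temp files."""

from __future__ import annotations

import pytest

from geneqc.simulate import SimulationConfig, simulate_genome, simulate_reads_sam


@pytest.fixture(scope="session")
def small_sim():
    """A 60-gene simulation with diverged duplicates (session-cached)."""
    config = SimulationConfig(
        n_genes=60,
        gene_length_bp=300,
        duplicate_fraction=0.3,
        divergence=0.02,
        read_length_bp=75,
        mean_depth=10,
        seed=7,
    )
    fasta_text, gff3_text, truth, genes = simulate_genome(config)
    genome = "".join(fasta_text.split("\n")[1:])
    sam_text = simulate_reads_sam(genome, genes, config)
    return {
        "config": config,
        "fasta": fasta_text,
        "gff3": gff3_text,
        "sam": sam_text,
        "truth": truth,
        "genes": genes,
        "genome": genome,
    }


@pytest.fixture(scope="session")
def small_sim_paths(small_sim, tmp_path_factory):
    base = tmp_path_factory.mktemp("smallsim")
    (base / "genome.fasta").write_text(small_sim["fasta"])
    (base / "genes.gff3").write_text(small_sim["gff3"])
    (base / "reads.sam").write_text(small_sim["sam"])
    return {
        "fasta": str(base / "genome.fasta"),
        "gff": str(base / "genes.gff3"),
        "sam": str(base / "reads.sam"),
    }
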