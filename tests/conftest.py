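"""Shared synthetic fixtures, session-scoped where construction is costly."""

from __future__ import annotations

import numpy as np
import pytest

from conifersnp import genoclone, kmer_lowcopy, mapcall, simgen
from conifersnp.config import PipelineConfig
from conifersnp.seqio import ReadSet


@pytest.fixture(scope="session")
def toy_genome():
    """200 kb repeat-rich genome (the study-scale toy): 75% repeats,
    2% related-species divergence, fragmented draft contigs."""
    return simgen.generate_genome(200_000, seed=11)


@pytest.fixture(scope="session")
def toy_haploids(toy_genome):
    haploids, truth = simgen.sample_haploids(toy_genome, seed=12)
    return haploids, truth


@pytest.fixture(scope="session")
def toy_reads(toy_haploids):
    """Per-sample 5x paired reads (pooled ~20x) with default error rate."""
    haploids, _ = toy_haploids
    return {
        name: simgen.simulate_reads(seq, coverage=5.0, err=0.002, seed=40 + i, sample=name)
        for i, (name, seq) in enumerate(haploids.items())
    }


@pytest.fixture(scope="session")
def toy_kmer_table(toy_reads):
    merged = ReadSet([r for rs in toy_reads.values() for r in rs])
    return merged, kmer_lowcopy.count_kmers(merged, 25)


@pytest.fixture(scope="session")
def clean_callset():
    """Error-free, repeat-free run through mapping and raw pileup calling
    against the draft contigs; used for exact-recovery checks."""
    genome = simgen.generate_genome(
        60_000, repeat_fraction=0.0, divergence=0.02, seed=3,
        n_paralogs=0, contig_noise=0.0
    )
    haploids, truth = simgen.sample_haploids(genome, seed=4)
    idx = mapcall.SeedIndex(genome.draft_contigs)
    alignments = {}
    for i, (name, seq) in enumerate(haploids.items()):
        reads = simgen.simulate_reads(seq, coverage=8.0, err=0.0, seed=20 + i, sample=name)
        alns, _ = mapcall.seed_map(reads, idx)
        alignments[name] = alns
    raw = mapcall.pileup_call(alignments, genome.draft_contigs, method="mas")
    result = mapcall.filter_variants(raw, PipelineConfig())
    return genome, truth, alignments, raw, result


@pytest.fixture(scope="session")
def unique20x():
    """50 kb unique genome with four 5x err-free haploid read sets (pooled
    20x), for the reference-free calling checks."""
    genome = simgen.generate_genome(
        50_000, repeat_fraction=0.0, divergence=0.0, seed=5, n_paralogs=0
    )
    haploids, truth = simgen.sample_haploids(genome, seed=6)
    reads = []
    for i, (name, seq) in enumerate(haploids.items()):
        reads.extend(
            simgen.simulate_reads(seq, coverage=5.0, err=0.0, seed=30 + i, sample=name).reads
        )
    return genome, truth, ReadSet(reads)


@pytest.fixture(scope="session")
def clone_panel():
    """Study-sized clonal population (342 individuals, 5 planted mislabels)
    with called and filtered amplicon genotypes."""
    pop = simgen.build_clone_population(88, 26, 26, 5, seed=7, n_unrelated=1)
    ref_c, alt_c = simgen.simulate_amplicons(pop, seed=8)
    gm = genoclone.call_amplicon_genotypes(ref_c, alt_c)
    panel = genoclone.filter_panel(gm)
    return pop, ref_c, alt_c, panel.gm
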