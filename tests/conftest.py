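"""Shared fixtures: tiny deterministic assemblies and simulated datasets."""

from __future__ import annotations

import pytest

from linkscaf.assembly_io import Contig
from linkscaf.pipeline import RunConfig, run_pipeline
from linkscaf.simulator import (SimConfig, fragment_genome, simulate_genome,
                                simulate_linked_reads)


@pytest.fixture(scope="session")
def small_sim():
    """Small favourable regime: molecules much shorter than contigs.

    10 contigs of ~40-90 kbp, 15 kbp molecules, light barcode reuse, ~10x
    read depth.  Every stage of the pipeline has strong signal here, so
    end-to-end recovery should be essentially perfect.
    """
    config = SimConfig(genome_length=500_000, n_contigs=10,
                       gap_range=(0, 3000), molecule_length_mean=15_000,
                       molecules_per_barcode=2, n_barcodes=1600, seed=7)
    genome = simulate_genome(config)
    contigs, truth = fragment_genome(genome, config)
    pairs, read_truth = simulate_linked_reads(genome, config)
    return {"config": config, "genome": genome, "contigs": contigs,
            "truth": truth, "pairs": pairs, "read_truth": read_truth}


@pytest.fixture(scope="session")
def small_run(small_sim):
    config = RunConfig(k=40, e=8000, j=0.55, c=2, z=500, m=(2, 10_000),
                       D=True, B=5, a=0.5)
    result = run_pipeline(small_sim["contigs"], small_sim["pairs"], config)
    return {**small_sim, "run_config": config, "result": result}


@pytest.fixture
def toy_contigs():
    import numpy as np

    rng = np.random.default_rng(123)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    def seq(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()
    return [Contig("cA", seq(4000)), Contig("cB", seq(4000)),
            Contig("cC", seq(4000))]
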