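"""The package's reference study: fixed desk-scale conditions for replication.

One canonical configuration — a 2 Mbp genome in 40 near-equal ~50 kbp contigs
with 0-5 kbp gaps, Chromium-like reads (exponential molecules of mean 50 kbp,
10 molecules per barcode, ~20x read depth) scaffolded at k=40, e=10 kbp,
c=3, m=2-10000, a=0.5 with gap estimation on — used by the reproducibility
harness and the acceptance tests.  Keeping it in the package guarantees the
tests and the command-line replication script measure the same experiment.

Note the deliberate stress in these conditions: molecule length is comparable
to contig length and each barcode's molecule footprint covers a substantial
fraction of the small genome, so orientation evidence and gap estimates are
much noisier than at real-genome scale (see docs/methods.md).
"""

from __future__ import annotations

from linkscaf.evaluate import evaluate_layouts
from linkscaf.pipeline import RunConfig, run_pipeline
from linkscaf.simulator import (SimConfig, fragment_genome, simulate_genome,
                                simulate_linked_reads)


def reference_sim_config(seed: int) -> SimConfig:
    """Simulator defaults are the reference conditions; only the seed varies."""
    return SimConfig(seed=seed)


def reference_run_config() -> RunConfig:
    return RunConfig(k=40, e=10_000, j=0.55, c=3, l=0, r=0.05, z=500,
                     m=(2, 10_000), B=20, a=0.5, D=True)


def run_reference_study(seed: int):
    """Simulate, scaffold, and score the reference conditions.

    Returns (contigs, read_pairs, truth, pipeline_result, layout_score).
    """
    sim = reference_sim_config(seed)
    genome = simulate_genome(sim)
    contigs, truth = fragment_genome(genome, sim)
    pairs, _ = simulate_linked_reads(genome, sim)
    result = run_pipeline(contigs, pairs, reference_run_config())
    score = evaluate_layouts(result.layouts, truth)
    return contigs, pairs, truth, result, score
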