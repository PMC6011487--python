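"""End-to-end scaffolding pipeline: index -> map -> tally -> test -> layout.

``run_pipeline`` is the library entry point the CLI wraps: it takes contigs
and read pairs already in memory and returns every intermediate product, so
each stage stays inspectable in tests and notebooks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

from linkscaf.assembly_io import Contig, LinkedReadPair
from linkscaf.distance_model import DistanceModel, train
from linkscaf.kmer_index import IndexStats, KmerIndex, build_index
from linkscaf.mapping import (BarcodeMap, MappingParams, MappingStats,
                              build_barcode_map)
from linkscaf.pairing_graph import (GraphParams, PairTally, ScaffoldEdge,
                                    edges_to_frame, emit_edges, tally_pairs)
from linkscaf.scaffolder import (PathParams, ScaffoldLayout, build_layouts,
                                 layouts_to_frame, write_scaffolds)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters, named after the tool's command-line flags.

    k: kmer length; e: end-region length (bp); j: minimum read-kmer match
    fraction; c: minimum read pairs per barcode-end association; l: minimum
    shared barcodes per edge (strict >); r: orientation-test significance;
    z: minimum contig length for graph participation; m: allowed barcode
    multiplicity range; B: distance-estimator neighbourhood size; a: path
    ambiguity ratio; D: emit gap estimates; t: threads (results are
    thread-count invariant; execution is sequential).
    """

    k: int = 60
    e: int = 30_000
    j: float = 0.55
    c: int = 5
    l: int = 0
    r: float = 0.05
    z: int = 3000
    m: tuple[int, int] = (50, 6000)
    B: int = 20
    a: float = 0.5
    D: bool = False
    t: int = 1
    default_gap: int = 100

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.e < 1:
            raise ValueError("e must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")

    def mapping_params(self) -> MappingParams:
        return MappingParams(j_min=self.j, c_min=self.c,
                             m_lo=self.m[0], m_hi=self.m[1])

    def graph_params(self) -> GraphParams:
        return GraphParams(l_min=self.l, r_alpha=self.r)

    def path_params(self) -> PathParams:
        return PathParams(a_max=self.a, default_gap=self.default_gap)


@dataclass
class PipelineResult:
    config: RunConfig
    index: KmerIndex
    index_stats: IndexStats
    barcode_map: BarcodeMap
    mapping_stats: MappingStats
    tally: PairTally
    distance_model: DistanceModel | None
    edges: list[ScaffoldEdge]
    layouts: list[ScaffoldLayout] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "config": {**asdict(self.config), "m": list(self.config.m)},
            "index": asdict(self.index_stats),
            "mapping": asdict(self.mapping_stats),
            "n_contig_pairs_tallied": len(self.tally.counts),
            "n_edges": len(self.edges),
            "n_scaffolds": len(self.layouts),
            "n_joins": sum(len(lay) - 1 for lay in self.layouts),
            "distance_model_samples": (len(self.distance_model)
                                       if self.distance_model else 0),
        }


def run_pipeline(contigs: list[Contig],
                 read_pairs: Iterable[LinkedReadPair],
                 config: RunConfig = RunConfig()) -> PipelineResult:
    """Run every stage and return all intermediates (deterministic)."""
    index, index_stats = build_index(contigs, k=config.k, e=config.e,
                                     z=config.z)
    bmap, map_stats = build_barcode_map(read_pairs, index,
                                        config.mapping_params())
    tally = tally_pairs(bmap)
    model = None
    if config.D:
        model = train(contigs, bmap, e=config.e, B=config.B)
        if not model.samples:
            model = None
    edges = emit_edges(tally, config.graph_params(), dist_model=model,
                       bmap=bmap)
    layouts = build_layouts(edges, contigs, config.path_params())
    return PipelineResult(config=config, index=index, index_stats=index_stats,
                          barcode_map=bmap, mapping_stats=map_stats,
                          tally=tally, distance_model=model, edges=edges,
                          layouts=layouts)


def write_outputs(result: PipelineResult, contigs: list[Contig],
                  outdir: str | Path) -> dict[str, Path]:
    """Write the edge TSV, layout TSV, scaffold FASTA, and a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "layout": outdir / "layout.tsv",
        "scaffolds": outdir / "scaffolds.fa",
        "report": outdir / "report.json",
    }
    edges_to_frame(result.edges).to_csv(paths["edges"], sep="\t", index=False)
    layouts_to_frame(result.layouts).to_csv(paths["layout"], sep="\t",
                                            index=False)
    write_scaffolds(result.layouts, contigs, paths["scaffolds"])
    with open(paths["report"], "wt") as fh:
        json.dump(result.report(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
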