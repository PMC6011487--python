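"""Shared-barcode tallies, orientation testing, and scaffold-graph edges.

For every barcode, each unordered pair of distinct contigs among its
associated ends increments one of four orientation cells (HH, HT, TH, TT:
which end of each contig faces the join).  A candidate contig pair supported
in multiple orientations is resolved with an exact two-sided binomial test of
the null hypothesis that the two orientations with the highest shared-barcode
counts are equally likely; the pair is kept only when the test rejects at
level r.  Surviving pairs whose winning count exceeds the -l threshold become
scaffold-graph edges, optionally annotated with a gap-size estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import pandas as pd

from linkscaf.mapping import BarcodeMap

# cell order is fixed: which end of contig A (lexicographically smaller id)
# meets which end of contig B
ORIENTATIONS = ("HH", "HT", "TH", "TT")
_ORI_POS = {o: i for i, o in enumerate(ORIENTATIONS)}


@dataclass(frozen=True)
class GraphParams:
    """l_min: minimum shared-barcode count, strict > (-l).
    r_alpha: significance level of the orientation test (-r)."""

    l_min: int = 0
    r_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.r_alpha < 1.0:
            raise ValueError("r_alpha must lie in (0, 1)")
        if self.l_min < 0:
            raise ValueError("l_min must be >= 0")


@dataclass
class PairTally:
    """(contigA_id, contigB_id) -> shared-barcode counts per orientation.

    Keys always carry the lexicographically smaller contig id first.
    """

    counts: dict[tuple[str, str], list[int]] = field(default_factory=dict)


@dataclass(frozen=True)
class ScaffoldEdge:
    """An oriented, tested link between the ends of two contigs."""

    contigA_id: str
    contigB_id: str
    orientation: str  # HH / HT / TH / TT, A < B by id
    n_shared: int
    p_value: float
    est_distance: int | None = None

    @property
    def end_a(self) -> tuple[str, str]:
        return (self.contigA_id, self.orientation[0])

    @property
    def end_b(self) -> tuple[str, str]:
        return (self.contigB_id, self.orientation[1])


def tally_pairs(bmap: BarcodeMap) -> PairTally:
    """Count barcodes shared by each candidate pair of contig ends.

    Each barcode contributes at most 1 to any given cell (set semantics over
    barcodes); pairs of ends on the same contig are skipped.
    """
    tally = PairTally()
    counts = tally.counts
    for ends in bmap.assoc.values():
        end_list = sorted(ends)  # deterministic; ContigEnd sorts as a tuple
        for i in range(len(end_list)):
            ei = end_list[i]
            for j in range(i + 1, len(end_list)):
                ej = end_list[j]
                if ei.contig_id == ej.contig_id:
                    continue
                if ei.contig_id < ej.contig_id:
                    key = (ei.contig_id, ej.contig_id)
                    ori = ei.which + ej.which
                else:
                    key = (ej.contig_id, ei.contig_id)
                    ori = ej.which + ei.which
                cell = counts.get(key)
                if cell is None:
                    cell = counts[key] = [0, 0, 0, 0]
                cell[_ORI_POS[ori]] += 1
    return tally


def exact_binomial_p(x: int, n: int) -> float:
    """Exact two-sided binomial p-value of x successes in n trials at p0=1/2.

    Computed with integer arithmetic: the sum of C(n, i)/2**n over all
    outcomes i whose probability does not exceed that of x.
    """
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if n == 0:
        return 1.0
    thresh = comb(n, x)
    mass = sum(c for i in range(n + 1) if (c := comb(n, i)) <= thresh)
    return mass / (1 << n)


def binomial_orientation_test(counts: list[int] | tuple[int, ...],
                              r_alpha: float = 0.05
                              ) -> tuple[str, float] | None:
    """Resolve the orientation of a contig pair from its four cell counts.

    Returns (winning orientation, p-value) when the two largest counts differ
    significantly (p < r_alpha), else None (the pair is dropped).  The test
    only arbitrates *competing* orientations: a pair supported in a single
    orientation is accepted outright, carrying the degenerate p-value of c1
    successes in c1 trials for a uniform output schema.
    """
    if len(counts) != 4:
        raise ValueError("expected four orientation counts")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    order = sorted(range(4), key=lambda i: (-counts[i], i))
    c1, c2 = counts[order[0]], counts[order[1]]
    if c1 == 0:
        return None
    p = exact_binomial_p(c1, c1 + c2)
    if c2 > 0 and p >= r_alpha:
        return None
    return ORIENTATIONS[order[0]], p


def emit_edges(tally: PairTally, params: GraphParams,
               dist_model=None, bmap: BarcodeMap | None = None
               ) -> list[ScaffoldEdge]:
    """Scaffold-graph edges for all pairs passing the orientation test and -l.

    When a distance model is supplied (the -D mode), each edge is annotated
    with the gap estimated from the barcode Jaccard index of its two ends;
    ``bmap`` is then required to recover the per-end barcode sets.  Output is
    sorted by contig ids for determinism.
    """
    bc_lookup: dict[tuple[str, str], set[str]] = {}
    if dist_model is not None:
        if bmap is None:
            raise ValueError("bmap is required to estimate distances")
        from linkscaf.distance_model import barcode_sets

        bc_lookup = {
            (end.contig_id, end.which): bcs
            for end, bcs in barcode_sets(bmap).items()
        }

    edges: list[ScaffoldEdge] = []
    for (a, b), cells in sorted(tally.counts.items()):
        result = binomial_orientation_test(cells, params.r_alpha)
        if result is None:
            continue
        orientation, p = result
        n_shared = cells[_ORI_POS[orientation]]
        if not n_shared > params.l_min:
            continue
        est = None
        if dist_model is not None:
            from linkscaf.distance_model import estimate_distance

            bc_a = bc_lookup.get((a, orientation[0]), set())
            bc_b = bc_lookup.get((b, orientation[1]), set())
            est = estimate_distance(bc_a, bc_b, dist_model)
        edges.append(ScaffoldEdge(a, b, orientation, n_shared, p, est))
    return edges


def edges_to_frame(edges: list[ScaffoldEdge]) -> pd.DataFrame:
    """Edge table: contigA, contigB, orientation, shared_barcodes, p_value,
    est_distance (NA when absent)."""
    return pd.DataFrame(
        [
            (e.contigA_id, e.contigB_id, e.orientation, e.n_shared, e.p_value,
             e.est_distance if e.est_distance is not None else pd.NA)
            for e in edges
        ],
        columns=["contigA", "contigB", "orientation", "shared_barcodes",
                 "p_value", "est_distance"],
    )
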