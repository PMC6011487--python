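"""Walk unambiguous paths of the scaffold graph into scaffold sequences.

A deliberately simple path builder stands in for a full downstream scaffolder:
at every contig end the incident edges are ranked by shared-barcode support,
and the end is extendable only when its best edge is also the best edge of
the partner end (reciprocal best) and the runner-up support at both ends is
at most ``a_max`` times the best (ambiguity ratio).  Chains of extendable
links become scaffold layouts; everything else stays a singleton.  Cycles are
broken at their weakest link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from linkscaf.assembly_io import Contig, HEAD, TAIL, write_fasta
from linkscaf.kmer_index import revcomp
from linkscaf.pairing_graph import ScaffoldEdge

MIN_GAP_NS = 10  # joins stay visible to downstream scaffold-splitting tools


@dataclass(frozen=True)
class PathParams:
    """a_max: maximum runner-up/best support ratio for an unambiguous end.
    default_gap: N-run length when an edge carries no distance estimate."""

    a_max: float = 0.5
    default_gap: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.a_max <= 1.0:
            raise ValueError("a_max must lie in (0, 1]")
        if self.default_gap < 1:
            raise ValueError("default_gap must be >= 1")


@dataclass
class LayoutEntry:
    contig_id: str
    strand: str  # '+' or '-'
    gap_after: int | None = None  # N-run length before the next entry
    est_distance: int | None = None  # raw edge estimate, for evaluation


@dataclass
class ScaffoldLayout:
    entries: list[LayoutEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def _edge_sort_key(edge: ScaffoldEdge):
    return (-edge.n_shared, edge.contigA_id, edge.contigB_id, edge.orientation)


def _gap_for(edge: ScaffoldEdge, params: PathParams) -> int:
    if edge.est_distance is not None:
        return max(edge.est_distance, MIN_GAP_NS)
    return params.default_gap


def build_layouts(edges: list[ScaffoldEdge], contigs: list[Contig],
                  params: PathParams = PathParams()) -> list[ScaffoldLayout]:
    """Greedy unambiguous-path layouts; every contig appears exactly once."""
    incident: dict[tuple[str, str], list[ScaffoldEdge]] = {}
    for edge in edges:
        incident.setdefault(edge.end_a, []).append(edge)
        incident.setdefault(edge.end_b, []).append(edge)

    best_at: dict[tuple[str, str], ScaffoldEdge] = {}
    unambiguous: dict[tuple[str, str], bool] = {}
    for end, lst in incident.items():
        lst.sort(key=_edge_sort_key)
        best = lst[0]
        ok = True
        if len(lst) > 1:
            second = lst[1]
            if second.n_shared >= best.n_shared:
                ok = False  # tie for best support: ambiguous
            elif second.n_shared / best.n_shared > params.a_max:
                ok = False
        best_at[end] = best
        unambiguous[end] = ok

    links: list[ScaffoldEdge] = []
    for edge in edges:
        if (best_at.get(edge.end_a) is edge and best_at.get(edge.end_b) is edge
                and unambiguous[edge.end_a] and unambiguous[edge.end_b]):
            links.append(edge)

    # each end now carries at most one accepted link
    link_at: dict[tuple[str, str], ScaffoldEdge] = {}
    for edge in links:
        link_at[edge.end_a] = edge
        link_at[edge.end_b] = edge

    # break cycles (components where every end that could terminate a walk is
    # taken) at their minimum-support link
    links = _break_cycles(links, params)
    link_at = {}
    for edge in links:
        link_at[edge.end_a] = edge
        link_at[edge.end_b] = edge

    layouts: list[ScaffoldLayout] = []
    placed: set[str] = set()
    # deterministic walk order: chain termini sorted by contig id
    candidates = sorted(
        {c.id for c in contigs},
    )
    for cid in candidates:
        if cid in placed:
            continue
        head_link = link_at.get((cid, HEAD))
        tail_link = link_at.get((cid, TAIL))
        if head_link is not None and tail_link is not None:
            continue  # interior contig of a chain; reached from a terminus
        layouts.append(_walk_chain(cid, link_at, params, placed))
    # anything still unplaced would sit on an unbroken cycle; emit defensively
    for cid in candidates:
        if cid not in placed:
            layouts.append(_walk_chain(cid, link_at, params, placed,
                                       force=True))
    return layouts


def _other_side(edge: ScaffoldEdge, end: tuple[str, str]) -> tuple[str, str]:
    return edge.end_b if end == edge.end_a else edge.end_a


def _walk_chain(start: str, link_at: dict, params: PathParams,
                placed: set[str], force: bool = False) -> ScaffoldLayout:
    layout = ScaffoldLayout()
    # choose the free end of the start contig as the scaffold's left edge
    if link_at.get((start, HEAD)) is None and not force:
        exit_end = (start, TAIL)
        strand = "+"
    else:
        exit_end = (start, HEAD)
        strand = "-" if not force else "+"
    if force:
        exit_end = (start, TAIL)
    layout.entries.append(LayoutEntry(start, strand))
    placed.add(start)
    while True:
        edge = link_at.get(exit_end)
        if edge is None:
            break
        entered = _other_side(edge, exit_end)
        nxt, which = entered
        if nxt in placed:  # safety against residual cycles
            break
        layout.entries[-1].gap_after = _gap_for(edge, params)
        layout.entries[-1].est_distance = edge.est_distance
        strand = "+" if which == HEAD else "-"
        layout.entries.append(LayoutEntry(nxt, strand))
        placed.add(nxt)
        exit_end = (nxt, TAIL if which == HEAD else HEAD)
    return layout


def _break_cycles(links: list[ScaffoldEdge],
                  params: PathParams) -> list[ScaffoldEdge]:
    # union-find over contigs; an added link closing a loop within one
    # component marks that component as a cycle
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept: list[ScaffoldEdge] = []
    # weakest-first removal: consider links strongest-first and drop any link
    # that would close a loop (deterministic tie-break via the sort key)
    for edge in sorted(links, key=_edge_sort_key):
        ra, rb = find(edge.contigA_id), find(edge.contigB_id)
        if ra == rb:
            continue  # this is the weakest link of its cycle: break here
        parent[ra] = rb
        kept.append(edge)
    return kept


def layouts_to_frame(layouts: list[ScaffoldLayout]) -> pd.DataFrame:
    """Layout table: scaffold_id, position, contig_id, strand, gap_after,
    est_distance (the raw edge estimate behind the resolved gap)."""
    rows = []
    for s, layout in enumerate(layouts):
        for pos, entry in enumerate(layout.entries):
            rows.append((f"scaffold{s + 1}", pos, entry.contig_id, entry.strand,
                         entry.gap_after if entry.gap_after is not None
                         else pd.NA,
                         entry.est_distance if entry.est_distance is not None
                         else pd.NA))
    return pd.DataFrame(
        rows, columns=["scaffold_id", "position", "contig_id", "strand",
                       "gap_after", "est_distance"])


def write_scaffolds(layouts: list[ScaffoldLayout], contigs: list[Contig],
                    out_path) -> None:
    """Merge layouts into scaffold FASTA records.

    Minus-strand contigs are reverse complemented; joins are separated by
    N-runs of the layout's resolved gap length.  Scaffold headers record the
    constituent contigs and strands.
    """
    by_id = {c.id: c for c in contigs}
    records = []
    for s, layout in enumerate(layouts):
        parts: list[str] = []
        label: list[str] = []
        for entry in layout.entries:
            seq = by_id[entry.contig_id].seq
            parts.append(seq if entry.strand == "+" else revcomp(seq))
            label.append(f"{entry.contig_id}{entry.strand}")
            if entry.gap_after is not None:
                parts.append("N" * entry.gap_after)
        records.append((f"scaffold{s + 1} {','.join(label)}", "".join(parts)))
    write_fasta(records, out_path)
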