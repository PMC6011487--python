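"""Score scaffold layouts against simulator ground truth.

A layout join (two contigs placed adjacently in one scaffold) is counted
correct when the two contigs are genomic neighbours in the truth table AND
the relative orientation implied by the layout matches the genome.  The
orientation check converts each layout strand (relative to the emitted draft)
into a genome orientation via the truth table's draft strand, then requires
both contigs to face the same way with the genomic predecessor on the correct
side.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import pearsonr

from linkscaf.scaffolder import ScaffoldLayout


@dataclass
class LayoutScore:
    n_true_adjacencies: int
    n_joins: int
    n_correct_joins: int  # correct adjacency AND relative orientation
    n_adjacent_joins: int  # correct adjacency, orientation ignored
    adjacency_recall: float
    join_accuracy: float  # correct joins / all joins
    orientation_accuracy: float  # correct joins / adjacent joins
    gap_pearson_r: float | None
    n_gap_estimates: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _joins(layouts: list[ScaffoldLayout]):
    for layout in layouts:
        for left, right in zip(layout.entries, layout.entries[1:]):
            yield left, right


def evaluate_layouts(layouts: list[ScaffoldLayout],
                     truth: pd.DataFrame) -> LayoutScore:
    """Adjacency recall, join accuracy, and gap-estimate correlation."""
    info = truth.set_index("contig_id")
    order = truth.sort_values("genome_order")
    successor: dict[str, str] = {}
    true_gap: dict[tuple[str, str], int] = {}
    ids = list(order["contig_id"])
    gaps = list(order["gap_after"])
    for a, b, g in zip(ids, ids[1:], gaps):
        successor[a] = b
        true_gap[(a, b)] = int(g)

    n_joins = n_adj = n_correct = 0
    est_pairs: list[tuple[int, int]] = []
    for left, right in _joins(layouts):
        n_joins += 1
        a, b = left.contig_id, right.contig_id
        fa = info.at[a, "draft_strand"]
        fb = info.at[b, "draft_strand"]
        # genome orientation of each contig as laid out
        ga = "+" if left.strand == fa else "-"
        gb = "+" if right.strand == fb else "-"
        adjacent = successor.get(a) == b or successor.get(b) == a
        if adjacent:
            n_adj += 1
        oriented = (
            ga == gb
            and ((ga == "+" and successor.get(a) == b)
                 or (ga == "-" and successor.get(b) == a))
        )
        if oriented:
            n_correct += 1
            key = (a, b) if successor.get(a) == b else (b, a)
            if left.est_distance is not None:
                est_pairs.append((left.est_distance, true_gap[key]))

    r = None
    if len(est_pairs) >= 3:
        est, true = zip(*est_pairs)
        if len(set(est)) > 1 and len(set(true)) > 1:
            r = float(pearsonr(est, true)[0])

    n_true = len(successor)
    return LayoutScore(
        n_true_adjacencies=n_true,
        n_joins=n_joins,
        n_correct_joins=n_correct,
        n_adjacent_joins=n_adj,
        adjacency_recall=n_adj / n_true if n_true else 0.0,
        join_accuracy=n_correct / n_joins if n_joins else 0.0,
        orientation_accuracy=n_correct / n_adj if n_adj else 0.0,
        gap_pearson_r=r,
        n_gap_estimates=len(est_pairs),
    )
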