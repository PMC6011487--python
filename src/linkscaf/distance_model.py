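"""Empirical Jaccard-to-distance model for gap-size estimation.

Pairs of contig ends that are farther apart share fewer droplet barcodes, but
the shape of that decay depends on sequencing depth and on the long-molecule
length distribution, so it is learned from the data itself: every contig
longer than twice the end-region length contributes one training sample — the
known distance between its own head and tail regions (length − 2e) paired
with the Jaccard index of their barcode sets

    J(x, y) = |barcodes(x) ∩ barcodes(y)| / |barcodes(x) ∪ barcodes(y)|.

A candidate join's gap is then estimated as the median training distance of
the B samples whose Jaccard indices are closest to the join's own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from linkscaf.assembly_io import Contig, contig_ends
from linkscaf.mapping import BarcodeMap


@dataclass
class DistanceModel:
    """Intra-contig (jaccard, distance) training samples plus the -B width."""

    samples: list[tuple[float, int]] = field(default_factory=list)
    B: int = 20

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["jaccard", "distance"])


def jaccard(x: set[str], y: set[str]) -> float:
    """Jaccard index of two barcode sets; 0 when both are empty."""
    if not x and not y:
        return 0.0
    return len(x & y) / len(x | y)


def barcode_sets(bmap: BarcodeMap) -> dict:
    """Invert a BarcodeMap: contig end -> set of associated barcodes."""
    out: dict = {}
    for bc, ends in bmap.assoc.items():
        for end in ends:
            out.setdefault(end, set()).add(bc)
    return out


def train(contigs: list[Contig], bmap: BarcodeMap, e: int,
          B: int = 20) -> DistanceModel:
    """Fit the model from intra-contig head/tail pairs.

    Only contigs with length strictly greater than 2e are eligible; each
    contributes distance = length − 2e and the Jaccard index of its head and
    tail barcode sets (0 when an end has no associations).  Samples are kept
    in input contig order, which also fixes estimator tie-breaking.
    """
    if e <= 0:
        raise ValueError("e must be positive")
    end_bc = barcode_sets(bmap)
    model = DistanceModel(B=B)
    for contig in contigs:
        if contig.length <= 2 * e:
            continue
        head, tail = contig_ends(contig, e)
        j = jaccard(end_bc.get(head, set()), end_bc.get(tail, set()))
        model.samples.append((j, contig.length - 2 * e))
    if not model.samples:
        import warnings

        warnings.warn("no contig longer than 2e; distance model is empty "
                      "and estimates will be None", stacklevel=2)
    return model


def _median_int(values: list[int]) -> int:
    """Median; for an even count, the mean of the central pair rounded half-up."""
    ordered = sorted(values)
    n = len(ordered)
    if n % 2 == 1:
        return ordered[n // 2]
    mid = (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    return math.floor(mid + 0.5)


def estimate_distance(x: set[str], y: set[str],
                      model: DistanceModel) -> int | None:
    """Gap estimate for the join of barcode sets x, y, or None if untrained.

    Selects the B training samples minimising |J(x,y) − sample jaccard| (ties
    broken by training order, B capped at the sample count) and returns the
    median of their distances.
    """
    if model is None or not model.samples:
        return None
    q = jaccard(x, y)
    b = min(model.B, len(model.samples))
    nearest = sorted(
        range(len(model.samples)),
        key=lambda i: (abs(q - model.samples[i][0]), i),
    )[:b]
    return _median_int([model.samples[i][1] for i in nearest])


def plot_training(model: DistanceModel, out_path: str) -> None:
    """Diagnostic scatter of training Jaccard index vs intra-contig distance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = model.to_frame()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(frame["distance"], frame["jaccard"], s=12, alpha=0.7)
    ax.set_xlabel("intra-contig head-tail distance (bp)")
    ax.set_ylabel("barcode Jaccard index")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
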