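"""Read-pair mapping by kmer fraction and the barcode -> contig-end table.

Each read is scored against candidate contig ends with

    score_j(end, read) = |kmers(end) ∩ kmers(read)| / |kmers(read)|

where kmer sets are canonical and the denominator counts every valid read
kmer (including kmers that were dropped from the index as multimapped).  A
read maps to the unique best-scoring end with score >= j_min; score ties are
discarded as ambiguous.  Both mates of a pair must map to the same contig end
for the pair to count.

Surviving pairs populate a barcode -> {contig end -> read-pair count} table,
after a barcode-multiplicity filter (total read pairs per barcode must lie in
[m_lo, m_hi]) and a per-association minimum read-pair count (c_min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from linkscaf.assembly_io import ContigEnd, LinkedReadPair
from linkscaf.kmer_index import KmerIndex, kmerize


@dataclass(frozen=True)
class MappingParams:
    """Read-mapping and barcode-filter thresholds.

    j_min: minimum fraction of read kmers matching the chosen end (-j).
    c_min: minimum read pairs per (barcode, contig end) association (-c).
    m_lo, m_hi: allowed range of total read pairs per barcode (-m).
    """

    j_min: float = 0.55
    c_min: int = 5
    m_lo: int = 50
    m_hi: int = 6000

    def __post_init__(self) -> None:
        if not 0.0 <= self.j_min <= 1.0:
            raise ValueError("j_min must lie in [0, 1]")
        if self.c_min < 1:
            raise ValueError("c_min must be >= 1")
        if self.m_lo > self.m_hi:
            raise ValueError("m_lo must be <= m_hi")


@dataclass
class BarcodeMap:
    """barcode -> (contig end -> mapped read-pair count), plus multiplicities."""

    assoc: dict[str, dict[ContigEnd, int]] = field(default_factory=dict)
    barcode_multiplicity: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """TSV-friendly checkpoint: barcode, contig_id, end, count."""
        rows = [
            (bc, end.contig_id, end.which, n)
            for bc, ends in sorted(self.assoc.items())
            for end, n in sorted(ends.items())
        ]
        return pd.DataFrame(rows, columns=["barcode", "contig_id", "end", "count"])


@dataclass
class MappingStats:
    """Per-pair accounting; the categories partition n_pairs_total."""

    n_pairs_total: int = 0
    n_pairs_no_barcode: int = 0
    n_pairs_multiplicity_filtered: int = 0
    n_pairs_unmapped: int = 0
    n_pairs_discordant: int = 0
    n_pairs_pruned_low_count: int = 0
    n_pairs_stored: int = 0


def score_read(read: str, candidate_end: ContigEnd, index: KmerIndex) -> float:
    """score_j of one read against one contig end, via the index."""
    read_kmers = set(kmerize(read, index.k))
    if not read_kmers:
        return 0.0
    table = index.table
    hits = sum(1 for km in read_kmers if table.get(km) == candidate_end)
    return hits / len(read_kmers)


def _candidate_scores(read: str, index: KmerIndex
                      ) -> tuple[dict[ContigEnd, int], int]:
    read_kmers = set(kmerize(read, index.k))
    table = index.table
    hits: dict[ContigEnd, int] = {}
    for km in read_kmers:
        end = table.get(km)
        if end is not None:
            hits[end] = hits.get(end, 0) + 1
    return hits, len(read_kmers)


def map_read(read: str, index: KmerIndex, j_min: float = 0.55
             ) -> ContigEnd | None:
    """Best-scoring contig end with score >= j_min, or None.

    Ties for the best score are ambiguous and return None.
    """
    hits, n_kmers = _candidate_scores(read, index)
    if not hits or n_kmers == 0:
        return None
    best_n = max(hits.values())
    if best_n / n_kmers < j_min:
        return None
    best_ends = [end for end, n in hits.items() if n == best_n]
    if len(best_ends) > 1:
        return None
    return best_ends[0]


def map_read_pair(pair: LinkedReadPair, index: KmerIndex,
                  params: MappingParams) -> ContigEnd | None:
    """Common contig end of both mates, or None (same-target rule).

    The same-target rule is enforced at contig-END granularity: a pair whose
    mates hit the head and the tail of one contig is discarded.
    """
    end1 = map_read(pair.read1, index, params.j_min)
    if end1 is None:
        return None
    end2 = map_read(pair.read2, index, params.j_min)
    if end2 != end1:
        return None
    return end1


def build_barcode_map(reads: Iterable[LinkedReadPair], index: KmerIndex,
                      params: MappingParams) -> tuple[BarcodeMap, MappingStats]:
    """Map read pairs and accumulate the barcode -> contig-end table.

    Pass 1 counts read pairs per barcode over the whole dataset (mapped or
    not); barcodes with multiplicity outside [m_lo, m_hi] are excluded.  Pass
    2 maps the surviving pairs.  Finally, (barcode, end) associations with
    fewer than c_min supporting pairs are pruned.
    """
    pairs = list(reads)
    stats = MappingStats(n_pairs_total=len(pairs))
    if not pairs:
        import warnings

        warnings.warn("empty read stream; barcode map is empty", stacklevel=2)
        return BarcodeMap(), stats

    multiplicity: dict[str, int] = {}
    for pair in pairs:
        if pair.has_barcode:
            multiplicity[pair.barcode] = multiplicity.get(pair.barcode, 0) + 1

    bmap = BarcodeMap(barcode_multiplicity=multiplicity)
    assoc = bmap.assoc
    for pair in pairs:
        if not pair.has_barcode:
            stats.n_pairs_no_barcode += 1
            continue
        if not params.m_lo <= multiplicity[pair.barcode] <= params.m_hi:
            stats.n_pairs_multiplicity_filtered += 1
            continue
        end1 = map_read(pair.read1, index, params.j_min)
        end2 = map_read(pair.read2, index, params.j_min)
        if end1 is None or end2 is None:
            stats.n_pairs_unmapped += 1
            continue
        if end1 != end2:
            stats.n_pairs_discordant += 1
            continue
        assoc.setdefault(pair.barcode, {})
        assoc[pair.barcode][end1] = assoc[pair.barcode].get(end1, 0) + 1

    for bc in list(assoc):
        ends = assoc[bc]
        for end in list(ends):
            if ends[end] < params.c_min:
                stats.n_pairs_pruned_low_count += ends.pop(end)
        if not ends:
            del assoc[bc]
    stats.n_pairs_stored = sum(n for ends in assoc.values() for n in ends.values())
    return bmap, stats
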