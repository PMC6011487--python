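"""Canonical-kmer hash index of contig end regions.

The index associates every canonical kmer that occurs in exactly one contig
end region with that end.  Kmers occurring in two or more distinct ends are
recorded as multimapped and excluded from the table, so an index lookup can
never attribute a read kmer to the wrong end.  Kmers are strand-folded
(canonical = lexicographic min of the kmer and its reverse complement) so
reads map identically from either sequencing strand; only windows over
{A,C,G,T} are considered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from linkscaf.assembly_io import Contig, ContigEnd, contig_ends, end_sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGT = re.compile(r"[^ACGT]")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def kmerize(seq: str, k: int) -> list[str]:
    """All canonical kmers of ``seq`` by sliding window, in order.

    Windows containing a non-ACGT character are skipped.  A sequence shorter
    than ``k`` yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(seq)
    if n < k:
        return []
    rc = seq.translate(_COMPLEMENT)[::-1]
    last = n - k
    out: list[str] = []
    append = out.append
    if _NON_ACGT.search(seq) is None:
        for i in range(last + 1):
            f = seq[i:i + k]
            r = rc[last - i:last - i + k]
            append(f if f <= r else r)
        return out
    # slow path: skip windows overlapping an invalid character
    bad = [m.start() for m in _NON_ACGT.finditer(seq)]
    bi = 0
    for i in range(last + 1):
        while bi < len(bad) and bad[bi] < i:
            bi += 1
        if bi < len(bad) and bad[bi] < i + k:
            continue
        f = seq[i:i + k]
        r = rc[last - i:last - i + k]
        append(f if f <= r else r)
    return out


@dataclass
class IndexStats:
    n_ends_indexed: int = 0
    n_kmers_stored: int = 0
    n_kmers_dropped_multimapped: int = 0
    n_kmers_dropped_nonACGT: int = 0


@dataclass
class KmerIndex:
    """Map canonical kmer -> its unique contig end; cross-end kmers dropped."""

    k: int
    table: dict[str, ContigEnd] = field(default_factory=dict)
    multimapped: set[str] = field(default_factory=set)


def build_index(contigs: list[Contig], k: int, e: int,
                z: int = 0) -> tuple[KmerIndex, IndexStats]:
    """Index the end regions of all contigs of length >= ``z``.

    Contigs shorter than ``z`` (and degenerate contigs shorter than 2 bp) are
    excluded from indexing; they are carried through to output unscaffolded by
    the caller.  A kmer seen in two or more distinct end regions is moved to
    the multimapped set; repeats *within* a single end are kept (only
    cross-end ambiguity is discarded).
    """
    index = KmerIndex(k=k)
    stats = IndexStats()
    table = index.table
    multi = index.multimapped
    for contig in contigs:
        if contig.length < z or contig.length < 2:
            continue
        for end in contig_ends(contig, e):
            if end.stop <= end.start:
                continue
            region = end_sequence(contig, end)
            kmers = kmerize(region, k)
            n_windows = max(len(region) - k + 1, 0)
            stats.n_kmers_dropped_nonACGT += n_windows - len(kmers)
            stats.n_ends_indexed += 1
            for km in kmers:
                if km in multi:
                    continue
                owner = table.get(km)
                if owner is None:
                    table[km] = end
                elif owner != end:
                    del table[km]
                    multi.add(km)
    stats.n_kmers_stored = len(table)
    stats.n_kmers_dropped_multimapped = len(multi)
    if stats.n_ends_indexed == 0:
        import warnings

        warnings.warn("no contig passed the minimum-length (z) filter; "
                      "index is empty", stacklevel=2)
    return index, stats
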