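"""score_j mapping, the same-target rule, and barcode-table filters."""

from __future__ import annotations

import pytest

from linkscaf.assembly_io import Contig, LinkedReadPair, contig_ends
from linkscaf.kmer_index import build_index, kmerize, revcomp
from linkscaf.mapping import (MappingParams, build_barcode_map, map_read,
                              map_read_pair, score_read)


@pytest.fixture(scope="module")
def indexed():
    import numpy as np

    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def seq(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()

    contigs = [Contig("cA", seq(6000)), Contig("cB", seq(6000))]
    index, _ = build_index(contigs, k=21, e=2000, z=0)
    return contigs, index


def brute_force_map(read, contigs, k, e, j_min):
    """Index-free oracle: score every end from its literal kmer set, after
    discarding kmers with multiple end memberships."""
    from linkscaf.assembly_io import end_sequence

    end_kmers = {}
    for contig in contigs:
        for end in contig_ends(contig, e):
            end_kmers[end] = set(kmerize(end_sequence(contig, end), k))
    counts = {}
    for kmers in end_kmers.values():
        for km in kmers:
            counts[km] = counts.get(km, 0) + 1
    multi = {km for km, n in counts.items() if n > 1}
    read_kmers = set(kmerize(read, k))
    if not read_kmers:
        return None
    scores = {end: len((kmers - multi) & read_kmers) / len(read_kmers)
              for end, kmers in end_kmers.items()}
    best = max(scores.values())
    if best < j_min:
        return None
    winners = [end for end, s in scores.items() if s == best]
    return winners[0] if len(winners) == 1 else None


class TestScoreRead:
    def test_identity_read_scores_one(self, indexed):
        contigs, index = indexed
        head = contig_ends(contigs[0], 2000)[0]
        read = contigs[0].seq[100:200]
        assert score_read(read, head, index) == 1.0

    def test_partial_overlap_fraction(self, indexed):
        contigs, index = indexed
        head = contig_ends(contigs[0], 2000)[0]
        # read straddling the region boundary: only a prefix of kmers match
        read = contigs[0].seq[1950:2050]
        score = score_read(read, head, index)
        n_kmers = len(set(kmerize(read, 21)))
        matching = sum(1 for km in set(kmerize(read, 21))
                       if index.table.get(km) == head)
        assert score == pytest.approx(matching / n_kmers)
        assert 0 < score < 1

    def test_no_kmers_scores_zero(self, indexed):
        _, index = indexed
        assert score_read("NNNNNNNNNNNNNNNNNNNNNNNN", None, index) == 0.0


class TestMapRead:
    def test_maps_to_origin_end(self, indexed):
        contigs, index = indexed
        head = contig_ends(contigs[1], 2000)[0]
        assert map_read(contigs[1].seq[500:650], index) == head

    def test_reverse_strand_maps_identically(self, indexed):
        contigs, index = indexed
        read = contigs[1].seq[500:650]
        assert map_read(revcomp(read), index) == map_read(read, index)

    def test_interior_read_unmapped(self, indexed):
        contigs, index = indexed
        # interior (masked) sequence: [2000, 4000) of a 6000 bp contig
        assert map_read(contigs[0].seq[2800:2950], index) is None

    def test_below_threshold_unmapped(self, indexed):
        contigs, index = indexed
        read = contigs[0].seq[1950:2050]  # boundary read, score < 0.55
        score = score_read(read, contig_ends(contigs[0], 2000)[0], index)
        assert score < 0.55
        assert map_read(read, index, j_min=0.55) is None
        assert map_read(read, index, j_min=score) is not None

    def test_oracle_equivalence_random_reads(self, indexed):
        import numpy as np

        contigs, index = indexed
        rng = np.random.default_rng(9)
        genome = contigs[0].seq + contigs[1].seq
        for _ in range(300):
            start = int(rng.integers(0, len(genome) - 150))
            read = genome[start:start + 150]
            if rng.random() < 0.5:
                read = revcomp(read)
            assert map_read(read, index, 0.55) == brute_force_map(
                read, contigs, 21, 2000, 0.55)


class TestMapReadPair:
    def test_same_end_accepted(self, indexed):
        contigs, index = indexed
        params = MappingParams(c_min=1, m_lo=1, m_hi=10**9)
        pair = LinkedReadPair(contigs[0].seq[100:250],
                              revcomp(contigs[0].seq[400:550]), "B-1", True)
        head = contig_ends(contigs[0], 2000)[0]
        assert map_read_pair(pair, index, params) == head

    def test_head_tail_discordant(self, indexed):
        contigs, index = indexed
        params = MappingParams(c_min=1, m_lo=1, m_hi=10**9)
        pair = LinkedReadPair(contigs[0].seq[100:250],
                              contigs[0].seq[4500:4650], "B-1", True)
        assert map_read_pair(pair, index, params) is None

    def test_one_mate_unmapped(self, indexed):
        contigs, index = indexed
        params = MappingParams(c_min=1, m_lo=1, m_hi=10**9)
        pair = LinkedReadPair(contigs[0].seq[100:250],
                              contigs[0].seq[2800:2950], "B-1", True)
        assert map_read_pair(pair, index, params) is None


class TestBuildBarcodeMap:
    def _pairs(self, contigs, barcode, n, start=100):
        seq = contigs[0].seq
        return [LinkedReadPair(seq[start + 10 * i:start + 10 * i + 150],
                               revcomp(seq[start + 200:start + 350]),
                               barcode, True)
                for i in range(n)]

    def test_multiplicity_window(self, indexed):
        contigs, index = indexed
        params = MappingParams(c_min=1, m_lo=50, m_hi=6000)
        pairs = self._pairs(contigs, "LOW-1", 49)
        bmap, stats = build_barcode_map(pairs, index, params)
        assert stats.n_pairs_multiplicity_filtered == 49
        assert "LOW-1" not in bmap.assoc
        pairs = self._pairs(contigs, "OK-1", 50)
        bmap, stats = build_barcode_map(pairs, index, params)
        assert stats.n_pairs_multiplicity_filtered == 0
        assert "OK-1" in bmap.assoc

    def test_c_min_boundary(self, indexed):
        contigs, index = indexed
        params = MappingParams(c_min=5, m_lo=1, m_hi=10**9)
        head = contig_ends(contigs[0], 2000)[0]
        bmap, stats = build_barcode_map(self._pairs(contigs, "B-1", 5), index,
                                        params)
        assert bmap.assoc["B-1"][head] == 5
        bmap, stats = build_barcode_map(self._pairs(contigs, "B-1", 4), index,
                                        params)
        assert "B-1" not in bmap.assoc
        assert stats.n_pairs_pruned_low_count == 4

    def test_no_barcode_skipped(self, indexed):
        contigs, index = indexed
        params = MappingParams(c_min=1, m_lo=1, m_hi=10**9)
        pair = LinkedReadPair(contigs[0].seq[100:250],
                              contigs[0].seq[300:450], "", False)
        bmap, stats = build_barcode_map([pair], index, params)
        assert stats.n_pairs_no_barcode == 1
        assert not bmap.assoc

    def test_empty_stream_warns(self, indexed):
        _, index = indexed
        with pytest.warns(UserWarning, match="empty read stream"):
            bmap, stats = build_barcode_map([], index, MappingParams())
        assert stats.n_pairs_total == 0

    def test_stats_partition(self, small_run):
        stats = small_run["result"].mapping_stats
        assert (stats.n_pairs_no_barcode + stats.n_pairs_multiplicity_filtered
                + stats.n_pairs_unmapped + stats.n_pairs_discordant
                + stats.n_pairs_pruned_low_count + stats.n_pairs_stored
                ) == stats.n_pairs_total

    def test_reverse_complementing_reads_is_invariant(self, indexed):
        contigs, index = indexed
        params = MappingParams(c_min=1, m_lo=1, m_hi=10**9)
        pairs = self._pairs(contigs, "B-1", 6)
        flipped = [LinkedReadPair(revcomp(p.read1), revcomp(p.read2),
                                  p.barcode, True) for p in pairs]
        bmap1, _ = build_barcode_map(pairs, index, params)
        bmap2, _ = build_barcode_map(flipped, index, params)
        assert bmap1.assoc == bmap2.assoc
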