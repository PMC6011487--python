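"""Chromium-style linked-read and draft-assembly simulator with ground truth.

Emulates droplet-based linked-read sequencing: each barcode tags several long
DNA molecules sampled from the genome (barcode reuse), molecule lengths are
exponential, and each molecule is sequenced to low depth (well below 1x) with
short paired-end reads carrying the barcode in a BX:Z tag.  A companion
fragmenter cuts the genome into a shuffled, randomly strand-flipped draft
assembly with known contig order, orientation, and gap sizes, so scaffolding
output can be scored against truth.

Defaults describe the package's reference study conditions: a 2 Mbp genome in
40 near-equal ~50 kbp contigs with 0–5 kbp gaps, exponential molecules of
mean 50 kbp, 10 molecules per barcode, and ~20x total read depth at ~0.1x
per-molecule depth (150 bp pairs at 0.35 pairs per molecule kbp).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from linkscaf.assembly_io import Contig, LinkedReadPair
from linkscaf.kmer_index import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 2_000_000
    n_contigs: int = 40
    gap_range: tuple[int, int] = (0, 5000)
    min_contig_length: int = 1000
    contig_length_jitter: float = 0.25  # +/- fraction around the even split
    molecule_length_mean: int = 50_000
    molecules_per_barcode: int = 10
    read_length: int = 150
    read_pairs_per_molecule_per_kbp: float = 0.35
    insert_size_mean: int = 400
    insert_size_sd: int = 50
    n_barcodes: int = 760
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.gap_range[0] > self.gap_range[1] or self.gap_range[0] < 0:
            raise ValueError("invalid gap_range")
        for name in ("molecule_length_mean", "molecules_per_barcode",
                     "read_length", "n_barcodes", "min_contig_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.read_pairs_per_molecule_per_kbp <= 0:
            raise ValueError("read pair rate must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")

    @property
    def per_molecule_coverage(self) -> float:
        """Expected read depth within one molecule (should be well below 1)."""
        return (2 * self.read_length
                * self.read_pairs_per_molecule_per_kbp / 1000.0)

    @property
    def expected_read_coverage(self) -> float:
        """Expected genome-wide read depth implied by the configuration."""
        total_pairs = (self.n_barcodes * self.molecules_per_barcode
                       * self.molecule_length_mean / 1000.0
                       * self.read_pairs_per_molecule_per_kbp)
        return total_pairs * 2 * self.read_length / self.genome_length


def simulate_genome(config: SimConfig) -> str:
    """Uniform random ACGT genome of the configured length (deterministic)."""
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, 4, size=config.genome_length)
    return _BASES[idx].tobytes().decode("ascii")


def barcode_string(i: int, length: int = 16) -> str:
    """Deterministic unique ACGT barcode in the BX style, e.g. 'ACGT...-1'."""
    chars = []
    for _ in range(length):
        chars.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(chars)) + "-1"


def fragment_genome(genome: str, config: SimConfig
                    ) -> tuple[list[Contig], pd.DataFrame]:
    """Cut the genome into a shuffled, strand-flipped draft with truth.

    Consecutive contigs lose a Uniform(gap_range) stretch of sequence between
    them (the gap); contig lengths are a near-even split of the remainder
    with +/- contig_length_jitter relative jitter, never below
    min_contig_length.  The returned truth table records, per contig, its
    genomic order, coordinates, emitted strand, and the gap to its genomic
    successor.
    """
    n = config.n_contigs
    if n < 2:
        raise ValueError("need n_contigs >= 2 to define adjacencies")
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    glen = len(genome)
    gaps = rng.integers(config.gap_range[0], config.gap_range[1] + 1,
                        size=n - 1)
    remaining = glen - int(gaps.sum())
    base = remaining / n
    if base < config.min_contig_length:
        raise ValueError("constraints infeasible: contigs would be shorter "
                         "than min_contig_length")
    jitter = rng.uniform(-config.contig_length_jitter,
                         config.contig_length_jitter, size=n)
    weights = 1.0 + jitter
    lengths = np.floor(remaining * weights / weights.sum()).astype(np.int64)
    # hand the rounding remainder out one base at a time (preserves the sum)
    lengths[: remaining - int(lengths.sum())] += 1
    if lengths.min() < config.min_contig_length:
        raise ValueError("constraints infeasible: jitter drives a contig "
                         "below min_contig_length")

    order = rng.permutation(n)  # genomic rank -> draft position
    draft_pos = np.empty(n, dtype=np.int64)
    draft_pos[order] = np.arange(n)
    flips = rng.random(n) < 0.5

    contigs: list[Contig] = [None] * n  # type: ignore[list-item]
    rows = []
    pos = 0
    width = len(str(n))
    for rank in range(n):
        length = int(lengths[rank])
        seq = genome[pos:pos + length]
        cid = f"contig{int(draft_pos[rank]) + 1:0{width}d}"
        strand = "-" if flips[rank] else "+"
        if strand == "-":
            seq = revcomp(seq)
        contigs[int(draft_pos[rank])] = Contig(id=cid, seq=seq)
        rows.append({
            "contig_id": cid,
            "genome_order": rank,
            "genome_start": pos,
            "genome_end": pos + length,
            "draft_strand": strand,
            "gap_after": int(gaps[rank]) if rank < n - 1 else pd.NA,
        })
        pos += length
        if rank < n - 1:
            pos += int(gaps[rank])
    assert pos == glen
    truth = pd.DataFrame(rows)
    return contigs, truth


def simulate_linked_reads(genome: str, config: SimConfig
                          ) -> tuple[list[LinkedReadPair], pd.DataFrame]:
    """Draw barcoded molecules and paired-end reads from the genome.

    Per barcode, ``molecules_per_barcode`` molecules start uniformly on the
    genome with Exponential(molecule_length_mean) lengths truncated to the
    genome end; each molecule yields Poisson(rate * length_kbp) read pairs of
    forward/reverse-complement windows joined by a Normal insert.  With
    error_rate > 0, bases are substituted uniformly.  Returns the pairs plus
    a per-pair provenance table (barcode, molecule, fragment coordinates).
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(
        2**31, 2**32))
    glen = len(genome)
    L = config.read_length
    pairs: list[LinkedReadPair] = []
    rows = []
    molecule_id = 0
    for b in range(config.n_barcodes):
        barcode = barcode_string(b)
        for _ in range(config.molecules_per_barcode):
            start = int(rng.integers(0, glen))
            length = int(rng.exponential(config.molecule_length_mean)) + 1
            stop = min(start + length, glen)
            mol_len = stop - start
            n_pairs = rng.poisson(
                config.read_pairs_per_molecule_per_kbp * mol_len / 1000.0)
            for _ in range(int(n_pairs)):
                insert = int(rng.normal(config.insert_size_mean,
                                        config.insert_size_sd))
                insert = max(insert, 2 * L)
                if mol_len < insert:
                    insert = mol_len
                if insert < 2 * L:
                    continue  # molecule too short for a proper pair
                fs = start + int(rng.integers(0, mol_len - insert + 1))
                fe = fs + insert
                fwd = genome[fs:fs + L]
                rev = revcomp(genome[fe - L:fe])
                if config.error_rate > 0.0:
                    fwd = _mutate(fwd, config.error_rate, rng)
                    rev = _mutate(rev, config.error_rate, rng)
                if rng.random() < 0.5:  # sequencing strand of the fragment
                    r1, r2 = fwd, rev
                else:
                    r1, r2 = rev, fwd
                pairs.append(LinkedReadPair(r1, r2, barcode, True))
                rows.append((barcode, molecule_id, start, stop, fs, fe))
            molecule_id += 1
    truth = pd.DataFrame(rows, columns=["barcode", "molecule_id",
                                        "molecule_start", "molecule_end",
                                        "fragment_start", "fragment_end"])
    return pairs, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode("ascii")


def write_interleaved_fastq(pairs: list[LinkedReadPair],
                            out_path: str | Path) -> None:
    """Interleaved FASTQ with BX:Z barcode tags and uniform qualities."""
    with open(out_path, "wt") as fh:
        for i, pair in enumerate(pairs):
            tag = f" BX:Z:{pair.barcode}" if pair.has_barcode else ""
            fh.write(f"@r{i:07d}{tag}\n{pair.read1}\n+\n{'I' * len(pair.read1)}\n")
            fh.write(f"@r{i:07d}{tag}\n{pair.read2}\n+\n{'I' * len(pair.read2)}\n")
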