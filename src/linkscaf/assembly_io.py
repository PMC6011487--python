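"""Sequence I/O and the coordinate conventions for contig end regions.

A draft assembly sequence ("contig", inclusively covering contigs and
scaffolds) contributes two *end regions* — a head and a tail — which are the
only parts of the sequence retained for read mapping; the interior is masked.
Coordinates are 0-based, half-open throughout.

Linked reads arrive as FASTQ with the droplet barcode carried in a
``BX:Z:<barcode>`` token in the header comment, the convention used by
Long Ranger output.  Both interleaved single-file and two-file paired input
are accepted; gzip compression is transparent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

HEAD = "H"
TAIL = "T"


@dataclass(frozen=True)
class Contig:
    """One draft assembly sequence (uppercase DNA over {A,C,G,T,N})."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")


class ContigEnd(NamedTuple):
    """A head or tail region of a contig; the unit of mapping and graph nodes.

    ``start``/``stop`` are 0-based half-open coordinates on the contig.
    """

    contig_id: str
    which: str  # HEAD or TAIL
    start: int
    stop: int


@dataclass(frozen=True)
class LinkedReadPair:
    """A barcoded paired-end read; ``barcode`` is the BX tag value."""

    read1: str
    read2: str
    barcode: str
    has_barcode: bool

    def __post_init__(self) -> None:
        if not self.read1 or not self.read2:
            raise ValueError("reads must be non-empty")
        if self.has_barcode and not self.barcode:
            raise ValueError("barcode must be non-empty when has_barcode")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_assembly(fasta_path: str | Path) -> list[Contig]:
    """Read a draft assembly FASTA into a list of contigs.

    Ids are the first whitespace-delimited token of the header; sequences are
    uppercased; record order is preserved.  Duplicate ids are a hard error.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    with _open_text(fasta_path) as fh:
        for title, seq in SimpleFastaParser(fh):
            cid = title.split()[0] if title.split() else ""
            if not cid:
                raise ValueError(f"FASTA record with empty id in {fasta_path!s}")
            if cid in seen:
                raise ValueError(f"duplicate contig id {cid!r} in {fasta_path!s}")
            seen.add(cid)
            contigs.append(Contig(id=cid, seq=seq.upper()))
    return contigs


def write_fasta(records: Iterable[tuple[str, str]], out_path: str | Path,
                width: int = 80) -> None:
    """Write (id-or-header, seq) records as FASTA with wrapped lines."""
    with open(out_path, "wt") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def contig_ends(contig: Contig, e: int) -> tuple[ContigEnd, ContigEnd]:
    """Head and tail end regions of a contig for end-region length ``e``.

    Contigs of length >= 2e get fixed-length regions [0, e) and
    [length-e, length).  Shorter contigs are split at the midpoint into
    non-overlapping halves, so a barcode spanning the whole contig still
    discriminates its two ends.  Contigs shorter than 2 bp cannot form two
    non-empty ends and must be filtered out by the caller before indexing.
    """
    if e <= 0:
        raise ValueError("end-region length e must be positive")
    n = contig.length
    if n >= 2 * e:
        head = ContigEnd(contig.id, HEAD, 0, e)
        tail = ContigEnd(contig.id, TAIL, n - e, n)
    else:
        mid = n // 2
        head = ContigEnd(contig.id, HEAD, 0, mid)
        tail = ContigEnd(contig.id, TAIL, mid, n)
    return head, tail


def end_sequence(contig: Contig, end: ContigEnd) -> str:
    if end.contig_id != contig.id:
        raise ValueError(f"end {end} does not belong to contig {contig.id}")
    return contig.seq[end.start:end.stop]


def extract_barcode(title: str) -> str | None:
    """Pull the BX:Z barcode out of a FASTQ title line (position-independent)."""
    for token in title.split()[1:]:
        if token.startswith("BX:Z:"):
            bc = token[5:]
            if bc:
                return bc
    return None


def _read_id(title: str) -> str:
    rid = title.split()[0]
    # strip /1 /2 mate suffixes so paired files can be compared
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def _pair(t1: str, s1: str, t2: str, s2: str) -> LinkedReadPair:
    bc = extract_barcode(t1) or extract_barcode(t2)
    return LinkedReadPair(
        read1=s1.upper(),
        read2=s2.upper(),
        barcode=bc or "",
        has_barcode=bc is not None,
    )


def stream_linked_reads(fastq_paths: list[str | Path] | str | Path,
                        ) -> Iterator[LinkedReadPair]:
    """Yield barcoded read pairs from interleaved (1 file) or paired (2 files) FASTQ.

    Pairs lacking a BX tag are yielded with ``has_barcode=False`` (downstream
    filters skip them).  An odd record count in interleaved mode or mismatched
    read ids between paired files is a hard error.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if len(fastq_paths) == 1:
        with _open_text(fastq_paths[0]) as fh:
            it = FastqGeneralIterator(fh)
            for title1, seq1, _ in it:
                try:
                    title2, seq2, _ = next(it)
                except StopIteration:
                    raise ValueError(
                        f"odd record count in interleaved FASTQ {fastq_paths[0]!s}"
                    ) from None
                yield _pair(title1, seq1, title2, seq2)
    elif len(fastq_paths) == 2:
        with _open_text(fastq_paths[0]) as fh1, _open_text(fastq_paths[1]) as fh2:
            it1 = FastqGeneralIterator(fh1)
            it2 = FastqGeneralIterator(fh2)
            for (title1, seq1, _), (title2, seq2, _) in zip(it1, it2, strict=True):
                if _read_id(title1) != _read_id(title2):
                    raise ValueError(
                        f"mismatched read ids between paired files: "
                        f"{title1.split()[0]!r} vs {title2.split()[0]!r}"
                    )
                yield _pair(title1, seq1, title2, seq2)
    else:
        raise ValueError("expected one (interleaved) or two (paired) FASTQ paths")
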