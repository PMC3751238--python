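"""Exhaustive allele-specific read tiling.

Reads of a fixed length k are generated starting at every possible position
of every exon, on both strands, for both alleles. For an exon of length n
this yields max(0, n-k+1) reads per strand, so the two alleles contribute
reads in exactly equal amounts by construction -- the property that lets any
downstream departure from a 50:50 allele ratio be attributed to the
alignment strategy rather than to the input.

A read is *informative* for allele-specific analysis only if its window
overlaps at least one differentiating site; all other reads are identical
between the alleles.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from .sequences import Exome, VariantSet, reverse_complement

REF = "REF"
ALT = "ALT"


@dataclass(frozen=True)
class SimulatedRead:
    """A k-base read with truth-of-origin metadata.

    ``start`` is the 0-based leftmost position of the origin window in the
    origin allele's coordinates; for strand '-', ``sequence`` is the reverse
    complement of that window. Ids encode the origin as
    ``allele|exon|start|strand``.
    """

    id: str
    sequence: str
    allele: str
    exon_id: str
    start: int
    strand: str
    informative: bool | None = None

    @classmethod
    def from_window(
        cls, allele: str, exon_id: str, start: int, strand: str, window: str
    ) -> "SimulatedRead":
        seq = window if strand == "+" else reverse_complement(window)
        rid = f"{allele}|{exon_id}|{start}|{strand}"
        return cls(rid, seq, allele, exon_id, start, strand)

    @classmethod
    def from_id(cls, rid: str, sequence: str) -> "SimulatedRead":
        allele, exon_id, start, strand = rid.split("|")
        return cls(rid, sequence, allele, exon_id, int(start), strand)


def tile_reads(exome: Exome, k: int, allele: str = REF) -> Iterator[SimulatedRead]:
    """Tile all k-base reads from one allele, both strands.

    Exons shorter than k yield no reads; reads never span exon boundaries.
    """
    if k < 1:
        raise ValueError("read length k must be >= 1")
    for exon in exome:
        seq = exon.sequence
        for start in range(exon.length - k + 1):
            window = seq[start : start + k]
            yield SimulatedRead.from_window(allele, exon.id, start, "+", window)
            yield SimulatedRead.from_window(allele, exon.id, start, "-", window)


def tile_allele_pair(ref: Exome, alt: Exome, k: int) -> Iterator[SimulatedRead]:
    """Tile both alleles of an exome pair."""
    return itertools.chain(tile_reads(ref, k, REF), tile_reads(alt, k, ALT))


def expected_read_count(exome: Exome, k: int, n_strands: int = 2) -> int:
    """Total reads one allele emits: sum over exons of strands * (n-k+1)."""
    return sum(n_strands * max(0, e.length - k + 1) for e in exome)


def flag_informative(
    reads: Iterable[SimulatedRead], variants: VariantSet
) -> list[SimulatedRead]:
    """Mark each read informative iff its origin window overlaps >= 1 site.

    Site positions are taken in the read's own allele's coordinates (ref
    positions for REF-origin reads, alt positions for ALT-origin reads).
    """
    pos_cache: dict[tuple[str, str], list[int]] = {}
    out = []
    for read in reads:
        key = (read.allele, read.exon_id)
        if key not in pos_cache:
            coords = "ref" if read.allele == REF else "alt"
            pos_cache[key] = variants.positions(read.exon_id, coords)
        positions = pos_cache[key]
        k = len(read.sequence)
        i = bisect_left(positions, read.start)
        informative = i < len(positions) and positions[i] < read.start + k
        out.append(replace(read, informative=informative))
    return out


def write_reads_fasta(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n{read.sequence}\n")


def write_reads_fastq(
    reads: Iterable[SimulatedRead], path: str | Path, quality: int = 40
) -> None:
    """FASTQ with a constant base quality (default Q40, the value assumed
    for FASTA input by quality-aware aligners)."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qchar * len(read.sequence)}\n")


def read_reads_fasta(path: str | Path) -> list[SimulatedRead]:
    """Read back reads whose FASTA headers carry the origin encoding."""
    from Bio import SeqIO

    return [
        SimulatedRead.from_id(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
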