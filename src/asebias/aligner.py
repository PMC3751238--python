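"""Mismatch-tolerant, uniqueness-enforcing read placement.

Single-genome mode reproduces the classic "-m 1 -v m --best" contract of
ungapped short-read aligners: a read is reported only if it has exactly one
location in the genome (over both strands) within a whole-read Hamming
distance of m; reads with two or more valid locations are suppressed as
multimapped regardless of mismatch strata, and reads with none are
unaligned. Dual-parental mode assigns a read to an allele when it aligns
uniquely, with zero mismatches, to exactly one of two allele-specific
genomes.

The hit finder is pigeonhole-seeded: the read is split into m+1 disjoint
exact seeds, candidate windows are gathered by hash lookup and verified by
Hamming count. Any window within m mismatches must match at least one seed
exactly, so the hit set is complete -- identical to a brute-force scan of
every window on both strands (the contract the tests enforce against an
independent oracle).

'N' in either the read or the target matches nothing (it counts as a
mismatch against every base, including N), so indel masking behaves as read
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .sequences import Exome, reverse_complement

UNIQUE = "UNIQUE"
MULTIMAPPED = "MULTIMAPPED"
UNALIGNED = "UNALIGNED"

AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class AlignmentHit:
    """One valid location: (exon, start, strand) plus its mismatch count.

    strand '-' means the reverse complement of the read matches the forward
    genome window [start, start+k).
    """

    exon_id: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class AlignmentResult:
    status: str
    hit_count: int
    hit: AlignmentHit | None = None

    def __post_init__(self) -> None:
        if (self.status == UNIQUE) != (self.hit_count == 1):
            raise ValueError("status UNIQUE iff hit_count == 1")
        if self.status == UNIQUE and self.hit is None:
            raise ValueError("UNIQUE result requires a hit")


@dataclass(frozen=True)
class AlleleAssignment:
    """Allele call from dual-parental alignment.

    REF: unique in the reference genome, zero hits in the alternative (and
    symmetrically for ALT). AMBIGUOUS covers every other case in which the
    read aligned somewhere (e.g. unique in both genomes, or multimapped);
    UNALIGNED means no hits in either genome.
    """

    call: str
    ref_result: AlignmentResult
    alt_result: AlignmentResult


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


class HitFinder:
    """Complete Hamming-distance search over an exome for fixed (k, m)."""

    def __init__(self, exome: Exome, k: int, m: int):
        if k < 1:
            raise ValueError("read length k must be >= 1")
        if m < 0:
            raise ValueError("mismatch allowance m must be >= 0")
        if k <= m:
            raise ValueError("k must exceed m for seeding to be possible")
        self.k = k
        self.m = m
        self.seed_len = k // (m + 1)
        self.exon_ids: list[str] = []
        self.seqs: list[str] = []
        index: dict[str, list[tuple[int, int]]] = {}
        sl = self.seed_len
        for ei, exon in enumerate(exome):
            self.exon_ids.append(exon.id)
            seq = exon.sequence
            self.seqs.append(seq)
            for p in range(len(seq) - sl + 1):
                smer = seq[p : p + sl]
                if "N" in smer:
                    continue
                index.setdefault(smer, []).append((ei, p))
        self._index = index

    def find_hits(self, read_seq: str) -> list[AlignmentHit]:
        """All (exon, start, strand) within m mismatches of the read."""
        if len(read_seq) != self.k:
            raise ValueError(
                f"read length {len(read_seq)} does not match index k={self.k}"
            )
        sl, m, k = self.seed_len, self.m, self.k
        hits: list[tuple[int, int, str, int]] = []
        for strand, seq in (("+", read_seq), ("-", reverse_complement(read_seq))):
            seen: set[tuple[int, int]] = set()
            for ci in range(m + 1):
                chunk = seq[ci * sl : (ci + 1) * sl]
                for ei, p in self._index.get(chunk, ()):
                    start = p - ci * sl
                    if start < 0 or (ei, start) in seen:
                        continue
                    target = self.seqs[ei]
                    if start + k > len(target):
                        continue
                    seen.add((ei, start))
                    mm = _mismatches(seq, target[start : start + k], m)
                    if mm <= m:
                        hits.append((ei, start, strand, mm))
        hits.sort()
        return [
            AlignmentHit(self.exon_ids[ei], start, strand, mm)
            for ei, start, strand, mm in hits
        ]

    def align_unique(self, read_seq: str) -> AlignmentResult:
        hits = self.find_hits(read_seq)
        if len(hits) == 1:
            return AlignmentResult(UNIQUE, 1, hits[0])
        if not hits:
            return AlignmentResult(UNALIGNED, 0)
        return AlignmentResult(MULTIMAPPED, len(hits))


def get_finder(exome: Exome, k: int, m: int) -> HitFinder:
    """A per-exome cached HitFinder (exomes are treated as immutable)."""
    cache = getattr(exome, "_finder_cache", None)
    if cache is None:
        cache = exome._finder_cache = {}
    key = (k, m)
    if key not in cache:
        cache[key] = HitFinder(exome, k, m)
    return cache[key]


def find_hits(read_seq: str, exome: Exome, m: int) -> list[AlignmentHit]:
    return get_finder(exome, len(read_seq), m).find_hits(read_seq)


def align_unique(read_seq: str, exome: Exome, m: int) -> AlignmentResult:
    return get_finder(exome, len(read_seq), m).align_unique(read_seq)


def align_dual(read_seq: str, ref_exome: Exome, alt_exome: Exome) -> AlleleAssignment:
    """Assign a read to an allele by unique zero-mismatch alignment to
    exactly one of two allele-specific genomes."""
    ref_res = align_unique(read_seq, ref_exome, 0)
    alt_res = align_unique(read_seq, alt_exome, 0)
    if ref_res.status == UNIQUE and alt_res.hit_count == 0:
        call = "REF"
    elif alt_res.status == UNIQUE and ref_res.hit_count == 0:
        call = "ALT"
    elif ref_res.hit_count == 0 and alt_res.hit_count == 0:
        call = UNALIGNED
    else:
        call = AMBIGUOUS
    return AlleleAssignment(call, ref_res, alt_res)


def summarize_alignments(pairs) -> "pandas.DataFrame":
    """Status counts per allele of origin for (read, result) pairs."""
    import pandas as pd

    rows: dict[tuple[str, str], int] = {}
    for read, res in pairs:
        status = res.status if hasattr(res, "status") else res.call
        key = (read.allele, status)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [
            {"allele": allele, "status": status, "n_reads": n}
            for (allele, status), n in sorted(rows.items())
        ]
    )


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------


def write_sam(pairs: Iterable[tuple], exome: Exome, path: str | Path) -> None:
    """Write (read, AlignmentResult) pairs as SAM.

    UNIQUE hits become mapped records with the NM tag carrying the mismatch
    count; multimapped and unaligned reads are written as unmapped records
    flagged with the custom tags ZS (status) and ZN (hit count), mirroring
    the convention of suppressing rather than reporting multi-hits.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": e.id, "LN": e.length} for e in exome],
    }
    tids = {e.id: i for i, e in enumerate(exome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, res in pairs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.id
            if res.status == UNIQUE:
                hit = res.hit
                a.flag = 16 if hit.strand == "-" else 0
                a.reference_id = tids[hit.exon_id]
                a.reference_start = hit.start
                a.mapping_quality = 255
                a.cigarstring = f"{len(read.sequence)}M"
                # SAM stores the forward-genome sequence
                a.query_sequence = (
                    read.sequence
                    if hit.strand == "+"
                    else reverse_complement(read.sequence)
                )
                a.set_tag("NM", hit.mismatches)
            else:
                a.flag = 4
                a.query_sequence = read.sequence
                a.set_tag("ZN", res.hit_count)
            a.set_tag("ZS", res.status)
            out.write(a)


def read_sam(path: str | Path) -> list[tuple[str, AlignmentResult, str]]:
    """Parse a SAM written by :func:`write_sam`.

    Returns (query_name, AlignmentResult, forward_genome_sequence) tuples;
    for unmapped records the sequence is the read as written.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped:
                status = rec.get_tag("ZS") if rec.has_tag("ZS") else UNALIGNED
                count = rec.get_tag("ZN") if rec.has_tag("ZN") else 0
                res = AlignmentResult(status, int(count))
            else:
                hit = AlignmentHit(
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    int(rec.get_tag("NM")),
                )
                res = AlignmentResult(UNIQUE, 1, hit)
            out.append((rec.query_name, res, rec.query_sequence))
    return out
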