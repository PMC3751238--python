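"""Data model and IO for exome-based allele pairs.

An :class:`Exome` is an ordered collection of named exon sequences used as an
alignment target. Two allele-specific exomes (e.g. a reference strain and an
alternative strain, or two species) differ at *differentiating sites* --
single-nucleotide positions where the alleles carry different bases
(:class:`Variant`) -- and may additionally differ by insertions/deletions
(:class:`IndelInterval`): stretches present in one allele but not the other.

Coordinates are 0-based half-open everywhere in this package; the only 1-based
surfaces are the variant TSV/VCF exports, which follow their formats'
conventions.

Differentiating sites and indels can either be supplied directly or derived
from two allele-specific exon sequences by global pairwise alignment
(:func:`align_exon_pair` + :func:`call_differences`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
VARIANT_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the alphabet {A,C,G,T,N} (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Exon:
    """A named DNA sequence standing in for a constitutive exon."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("exon id must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"exon {self.id!r} contains invalid characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class Exome:
    """An ordered collection of exons with unique ids.

    Exomes are treated as immutable once constructed: the read aligner caches
    a seed index on the instance, so do not mutate exon sequences in place.
    """

    def __init__(self, exons: Iterable[Exon]):
        self._exons: dict[str, Exon] = {}
        for exon in exons:
            if exon.id in self._exons:
                raise ValueError(f"duplicate exon id {exon.id!r}")
            self._exons[exon.id] = exon
        # lazily populated by asebias.aligner.get_finder
        self._finder_cache: dict = {}

    def __iter__(self) -> Iterator[Exon]:
        return iter(self._exons.values())

    def __len__(self) -> int:
        return len(self._exons)

    def __contains__(self, exon_id: str) -> bool:
        return exon_id in self._exons

    def __getitem__(self, exon_id: str) -> Exon:
        return self._exons[exon_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Exome):
            return NotImplemented
        return list(self) == list(other)

    def ids(self) -> list[str]:
        return list(self._exons)

    @property
    def total_length(self) -> int:
        return sum(e.length for e in self)


@dataclass(frozen=True)
class Variant:
    """A differentiating site between two alleles on reference coordinates.

    ``alt_pos`` is the position of the same site in the alternative allele's
    own coordinate system; it differs from ``pos`` only when indels upstream
    of the site shift the coordinates. ``None`` means "same as ``pos``".
    """

    exon_id: str
    pos: int
    ref_base: str
    alt_base: str
    alt_pos: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("variant position must be non-negative")
        if self.ref_base not in VARIANT_BASES or self.alt_base not in VARIANT_BASES:
            raise ValueError("variant bases must be one of A,C,G,T")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.alt_pos is None:
            object.__setattr__(self, "alt_pos", self.pos)

    @property
    def alt_position(self) -> int:
        return self.alt_pos

    @property
    def key(self) -> tuple[str, int]:
        return (self.exon_id, self.pos)


class VariantSet:
    """Differentiating sites, indexed by exon and sorted by position."""

    def __init__(self, variants: Iterable[Variant] = ()):
        self._by_exon: dict[str, list[Variant]] = {}
        seen: set[tuple[str, int]] = set()
        for v in variants:
            if v.key in seen:
                raise ValueError(f"duplicate variant at {v.exon_id}:{v.pos}")
            seen.add(v.key)
            self._by_exon.setdefault(v.exon_id, []).append(v)
        for lst in self._by_exon.values():
            lst.sort(key=lambda v: v.pos)

    def __iter__(self) -> Iterator[Variant]:
        return itertools.chain.from_iterable(self._by_exon.values())

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_exon.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantSet):
            return NotImplemented
        return sorted(self, key=lambda v: v.key) == sorted(other, key=lambda v: v.key)

    def exon_ids(self) -> list[str]:
        return list(self._by_exon)

    def by_exon(self, exon_id: str) -> tuple[Variant, ...]:
        return tuple(self._by_exon.get(exon_id, ()))

    def positions(self, exon_id: str, coords: str = "ref") -> list[int]:
        """Sorted site positions in one exon, on ref or alt coordinates."""
        vs = self._by_exon.get(exon_id, ())
        if coords == "ref":
            return [v.pos for v in vs]
        if coords == "alt":
            return sorted(v.alt_position for v in vs)
        raise ValueError(f"unknown coordinate system {coords!r}")

    def validate_against(self, exome: Exome) -> None:
        """Check every site's position and reference base against an exome."""
        for v in self:
            if v.exon_id not in exome:
                raise ValueError(f"variant refers to unknown exon {v.exon_id!r}")
            seq = exome[v.exon_id].sequence
            if v.pos >= len(seq):
                raise ValueError(f"variant {v.exon_id}:{v.pos} beyond exon end")
            if seq[v.pos] != v.ref_base:
                raise ValueError(
                    f"variant {v.exon_id}:{v.pos} expects ref base {v.ref_base!r} "
                    f"but exome has {seq[v.pos]!r}"
                )


@dataclass(frozen=True)
class IndelInterval:
    """A region present in one allele but not the other.

    ``[start, end)`` on reference-exon coordinates covers the reference bases
    involved (empty for a pure insertion into the alternative allele);
    ``alt_length`` is the number of alternative-allele bases over the same
    alignment columns (0 for a pure deletion from the alternative allele).
    """

    exon_id: str
    start: int
    end: int
    alt_length: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError("indel interval must satisfy 0 <= start <= end")
        if self.alt_length < 0:
            raise ValueError("alt_length must be non-negative")
        if self.end == self.start and self.alt_length == 0:
            raise ValueError("empty indel (no ref bases and no alt bases)")

    @property
    def ref_length(self) -> int:
        return self.end - self.start

    def breakpoints(self) -> tuple[int, int]:
        return (self.start, self.end)


class IndelSet:
    """Indel intervals indexed by exon; provides ref->alt coordinate shifts."""

    def __init__(self, indels: Iterable[IndelInterval] = ()):
        self._by_exon: dict[str, list[IndelInterval]] = {}
        for iv in indels:
            self._by_exon.setdefault(iv.exon_id, []).append(iv)
        for lst in self._by_exon.values():
            lst.sort(key=lambda iv: (iv.start, iv.end))

    def __iter__(self) -> Iterator[IndelInterval]:
        return itertools.chain.from_iterable(self._by_exon.values())

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_exon.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndelSet):
            return NotImplemented
        return list(self) == list(other)

    def by_exon(self, exon_id: str) -> tuple[IndelInterval, ...]:
        return tuple(self._by_exon.get(exon_id, ()))

    def alt_position(self, exon_id: str, ref_pos: int) -> int:
        """Map a reference coordinate (outside any indel) to alt coordinates."""
        shift = 0
        for iv in self._by_exon.get(exon_id, ()):
            if iv.end <= ref_pos:
                shift += iv.alt_length - iv.ref_length
            elif iv.start <= ref_pos < iv.end:
                raise ValueError(
                    f"position {exon_id}:{ref_pos} lies inside an indel interval"
                )
        return ref_pos + shift

    def alt_start(self, indel: IndelInterval) -> int:
        """Start of an indel's alternative-allele bases, in alt coordinates."""
        shift = 0
        for iv in self._by_exon.get(indel.exon_id, ()):
            if iv.end <= indel.start and iv is not indel:
                shift += iv.alt_length - iv.ref_length
        return indel.start + shift


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment of two exon sequences (a = ref, b = alt)."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" and cb == "-":
                raise ValueError("alignment column with gaps in both rows")

    def sequence_a(self) -> str:
        return self.aligned_a.replace("-", "")

    def sequence_b(self) -> str:
        return self.aligned_b.replace("-", "")


# ---------------------------------------------------------------------------
# FASTA / TSV / VCF IO
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Exome:
    """Read an exome from FASTA. Sequences are uppercased on read."""
    exons = []
    for rec in SeqIO.parse(str(path), "fasta"):
        exons.append(Exon(rec.id, str(rec.seq).upper()))
    return Exome(exons)


def write_fasta(exome: Exome, path: str | Path) -> None:
    records = [SeqRecord(Seq(e.sequence), id=e.id, description="") for e in exome]
    SeqIO.write(records, str(path), "fasta")


def read_variants_tsv(path: str | Path) -> VariantSet:
    """Read variants from TSV with columns exon_id, pos (1-based), ref, alt.

    An optional fifth column carries the 1-based alt-coordinate position.
    Lines starting with '#' are ignored.
    """
    variants = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            exon_id, pos1, ref, alt = fields[:4]
            alt_pos = int(fields[4]) - 1 if len(fields) > 4 and fields[4] else None
            variants.append(Variant(exon_id, int(pos1) - 1, ref, alt, alt_pos))
    return VariantSet(variants)


def write_variants_tsv(variants: VariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#exon_id\tpos\tref\talt\talt_pos\n")
        for v in sorted(variants, key=lambda v: v.key):
            fh.write(
                f"{v.exon_id}\t{v.pos + 1}\t{v.ref_base}\t{v.alt_base}"
                f"\t{v.alt_position + 1}\n"
            )


def read_variants_vcf(path: str | Path) -> VariantSet:
    """Read single-nucleotide records from a minimal VCF (CHROM/POS/REF/ALT)."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref) != 1 or len(alts) != 1 or len(alts[0]) != 1:
                raise ValueError(
                    f"non-SNV record at {rec.chrom}:{rec.pos}; only "
                    "single-nucleotide records are supported"
                )
            variants.append(Variant(rec.chrom, rec.pos - 1, rec.ref, alts[0]))
    return VariantSet(variants)


def write_variants_vcf(variants: VariantSet, exome: Exome, path: str | Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    for exon in exome:
        header.contigs.add(exon.id, length=exon.length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: v.key):
            rec = vcf.new_record(
                contig=v.exon_id, start=v.pos, stop=v.pos + 1,
                alleles=(v.ref_base, v.alt_base),
            )
            vcf.write(rec)


def read_indels_tsv(path: str | Path) -> IndelSet:
    """Read indels from BED-like TSV: exon_id, start, end (0-based half-open),
    alt_length."""
    indels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            exon_id, start, end, alt_length = line.split("\t")[:4]
            indels.append(IndelInterval(exon_id, int(start), int(end), int(alt_length)))
    return IndelSet(indels)


def write_indels_tsv(indels: IndelSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#exon_id\tstart\tend\talt_length\n")
        for iv in indels:
            fh.write(f"{iv.exon_id}\t{iv.start}\t{iv.end}\t{iv.alt_length}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def apply_variants(ref: Exome, variants: VariantSet) -> Exome:
    """Return the exome obtained by substituting alt bases at every variant.

    Raises ValueError naming the site if a variant's ref_base does not match
    the reference sequence.
    """
    variants.validate_against(ref)
    out = []
    for exon in ref:
        vs = variants.by_exon(exon.id)
        if not vs:
            out.append(exon)
            continue
        seq = list(exon.sequence)
        for v in vs:
            seq[v.pos] = v.alt_base
        out.append(Exon(exon.id, "".join(seq)))
    return Exome(out)


def swap_variants(variants: VariantSet) -> VariantSet:
    """Swap ref and alt roles (applying the result to the alt exome recovers
    the reference on SNV-only exons)."""
    return VariantSet(
        Variant(v.exon_id, v.alt_position, v.alt_base, v.ref_base, alt_pos=v.pos)
        for v in variants
    )


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring: a gap of length L costs |gap_open| + L*|gap_extend|."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_SCORING = AlignmentScoring()


def align_exon_pair(
    seq_a: str, seq_b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global alignment of two exon sequences with affine gaps.

    Deterministic: among co-optimal alignments the first of the aligner's
    enumeration is returned.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython's open_gap_score already includes the first gapped base.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def call_differences(
    aln: PairwiseAlignment, exon_id: str = "exon"
) -> tuple[VariantSet, IndelSet]:
    """Extract differentiating sites and indels from a pairwise alignment.

    Substitution columns become :class:`Variant` records on reference
    coordinates (with alt coordinates filled in); maximal runs of gapped
    columns become :class:`IndelInterval` records. Columns involving N are
    not called as variants.
    """
    a, b = aln.aligned_a, aln.aligned_b
    variants: list[Variant] = []
    indels: list[IndelInterval] = []
    ra = rb = i = 0
    n = len(a)
    while i < n:
        if a[i] != "-" and b[i] != "-":
            if a[i] != b[i] and a[i] in VARIANT_BASES and b[i] in VARIANT_BASES:
                variants.append(Variant(exon_id, ra, a[i], b[i], alt_pos=rb))
            ra += 1
            rb += 1
            i += 1
        else:
            start = ra
            alt_len = 0
            while i < n and (a[i] == "-" or b[i] == "-"):
                if a[i] != "-":
                    ra += 1
                if b[i] != "-":
                    rb += 1
                    alt_len += 1
                i += 1
            indels.append(IndelInterval(exon_id, start, ra, alt_len))
    return VariantSet(variants), IndelSet(indels)


def diff_exomes(ref: Exome, alt: Exome) -> tuple[VariantSet, IndelSet]:
    """Call differences for every exon pair shared between two exomes."""
    variants: list[Variant] = []
    indels: list[IndelInterval] = []
    for exon in ref:
        if exon.id not in alt:
            raise ValueError(f"exon {exon.id!r} missing from alternative exome")
        other = alt[exon.id].sequence
        if other == exon.sequence:
            continue
        aln = align_exon_pair(exon.sequence, other)
        vs, ivs = call_differences(aln, exon.id)
        variants.extend(vs)
        indels.extend(ivs)
    return VariantSet(variants), IndelSet(indels)


def mask_indels(exome: Exome, indels: Iterable[IndelInterval]) -> Exome:
    """Replace every base inside the given intervals with 'N'.

    Because N matches nothing during alignment (it counts as a mismatch
    against every base, including N), masking behaves as read exclusion: no
    zero-mismatch read can cover a masked position.
    """
    by_exon: dict[str, list[IndelInterval]] = {}
    for iv in indels:
        by_exon.setdefault(iv.exon_id, []).append(iv)
    out = []
    for exon in exome:
        ivs = by_exon.pop(exon.id, None)
        if not ivs:
            out.append(exon)
            continue
        seq = list(exon.sequence)
        for iv in ivs:
            if iv.end > len(seq):
                raise ValueError(
                    f"indel interval [{iv.start},{iv.end}) out of bounds for "
                    f"exon {exon.id!r} (length {len(seq)})"
                )
            for p in range(iv.start, iv.end):
                seq[p] = "N"
        out.append(Exon(exon.id, "".join(seq)))
    if by_exon:
        raise ValueError(f"indels refer to unknown exons {sorted(by_exon)!r}")
    return Exome(out)


def dual_masking_intervals(
    indels: IndelSet, ref: Exome, alt: Exome
) -> tuple[list[IndelInterval], list[IndelInterval]]:
    """Per-genome masking intervals for dual-parental alignment.

    Each indel is masked symmetrically in alignment-column space: the allele
    carrying the extra bases gets those bases plus the first base to their
    right masked; the other allele gets the single junction base masked. Both
    masks then occupy the same alignment columns, so surviving read windows
    are mirror images between the two alleles -- which is what makes the
    dual-genome allele proportions exactly symmetric around indels.
    """
    ref_ivals: list[IndelInterval] = []
    alt_ivals: list[IndelInterval] = []
    for iv in indels:
        ref_len = ref[iv.exon_id].length
        alt_len = alt[iv.exon_id].length
        a_start = indels.alt_start(iv)
        ref_end = min(iv.end + 1, ref_len)
        alt_end = min(a_start + iv.alt_length + 1, alt_len)
        if ref_end > iv.start:
            ref_ivals.append(IndelInterval(iv.exon_id, iv.start, ref_end, 0))
        if alt_end > a_start:
            alt_ivals.append(IndelInterval(iv.exon_id, a_start, alt_end, 0))
    return ref_ivals, alt_ivals


def drop_masked_variants(
    variants: VariantSet,
    ref_intervals: Sequence[IndelInterval],
    alt_intervals: Sequence[IndelInterval],
) -> VariantSet:
    """Drop sites whose base is masked in either allele (unobservable)."""

    def _covered(pos: int, exon_id: str, ivals: Sequence[IndelInterval]) -> bool:
        return any(
            iv.exon_id == exon_id and iv.start <= pos < iv.end for iv in ivals
        )

    kept = [
        v
        for v in variants
        if not _covered(v.pos, v.exon_id, ref_intervals)
        and not _covered(v.alt_position, v.exon_id, alt_intervals)
    ]
    return VariantSet(kept)
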