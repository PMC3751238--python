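"""Per-site allelic counting and the sequential site filter.

Counting is pileup-style: every uniquely aligned read overlapping a
differentiating site contributes the base it carries at the aligned offset
(complemented for minus-strand alignments), incrementing the reference
count, the alternative count, or an "other" count for third alleles. The
reference proportion ref/(ref+alt) is the per-site measure of relative
allelic abundance; 0.5 is expected when every overlapping read is correctly
assigned.

Sites are then flagged by the three diagnostics -- at least as many
neighboring differentiating sites as mismatches allowed, imperfect
mappability, an indel nearby -- and excluded sequentially in a fixed order,
recording per-step attrition so each factor's contribution is visible.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .aligner import AlignmentResult, AlleleAssignment, UNIQUE
from .metrics import IMPERFECT, SiteAnnotation, classify_mappability
from .sequences import Variant, VariantSet

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

FILTER_STEPS = ("density", "mappability", "indel")


@dataclass
class SiteCounts:
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count + self.other_count

    @property
    def informative(self) -> int:
        return self.ref_count + self.alt_count


def reference_proportion(counts: SiteCounts) -> float | None:
    """ref/(ref+alt); None (missing) with zero informative coverage.

    Third-allele ("other") reads are tracked but excluded from the
    denominator: only reads matching the reference or the alternative base
    carry allele information.
    """
    if counts.informative == 0:
        return None
    return counts.ref_count / counts.informative


def _variant_lookup(variants: VariantSet, coords: str):
    """Per-exon sorted (target_pos, variant) lists for pileup."""
    table: dict[str, tuple[list[int], list[Variant]]] = {}
    for exon_id in variants.exon_ids():
        pairs = sorted(
            (
                (v.pos if coords == "ref" else v.alt_position, v)
                for v in variants.by_exon(exon_id)
            ),
            key=lambda t: t[0],
        )
        table[exon_id] = ([p for p, _ in pairs], [v for _, v in pairs])
    return table


def _genome_base(read_seq: str, strand: str, offset: int) -> str:
    """The base a read shows at a genome offset of its aligned window."""
    if strand == "+":
        return read_seq[offset]
    return _COMP[read_seq[len(read_seq) - 1 - offset]]


def pileup(
    pairs: Iterable[tuple],
    variants: VariantSet,
    coords: str = "ref",
) -> dict[tuple[str, int], SiteCounts]:
    """Count alleles at every differentiating site from unique alignments.

    ``pairs`` is an iterable of (read, AlignmentResult); only UNIQUE results
    are counted, each read at most once per site. ``coords`` names the
    coordinate system of the alignment target ("ref" when reads were aligned
    to the reference exome, "alt" for the mirror analysis against the
    alternative exome); site keys in the returned map are always
    (exon_id, reference position).
    """
    counts = {v.key: SiteCounts() for v in variants}
    lookup = _variant_lookup(variants, coords)
    for read, res in pairs:
        if res.status != UNIQUE:
            continue
        hit = res.hit
        entry = lookup.get(hit.exon_id)
        if entry is None:
            continue
        positions, vs = entry
        k = len(read.sequence)
        i = bisect_left(positions, hit.start)
        while i < len(positions) and positions[i] < hit.start + k:
            v = vs[i]
            base = _genome_base(read.sequence, hit.strand, positions[i] - hit.start)
            c = counts[v.key]
            if base == v.ref_base:
                c.ref_count += 1
            elif base == v.alt_base:
                c.alt_count += 1
            else:
                c.other_count += 1
            i += 1
    return counts


def dual_pileup(
    pairs: Iterable[tuple],
    variants: VariantSet,
) -> dict[tuple[str, int], SiteCounts]:
    """Count alleles from dual-parental assignments.

    ``pairs`` is an iterable of (read, AlleleAssignment). A REF-called read
    increments ref_count at every site its reference-genome alignment
    window covers; an ALT-called read increments alt_count at every site
    (in alternative-allele coordinates) its alternative-genome window
    covers. AMBIGUOUS and UNALIGNED reads contribute nothing.
    """
    counts = {v.key: SiteCounts() for v in variants}
    ref_lookup = _variant_lookup(variants, "ref")
    alt_lookup = _variant_lookup(variants, "alt")
    for read, asn in pairs:
        if asn.call == "REF":
            hit, lookup, which = asn.ref_result.hit, ref_lookup, "ref"
        elif asn.call == "ALT":
            hit, lookup, which = asn.alt_result.hit, alt_lookup, "alt"
        else:
            continue
        entry = lookup.get(hit.exon_id)
        if entry is None:
            continue
        positions, vs = entry
        k = len(read.sequence)
        i = bisect_left(positions, hit.start)
        while i < len(positions) and positions[i] < hit.start + k:
            c = counts[vs[i].key]
            if which == "ref":
                c.ref_count += 1
            else:
                c.alt_count += 1
            i += 1
    return counts


@dataclass
class SiteRecord:
    """Everything known about one differentiating site."""

    site: Variant
    counts: SiteCounts
    annotation: SiteAnnotation
    proportion: float | None = None
    flags: dict = field(default_factory=dict)
    excluded_at: str | None = None
    retained: bool = True
    test: "asebias.stats.TestResult | None" = None


def build_records(
    variants: VariantSet,
    counts: dict[tuple[str, int], SiteCounts],
    annotations: dict[tuple[str, int], SiteAnnotation],
) -> list[SiteRecord]:
    records = []
    for v in sorted(variants, key=lambda v: v.key):
        c = counts[v.key]
        records.append(
            SiteRecord(
                site=v,
                counts=c,
                annotation=annotations[v.key],
                proportion=reference_proportion(c),
            )
        )
    return records


def classify_and_filter(
    records: Sequence[SiteRecord],
    m: int,
    mode: str = "single_reference",
    order: Sequence[str] = FILTER_STEPS,
) -> tuple[list[SiteRecord], list[dict]]:
    """Flag problematic sites and apply the sequential exclusion filter.

    Flags:
      * ``biased_density`` -- at least as many neighboring differentiating
        sites as mismatches allowed (single-reference mode only; the dual
        strategy is immune to density);
      * ``imperfect_mappability`` -- average mappability < 1 (single) or
        summed dual mappability < 2 (dual);
      * ``indel_nearby`` -- indel breakpoint within a read length.

    Each record's ``excluded_at`` names the first step in ``order`` whose
    flag is set; ``retained`` is True iff no flag is set. The returned step
    table records sites excluded and remaining at each step.
    """
    if set(order) != set(FILTER_STEPS):
        raise ValueError(f"order must be a permutation of {FILTER_STEPS}")
    flag_of_step = {
        "density": "biased_density",
        "mappability": "imperfect_mappability",
        "indel": "indel_nearby",
    }
    out = []
    for rec in records:
        ann = rec.annotation
        if mode == "single_reference":
            score = ann.mappability
        elif mode == "dual_parental":
            score = ann.dual_mappability
        else:
            raise ValueError(f"unknown mode {mode!r}")
        flags = {
            "biased_density": mode == "single_reference" and ann.density >= m,
            "imperfect_mappability": classify_mappability(score, mode) == IMPERFECT,
            "indel_nearby": ann.indel_nearby,
        }
        excluded_at = next(
            (step for step in order if flags[flag_of_step[step]]), None
        )
        out.append(
            replace(
                rec,
                flags=flags,
                excluded_at=excluded_at,
                retained=excluded_at is None,
            )
        )
    steps = []
    remaining = len(out)
    for step in order:
        excluded = sum(1 for r in out if r.excluded_at == step)
        remaining -= excluded
        steps.append({"step": step, "n_excluded": excluded, "n_remaining": remaining})
    return out, steps


def records_to_frame(records: Sequence[SiteRecord]) -> "pandas.DataFrame":
    """Per-site results table (positions exported 1-based)."""
    import pandas as pd

    rows = []
    for r in records:
        v, c, ann = r.site, r.counts, r.annotation
        row = {
            "exon_id": v.exon_id,
            "pos": v.pos + 1,
            "ref": v.ref_base,
            "alt": v.alt_base,
            "ref_count": c.ref_count,
            "alt_count": c.alt_count,
            "other_count": c.other_count,
            "proportion": r.proportion,
            "density": ann.density,
            "mappability": ann.mappability,
            "dual_mappability": ann.dual_mappability,
            "indel_nearby": ann.indel_nearby,
            "biased_density": r.flags.get("biased_density"),
            "imperfect_mappability": r.flags.get("imperfect_mappability"),
            "excluded_at": r.excluded_at,
            "retained": r.retained,
        }
        if r.test is not None:
            row.update(
                {
                    "tested": r.test.tested,
                    "p": r.test.p_value,
                    "q": r.test.q_value,
                    "significant": r.test.significant,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
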