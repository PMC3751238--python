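"""Per-site diagnostics: neighbor density, mappability, indel proximity.

Three properties of a differentiating site predict whether its allele
counts, measured after aligning reads to a single reference genome, will be
biased or unreliable:

* *Neighbor density* d -- the maximum number of OTHER differentiating sites
  contained in any k-base read window covering the focal site. Alternative-
  allele reads from a window holding the focal site plus d other sites carry
  d+1 mismatches to the reference, so whenever d >= m (the mismatch
  allowance) some alternative reads cannot align and the reference allele is
  overcounted.
* *Mappability* -- the reciprocal of the number of genome locations a read
  beginning at a position aligns to within m mismatches; a site's score is
  the average over every read position overlapping it, and 1.0 means every
  covering read is uniquely placeable. In dual-parental mode the two
  alleles' scores are summed and compared against 2.
* *Indel proximity* -- an indel breakpoint within a read length of the site
  (or an indel spanning it) makes reads that cross the indel unalignable
  without gaps.

Mappability here is exact by brute force: counts come from the aligner's
complete hit enumeration rather than an approximate index.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .aligner import get_finder
from .sequences import Exome, IndelSet, Variant, VariantSet

PERFECT = "perfect"
IMPERFECT = "imperfect"

# guard against float dust when averaging reciprocals; a true score of 1 or 2
# is an exact sum of ones, anything imperfect falls short by >= 1/(2k)
_EPS = 1e-9


@dataclass(frozen=True)
class SiteAnnotation:
    """The three diagnostics for one differentiating site."""

    site: Variant
    density: int
    mappability: float | None = None
    dual_mappability: float | None = None
    indel_nearby: bool = False


def neighbor_density(
    site_positions: list[int], focal_pos: int, k: int, exon_length: int
) -> int:
    """Maximum number of other sites sharing a k-base window with the focal
    site, over all windows [s, s+k) that fit the exon and cover the site.

    Raises ValueError when no k-base window fits the exon (no read could
    cover the site).
    """
    if exon_length < k:
        raise ValueError(
            f"no k-base window fits: k={k} exceeds exon length {exon_length}"
        )
    if focal_pos not in site_positions:
        raise ValueError("focal position must be among the site positions")
    lo = max(0, focal_pos - k + 1)
    hi = min(focal_pos, exon_length - k)
    best = 0
    for s in range(lo, hi + 1):
        inside = bisect_left(site_positions, s + k) - bisect_left(site_positions, s)
        best = max(best, inside - 1)  # exclude the focal site itself
    return best


def position_mappability(exome: Exome, exon_id: str, pos: int, k: int, m: int) -> float:
    """1 / (number of locations the k-base read beginning at pos aligns to
    within m mismatches), counting both strands.

    Returns 0.0 when the window read aligns nowhere, which can happen only
    when the window overlaps an N-masked interval (N matches nothing, so
    such a read cannot align even to its own origin).
    """
    exon = exome[exon_id]
    if pos < 0 or pos + k > exon.length:
        raise ValueError(
            f"window [{pos},{pos + k}) does not fit exon {exon_id!r} "
            f"(length {exon.length})"
        )
    window = exon.sequence[pos : pos + k]
    n_hits = len(get_finder(exome, k, m).find_hits(window))
    return 1.0 / n_hits if n_hits else 0.0


def site_mappability(
    exome: Exome,
    exon_id: str,
    pos: int,
    k: int,
    m: int,
    _cache: dict | None = None,
) -> float:
    """Mean of position_mappability over every read start covering the site.

    Windows are exon-bounded (reads never cross exon ends), so edge sites
    average over fewer covering windows.
    """
    exon = exome[exon_id]
    lo = max(0, pos - k + 1)
    hi = min(pos, exon.length - k)
    if hi < lo:
        raise ValueError(f"no k-base window covers {exon_id}:{pos}")
    total = 0.0
    for s in range(lo, hi + 1):
        if _cache is not None:
            key = (exon_id, s)
            if key not in _cache:
                _cache[key] = position_mappability(exome, exon_id, s, k, m)
            total += _cache[key]
        else:
            total += position_mappability(exome, exon_id, s, k, m)
    return total / (hi - lo + 1)


def classify_mappability(score: float, mode: str = "single_reference") -> str:
    """Perfect/imperfect call: single mode is imperfect iff the score < 1;
    dual mode is imperfect iff the summed per-allele score < 2."""
    threshold = {"single_reference": 1.0, "dual_parental": 2.0}[mode]
    return IMPERFECT if score < threshold - _EPS else PERFECT


def indel_near_site(site: Variant, indels: IndelSet, k: int) -> bool:
    """True iff an indel breakpoint lies within k-1 bases of the site (one
    k-base read can contain both) or an indel interval spans the site."""
    for iv in indels.by_exon(site.exon_id):
        if iv.start <= site.pos < iv.end:
            return True
        if any(abs(b - site.pos) <= k - 1 for b in iv.breakpoints()):
            return True
    return False


def annotate_sites(
    variants: VariantSet,
    exome: Exome,
    k: int,
    m: int,
    indels: IndelSet | None = None,
    alt_exome: Exome | None = None,
) -> dict[tuple[str, int], SiteAnnotation]:
    """Compute all per-site diagnostics for a variant set.

    ``exome`` is the genome used for single-reference mappability (and for
    the reference half of the dual score). When ``alt_exome`` is given, the
    dual score adds the alternative allele's mappability at the site's alt
    coordinates; for dual-parental workflows pass the indel-masked exomes
    and m=0, matching the alignment conditions.
    """
    indels = indels if indels is not None else IndelSet()
    ref_cache: dict = {}
    alt_cache: dict = {}
    out: dict[tuple[str, int], SiteAnnotation] = {}
    for exon_id in variants.exon_ids():
        positions = variants.positions(exon_id)
        exon_length = exome[exon_id].length
        for v in variants.by_exon(exon_id):
            density = neighbor_density(positions, v.pos, k, exon_length)
            mapp = site_mappability(exome, exon_id, v.pos, k, m, _cache=ref_cache)
            dual = None
            if alt_exome is not None:
                dual = mapp + site_mappability(
                    alt_exome, exon_id, v.alt_position, k, m, _cache=alt_cache
                )
            out[v.key] = SiteAnnotation(
                site=v,
                density=density,
                mappability=mapp,
                dual_mappability=dual,
                indel_nearby=indel_near_site(v, indels, k),
            )
    return out


def annotations_to_frame(annotations: dict) -> "pandas.DataFrame":
    """Site-annotation table (positions exported 1-based)."""
    import pandas as pd

    rows = []
    for ann in annotations.values():
        v = ann.site
        rows.append(
            {
                "exon_id": v.exon_id,
                "pos": v.pos + 1,
                "ref": v.ref_base,
                "alt": v.alt_base,
                "density": ann.density,
                "mappability": ann.mappability,
                "dual_mappability": ann.dual_mappability,
                "indel_nearby": ann.indel_nearby,
            }
        )
    return pd.DataFrame(rows).sort_values(["exon_id", "pos"]).reset_index(drop=True)
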