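"""Synthetic allele pairs with controlled divergence, indels and repeats.

The generator emulates the inputs of an exome-based allele-specific read
simulation: a set of exon sequences (the reference allele), a second allele
derived from it by single-nucleotide variants at a configurable per-base
rate, optional indels (for interspecific-style divergence), and optional
exact-duplicate exons that break mappability. A :class:`TruthTable` records
exactly which edits were made, so every downstream stage can be checked
against ground truth.

SNVs are drawn i.i.d. per base with a uniformly random alternative base; the
downstream analysis depends only on site positions, not substitution type.
Reads tiled from these exomes are exact substrings -- there is no sequencing
error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import (
    Exome,
    Exon,
    IndelInterval,
    IndelSet,
    Variant,
    VariantSet,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Tunables for one synthetic allele pair.

    Defaults describe an intraspecific-style comparison: 50 exons of
    300-600 bp, ~1% per-base divergence, no indels, no duplicated exons.
    Indels (``indel_rate`` expected per exon) belong to interspecific-style
    runs and are kept at least ``indel_margin`` bases from exon ends so that
    every indel-adjacent site retains valid read windows on both sides.
    """

    seed: int
    n_exons: int = 50
    exon_length_range: tuple[int, int] = (300, 600)
    gc_fraction: float = 0.5
    snv_rate: float = 0.01
    indel_rate: float = 0.0
    indel_length_range: tuple[int, int] = (3, 12)
    duplication_fraction: float = 0.0
    indel_margin: int = 50

    def validate(self) -> None:
        if self.n_exons <= 0:
            raise ValueError("n_exons must be positive")
        for name in ("snv_rate", "duplication_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be non-negative")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0,1)")
        lo, hi = self.exon_length_range
        if not 0 < lo <= hi:
            raise ValueError("exon_length_range must satisfy 0 < min <= max")
        ilo, ihi = self.indel_length_range
        if not 0 < ilo <= ihi:
            raise ValueError("indel_length_range must satisfy 0 < min <= max")
        if self.duplication_fraction > 0.5:
            raise ValueError(
                "duplication_fraction > 0.5 is infeasible: every duplicate "
                "needs a distinct original"
            )
        if self.indel_rate > 0 and ihi + 2 * self.indel_margin > lo:
            raise ValueError(
                "infeasible config: longest indel plus margins exceeds the "
                "shortest exon"
            )


@dataclass
class TruthTable:
    """Ground truth for a generated allele pair."""

    variants: VariantSet
    indels: IndelSet
    duplicates: list[tuple[str, str]] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _place_indels(
    rng: np.random.Generator, cfg: SimulationConfig, exon_id: str, n: int
) -> list[tuple[IndelInterval, str]]:
    """Place non-overlapping indels away from exon ends.

    Returns (interval, inserted_sequence) pairs; inserted_sequence is empty
    for deletions. Placement keeps indels >= indel_margin apart so their
    masked footprints never merge.
    """
    count = rng.poisson(cfg.indel_rate)
    placed: list[tuple[IndelInterval, str]] = []
    for _ in range(count):
        length = int(rng.integers(cfg.indel_length_range[0], cfg.indel_length_range[1] + 1))
        is_deletion = bool(rng.random() < 0.5)
        ref_len = length if is_deletion else 0
        lo = cfg.indel_margin
        hi = n - cfg.indel_margin - ref_len
        if hi < lo:
            continue
        for _attempt in range(50):
            start = int(rng.integers(lo, hi + 1))
            end = start + ref_len
            if all(
                end + cfg.indel_margin <= iv.start or iv.end + cfg.indel_margin <= start
                for iv, _ in placed
            ):
                if is_deletion:
                    placed.append((IndelInterval(exon_id, start, end, 0), ""))
                else:
                    ins = _random_sequence(rng, length, cfg.gc_fraction)
                    placed.append((IndelInterval(exon_id, start, start, length), ins))
                break
    placed.sort(key=lambda t: t[0].start)
    return placed


def simulate_allele_pair(cfg: SimulationConfig) -> tuple[Exome, Exome, TruthTable]:
    """Generate a (reference, alternative) exome pair plus its truth table.

    Deterministic: the same config yields byte-identical FASTA and truth
    tables. One RNG stream is keyed by ``cfg.seed``; per-exon sub-streams are
    spawned from it so exon content is independent of n_exons ordering.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    master = np.random.default_rng(ss)

    n_dup = int(round(cfg.duplication_fraction * cfg.n_exons))
    n_orig = cfg.n_exons - n_dup
    children = ss.spawn(n_orig)

    ref_exons: list[Exon] = []
    alt_exons: list[Exon] = []
    variants: list[Variant] = []
    indels: list[IndelInterval] = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        exon_id = f"exon{i:04d}"
        n = int(rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1))
        ref_seq = _random_sequence(rng, n, cfg.gc_fraction)

        placed = _place_indels(rng, cfg, exon_id, n) if cfg.indel_rate > 0 else []
        deleted = np.zeros(n, dtype=bool)
        for iv, _ in placed:
            deleted[iv.start : iv.end] = True

        snv_mask = rng.random(n) < cfg.snv_rate
        snv_positions = [p for p in np.flatnonzero(snv_mask) if not deleted[p]]

        snv_seq = list(ref_seq)
        exon_variants: list[tuple[int, str, str]] = []
        for p in snv_positions:
            ref_base = ref_seq[p]
            choices = [b for b in "ACGT" if b != ref_base]
            alt_base = choices[int(rng.integers(0, 3))]
            snv_seq[p] = alt_base
            exon_variants.append((int(p), ref_base, alt_base))

        # apply indels right-to-left so earlier coordinates stay valid
        alt_seq = snv_seq[:]
        for iv, ins in reversed(placed):
            alt_seq[iv.start : iv.end] = list(ins)
        alt_seq = "".join(alt_seq)

        exon_indels = IndelSet(iv for iv, _ in placed)
        for p, ref_base, alt_base in exon_variants:
            variants.append(
                Variant(exon_id, p, ref_base, alt_base,
                        alt_pos=exon_indels.alt_position(exon_id, p))
            )
        indels.extend(iv for iv, _ in placed)

        ref_exons.append(Exon(exon_id, ref_seq))
        alt_exons.append(Exon(exon_id, alt_seq))

    duplicates: list[tuple[str, str]] = []
    if n_dup:
        chosen = master.choice(n_orig, size=n_dup, replace=False)
        for idx in sorted(int(c) for c in chosen):
            orig = ref_exons[idx]
            dup_id = f"{orig.id}_dup"
            ref_exons.append(Exon(dup_id, orig.sequence))
            alt_exons.append(Exon(dup_id, alt_exons[idx].sequence))
            for v in [v for v in variants if v.exon_id == orig.id]:
                variants.append(Variant(dup_id, v.pos, v.ref_base, v.alt_base, v.alt_pos))
            for iv in [iv for iv in indels if iv.exon_id == orig.id]:
                indels.append(IndelInterval(dup_id, iv.start, iv.end, iv.alt_length))
            duplicates.append((orig.id, dup_id))

    truth = TruthTable(VariantSet(variants), IndelSet(indels), duplicates)
    return Exome(ref_exons), Exome(alt_exons), truth


def write_duplicates_tsv(duplicates: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("#original\tduplicate\n")
        for orig, dup in duplicates:
            fh.write(f"{orig}\t{dup}\n")


def read_duplicates_tsv(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            orig, dup = line.split("\t")[:2]
            out.append((orig, dup))
    return out
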