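"""End-to-end orchestration and summary tables.

`run_pipeline` wires the stages together: obtain an allele pair (synthetic
or from FASTA), derive differentiating sites and indels (from truth tables,
input files, or pairwise exon alignment), tile all reads from both alleles,
align them -- to the single reference genome with a mismatch allowance, or
to both indel-masked parental genomes with zero mismatches -- count alleles
at every site, annotate and filter, and (optionally) test.

The summary tables underlie the standard diagnostic views: proportion
distributions stratified by neighbor density, sequential-filter attrition
with the fraction of equal-abundance sites after each exclusion, and
site/exon retention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .aligner import align_dual, align_unique, summarize_alignments
from .metrics import annotate_sites, annotations_to_frame
from .quantify import (
    FILTER_STEPS,
    SiteRecord,
    build_records,
    classify_and_filter,
    dual_pileup,
    pileup,
    records_to_frame,
)
from .readsim import flag_informative, tile_allele_pair
from .sequences import (
    Exome,
    IndelSet,
    VariantSet,
    diff_exomes,
    drop_masked_variants,
    dual_masking_intervals,
    mask_indels,
    read_fasta,
    read_indels_tsv,
    read_variants_tsv,
    write_fasta,
    write_indels_tsv,
    write_variants_tsv,
)
from .stats import test_sites
from .synthetic import SimulationConfig, simulate_allele_pair, write_duplicates_tsv

SINGLE = "single_reference"
DUAL = "dual_parental"


@dataclass
class RunConfig:
    """All tunables of one pipeline run.

    Defaults mirror the standard short-read setting: 36-base reads, one
    mismatch, 20-read coverage threshold, FDR 0.05. Dual-parental mode
    requires m = 0 (no mismatches are allowed against either parental
    genome; a single mismatch would let alternative-allele reads align to
    the wrong parent).
    """

    mode: str = SINGLE
    k: int = 36
    m: int = 1
    min_coverage: int = 20
    alpha: float = 0.05
    filter_order: tuple[str, ...] = FILTER_STEPS
    run_tests: bool = False
    seed: int = 0
    sim: SimulationConfig | None = None
    ref_fasta: str | None = None
    alt_fasta: str | None = None
    variants_tsv: str | None = None
    indels_tsv: str | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in (SINGLE, DUAL):
            raise ValueError(f"mode must be {SINGLE!r} or {DUAL!r}")
        if self.mode == DUAL and self.m != 0:
            raise ValueError("dual_parental mode requires m == 0")
        if self.k < 1 or self.m < 0:
            raise ValueError("k must be >= 1 and m >= 0")
        if self.sim is None and (self.ref_fasta is None or self.alt_fasta is None):
            raise ValueError(
                "either a simulation config or ref/alt FASTA paths are required"
            )

    def config_hash(self) -> str:
        text = repr(sorted((f.name, str(getattr(self, f.name))) for f in dc_fields(self)))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a flat key = value config file.

    Keys match RunConfig fields; simulation keys are prefixed ``sim.``
    (``sim.n_exons = 50``). Presence of any ``sim.`` key enables synthetic
    input; ``sim.seed`` defaults to the run seed.
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value

    def _convert(value: str, target):
        if target is bool:
            return value.lower() in ("1", "true", "yes")
        if target is int:
            return int(value)
        if target is float:
            return float(value)
        if target is tuple:
            return tuple(item.strip() for item in value.split(","))
        return value

    cfg_kwargs = {}
    sim_kwargs = {}
    run_fields = {f.name: f for f in dc_fields(RunConfig)}
    sim_fields = {f.name: f for f in dc_fields(SimulationConfig)}
    for key, value in raw.items():
        if key.startswith("sim."):
            name = key[4:]
            if name not in sim_fields:
                raise ValueError(f"unknown simulation key {key!r}")
            if name in ("exon_length_range", "indel_length_range"):
                lo, hi = value.split(",")
                sim_kwargs[name] = (int(lo), int(hi))
            else:
                ftype = {"seed": int, "n_exons": int, "indel_margin": int}.get(name, float)
                sim_kwargs[name] = ftype(value)
        else:
            if key not in run_fields:
                raise ValueError(f"unknown config key {key!r}")
            target = {
                "k": int, "m": int, "min_coverage": int, "seed": int,
                "alpha": float, "run_tests": bool, "filter_order": tuple,
            }.get(key, str)
            cfg_kwargs[key] = _convert(value, target)
    if sim_kwargs:
        sim_kwargs.setdefault("seed", cfg_kwargs.get("seed", 0))
        cfg_kwargs["sim"] = SimulationConfig(**sim_kwargs)
    return RunConfig(**cfg_kwargs)


@dataclass
class PipelineResult:
    config: RunConfig
    ref: Exome
    alt: Exome
    variants: VariantSet
    indels: IndelSet
    records: list[SiteRecord]
    filter_steps: list[dict]
    alignment_summary: pd.DataFrame
    density_table: pd.DataFrame
    filter_table: pd.DataFrame
    class_table: pd.DataFrame
    retention: tuple[float, float]
    log: list[str] = field(default_factory=list)


def _is_equal(record: SiteRecord, equal: str) -> bool:
    if equal == "counts":
        return (
            record.counts.informative > 0
            and record.counts.ref_count == record.counts.alt_count
        )
    if equal == "test":
        return record.test is not None and record.test.tested and not record.test.significant
    raise ValueError(f"unknown equality definition {equal!r}")


def summarize_by_density(
    records: Sequence[SiteRecord], equal: str = "counts"
) -> pd.DataFrame:
    """One row per neighbor-density class: site count, proportion quartiles,
    and equal/unequal counts.

    ``equal='counts'`` (exhaustive simulations) means ref_count ==
    alt_count exactly; ``equal='test'`` (stochastic data) means tested and
    not significant.
    """
    rows = []
    by_density: dict[int, list[SiteRecord]] = {}
    for r in records:
        by_density.setdefault(r.annotation.density, []).append(r)
    for density in sorted(by_density):
        recs = by_density[density]
        props = [r.proportion for r in recs if r.proportion is not None]
        n_equal = sum(1 for r in recs if _is_equal(r, equal))
        quart = (
            pd.Series(props).quantile([0.25, 0.5, 0.75]).tolist()
            if props
            else [float("nan")] * 3
        )
        rows.append(
            {
                "density": density,
                "n_sites": len(recs),
                "q1": quart[0],
                "median": quart[1],
                "q3": quart[2],
                "n_equal": n_equal,
                "n_unequal": len(recs) - n_equal,
            }
        )
    return pd.DataFrame(
        rows, columns=["density", "n_sites", "q1", "median", "q3", "n_equal", "n_unequal"]
    )


def summarize_filters(
    records: Sequence[SiteRecord],
    order: Sequence[str] = FILTER_STEPS,
    equal: str = "counts",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential retention table plus the problematic-class breakdown.

    The first table walks the exclusion steps in order, recording sites
    excluded at each step, sites remaining, and the fraction of remaining
    sites with equal allelic abundance. The second tallies every
    combination of the three flags (multi-flag sites appear once, under
    their combination), the view behind class-proportion summaries.
    """
    flag_of_step = {
        "density": "biased_density",
        "mappability": "imperfect_mappability",
        "indel": "indel_nearby",
    }
    remaining = list(records)

    def _frac_equal(recs):
        with_cov = [r for r in recs if r.proportion is not None]
        if not with_cov:
            return float("nan")
        return sum(1 for r in with_cov if _is_equal(r, equal)) / len(with_cov)

    rows = [
        {
            "step": "none",
            "n_excluded": 0,
            "n_remaining": len(remaining),
            "frac_equal": _frac_equal(remaining),
        }
    ]
    for step in order:
        flag = flag_of_step[step]
        excluded = [r for r in remaining if r.flags.get(flag)]
        remaining = [r for r in remaining if not r.flags.get(flag)]
        rows.append(
            {
                "step": step,
                "n_excluded": len(excluded),
                "n_remaining": len(remaining),
                "frac_equal": _frac_equal(remaining),
            }
        )
    steps = pd.DataFrame(rows)

    combos: dict[tuple[str, ...], int] = {}
    for r in records:
        active = tuple(sorted(name for name, on in r.flags.items() if on))
        if active:
            combos[active] = combos.get(active, 0) + 1
    classes = pd.DataFrame(
        [
            {"flags": "+".join(combo), "n_sites": n}
            for combo, n in sorted(combos.items())
        ],
        columns=["flags", "n_sites"],
    )
    return steps, classes


def retention_summary(records: Sequence[SiteRecord]) -> tuple[float, float]:
    """(fraction of sites retained, fraction of exons with >= 1 retained
    site), over sites/exons that had at least one differentiating site."""
    if not records:
        return (float("nan"), float("nan"))
    n_retained = sum(1 for r in records if r.retained)
    exons = {r.site.exon_id for r in records}
    exons_retained = {r.site.exon_id for r in records if r.retained}
    return (n_retained / len(records), len(exons_retained) / len(exons))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow; deterministic given the config seed."""
    config.validate()
    log = [
        f"asebias {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
        f"mode {config.mode} k {config.k} m {config.m}",
    ]

    if config.sim is not None:
        ref, alt, truth = simulate_allele_pair(config.sim)
        variants, indels = truth.variants, truth.indels
        log.append(
            f"simulated {len(ref)} exons, {len(variants)} variants, "
            f"{len(indels)} indels"
        )
    else:
        ref = read_fasta(config.ref_fasta)
        alt = read_fasta(config.alt_fasta)
        if config.variants_tsv:
            variants = read_variants_tsv(config.variants_tsv)
            indels = (
                read_indels_tsv(config.indels_tsv) if config.indels_tsv else IndelSet()
            )
        else:
            variants, indels = diff_exomes(ref, alt)
        log.append(
            f"loaded {len(ref)} exons, {len(variants)} variants, {len(indels)} indels"
        )

    reads = flag_informative(tile_allele_pair(ref, alt, config.k), variants)
    log.append(f"tiled {len(reads)} reads (k={config.k}, both alleles, both strands)")

    if config.mode == SINGLE:
        pairs = [(r, align_unique(r.sequence, ref, config.m)) for r in reads]
        aln_summary = summarize_alignments(pairs)
        counts = pileup(pairs, variants)
        annotations = annotate_sites(variants, ref, config.k, config.m, indels)
        site_variants = variants
    else:
        ref_ivals, alt_ivals = dual_masking_intervals(indels, ref, alt)
        masked_ref = mask_indels(ref, ref_ivals)
        masked_alt = mask_indels(alt, alt_ivals)
        site_variants = drop_masked_variants(variants, ref_ivals, alt_ivals)
        pairs = [(r, align_dual(r.sequence, masked_ref, masked_alt)) for r in reads]
        aln_summary = summarize_alignments(pairs)
        counts = dual_pileup(pairs, site_variants)
        annotations = annotate_sites(
            site_variants, masked_ref, config.k, 0, indels, alt_exome=masked_alt
        )
        log.append(
            f"masked {len(ref_ivals)} ref / {len(alt_ivals)} alt intervals; "
            f"{len(site_variants)} sites observable"
        )

    records = build_records(site_variants, counts, annotations)
    records, filter_steps = classify_and_filter(
        records, config.m, config.mode, config.filter_order
    )
    if config.run_tests:
        records = test_sites(records, config.min_coverage, config.alpha)
        log.append(
            f"tested {sum(1 for r in records if r.test.tested)} sites "
            f"(min coverage {config.min_coverage}, FDR alpha {config.alpha})"
        )

    equal = "test" if config.run_tests else "counts"
    density_table = summarize_by_density(records, equal=equal)
    filter_table, class_table = summarize_filters(
        records, config.filter_order, equal=equal
    )
    retention = retention_summary(records)
    for step in filter_steps:
        log.append(
            f"filter {step['step']}: excluded {step['n_excluded']}, "
            f"remaining {step['n_remaining']}"
        )
    log.append(
        f"retention: {retention[0]:.4f} of sites, {retention[1]:.4f} of exons"
    )

    return PipelineResult(
        config=config,
        ref=ref,
        alt=alt,
        variants=site_variants,
        indels=indels,
        records=records,
        filter_steps=filter_steps,
        alignment_summary=aln_summary,
        density_table=density_table,
        filter_table=filter_table,
        class_table=class_table,
        retention=retention,
        log=log,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the artifact bundle: FASTA, truth tables, per-site TSV,
    summary tables, and the run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.ref, out / "ref.fasta")
    write_fasta(result.alt, out / "alt.fasta")
    write_variants_tsv(result.variants, out / "variants.tsv")
    write_indels_tsv(result.indels, out / "indels.tsv")
    if result.config.sim is not None:
        # duplicate-pair table only exists for synthetic input
        _, _, truth = simulate_allele_pair(result.config.sim)
        write_duplicates_tsv(truth.duplicates, out / "duplicates.tsv")
    records_to_frame(result.records).to_csv(out / "sites.tsv", sep="\t", index=False)
    result.alignment_summary.to_csv(out / "alignment_summary.tsv", sep="\t", index=False)
    result.density_table.to_csv(out / "density_summary.tsv", sep="\t", index=False)
    result.filter_table.to_csv(out / "filter_summary.tsv", sep="\t", index=False)
    result.class_table.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    (out / "run.log").write_text("\n".join(result.log) + "\n")
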