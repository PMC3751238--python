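"""Pipeline orchestration, summary tables, config parsing, CLI."""

from __future__ import annotations

import pytest
from click.testing import CliRunner

from asebias.cli import main as cli_main
from asebias.metrics import SiteAnnotation
from asebias.quantify import SiteCounts, SiteRecord, classify_and_filter, reference_proportion
from asebias.report import (
    RunConfig,
    load_run_config,
    retention_summary,
    run_pipeline,
    summarize_by_density,
    summarize_filters,
    write_outputs,
)
from asebias.sequences import Variant
from asebias.synthetic import SimulationConfig


def _record(pos=10, exon="e", density=0, mapp=1.0, indel=False, counts=(5, 5, 0)):
    site = Variant(exon, pos, "A", "G")
    c = SiteCounts(*counts)
    return SiteRecord(site=site, counts=c,
                      annotation=SiteAnnotation(site, density, mapp, None, indel),
                      proportion=reference_proportion(c))


@pytest.fixture(scope="module")
def single_run():
    cfg = RunConfig(
        mode="single_reference", k=36, m=1,
        sim=SimulationConfig(seed=21, n_exons=15, exon_length_range=(300, 500),
                             snv_rate=0.01),
    )
    return run_pipeline(cfg)


class TestSummarizeByDensity:
    def test_all_equal_single_row(self):
        table = summarize_by_density([_record(pos=i) for i in range(4)])
        assert len(table) == 1
        assert table.loc[0, "n_equal"] == 4 and table.loc[0, "n_unequal"] == 0

    def test_empty_records(self):
        assert summarize_by_density([]).empty

    def test_density_zero_median_half_above_biased(self, single_run):
        """Synthetic run, m=1: density-0 sites sit at 0.5 exactly; denser
        classes have medians above 0.5 (reference bias)."""
        table = single_run.density_table.set_index("density")
        assert table.loc[0, "median"] == 0.5
        assert table.loc[0, "n_unequal"] == 0
        for density in table.index:
            if density >= 1:
                assert table.loc[density, "median"] > 0.5


class TestSummarizeFilters:
    def test_no_flags_full_retention(self):
        records, _ = classify_and_filter([_record(), _record(pos=20)], m=1)
        steps, classes = summarize_filters(records)
        assert (steps["n_remaining"] == 2).all()
        assert classes.empty

    def test_disjoint_flags_partition(self):
        records, _ = classify_and_filter(
            [
                _record(pos=1, density=5),
                _record(pos=2, mapp=0.5),
                _record(pos=3, indel=True),
                _record(pos=4),
            ],
            m=1,
        )
        steps, classes = summarize_filters(records)
        assert steps["n_excluded"].tolist() == [0, 1, 1, 1]
        assert classes["n_sites"].sum() == 3

    def test_multiflag_site_counted_once_in_overlap(self):
        records, _ = classify_and_filter(
            [
                _record(pos=1, density=5, mapp=0.5),
                _record(pos=2, density=5),
                _record(pos=3, mapp=0.5),
                _record(pos=4),
                _record(pos=5),
            ],
            m=1,
        )
        steps, classes = summarize_filters(records)
        # the double-flagged site is excluded at the density step
        assert steps.set_index("step").loc["density", "n_excluded"] == 2
        assert steps.set_index("step").loc["mappability", "n_excluded"] == 1
        combo = classes.set_index("flags")
        assert combo.loc["biased_density+imperfect_mappability", "n_sites"] == 1
        assert classes["n_sites"].sum() == 3


class TestRetentionSummary:
    def test_all_retained(self):
        records, _ = classify_and_filter([_record(pos=1), _record(pos=2)], m=1)
        assert retention_summary(records) == (1.0, 1.0)

    def test_exon_retained_if_any_site_survives(self):
        records, _ = classify_and_filter(
            [_record(pos=1, density=5), _record(pos=2, density=5), _record(pos=3)],
            m=1,
        )
        frac_sites, frac_exons = retention_summary(records)
        assert frac_sites == pytest.approx(1 / 3)
        assert frac_exons == 1.0

    def test_exon_lost_when_all_sites_excluded(self):
        records, _ = classify_and_filter(
            [_record(pos=1, exon="a", density=5), _record(pos=2, exon="b")], m=1
        )
        _, frac_exons = retention_summary(records)
        assert frac_exons == 0.5


class TestPipeline:
    def test_percent_equal_rises_after_filtering(self, single_run):
        steps = single_run.filter_table
        assert steps.iloc[-1]["frac_equal"] >= steps.iloc[0]["frac_equal"]
        assert steps.iloc[-1]["frac_equal"] == 1.0

    def test_deterministic_outputs(self, tmp_path, single_run):
        result2 = run_pipeline(single_run.config)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_outputs(single_run, d1)
        write_outputs(result2, d2)
        for name in ("sites.tsv", "ref.fasta", "variants.tsv", "density_summary.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_dual_mode_requires_zero_mismatches(self):
        cfg = RunConfig(mode="dual_parental", m=1, sim=SimulationConfig(seed=1))
        with pytest.raises(ValueError, match="m == 0"):
            run_pipeline(cfg)

    def test_mismatch_per_base_parity(self):
        """k=36,m=3 and k=50,m=4 on the same variant landscape give
        equal-abundance fractions within 2 percentage points."""
        fracs = []
        for k, m in ((36, 3), (50, 4)):
            cfg = RunConfig(
                mode="single_reference", k=k, m=m,
                sim=SimulationConfig(seed=33, n_exons=40,
                                     exon_length_range=(300, 600), snv_rate=0.01),
            )
            res = run_pipeline(cfg)
            with_cov = [r for r in res.records if r.proportion is not None]
            fracs.append(
                sum(1 for r in with_cov if r.counts.ref_count == r.counts.alt_count)
                / len(with_cov)
            )
        assert abs(fracs[0] - fracs[1]) <= 0.02


class TestRunConfigFile:
    def test_round_trip_parse(self, tmp_path):
        text = """
        # comment
        mode = single_reference
        k = 36
        m = 2
        seed = 7
        run_tests = true
        sim.n_exons = 5
        sim.snv_rate = 0.02
        sim.exon_length_range = 200, 300
        """
        p = tmp_path / "run.cfg"
        p.write_text("\n".join(l.strip() for l in text.splitlines()))
        cfg = load_run_config(p)
        assert cfg.m == 2 and cfg.run_tests
        assert cfg.sim.n_exons == 5 and cfg.sim.seed == 7
        assert cfg.sim.exon_length_range == (200, 300)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            load_run_config(p)


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(
            cli_main,
            ["simulate", "--seed", "3", "--n-exons", "4",
             "--exon-length", "200", "300", "--out-dir", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert (out / "ref.fasta").exists() and (out / "variants.tsv").exists()

        cfg = tmp_path / "run.cfg"
        cfg.write_text(
            "mode = single_reference\nk = 36\nm = 1\nseed = 3\n"
            "sim.n_exons = 4\nsim.exon_length_range = 200, 300\n"
        )
        r = runner.invoke(
            cli_main, ["run", str(cfg), "--out-dir", str(tmp_path / "runout")]
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "runout" / "sites.tsv").exists()

    def test_tile_align_quantify_chain(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        runner.invoke(
            cli_main,
            ["simulate", "--seed", "5", "--n-exons", "3",
             "--exon-length", "150", "200", "--out-dir", str(sim)],
        )
        reads = tmp_path / "reads.fasta"
        r = runner.invoke(
            cli_main,
            ["tile", str(sim / "alt.fasta"), "-k", "36", "--allele", "ALT",
             "-o", str(reads)],
        )
        assert r.exit_code == 0, r.output
        sam = tmp_path / "aln.sam"
        r = runner.invoke(
            cli_main,
            ["align", str(reads), str(sim / "ref.fasta"), "-m", "1",
             "--sam", str(sam)],
        )
        assert r.exit_code == 0, r.output
        assert sam.read_text().startswith("@HD")
        sites = tmp_path / "sites.tsv"
        r = runner.invoke(
            cli_main,
            ["quantify", str(reads), str(sim / "ref.fasta"),
             str(sim / "variants.tsv"), "-m", "1", "-o", str(sites)],
        )
        assert r.exit_code == 0, r.output
        assert "proportion" in sites.read_text().splitlines()[0]
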