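"""Correlation clustering, report tables, and the orchestrated pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from triohet.cli import main as cli_main
from triohet.modes import GeneActionMode as M
from triohet.modes import summary_from_counts
from triohet.reporting import (
    PipelineConfig,
    correlation_matrix,
    log_normalized,
    mode_table,
    run_pipeline,
)
from triohet.synthetic_data import (
    TrioSimConfig,
    simulate_long_reads,
    simulate_splice_events,
    simulate_trio_counts,
)


class TestCorrelation:
    def test_duplicated_sample_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        df = pd.DataFrame(
            {
                "a": base,
                "a_copy": base,
                "b": rng.normal(size=50),
                "c": rng.normal(size=50),
            }
        )
        rep = correlation_matrix(df)
        assert rep.corr.loc["a", "a_copy"] == pytest.approx(1.0)
        left, right = rep.top_split()
        cluster_with_a = left if "a" in left else right
        assert "a_copy" in cluster_with_a

    def test_negated_sample_anticorrelates(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        df = pd.DataFrame({"a": base, "neg": -base, "b": rng.normal(size=30)})
        rep = correlation_matrix(df)
        assert rep.corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_zero_variance_sample_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)

    def test_matrix_is_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        rep = correlation_matrix(df)
        np.testing.assert_allclose(rep.corr, rep.corr.T)
        np.testing.assert_allclose(np.diag(rep.corr), 1.0)
        assert rep.corr.to_numpy().min() >= -1.0 - 1e-12

    def test_tissue_dominant_design_splits_by_tissue(self):
        """Strong tissue effects put the dendrogram's top split between tissues."""
        hits = 0
        for seed in range(20):
            cfg = TrioSimConfig(
                n_genes=300,
                seed=seed,
                tissues=("muscle", "brain"),
                effect_size_log2=0.5,
                tissue_effect_log2_sd=2.0,
            )
            cm, sheet, _ = simulate_trio_counts(cfg)
            rep = correlation_matrix(log_normalized(cm))
            left, right = rep.top_split()
            tissues = lambda ss: {s.split("_")[0] for s in ss}  # noqa: E731
            if tissues(left) != tissues(right) and len(tissues(left)) == 1 == len(tissues(right)):
                hits += 1
        assert hits == 20


class TestModeTable:
    def test_single_summary_row_order(self):
        s = summary_from_counts({M.OVER_DOMINANCE: 3, M.ADDITIVE: 1})
        table = mode_table({("muscle", "mule"): s})
        assert list(table.columns[:8]) == [
            "tissue",
            "hybrid",
            "other_non_additive",
            "over_dominance",
            "high_parent_dominance",
            "additive",
            "low_parent_dominance",
            "under_dominance",
        ]
        assert table.loc[0, "total_classified"] == 4

    def test_dominance_heavy_row_aggregates(self):
        s = summary_from_counts(
            {
                M.OVER_DOMINANCE: 173,
                M.HIGH_PARENT_DOMINANCE: 950,
                M.ADDITIVE: 287,
                M.LOW_PARENT_DOMINANCE: 633,
                M.UNDER_DOMINANCE: 198,
            }
        )
        table = mode_table({("muscle", "mule"): s})
        assert int(table.loc[0, "over_plus_under"] + table.loc[0, "high_plus_low"]) == 1954

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mode_table({})


@pytest.fixture(scope="module")
def sim_dataset(tmp_path_factory):
    """A small simulated dataset written to disk once for pipeline tests."""
    from triohet import io_formats

    outdir = tmp_path_factory.mktemp("sim")
    cfg = TrioSimConfig(n_genes=300, n_events=120, seed=21, longread_depth=8.0)
    cm, sheet, truth_g = simulate_trio_counts(cfg)
    events, _, truth_e = simulate_splice_events(cfg)
    reads = simulate_long_reads(events, truth_e, cfg)
    io_formats.write_counts(cm, outdir / "counts.tsv")
    io_formats.write_sample_sheet(sheet, outdir / "samples.tsv")
    io_formats.write_events(events, outdir / "events.tsv")
    io_formats.write_bed12(reads, outdir / "reads.bed")
    gene_ids = cm.gene_ids
    with open(outdir / "sets.gmt", "w") as fh:
        fh.write("setA\tfirst genes\t" + "\t".join(gene_ids[:40]) + "\n")
        fh.write("setB\tlast genes\t" + "\t".join(gene_ids[-40:]) + "\n")
    return outdir


class TestPipeline:
    def test_smoke_all_outputs_present(self, sim_dataset, tmp_path):
        cfg = PipelineConfig(
            counts=sim_dataset / "counts.tsv",
            samples=sim_dataset / "samples.tsv",
            events=sim_dataset / "events.tsv",
            reads=sim_dataset / "reads.bed",
            gene_sets=sim_dataset / "sets.gmt",
            outdir=tmp_path / "out",
        )
        bundle = run_pipeline(cfg)
        expected = [
            "de_hybrid_vs_paternal.tsv",
            "deg_counts.tsv",
            "modes_expression.tsv",
            "das_hybrid_vs_paternal.tsv",
            "modes_splicing.tsv",
            "mode_summary.tsv",
            "validation_summary.tsv",
            "correlation_expression.tsv",
            "run_manifest.json",
        ]
        for name in expected:
            assert (tmp_path / "out" / name).exists(), name
        manifest = json.loads((tmp_path / "out" / "run_manifest.json").read_text())
        assert manifest["alpha"] == 0.05
        assert "validation" in bundle

    def test_determinism_byte_identical(self, sim_dataset, tmp_path):
        kwargs = dict(
            counts=sim_dataset / "counts.tsv",
            samples=sim_dataset / "samples.tsv",
            events=sim_dataset / "events.tsv",
        )
        run_pipeline(PipelineConfig(outdir=tmp_path / "o1", **kwargs))
        run_pipeline(PipelineConfig(outdir=tmp_path / "o2", **kwargs))
        for f in sorted((tmp_path / "o1").iterdir()):
            if f.suffix == ".tsv":
                assert f.read_bytes() == (tmp_path / "o2" / f.name).read_bytes(), f.name

    def test_outputs_reparse_through_validators(self, sim_dataset, tmp_path):
        run_pipeline(
            PipelineConfig(
                counts=sim_dataset / "counts.tsv",
                samples=sim_dataset / "samples.tsv",
                outdir=tmp_path / "out",
            )
        )
        de = pd.read_csv(tmp_path / "out" / "de_hybrid_vs_paternal.tsv", sep="\t")
        assert {"gene_id", "log2fc", "padj", "direction"} <= set(de.columns)
        assert de["padj"].between(0, 1).all()


class TestCli:
    def test_simulate_then_report(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        res = runner.invoke(
            cli_main,
            ["simulate", "--seed", "5", "--outdir", str(sim_dir),
             "--n-genes", "120", "--n-events", "40"],
        )
        assert res.exit_code == 0, res.output
        for name in ["counts.tsv", "samples.tsv", "events.tsv", "reads.bed", "truth_genes.tsv"]:
            assert (sim_dir / name).exists()
        out = tmp_path / "report"
        res = runner.invoke(
            cli_main,
            ["report", "--counts", str(sim_dir / "counts.tsv"),
             "--samples", str(sim_dir / "samples.tsv"),
             "--events", str(sim_dir / "events.tsv"),
             "--reads", str(sim_dir / "reads.bed"),
             "--outdir", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert (out / "mode_summary.tsv").exists()

    def test_de_subcommand(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(cli_main, ["simulate", "--seed", "6", "--outdir", str(sim_dir), "--n-genes", "80"])
        res = runner.invoke(
            cli_main,
            ["de", "--counts", str(sim_dir / "counts.tsv"),
             "--samples", str(sim_dir / "samples.tsv"),
             "--out", str(tmp_path / "de.tsv")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "de.tsv").exists()
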