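"""Generator contracts: determinism, planted-truth invariants, calibrations."""

import math

import numpy as np
import pandas as pd
import pytest

from triohet.io_formats import write_bed12, write_counts, write_events, write_sample_sheet
from triohet.synthetic_data import (
    TrioSimConfig,
    simulate_long_reads,
    simulate_splice_events,
    simulate_trio_counts,
)


class TestConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrioSimConfig(mode_proportions={"conserved": 0.5})

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            TrioSimConfig(replicates_per_group=1)

    def test_delta_psi_must_be_fraction(self):
        with pytest.raises(ValueError):
            TrioSimConfig(delta_psi_planted=1.0)


class TestCounts:
    def test_same_seed_bit_identical(self):
        cfg = TrioSimConfig(n_genes=100, seed=42)
        c1, s1, t1 = simulate_trio_counts(cfg)
        c2, s2, t2 = simulate_trio_counts(cfg)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_series_equal(t1.library_factors, t2.library_factors)

    def test_different_seeds_differ(self):
        c1, _, _ = simulate_trio_counts(TrioSimConfig(n_genes=100, seed=1))
        c2, _, _ = simulate_trio_counts(TrioSimConfig(n_genes=100, seed=2))
        assert not c1.counts.equals(c2.counts)

    def test_conserved_only_centers_on_zero(self):
        cfg = TrioSimConfig(n_genes=500, seed=3, mode_proportions={"conserved": 1.0})
        cm, sheet, truth = simulate_trio_counts(cfg)
        assert (truth.genes[["mu_h", "mu_p", "mu_m"]].nunique(axis=1) == 1).all()
        hyb = cm.counts[sheet.samples_for("hybrid")].mean(axis=1)
        pat = cm.counts[sheet.samples_for("paternal_parent")].mean(axis=1)
        lfc = np.log2((hyb + 1) / (pat + 1))
        assert abs(lfc.mean()) < 0.1

    def test_truth_means_respect_declared_modes(self):
        cfg = TrioSimConfig(n_genes=600, seed=4)
        _, _, truth = simulate_trio_counts(cfg)
        g = truth.genes
        e = cfg.effect_size_log2
        over = g[g["true_mode"] == "over_dominance"]
        assert (np.log2(over["mu_h"] / over[["mu_p", "mu_m"]].max(axis=1)) >= e / 2 - 1e-9).all()
        under = g[g["true_mode"] == "under_dominance"]
        assert (np.log2(under[["mu_p", "mu_m"]].min(axis=1) / under["mu_h"]) >= e / 2 - 1e-9).all()
        add = g[g["true_mode"] == "additive"]
        np.testing.assert_allclose(add["mu_h"], 0.5 * (add["mu_p"] + add["mu_m"]), rtol=1e-12)
        assert (add["mu_p"] != add["mu_m"]).all()
        high = g[g["true_mode"] == "high_parent_dominance"]
        np.testing.assert_allclose(high["mu_h"], high[["mu_p", "mu_m"]].max(axis=1), rtol=1e-12)

    def test_dispersion_calibration_method_of_moments(self):
        """Moment-estimated dispersion from parent replicates recovers alpha=0.1."""
        cfg = TrioSimConfig(
            n_genes=2000,
            seed=5,
            replicates_per_group=10,
            mode_proportions={"conserved": 1.0},
            library_size_range=(1.0, 1.0),
            baseline_log_mean=(math.log(500), 0.3),
        )
        cm, sheet, _ = simulate_trio_counts(cfg)
        x = cm.counts[sheet.samples_for("paternal_parent")].to_numpy(dtype=float)
        mu = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        alpha_hat = (s2 - mu) / mu**2
        inside = ((alpha_hat >= 0.03) & (alpha_hat <= 0.3)).mean()
        assert inside >= 0.80  # noisy per-gene MoM, but centred on the truth
        assert 0.08 <= np.median(alpha_hat) <= 0.13

    def test_library_factors_within_range(self):
        cfg = TrioSimConfig(n_genes=50, seed=6, library_size_range=(0.5, 2.0))
        _, _, truth = simulate_trio_counts(cfg)
        assert truth.library_factors.between(0.5, 2.0).all()


class TestSpliceEvents:
    def test_same_seed_identical(self):
        cfg = TrioSimConfig(n_events=50, seed=7)
        e1, _, t1 = simulate_splice_events(cfg)
        e2, _, t2 = simulate_splice_events(cfg)
        assert e1 == e2
        pd.testing.assert_frame_equal(t1.events, t2.events)

    def test_psi_one_means_no_skipping(self):
        cfg = TrioSimConfig(n_events=30, seed=8, psi_base_range=(0.99, 0.995), delta_psi_planted=0.3, mode_proportions={"conserved": 1.0})
        events, _, truth = simulate_splice_events(cfg)
        # psi ~ 0.99+: binomial skip counts are near zero on average
        total_skip = sum(sum(ev.skipping_counts.values()) for ev in events)
        total = sum(sum(ev.inclusion_counts.values()) + sum(ev.skipping_counts.values()) for ev in events)
        assert total_skip / total < 0.05

    def test_truth_psi_respects_modes(self):
        cfg = TrioSimConfig(n_events=400, seed=9)
        _, _, truth = simulate_splice_events(cfg)
        t = truth.events
        delta = cfg.delta_psi_planted
        das = t[t["true_mode"].isin(["over_dominance", "under_dominance"])]
        assert (abs(das["psi_h"] - das["psi_p"]) >= delta - 1e-9).all()
        assert das["das_any"].all()
        cons = t[t["true_mode"] == "conserved"]
        assert (cons["psi_h"] == cons["psi_p"]).all()
        assert (~cons["das_any"]).all()
        assert t[["psi_h", "psi_p", "psi_m"]].stack().between(0, 1).all()

    def test_planted_delta_psi_recovered_empirically(self):
        """Mean estimated hybrid-parent delta-psi within 0.05 of the planted 0.3."""
        cfg = TrioSimConfig(
            n_events=500,
            seed=10,
            event_coverage_mean=200.0,
            mode_proportions={"over_dominance": 1.0},
        )
        events, sheet, truth = simulate_splice_events(cfg)
        hyb = sheet.samples_for("hybrid")
        pat = sheet.samples_for("paternal_parent")
        from triohet.splicing import group_psi

        est = np.array([group_psi(ev, hyb) - group_psi(ev, pat) for ev in events])
        assert abs(np.nanmean(est) - 0.3) < 0.05

    def test_emitted_table_roundtrips(self, tmp_path):
        from triohet.io_formats import read_events

        cfg = TrioSimConfig(n_events=20, seed=11)
        events, _, _ = simulate_splice_events(cfg)
        write_events(events, tmp_path / "e.tsv")
        assert read_events(tmp_path / "e.tsv") == events


class TestLongReads:
    def test_zero_depth_no_reads(self):
        cfg = TrioSimConfig(n_events=20, longread_depth=0.0, seed=12)
        events, _, truth = simulate_splice_events(cfg)
        assert simulate_long_reads(events, truth, cfg) == []

    def test_psi_one_emits_only_inclusion(self):
        cfg = TrioSimConfig(
            n_events=30, seed=13, longread_depth=10.0,
            psi_base_range=(0.99, 0.995), mode_proportions={"conserved": 1.0},
        )
        events, _, truth = simulate_splice_events(cfg)
        truth.events["psi_h"] = 1.0
        reads = simulate_long_reads(events, truth, cfg)
        by_event = {ev.event_id: ev for ev in events}
        for r in reads:
            ev = by_event["_".join(r.read_id.split("_")[1:3])]
            assert list(r.blocks) == [tuple(b) for b in ev.inclusion_chain]

    def test_coverage_fraction_matches_poisson_zero_mass(self):
        """covered fraction ~= (1-uncovered)*(1-exp(-depth))."""
        cfg = TrioSimConfig(
            n_events=1000, seed=14, longread_depth=5.0, uncovered_fraction=0.3
        )
        events, _, truth = simulate_splice_events(cfg)
        simulate_long_reads(events, truth, cfg)
        t = truth.events
        covered = ((t["n_reads_inclusion"] + t["n_reads_exclusion"]) > 0).mean()
        expected = 0.7 * (1.0 - math.exp(-5.0))
        assert abs(covered - expected) < 0.05

    def test_generated_files_pass_validators(self, tmp_path):
        from triohet.io_formats import read_bed12, read_counts, read_sample_sheet

        cfg = TrioSimConfig(n_genes=50, n_events=30, seed=15, longread_depth=3.0)
        cm, sheet, _ = simulate_trio_counts(cfg)
        events, _, truth = simulate_splice_events(cfg)
        reads = simulate_long_reads(events, truth, cfg)
        write_counts(cm, tmp_path / "c.tsv")
        write_sample_sheet(sheet, tmp_path / "s.tsv")
        write_bed12(reads, tmp_path / "r.bed")
        assert read_counts(tmp_path / "c.tsv").counts.shape == (50, 9)
        assert len(read_sample_sheet(tmp_path / "s.tsv").sample_ids) == 9
        assert len(read_bed12(tmp_path / "r.bed")) == len(reads)
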