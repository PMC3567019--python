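"""Pairwise r², the fixed distance classes, and the Sved decay fit."""

import numpy as np
import pandas as pd
import pytest

from snppop import MISSING, PanelError, PopulationSpec, SimulationConfig, simulate_genotypes
from snppop.ld import (
    BIN_EDGES_KB,
    SvedFit,
    bin_ld,
    fit_sved,
    interpopulation_ld,
    pairwise_r2,
    population_ld_fit,
)
from conftest import make_panel


def records(dists_kb, r2s):
    return pd.DataFrame(
        {
            "snp_a": [f"a{i}" for i in range(len(r2s))],
            "snp_b": [f"b{i}" for i in range(len(r2s))],
            "distance_bp": np.asarray(dists_kb) * 1000.0,
            "r2": r2s,
        }
    )


class TestPairwiseR2:
    def panel_from_cols(self, *cols):
        d = np.stack(cols, axis=1).astype(np.int8)
        return make_panel(d, positions=[10_000 * (i + 1) for i in range(len(cols))])

    def test_identical_vectors_give_one(self):
        g = np.array([0, 1, 2, 0, 2, 1, 1, 0, 2, 1])
        rec = pairwise_r2(self.panel_from_cols(g, g), min_maf=0.0)
        assert rec.r2.iloc[0] == pytest.approx(1.0)

    def test_complement_vector_gives_one(self):
        g = np.array([0, 1, 2, 0, 2, 1, 1, 0, 2, 1])
        rec = pairwise_r2(self.panel_from_cols(g, 2 - g), min_maf=0.0)
        assert rec.r2.iloc[0] == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        g1 = np.array([0, 1, 2, 0, 2])
        g2 = np.array([0, 1, 1, 0, 2])
        rec = pairwise_r2(self.panel_from_cols(g1, g2), min_maf=0.0)
        assert rec.r2.iloc[0] == pytest.approx(9 / 11.2)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, 40)
        g2 = rng.integers(0, 3, 40)
        a = pairwise_r2(self.panel_from_cols(g1, g2), min_maf=0.0).r2.iloc[0]
        b = pairwise_r2(self.panel_from_cols(2 - g1, g2), min_maf=0.0).r2.iloc[0]
        assert a == pytest.approx(b)

    def test_maf_and_missing_filters_applied(self):
        rare = np.array([1] + [0] * 19)  # maf 0.025 < 0.10
        gappy = np.array([1, 0] * 10)
        gappy = gappy.copy()
        common = np.array([0, 1, 2, 1] * 5)
        d = np.stack([rare, common, gappy], axis=1).astype(np.int8)
        d[:3, 2] = MISSING  # 15% missing
        panel = make_panel(d, positions=[10_000, 20_000, 30_000])
        rec = pairwise_r2(panel)
        assert len(rec) == 0  # only `common` survives -> no pair

    def test_max_distance_respected(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (30, 3)).astype(np.int8)
        panel = make_panel(d, positions=[1, 500_000, 2_000_000])
        rec = pairwise_r2(panel, min_maf=0.0)
        assert (rec.distance_bp <= 1_000_000).all()
        assert len(rec) == 1  # only the first two are within 1 Mb


class TestBinning:
    def test_class_membership(self):
        rec = records([150, 4, 0.5], [0.5, 0.5, 0.5])
        binned = bin_ld(rec)
        assert binned.loc[binned.bin == "120-160", "n_pairs"].iloc[0] == 1
        # exactly 4 kb falls in [4, 8), not [0, 4)
        assert binned.loc[binned.bin == "4-8", "n_pairs"].iloc[0] == 1
        assert binned.loc[binned.bin == "0-4", "n_pairs"].iloc[0] == 1

    def test_mean_within_class(self):
        rec = records([10, 11], [0.2, 0.6])
        binned = bin_ld(rec)
        row = binned[binned.bin == "8-12"].iloc[0]
        assert row.n_pairs == 2 and row.mean_r2 == pytest.approx(0.4)

    def test_nineteen_classes(self):
        assert len(BIN_EDGES_KB) - 1 == 19
        assert bin_ld(records([5], [0.1])).shape[0] == 19


class TestSvedFit:
    def test_noiseless_recovery(self):
        d = np.arange(1, 1001, dtype=float)
        rec = records(d, 1.0 / (1.0 + 0.01 * d))
        fit = fit_sved(rec)
        assert fit.beta_per_kb == pytest.approx(0.01, rel=1e-4)
        assert fit.rss < 1e-8

    def test_extent_algebra(self):
        fit = SvedFit(beta_per_kb=7 / 300, rss=0.0, n_pairs=10, threshold=0.3)
        assert fit.extent_kb == pytest.approx(100.0)
        fit2 = SvedFit(beta_per_kb=0.01, rss=0.0, n_pairs=10, threshold=0.5)
        assert fit2.extent_kb == pytest.approx(100.0)

    def test_no_decay_reports_infinite_extent(self):
        # r² constant at 1 over all distances: the best hyperbola is flat
        rec = records(np.arange(1, 50, dtype=float), np.ones(49))
        fit = fit_sved(rec)
        assert fit.beta_per_kb == 0.0
        assert np.isinf(fit.extent_kb)

    def test_extent_monotone_in_beta_and_threshold(self):
        betas = [0.005, 0.01, 0.02]
        extents = [SvedFit(b, 0.0, 1).extent_kb for b in betas]
        assert extents[0] > extents[1] > extents[2]
        thresholds = [0.2, 0.3, 0.5]
        ext_t = [SvedFit(0.01, 0.0, 1, threshold=t).extent_kb for t in thresholds]
        assert ext_t[0] > ext_t[1] > ext_t[2]

    def test_single_distance_errors(self):
        with pytest.raises(PanelError):
            fit_sved(records([10, 10], [0.5, 0.4]))


class TestInterpopulationLD:
    def _panel(self, seed=0):
        cfg = SimulationConfig(
            seed=seed, n_snps=600, snp_spacing_bp=20_000, n_chromosomes=2,
            populations=[PopulationSpec("A", 20, 0.15), PopulationSpec("B", 20, 0.15)],
            ld_beta_per_kb=0.02,
        )
        return simulate_genotypes(cfg)

    def test_single_population_equals_intrapopulation(self):
        panel = self._panel()
        rec_pool, fit_pool = interpopulation_ld(panel, ["A"], n_per_pop=100, seed=1)
        rows = panel.sample_indices("A")
        rec_direct = pairwise_r2(panel, rows)
        assert np.allclose(rec_pool.r2.to_numpy(), rec_direct.r2.to_numpy())
        assert fit_pool.beta_per_kb == pytest.approx(fit_sved(rec_direct).beta_per_kb)

    def test_seeded_subsample_deterministic(self):
        panel = self._panel()
        _, f1 = interpopulation_ld(panel, ["A", "B"], n_per_pop=10, seed=42)
        _, f2 = interpopulation_ld(panel, ["A", "B"], n_per_pop=10, seed=42)
        assert f1.beta_per_kb == f2.beta_per_kb

    def test_pooled_ld_shorter_than_intrapopulation(self):
        """Pooling diverged populations breaks shared haplotype phase, so the
        pooled LD extent is below the within-population extents."""
        panel = self._panel(seed=3)
        _, _, fit_a = population_ld_fit(panel, "A")
        _, _, fit_b = population_ld_fit(panel, "B")
        _, fit_pool = interpopulation_ld(panel, ["A", "B"], n_per_pop=20, seed=0)
        assert fit_pool.extent_kb < max(fit_a.extent_kb, fit_b.extent_kb)
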