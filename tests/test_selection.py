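"""Outlier-scan building blocks: count tables, BF conversion, fast MCMC checks.

The long-chain statistical properties (null calibration, planted-outlier
recovery) live in the acceptance suite; here the sampler runs tiny chains
to exercise contracts, determinism, and symmetry.
"""

import numpy as np
import pytest

from snppop import (
    MISSING,
    OutlierModelConfig,
    PanelError,
    allele_count_table,
    evidence_class,
    posterior_prob_from_bf,
    run_outlier_scan,
)
from conftest import make_panel


def tiny_config(seed=0, **kw):
    base = dict(
        n_pilot_runs=2, pilot_length=50, burn_in=200, sampling_steps=400,
        thinning=4, seed=seed,
    )
    base.update(kw)
    return OutlierModelConfig(**base)


class TestAlleleCountTable:
    def test_hand_tally_single_group(self):
        panel = make_panel([[0], [1], [2]], populations=["A", "A", "B"])
        a, n, markers, names = allele_count_table(panel, {"A": "g1", "B": "g2"})
        assert a[names.index("g1"), 0] == 1 and n[names.index("g1"), 0] == 4
        assert a[names.index("g2"), 0] == 2 and n[names.index("g2"), 0] == 2

    def test_all_missing_group_skips_snp(self):
        d = np.array([[1, MISSING], [1, MISSING], [0, 1], [2, 1]], dtype=np.int8)
        panel = make_panel(d, populations=["A", "A", "B", "B"])
        a, n, markers, _ = allele_count_table(panel, {"A": "g1", "B": "g2"})
        assert list(markers.snp_id) == ["s0"]

    def test_three_snp_two_group_tally(self):
        d = np.array(
            [[0, 1, 2], [1, 1, 0], [2, 2, 2], [2, 0, 1]], dtype=np.int8
        )
        panel = make_panel(d, populations=["A", "A", "B", "B"])
        a, n, _, names = allele_count_table(panel, {"A": "g1", "B": "g2"})
        g1, g2 = names.index("g1"), names.index("g2")
        assert list(a[g1]) == [1, 2, 2] and list(n[g1]) == [4, 4, 4]
        assert list(a[g2]) == [4, 2, 3] and list(n[g2]) == [4, 4, 4]


class TestBayesFactorConversion:
    def test_printed_correspondences(self):
        assert round(posterior_prob_from_bf(10.0), 2) == 0.91
        assert posterior_prob_from_bf(100.0) >= 0.99

    def test_indifference(self):
        assert posterior_prob_from_bf(1.0) == 0.5

    def test_monotone(self):
        bfs = [0.1, 1.0, 3.0, 10.0, 100.0, 1e6]
        pps = [posterior_prob_from_bf(b) for b in bfs]
        assert all(b > a for a, b in zip(pps, pps[1:]))

    def test_negative_bf_rejected(self):
        with pytest.raises(PanelError):
            posterior_prob_from_bf(-1.0)

    def test_evidence_classes(self):
        assert evidence_class(0.5) == "none"
        assert evidence_class(1.0) == "strong"  # BF = 10
        assert evidence_class(2.5) == "decisive"


class TestSampler:
    def _counts(self, seed=0, L=30, planted=None):
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(0.2, 0.8, L)
        sc = 9.0  # F = 0.1
        p1 = rng.beta(p0 * sc, (1 - p0) * sc)
        p2 = rng.beta(p0 * sc, (1 - p0) * sc)
        n = np.full((2, L), 40)
        a = np.stack([rng.binomial(40, p1), rng.binomial(40, p2)])
        if planted is not None:
            a[0, planted], a[1, planted] = 39, 1
        return a, n

    def test_fixed_seed_bit_identical(self):
        a, n = self._counts()
        r1 = run_outlier_scan(a, n, tiny_config(seed=3))
        r2 = run_outlier_scan(a, n, tiny_config(seed=3))
        assert np.array_equal(r1.q.to_numpy(), r2.q.to_numpy())
        assert np.array_equal(r1.alpha_mean.to_numpy(), r2.alpha_mean.to_numpy())

    def test_planted_extreme_locus_ranks_first(self):
        a, n = self._counts(seed=1, planted=15)
        res = run_outlier_scan(a, n, tiny_config(seed=1, burn_in=500, sampling_steps=1500))
        assert res.log10_bf.idxmax() == 15
        assert res.alpha_mean[15] > 0

    def test_label_swap_symmetry_within_mc_tolerance(self):
        a, n = self._counts(seed=2, planted=10)
        flipped = a.copy()
        flipped[:, 10] = n[:, 10] - a[:, 10]
        r1 = run_outlier_scan(a, n, tiny_config(seed=5, sampling_steps=1500))
        r2 = run_outlier_scan(flipped, n, tiny_config(seed=5, sampling_steps=1500))
        assert r1.q[10] == pytest.approx(r2.q[10], abs=0.15)

    def test_invalid_counts_rejected(self):
        with pytest.raises(PanelError):
            run_outlier_scan(np.array([[5]]), np.array([[4]]), tiny_config())
        with pytest.raises(PanelError):
            run_outlier_scan(np.array([[1]]), np.array([[4]]), tiny_config())
        with pytest.raises(PanelError):
            run_outlier_scan(
                np.array([[1], [1]]), np.array([[4], [0]]), tiny_config()
            )

    def test_bayes_factor_matches_inclusion_odds(self):
        a, n = self._counts(seed=4)
        res = run_outlier_scan(a, n, tiny_config(seed=7))
        kept = 400 // 4
        q_c = np.clip(res.q, 1 / (2 * kept), 1 - 1 / (2 * kept))
        assert np.allclose(res.bayes_factor, q_c / (1 - q_c))
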