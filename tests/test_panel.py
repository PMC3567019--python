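"""Panel container, allele frequencies, and the chip QC filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snppop import (
    MISSING,
    FilterConfig,
    GenotypePanel,
    PanelError,
    allele_frequency,
    filter_snps,
    maf_subset,
)
from conftest import make_panel


class TestAlleleFrequency:
    def test_symmetric_genotypes_give_half(self):
        panel = make_panel([[0], [1], [2]])
        p, n = allele_frequency(panel, 0)
        assert p == 0.5 and n == 3

    def test_fixed_alt(self):
        panel = make_panel([[2], [2]])
        assert allele_frequency(panel, 0)[0] == 1.0

    def test_missing_excluded_from_denominator(self):
        panel = make_panel([[0], [1], [MISSING], [2], [1]])
        p, n = allele_frequency(panel, 0)
        assert p == 4 / 8 and n == 4

    def test_all_missing_raises_not_zero(self):
        panel = make_panel([[MISSING], [MISSING]])
        with pytest.raises(PanelError, match="missing"):
            allele_frequency(panel, 0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 2), min_size=2, max_size=12))
    def test_complement_allele_frequency(self, genos):
        panel = make_panel(np.array(genos)[:, None])
        flipped = make_panel(2 - np.array(genos)[:, None])
        p, _ = allele_frequency(panel, 0)
        q, _ = allele_frequency(flipped, 0)
        assert p + q == pytest.approx(1.0)


class TestFilterSnps:
    def test_call_rate_threshold(self):
        col = [1] * 8 + [MISSING] * 2  # 0.8 < 0.9
        panel = make_panel(np.array(col)[:, None])
        filtered, report = filter_snps(panel)
        assert filtered.n_snps == 0
        assert report.reason.iloc[0] == "call_rate"

    def test_maf_boundary_inclusive(self):
        col = [1] + [0] * 9  # maf exactly 0.05 over 20 copies
        panel = make_panel(np.array(col)[:, None])
        filtered, _ = filter_snps(panel)
        assert filtered.n_snps == 1

    def test_hand_built_panel_keeps_exactly_three(self):
        # 5 SNPs: ok / low maf / low call rate / ok / monomorphic
        d = np.array(
            [
                [1, 0, 1, 2, 0],
                [1, 0, MISSING, 1, 0],
                [0, 0, MISSING, 0, 0],
                [2, 0, 1, 1, 0],
                [1, 1, 1, 2, 0],
                [0, 0, 1, 0, 0],
                [1, 0, 1, 1, 0],
                [2, 0, 1, 2, 0],
                [0, 0, 1, 0, 0],
                [1, 0, 1, 1, 0],
            ],
            dtype=np.int8,
        )
        filtered, report = filter_snps(make_panel(d))
        assert list(report.kept) == [True, True, False, True, False]
        assert filtered.n_snps == 3

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        d[rng.uniform(size=d.shape) < 0.1] = MISSING
        once, _ = filter_snps(make_panel(d))
        twice, rep = filter_snps(once)
        assert twice.n_snps == once.n_snps
        assert rep.kept.all()


class TestMafSubset:
    def test_identity_when_all_pass(self):
        panel = make_panel([[1, 1], [0, 1], [1, 0], [2, 1]])
        out = maf_subset(panel, {"all": ["POP"]}, min_maf=0.2)
        assert out.n_snps == panel.n_snps

    def test_must_pass_in_every_group(self):
        # SNP0: maf 0.3 in A, 0.1 in B -> dropped; SNP1 passes both
        a = [[1, 1], [1, 1], [0, 1], [1, 0], [0, 1]]  # A: p0=3/10
        b = [[0, 1], [0, 1], [1, 1], [0, 0], [0, 1]]  # B: p0=1/10
        panel = make_panel(a + b, populations=["A"] * 5 + ["B"] * 5)
        out = maf_subset(panel, {"ga": ["A"], "gb": ["B"]}, min_maf=0.2)
        assert list(out.markers.snp_id) == ["s1"]

    def test_matches_brute_force_per_group_maf(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(20, 40)).astype(np.int8)
        pops = ["A"] * 10 + ["B"] * 10
        panel = make_panel(d, populations=pops)
        out = maf_subset(panel, {"ga": ["A"], "gb": ["B"]}, min_maf=0.2)
        expect = []
        for j in range(40):
            ok = True
            for rows in (range(10), range(10, 20)):
                p = np.mean([d[i, j] for i in rows]) / 2
                if min(p, 1 - p) < 0.2:
                    ok = False
            expect.append(ok)
        assert list(out.markers.snp_id) == [f"s{j}" for j in range(40) if expect[j]]

    def test_unknown_population_errors(self):
        panel = make_panel([[1], [0]])
        with pytest.raises(PanelError, match="unknown"):
            maf_subset(panel, {"g": ["NOPE"]})


class TestPanelInvariants:
    def test_shape_mismatch_rejected(self):
        panel = make_panel([[1], [0]])
        with pytest.raises(PanelError):
            GenotypePanel(panel.markers, panel.samples, panel.populations,
                          np.zeros((3, 1), dtype=np.int8))

    def test_autosomal_drops_sex_chromosomes(self):
        import pandas as pd
        markers = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "chromosome": ["1", "X"],
                "position_bp": [100, 100],
                "allele1": "A",
                "allele2": "B",
            }
        )
        panel = GenotypePanel(markers, ["s"], {"s": "P"},
                              np.zeros((1, 2), dtype=np.int8))
        assert list(panel.autosomal().markers.snp_id) == ["a"]
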