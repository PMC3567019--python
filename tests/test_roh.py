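"""Runs-of-homozygosity caller: window allowances, minimum length, summaries."""

import numpy as np
import pytest

from snppop import (
    MISSING,
    PanelError,
    PlantedRoh,
    PopulationSpec,
    RohConfig,
    SimulationConfig,
    detect_roh,
    detect_roh_all,
    roh_summary,
    simulate_genotypes,
)
from snppop.simulate import roh_sweep_panel
from conftest import make_panel


def het_background_panel(n_snps=1200, spacing=10_000, hom_run=None):
    """Alternating het/hom background; optional fully homozygous run
    given as (start_index, n_run_snps)."""
    d = np.where(np.arange(n_snps) % 2 == 0, 1, 2).astype(np.int8)
    if hom_run is not None:
        s, k = hom_run
        d[s : s + k] = 0
    positions = spacing * (1 + np.arange(n_snps))
    return make_panel(d[None, :], positions=positions)


class TestDetectRoh:
    def test_fully_heterozygous_chromosome_no_segments(self):
        panel = make_panel(
            np.ones((1, 800), dtype=np.int8),
            positions=10_000 * (1 + np.arange(800)),
        )
        assert detect_roh(panel, 0) == []

    def test_planted_two_mb_run_recovered(self):
        # 200 homozygous SNPs at 10 kb spacing ~ 2 Mb
        panel = het_background_panel(hom_run=(500, 201))
        segs = detect_roh(panel, 0)
        assert len(segs) == 1
        seg = segs[0]
        plant_start, plant_end = 10_000 * 501, 10_000 * 701
        overlap = min(seg.end_bp, plant_end) - max(seg.start_bp, plant_start)
        assert overlap >= 0.9 * (plant_end - plant_start)

    def test_short_run_below_minimum_not_called(self):
        # 400 kb homozygous run < 500 kb minimum
        panel = het_background_panel(hom_run=(500, 41))
        assert detect_roh(panel, 0) == []

    def test_single_het_inside_run_does_not_break_call(self):
        panel = het_background_panel(hom_run=(500, 201))
        d = panel.dosages.copy()
        d[0, 600] = 1  # one heterozygote mid-run: within the window allowance
        broken = make_panel(d, positions=panel.markers.position_bp.to_numpy())
        segs = detect_roh(broken, 0)
        assert len(segs) == 1
        assert segs[0].n_het == 1
        assert segs[0].length_bp >= 1_900_000

    def test_missing_calls_within_allowance_tolerated(self):
        panel = het_background_panel(hom_run=(500, 201))
        d = panel.dosages.copy()
        d[0, [560, 600, 640]] = MISSING
        seg = detect_roh(
            make_panel(d, positions=panel.markers.position_bp.to_numpy()), 0
        )
        assert len(seg) == 1

    def test_segments_never_overlap(self):
        panel = het_background_panel(n_snps=2000, hom_run=(300, 151))
        d = panel.dosages.copy()
        d[0, 900:1101] = 0  # second run
        segs = detect_roh(
            make_panel(d, positions=panel.markers.position_bp.to_numpy()), 0
        )
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            assert a.end_bp < b.start_bp

    def test_deterministic(self):
        panel = het_background_panel(hom_run=(500, 201))
        a = detect_roh(panel, 0)
        b = detect_roh(panel, 0)
        assert a == b

    def test_unknown_sample_errors(self):
        with pytest.raises(PanelError, match="unknown sample"):
            detect_roh(het_background_panel(), "GHOST")

    def test_minimum_length_threshold_from_sweep(self):
        """Sweeping planted homozygous tract lengths: 500 kb is the
        shortest tract the caller emits under the default configuration."""
        panel, plants = roh_sweep_panel(list(range(100, 1001, 50)))
        segs = detect_roh(panel, "S1")
        emitted = [
            lk
            for start, end, lk in plants
            if any(s.start_bp <= end and s.end_bp >= start for s in segs)
        ]
        assert min(emitted) == 500
        assert 450 not in emitted


class TestSummary:
    def test_fraction_zero_without_segments(self):
        panel = het_background_panel()
        table, hist = roh_summary(detect_roh_all(panel), panel)
        assert (table.autozygosity_fraction == 0).all()
        assert hist.n_segments.sum() == 0

    def test_fraction_of_known_segment(self):
        panel = het_background_panel(n_snps=10_001, hom_run=(500, 201))
        segs = detect_roh_all(panel)
        table, _ = roh_summary(segs, panel, genome_span_bp=100_000_000)
        expected = segs.length_bp.sum() / 1e8
        assert table.autozygosity_fraction.iloc[0] == pytest.approx(expected)
        assert table.autozygosity_fraction.iloc[0] == pytest.approx(0.02, rel=0.03)

    def test_planted_population_has_higher_autozygosity(self):
        cfg = SimulationConfig(
            seed=13, n_snps=3000, snp_spacing_bp=10_000,
            populations=[PopulationSpec("LOAD", 4, 0.1), PopulationSpec("FREE", 4, 0.1)],
            planted_roh=[
                PlantedRoh("LOAD", i, "1", 4_000_000 + 3_000_000 * i, 2_000_000)
                for i in range(4)
            ],
        )
        panel = simulate_genotypes(cfg)
        table, _ = roh_summary(detect_roh_all(panel), panel)
        by_pop = table.groupby("population").autozygosity_fraction.mean()
        assert by_pop["LOAD"] > by_pop["FREE"]

    def test_zero_genome_span_errors(self):
        panel = het_background_panel()
        with pytest.raises(PanelError, match="span"):
            roh_summary(detect_roh_all(panel), panel, genome_span_bp=0)


def test_config_validation():
    with pytest.raises(PanelError):
        RohConfig(window_hit_threshold=0.0)
    with pytest.raises(PanelError):
        RohConfig(min_roh_length_bp=10_000_000)
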