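import numpy as np
import pytest

from parscan.core import LABEL_SISTER, LABEL_X, LABEL_Y, MISSING, Window, tile_windows
from parscan.synthetic_data import (
    CrossDesign,
    InvalidConfigError,
    PanelConfig,
    Stratum,
    TruthSet,
    plant_sas_window,
    simulate_crosses,
    simulate_sex_panels,
)
from parscan.windowed_popgen import depth_ratio, window_fst, window_dxy

from conftest import make_neutral_panel


def focal_polymorphic_count(panel) -> int:
    focal = panel.alleles[(panel.labels == LABEL_X) | (panel.labels == LABEL_Y)]
    c = (focal == 1).sum(axis=0)
    n = focal.shape[0]
    return int(np.sum((c > 0) & (c < n)))


class TestSimulateSexPanels:
    def test_poisson_site_count(self, par_only_config):
        # 10 SNPs per 10 kb on 1 Mb => ~1000 polymorphic sites (+/- 3*sqrt(1000))
        panel, _ = simulate_sex_panels(par_only_config, seed=42)
        n_poly = focal_polymorphic_count(panel)
        assert abs(n_poly - 1000) <= 3 * np.sqrt(1000)

    def test_par_exchangeability_mean_fst(self):
        # no planted signal: mean window F_ST over 200 PAR windows is tiny
        panel = make_neutral_panel(seed=7, n_windows=200)
        windows = tile_windows(panel.chrom, 2_000_000, 10_000)
        fsts = [f for f in (window_fst(panel, w) for w in windows) if f is not None]
        assert len(fsts) > 150
        assert np.mean(fsts) < 0.05

    def test_zero_species_divergence(self):
        cfg = PanelConfig(chrom_length_bp=500_000, sdr_boundary_bp=1,
                          species_divergence_per_10kb=0.0, n_sister=4)
        panel, _ = simulate_sex_panels(cfg, seed=3)
        sister = panel.select(LABEL_SISTER)
        # sister panel carries no divergence: monomorphic ancestral everywhere
        assert np.all(sister == 0)
        w = Window(cfg.chrom, 1, 500_001)
        assert window_dxy(sister[:2], sister[2:], w) == 0.0

    def test_sdr_architecture(self):
        cfg = PanelConfig(chrom_length_bp=2_000_000, sdr_boundary_bp=1_000_000)
        panel, truth = simulate_sex_panels(cfg, seed=5)
        sdr = Window(cfg.chrom, 1, 1_000_000)
        par = Window(cfg.chrom, 1_000_000, 2_000_001)
        # X-Y divergence inside the SDR exceeds within-class differences
        sub = panel.in_window(sdr)
        x, y = sub.select(LABEL_X), sub.select(LABEL_Y)
        assert not np.all(x[0] == y[0])  # X and Y differ somewhere
        fst_sdr = window_fst(panel, sdr)
        fst_par = window_fst(panel, par)
        assert fst_sdr > 0.3 > abs(fst_par)
        # Y clonal inside SDR
        assert np.all(y == y[0])
        assert truth.sdr_boundary_bp == 1_000_000

    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            PanelConfig(chrom_length_bp=0)
        with pytest.raises(InvalidConfigError):
            PanelConfig(snp_per_10kb=-1.0)
        with pytest.raises(InvalidConfigError):
            PanelConfig(chrom_length_bp=100, sdr_boundary_bp=200)

    def test_seed_reproducibility(self, par_only_config):
        p1, _ = simulate_sex_panels(par_only_config, seed=9)
        p2, _ = simulate_sex_panels(par_only_config, seed=9)
        assert np.array_equal(p1.alleles, p2.alleles)
        assert np.array_equal(p1.positions, p2.positions)


class TestPlantSasWindow:
    def test_delta_one_fixed_difference(self):
        panel = make_neutral_panel(seed=11, n_windows=20)
        w = Window(panel.chrom, 100_001, 110_001)
        out = plant_sas_window(panel, w, 1.0, sdr_boundary_bp=1)
        sub = out.in_window(w)
        x, y = sub.select(LABEL_X), sub.select(LABEL_Y)
        # at the planted site: fixed difference => site F_ST = 1
        fx = (x == 1).mean(axis=0)
        fy = (y == 1).mean(axis=0)
        assert np.any((fx == 1.0) & (fy == 0.0))
        assert window_fst(out, w) > window_fst(panel, w)

    def test_delta_zero_unchanged(self):
        panel = make_neutral_panel(seed=12, n_windows=20)
        w = Window(panel.chrom, 50_001, 60_001)
        out = plant_sas_window(panel, w, 0.0, sdr_boundary_bp=1)
        assert np.array_equal(out.alleles, panel.alleles)

    def test_other_windows_untouched(self):
        panel = make_neutral_panel(seed=13, n_windows=20)
        w = Window(panel.chrom, 100_001, 110_001)
        out = plant_sas_window(panel, w, 0.7, sdr_boundary_bp=1)
        outside = np.ones(panel.n_sites, dtype=bool)
        sl = panel.site_slice(w)
        outside[sl] = False
        assert np.array_equal(out.alleles[:, outside], panel.alleles[:, outside])

    def test_delta_08_exceeds_99th_percentile(self):
        panel = make_neutral_panel(seed=14, n_windows=200)
        windows = tile_windows(panel.chrom, 2_000_000, 10_000)
        w = windows[100]
        out = plant_sas_window(panel, w, 0.8, sdr_boundary_bp=1)
        others = [
            f for f in (window_fst(out, v) for v in windows if v.start_bp != w.start_bp)
            if f is not None
        ]
        assert window_fst(out, w) > np.quantile(others, 0.99)

    def test_refuses_sdr_window(self):
        panel = make_neutral_panel(seed=15, n_windows=20)
        with pytest.raises(ValueError, match="SDR"):
            plant_sas_window(panel, Window(panel.chrom, 1, 10_001), 0.5,
                             sdr_boundary_bp=50_000)

    def test_monotonic_in_delta(self):
        # averaged over 50 seeds, window F_ST is non-decreasing in delta
        deltas = [0.0, 0.4, 0.8, 1.0]
        means = []
        for delta in deltas:
            vals = []
            for seed in range(50):
                panel = make_neutral_panel(seed=1000 + seed, n_windows=5)
                w = Window(panel.chrom, 20_001, 30_001)
                out = plant_sas_window(panel, w, delta, sdr_boundary_bp=1,
                                       seed=seed)
                f = window_fst(out, w)
                if f is not None:
                    vals.append(f)
            means.append(np.mean(vals))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestCrossDesign:
    def test_default_yields_58_individuals(self):
        design = CrossDesign()
        assert design.n_individuals == 58
        assert len(design.sample_names) == 58
        # one mother reused three times
        mothers = design.cross_mothers()
        assert len(mothers) == 15
        assert mothers.count("M01") == 3

    def test_pedigree_shape(self):
        trios = CrossDesign().pedigree()
        assert len(trios) == 30
        assert sum(t.sex == "M" for t in trios) == 15

    def test_invalid_designs(self):
        with pytest.raises(InvalidConfigError):
            CrossDesign(n_crosses=0)
        with pytest.raises(InvalidConfigError):
            CrossDesign(n_crosses=5, n_mothers=8)
        with pytest.raises(InvalidConfigError):
            CrossDesign(mother_reuse={"M01": 7})  # sums to wrong total


class TestSimulateCrosses:
    def test_vcf_has_58_columns(self, default_design):
        cfg = PanelConfig(chrom_length_bp=300_000, sdr_boundary_bp=1)
        panel, truth = simulate_sex_panels(cfg, seed=21)
        table, _ = simulate_crosses(panel, default_design, seed=22, truth=truth)
        assert len(table.samples) == 58

    def test_too_many_crosses_rejected(self):
        cfg = PanelConfig(chrom_length_bp=100_000, sdr_boundary_bp=1, n_x=5, n_y=5,
                          n_sister=4)
        panel, _ = simulate_sex_panels(cfg, seed=23)
        with pytest.raises(InvalidConfigError):
            simulate_crosses(panel, CrossDesign(), seed=24)

    def test_depth_ratio_mixture_expectation(self):
        # y_depth_factor 0.5 in a small stratum => son/daughter ratio ~ 0.75
        cfg = PanelConfig(
            chrom_length_bp=20_000_000,
            sdr_boundary_bp=1_000_000,
            snp_per_10kb=2.0,
            species_divergence_per_10kb=2.0,
            strata=[Stratum(1, 1_000_000, y_depth_factor=0.5,
                            xy_divergence_scale=2.0)],
        )
        panel, truth = simulate_sex_panels(cfg, seed=25)
        design = CrossDesign(mean_depth=30.0)
        table, truth = simulate_crosses(panel, design, seed=26, truth=truth)
        stratum_win = Window(cfg.chrom, 1, 1_000_000)
        r = depth_ratio(table, design.son_names, design.daughter_names, stratum_win)
        assert r == pytest.approx(0.75, abs=0.04)
        par_win = Window(cfg.chrom, 10_000_000, 20_000_001)
        r_par = depth_ratio(table, design.son_names, design.daughter_names, par_win)
        assert r_par == pytest.approx(1.0, abs=0.04)

    def test_phase_truth_recorded_before_noise(self):
        cfg = PanelConfig(chrom_length_bp=200_000, sdr_boundary_bp=1)
        panel, truth = simulate_sex_panels(cfg, seed=27)
        noisy = CrossDesign(genotyping_error=0.05, missing_rate=0.1)
        table, truth = simulate_crosses(panel, noisy, seed=28, truth=truth)
        # truth holds clean haplotypes even though genotypes carry noise
        for child, hap in truth.phase_truth.items():
            assert hap.shape == (panel.n_sites,)
            assert set(np.unique(hap)) <= {0, 1}
        assert np.any(table.gt == MISSING)

    def test_truthset_invariants(self):
        with pytest.raises(InvalidConfigError):
            TruthSet(sdr_boundary_bp=1_000_000,
                     planted_sas=[(Window("c", 500_000, 510_000), 0.5)])
        with pytest.raises(InvalidConfigError):
            TruthSet(sdr_boundary_bp=0,
                     planted_sas=[(Window("c", 500_000, 510_000), 1.5)])
        with pytest.raises(InvalidConfigError):
            Stratum(1, 100, y_depth_factor=0.0)
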