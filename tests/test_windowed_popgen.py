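import numpy as np
import pytest

from parscan.core import HaplotypePanel, Window, tile_windows
from parscan.synthetic_data import PanelConfig, simulate_sex_panels
from parscan.windowed_popgen import (
    DnDsRecord,
    depth_ratio,
    detect_boundary,
    dnds,
    gene_tree_consistency,
    site_fst,
    stats_frame,
    tajimas_d,
    tree_frame,
    window_dxy,
    window_fst,
    window_pi,
)

from conftest import make_neutral_panel
from oracles import brute_pairwise_mean, brute_tajimas_d, brute_window_fst


def random_panel(seed, n_hap=30, n_sites=40):
    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    positions = np.sort(
        rng.choice(np.arange(1, 200_000), size=n_sites, replace=False)
    )
    labels = np.array(["X"] * (n_hap // 2) + ["Y"] * (n_hap - n_hap // 2))
    return HaplotypePanel("chrT", positions, alleles, labels)


WIN = Window("chrT", 1, 200_001)


class TestSiteFst:
    def test_partial_differentiation(self):
        # X = {0,0,1,1}, Y = {1,1,1,1}: Hw = 1/3, Hb = 1/2 -> 1/3
        assert site_fst(0.5, 4, 1.0, 4) == pytest.approx(1 / 3)

    def test_fixed_difference(self):
        assert site_fst(0.0, 4, 1.0, 4) == pytest.approx(1.0)

    def test_no_differentiation_clamped(self):
        assert site_fst(0.5, 4, 0.5, 4) == 0.0

    def test_monomorphic_undefined(self):
        assert site_fst(0.0, 10, 0.0, 10) is None

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            site_fst(0.5, 1, 0.5, 4)


class TestWindowFst:
    def test_three_site_aggregate(self):
        m = np.array(
            [[0] * 3, [0] * 3] + [[1] * 3] * 6, dtype=np.int8
        )
        panel = HaplotypePanel(
            "chrT", np.array([10, 20, 30]), m, np.array(["X"] * 4 + ["Y"] * 4)
        )
        assert window_fst(panel, Window("chrT", 1, 10_001)) == pytest.approx(1 / 3)

    def test_all_fixed_differences(self):
        m = np.array([[0] * 5] * 4 + [[1] * 5] * 4, dtype=np.int8)
        panel = HaplotypePanel(
            "chrT", np.arange(1, 6) * 10, m, np.array(["X"] * 4 + ["Y"] * 4)
        )
        assert window_fst(panel, Window("chrT", 1, 101)) == pytest.approx(1.0)

    def test_no_polymorphism_undefined(self):
        m = np.zeros((8, 3), dtype=np.int8)
        panel = HaplotypePanel(
            "chrT", np.array([10, 20, 30]), m, np.array(["X"] * 4 + ["Y"] * 4)
        )
        assert window_fst(panel, Window("chrT", 1, 101)) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        panel = random_panel(seed)
        got = window_fst(panel, WIN)
        want = brute_window_fst(panel.select("X"), panel.select("Y"))
        assert got == pytest.approx(want, abs=1e-12)

    def test_row_order_and_label_swap_invariance(self):
        panel = random_panel(77)
        base = window_fst(panel, WIN)
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_haplotypes)
        shuffled = HaplotypePanel(
            panel.chrom, panel.positions, panel.alleles[perm],
            panel.labels[perm], [panel.names[i] for i in perm],
        )
        assert window_fst(shuffled, WIN) == pytest.approx(base, abs=1e-12)
        flipped = HaplotypePanel(
            panel.chrom, panel.positions, (1 - panel.alleles).astype(np.int8),
            panel.labels,
        )
        assert window_fst(flipped, WIN) == pytest.approx(base, abs=1e-12)


class TestWindowPi:
    def test_monomorphic_zero(self):
        m = np.zeros((5, 4), dtype=np.int8)
        assert window_pi(m, Window("c", 1, 10_001)) == 0.0

    def test_two_haplotypes_three_differences(self):
        m = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        assert window_pi(m, Window("c", 1, 10_001)) == pytest.approx(3 / 10_000)

    def test_single_haplotype_undefined(self):
        assert window_pi(np.zeros((1, 3), dtype=np.int8), Window("c", 1, 11)) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        panel = random_panel(seed, n_hap=12)
        got = window_pi(panel.alleles, WIN)
        want = brute_pairwise_mean(panel.alleles) / WIN.size
        assert got == pytest.approx(want, abs=1e-12)


class TestWindowDxy:
    def test_identical_monomorphic_panels(self):
        a = np.zeros((3, 5), dtype=np.int8)
        assert window_dxy(a, a.copy(), Window("c", 1, 10_001)) == 0.0

    def test_single_pair_one_difference(self):
        a = np.array([[0, 0]], dtype=np.int8)
        b = np.array([[1, 0]], dtype=np.int8)
        assert window_dxy(a, b, Window("c", 1, 10_001)) == pytest.approx(1 / 10_000)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, (4, 10)).astype(np.int8)
        b = rng.integers(0, 2, (6, 10)).astype(np.int8)
        w = Window("c", 1, 5_001)
        assert window_dxy(a, b, w) == pytest.approx(window_dxy(b, a, w), abs=1e-15)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            window_dxy(np.zeros((0, 3), dtype=np.int8),
                       np.zeros((2, 3), dtype=np.int8), Window("c", 1, 11))


class TestTajimasD:
    def test_three_singletons_n4(self):
        m = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8
        )
        assert tajimas_d(m) == pytest.approx(-0.7544510776527732, abs=1e-9)

    def test_no_segregating_sites(self):
        assert tajimas_d(np.zeros((6, 4), dtype=np.int8)) is None

    def test_small_n_undefined(self):
        assert tajimas_d(np.array([[0, 1], [1, 0], [0, 0]], dtype=np.int8)) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, (rng.integers(4, 20), 30)).astype(np.int8)
        want = brute_tajimas_d(m)
        got = tajimas_d(m)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want, abs=1e-9)


class TestDepthRatio:
    def _table(self, dp):
        from parscan.core import VariantTable

        n_sites, n_samp = dp.shape
        return VariantTable(
            chrom="c",
            positions=np.arange(1, n_sites + 1) * 10,
            qual=np.full(n_sites, 999.0),
            samples=[f"s{i}" for i in range(n_samp)],
            gt=np.zeros((n_sites, n_samp, 2), dtype=np.int8),
            gq=np.full((n_sites, n_samp), 99, dtype=np.int16),
            dp=dp.astype(np.int32),
        )

    def test_equal_depths(self):
        table = self._table(np.full((10, 4), 25))
        r = depth_ratio(table, ["s0", "s1"], ["s2", "s3"], Window("c", 1, 101))
        assert r == pytest.approx(1.0)

    def test_library_size_normalization(self):
        dp = np.full((10, 2), 20)
        dp[:, 1] = 40  # daughter sequenced twice as deep overall
        table = self._table(dp)
        r = depth_ratio(table, ["s0"], ["s1"], Window("c", 1, 101))
        assert r == pytest.approx(1.0)

    def test_requires_both_sexes(self):
        table = self._table(np.full((4, 2), 10))
        with pytest.raises(ValueError):
            depth_ratio(table, [], ["s0"], Window("c", 1, 41))


class TestGeneTreeConsistency:
    def test_sdr_like_pattern_is_consistent(self):
        rng = np.random.default_rng(1)
        m = np.zeros((30, 30), dtype=np.int8)
        m[15:, :8] = 1                       # Y-Y identical, X-Y divergent
        m[:15, 8:] = rng.integers(0, 2, (15, 22))
        panel = HaplotypePanel("c", np.arange(1, 31) * 100, m,
                               np.array(["X"] * 15 + ["Y"] * 15))
        consistent, newick = gene_tree_consistency(panel, Window("c", 1, 100_001))
        assert consistent is True
        assert newick.endswith(";")

    def test_random_labels_rarely_consistent(self):
        # permutation oracle: a random bipartition almost never matches
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            m = rng.integers(0, 2, (30, 25)).astype(np.int8)
            labels = np.array(["X"] * 15 + ["Y"] * 15)
            rng.shuffle(labels)
            panel = HaplotypePanel("c", np.arange(1, 26) * 100, m, labels)
            c, _ = gene_tree_consistency(panel, Window("c", 1, 100_001))
            hits += bool(c)
        assert hits / 40 < 0.05

    def test_no_variation_undefined(self):
        m = np.zeros((12, 3), dtype=np.int8)
        panel = HaplotypePanel("c", np.array([10, 20, 30]), m,
                               np.array(["X"] * 6 + ["Y"] * 6))
        c, t = gene_tree_consistency(panel, Window("c", 1, 1001))
        assert c is None and t is None

    def test_too_few_haplotypes_rejected(self):
        m = np.ones((4, 3), dtype=np.int8)
        panel = HaplotypePanel("c", np.array([10, 20, 30]), m,
                               np.array(["X"] * 2 + ["Y"] * 2))
        with pytest.raises(ValueError):
            gene_tree_consistency(panel, Window("c", 1, 1001))


class TestDetectBoundary:
    def test_simple_step(self):
        assert detect_boundary([True, True, True, False, False, False],
                               [1, 11, 21, 31, 41, 51]) == 31

    def test_constant_series_no_boundary(self):
        assert detect_boundary([False] * 6, [1, 11, 21, 31, 41, 51]) is None

    def test_recovers_synthetic_boundary(self):
        # boundary recovered within +/- 1 window in >= 90% of 50 seeds
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = PanelConfig(chrom_length_bp=2_000_000,
                              sdr_boundary_bp=1_000_001,
                              snp_per_10kb=4.0,
                              species_divergence_per_10kb=0.0,
                              n_sister=1)
            panel, truth = simulate_sex_panels(cfg, seed=seed)
            windows = tile_windows(cfg.chrom, cfg.chrom_length_bp, 100_000)
            frame = tree_frame(panel, windows)
            vals = [None if c is None else bool(c)
                    for c in frame["xy_consistent"]]
            b = detect_boundary(vals, frame["start_bp"].to_numpy())
            if b is not None and abs(b - truth.sdr_boundary_bp) <= 100_000:
                hits += 1
        assert hits / n_seeds >= 0.9


class TestDnDs:
    def test_identical_cds(self):
        r = dnds("ATGAAATTT", "ATGAAATTT")
        assert r.nd == 0 and r.sd == 0
        assert r.ratio is None

    def test_hand_counted_example(self):
        # ATG AAA TTT vs ATG AAG TTC: both changes synonymous
        r = dnds("ATGAAATTT", "ATGAAGTTC")
        assert r.nd == 0.0
        assert r.sd == 2.0
        assert r.s_sites == pytest.approx(2 / 3)
        assert r.n_sites == pytest.approx(25 / 3)

    def test_site_counts_sum_to_three_per_codon(self):
        r = dnds("ATGAAATTTGGG", "ATGAACTTAGGG")
        assert r.n_sites + r.s_sites == pytest.approx(3 * r.n_codons)

    def test_nonsynonymous_only_ratio_undefined(self):
        a = "ATGGCTGCTGCTGCT"
        b = "ATGGCTGCTGCTCCT"  # GCT->CCT: Ala->Pro, nonsynonymous
        r = dnds(a, b)
        assert r.dn > 0
        assert r.ds == 0.0
        assert r.ratio is None

    def test_length_validation(self):
        with pytest.raises(ValueError):
            dnds("ATGA", "ATGA")
        with pytest.raises(ValueError):
            dnds("ATG", "ATGATG")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            dnds("ATGTAAAAATTT", "ATGTAAAAATTT")

    def test_ambiguous_codons_skipped(self):
        r = dnds("ATGNNNTTT", "ATGAAATTC")
        assert r.n_codons == 2


class TestStatsFrame:
    def test_columns_and_invariants(self):
        panel = make_neutral_panel(seed=55, n_windows=20)
        windows = tile_windows(panel.chrom, 200_000, 10_000)
        frame = stats_frame(panel, windows)
        assert {"n_snps", "fst", "pi_x", "pi_y", "pi_all", "k_xy",
                "k_species", "tajima_d"} <= set(frame.columns)
        assert len(frame) == 20
        ok = frame.dropna(subset=["pi_x", "pi_y", "pi_all", "k_xy"])
        assert (ok["k_xy"] >= 0).all()
        # combined pi is a convex mix of pi_x, pi_y and k_xy
        lower = np.minimum(np.minimum(ok["pi_x"], ok["pi_y"]), ok["k_xy"])
        assert (ok["pi_all"] >= lower - 1e-12).all()

    def test_neutral_panmictic_calibration(self):
        # single exchangeable population: D near 0, F_ST near 0 on average
        panel = make_neutral_panel(seed=56, n_windows=1000, snp_per_10kb=10.0)
        windows = tile_windows(panel.chrom, 10_000_000, 10_000)
        frame = stats_frame(panel, windows)
        d = frame["tajima_d"].dropna()
        f = frame["fst"].dropna()
        assert len(d) > 800
        assert -0.3 < d.mean() < 0.3
        assert f.mean() < 0.05
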