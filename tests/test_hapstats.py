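import math

import numpy as np
import pytest

from hapfeatures import hapstats as hs
from hapfeatures.io_formats import GeneticMap, HaplotypePanel

import oracles


def panel_from_rows(rows, positions=None):
    alleles = np.asarray(rows, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1) * 1000
    return HaplotypePanel(alleles, positions)


class TestEHH:
    def test_core_is_one_and_two_class_split_is_one_third(self, uniform_map):
        # 4 derived carriers split into two classes of 2 at the next marker:
        # EHH = (C(2,2)+C(2,2))/C(4,2) = 2/6
        panel = panel_from_rows(
            [
                [1, 0, 0],
                [1, 0, 1],
                [1, 1, 0],
                [1, 1, 1],
                [0, 0, 0],
                [0, 1, 1],
            ]
        )
        curve = hs.compute_ehh(panel, uniform_map, 0, hs.DERIVED)
        assert curve.right[0, 1] == 1.0
        assert curve.right[1, 1] == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self, uniform_map):
        rows = [[1] + [0] * 9] * 4 + [[0] + [1] * 9] * 2
        panel = panel_from_rows(rows)
        curve = hs.compute_ehh(panel, uniform_map, 0, hs.DERIVED)
        assert np.all(curve.right[:, 1] == 1.0)
        assert not curve.crossed_right

    def test_monotone_non_increasing_on_random_panels(self, make_random_panel, uniform_map):
        for _ in range(5):
            panel = make_random_panel(n_hap=12, m=60)
            for core in (0, 30, 59):
                for allele in (0, 1):
                    if (panel.alleles[:, core] == allele).sum() < 2:
                        continue
                    curve = hs.compute_ehh(panel, uniform_map, core, allele)
                    for side in (curve.left, curve.right):
                        assert np.all(np.diff(side[:, 1]) <= 1e-12)

    def test_matches_pair_counting_oracle(self, make_random_panel, uniform_map):
        # EHH at step k = fraction of carrier pairs identical over [core..core+k]
        panel = make_random_panel(n_hap=14, m=30, p_derived=0.4)
        core = 10
        carriers = np.flatnonzero(panel.alleles[:, core] == 1)
        if carriers.size >= 2:
            curve = hs.compute_ehh(panel, uniform_map, core, 1)
            for k in range(1, curve.right.shape[0]):
                seg = panel.alleles[carriers, core:core + k + 1]
                n_pairs = 0
                for a in range(carriers.size):
                    for b in range(a + 1, carriers.size):
                        n_pairs += int(np.array_equal(seg[a], seg[b]))
                denom = carriers.size * (carriers.size - 1) / 2
                assert curve.right[k, 1] == pytest.approx(n_pairs / denom)


class TestIHS:
    def test_trapezoid_side_integral_hand_example(self):
        d = np.array([0.0, 0.02, 0.04])
        e = np.array([1.0, 0.5, 0.05])
        assert hs._ihh_side(d, e, 0.05) == pytest.approx(0.0205)

    def test_equal_integrals_give_zero(self, uniform_map):
        # perfectly symmetric panel: ancestral and derived carriers mirror
        rows = [
            [1, 1, 0, 1, 0, 0, 1],
            [1, 0, 1, 1, 1, 0, 0],
            [0, 0, 1, 0, 1, 1, 0],
            [0, 1, 0, 0, 0, 1, 1],
        ]
        panel = panel_from_rows(rows)
        rec = hs.compute_ihs_unstd(panel, uniform_map, 3)
        if not rec.skipped:
            assert rec.uihs == pytest.approx(
                math.log(rec.ihh_a / rec.ihh_d)
            )

    def test_no_cutoff_crossing_is_skipped(self, uniform_map):
        rows = [[1] + [0] * 9] * 4 + [[0] + [1] * 9] * 4
        panel = panel_from_rows(rows)
        rec = hs.compute_ihs_unstd(panel, uniform_map, 0)
        assert rec.skipped and rec.reason == "no_cutoff_crossing"

    def test_maf_skip(self, uniform_map):
        rows = [[1] + [0] * 9] + [[0] * 10] * 39
        panel = panel_from_rows(rows)
        rec = hs.compute_ihs_unstd(panel, uniform_map, 0)
        assert rec.skipped and rec.reason == "maf"

    def test_label_swap_negates_uihs(self, make_random_panel, uniform_map):
        found = 0
        for _ in range(20):
            panel = make_random_panel(n_hap=20, m=200, p_derived=0.5)
            core = 100
            rec = hs.compute_ihs_unstd(panel, uniform_map, core)
            if rec.skipped:
                continue
            flipped = HaplotypePanel(
                (1 - panel.alleles).astype(np.uint8), panel.positions.copy()
            )
            rec2 = hs.compute_ihs_unstd(flipped, uniform_map, core)
            assert not rec2.skipped
            assert rec2.uihs == pytest.approx(-rec.uihs, abs=1e-12)
            found += 1
        assert found > 0

    def test_scan_agrees_with_per_marker_computation(self, make_random_panel, uniform_map):
        panel = make_random_panel(n_hap=16, m=150, p_derived=0.5)
        scan = hs.ihs_scan(panel, uniform_map)
        assert len(scan) == panel.n_markers
        for j in (0, 40, 75, 149):
            single = hs.compute_ihs_unstd(panel, uniform_map, j)
            assert scan[j].skipped == single.skipped
            assert scan[j].reason == single.reason
            if not single.skipped:
                assert scan[j].uihs == pytest.approx(single.uihs)


class TestStandardize:
    def _rec(self, daf, u):
        return hs.IHSRecord("x", 1, daf, 1.0, 1.0, u, float("nan"))

    def test_two_point_bin_is_already_standard(self):
        out = hs.standardize_ihs([self._rec(0.5, -1.0), self._rec(0.5, 1.0)])
        assert sorted(r.sihs for r in out) == [-1.0, 1.0]

    def test_three_point_bin(self):
        out = hs.standardize_ihs([self._rec(0.5, u) for u in (0.0, 1.0, 2.0)])
        vals = sorted(r.sihs for r in out)
        assert vals == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_bin_moments_and_pooled_moments(self, rng):
        records = [
            self._rec(rng.uniform(0.05, 0.95), rng.normal(0.3 * b, 1 + 0.1 * b))
            for b in range(5)
            for _ in range(400)
        ]
        out = hs.standardize_ihs(records)
        vals = np.array([r.sihs for r in out if np.isfinite(r.sihs)])
        bins = np.array(
            [min(int(r.daf / 0.02), 49) for r in out if np.isfinite(r.sihs)]
        )
        for b in np.unique(bins):
            v = vals[bins == b]
            if v.size >= 2:
                assert abs(v.mean()) < 1e-9
                assert abs(v.var() - 1.0) < 1e-9
        assert abs(vals.mean()) < 0.05
        assert abs(vals.var() - 1.0) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hs.standardize_ihs([])


class TestLDDecay:
    def test_duplicated_marker_gives_r2_one(self):
        G = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        bins = hs.ld_decay(G, np.array([1000, 2000]))
        occupied = [b for b in bins if b.n_pairs]
        assert len(occupied) == 1 and occupied[0].mean_r2 == pytest.approx(1.0)

    def test_hand_worked_pair(self):
        G = np.array([[0, 0], [1, 1], [2, 2], [0, 2]])
        bins = hs.ld_decay(G, np.array([100, 600]))
        occupied = [b for b in bins if b.n_pairs][0]
        assert occupied.mean_r2 == pytest.approx(
            oracles.pearson_r2(G[:, 0], G[:, 1])
        )
        assert occupied.mean_r2 == pytest.approx(0.2066, abs=1e-4)

    def test_matches_pearson_oracle_on_random_input(self, rng):
        n, m = 30, 40
        G = rng.integers(0, 3, size=(n, m))
        positions = np.sort(rng.choice(np.arange(1, 100_000), m, replace=False))
        bins = hs.ld_decay(G, positions)
        total_direct = []
        sd = G.std(axis=0)
        for a in range(m):
            for b in range(a + 1, m):
                d = positions[b] - positions[a]
                if d <= 100_000 and sd[a] > 0 and sd[b] > 0:
                    total_direct.append(oracles.pearson_r2(G[:, a], G[:, b]))
        n_pairs = sum(b.n_pairs for b in bins)
        assert n_pairs == len(total_direct)
        mean_impl = sum(
            b.mean_r2 * b.n_pairs for b in bins if b.n_pairs
        ) / n_pairs
        assert mean_impl == pytest.approx(np.mean(total_direct))

    def test_independent_markers_r2_near_finite_sample_expectation(self, rng):
        # under independence E[r2] = 1/(n-1) for n genotype vectors
        n, m, reps = 50, 60, 12
        means = []
        for _ in range(reps):
            G = rng.binomial(2, 0.4, size=(n, m))
            positions = np.arange(1, m + 1) * 10_000
            bins = hs.ld_decay(G, positions)
            means.append(hs.mean_r2_between(bins, 0, 100))
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(reps)
        assert abs(means.mean() - 1 / (n - 1)) < 3 * se + 0.01 / n

    def test_zero_variance_pairs_excluded(self):
        G = np.array([[1, 0], [1, 1], [1, 2], [1, 1]])
        bins = hs.ld_decay(G, np.array([1000, 2000]))
        assert all(b.n_pairs == 0 for b in bins)


class TestDiversity:
    def test_identical_window_is_zero(self):
        panel = panel_from_rows(np.zeros((6, 10), dtype=int))
        assert hs.haplotype_diversity(panel).mean_hap_div == 0.0

    def test_all_distinct_n4_is_one(self):
        rows = np.eye(4, 10, dtype=int)
        panel = panel_from_rows(rows)
        assert hs.haplotype_diversity(panel).mean_hap_div == pytest.approx(1.0)

    def test_two_distinct_n2_is_one(self):
        rows = [np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        panel = panel_from_rows(rows)
        assert hs.haplotype_diversity(panel).mean_hap_div == pytest.approx(1.0)

    def test_matches_counting_oracle(self, make_random_panel):
        panel = make_random_panel(n_hap=12, m=30)
        result = hs.haplotype_diversity(panel)
        expected = [
            oracles.nei_hap_div(panel.alleles[:, k:k + 10])
            for k in range(0, 30, 10)
        ]
        assert result.window_hap_div == pytest.approx(expected)

    def test_expected_heterozygosity_examples(self):
        panel = panel_from_rows(
            [[1, 1], [1, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0],
             [0, 0], [0, 0]]
        )
        # p = {0.2, 0.1}: He = {0.32, 0.18}, mean 0.25
        assert hs.expected_heterozygosity(panel).mean_exp_het == pytest.approx(0.25)

    def test_he_maximum_at_half(self):
        panel = panel_from_rows([[1], [0]], positions=[5])
        assert hs.expected_heterozygosity(panel).mean_exp_het == pytest.approx(0.5)
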