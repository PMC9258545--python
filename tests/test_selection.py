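import math

import numpy as np
import pytest

from hapfeatures import selection as sel
from hapfeatures.hapstats import IHSRecord
from hapfeatures.io_formats import GeneticMap, HaplotypePanel


def rec(marker, sihs, daf=0.5):
    return IHSRecord(marker, 1, daf, 1.0, 1.0, 0.0, sihs)


class TestDeriveCutoffs:
    def test_full_pool_draw_gives_exact_extremes(self, rng):
        pool = rng.normal(size=500)
        pair = sel.derive_cutoffs(pool, n_tests=500, seed=1)
        assert pair.lo == pool.min() and pair.hi == pool.max()

    def test_exhaustive_small_pool(self):
        pool = [-3.0, -2.0, -1.0, 0.5, 1.0, 2.0, 3.0]
        pair = sel.derive_cutoffs(pool, n_tests=7, seed=0)
        assert (pair.lo, pair.hi) == (-3.0, 3.0)

    def test_single_test_draw_means_converge_to_pool_mean(self, rng):
        pool = np.concatenate([rng.normal(-2, 1, 300), rng.normal(2, 1, 300)])
        B = 4000
        pair = sel.derive_cutoffs(pool, n_tests=1, B=B, seed=3)
        se = pool.std() / math.sqrt(B)
        assert abs(pair.lo - pool.mean()) < 3 * se
        assert abs(pair.hi - pool.mean()) < 3 * se

    def test_monotone_in_n_tests(self, rng):
        pool = rng.standard_t(df=5, size=2000)
        pairs = [
            sel.derive_cutoffs(pool, n, B=400, seed=7)
            for n in (10, 50, 200, 1000, 2000)
        ]
        his = [p.hi for p in pairs]
        los = [p.lo for p in pairs]
        assert all(b >= a - 1e-9 for a, b in zip(his, his[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(los, los[1:]))

    def test_deterministic_given_seed(self, rng):
        pool = rng.normal(size=400)
        a = sel.derive_cutoffs(pool, 100, seed=5)
        b = sel.derive_cutoffs(pool, 100, seed=5)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_n_tests_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            sel.derive_cutoffs([-1.0, 1.0], 3)

    def test_tail_quantile_alternative(self, rng):
        pool = rng.normal(size=1000)
        pair = sel.derive_cutoffs(pool, 100, method="tail_quantile")
        assert pair.lo == pytest.approx(np.quantile(pool, 0.01))
        assert pair.hi == pytest.approx(np.quantile(pool, 0.99))


class TestFilterCandidates:
    def _cut(self, lo=-4.7, hi=3.8):
        return sel.CutoffPair(lo, hi, 100, 1000, 0)

    def test_inside_scores_yield_empty(self):
        records = [rec("a", 1.0), rec("b", -2.0)]
        assert sel.filter_candidates(records, self._cut(), "P") == []

    def test_boundary_is_strict(self):
        records = [rec("a", 3.8), rec("b", -4.7)]
        assert sel.filter_candidates(records, self._cut(), "P") == []

    def test_worked_pair_retained(self):
        records = [rec("a", -5.0), rec("b", 3.9)]
        got = sel.filter_candidates(records, self._cut(), "P")
        assert [c.marker_id for c in got] == ["a", "b"]

    def test_skipped_and_undefined_records_ignored(self):
        r = rec("a", 10.0)
        r.skipped = True
        out = sel.filter_candidates([r, rec("b", float("nan"))], self._cut(), "P")
        assert out == []

    def test_count_non_increasing_as_cutoffs_widen(self, rng):
        records = [rec(f"m{i}", s) for i, s in enumerate(rng.normal(0, 2, 500))]
        narrow = sel.filter_candidates(records, self._cut(-2.0, 2.0), "P")
        wide = sel.filter_candidates(records, self._cut(-3.0, 3.0), "P")
        wider = sel.filter_candidates(records, self._cut(-5.0, 5.0), "P")
        assert len(narrow) >= len(wide) >= len(wider)


class TestTallyShared:
    def _cand(self, marker, pop):
        return sel.SelectionCandidate(marker, pop, 5.0, -4.0, 4.0)

    def test_overlap_counting(self):
        unique, shared, total = sel.tally_shared(
            {
                "P1": [self._cand("A", "P1"), self._cand("B", "P1")],
                "P2": [self._cand("B", "P2"), self._cand("C", "P2")],
            }
        )
        assert (unique, shared, total) == (3, 1, 4)

    def test_disjoint_lists(self):
        unique, shared, total = sel.tally_shared(
            {"P1": [self._cand("A", "P1")], "P2": [self._cand("B", "P2")]}
        )
        assert (unique, shared, total) == (2, 0, 2)

    def test_empty_list_does_not_change_union(self):
        unique, shared, total = sel.tally_shared(
            {"P1": [self._cand("A", "P1")], "P2": []}
        )
        assert (unique, shared, total) == (1, 0, 1)


class TestTMRCAClosedForm:
    def test_worked_example(self):
        t_gen, years = sel.tmrca_from_r(0.0055)
        assert t_gen == pytest.approx(math.log(4) / 0.011)
        assert t_gen == pytest.approx(126.03, abs=0.01)
        assert years == pytest.approx(3781, abs=1.0)

    def test_halving_r_doubles_t(self):
        t1, _ = sel.tmrca_from_r(0.004)
        t2, _ = sel.tmrca_from_r(0.002)
        assert t2 == pytest.approx(2 * t1)

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError):
            sel.tmrca_from_r(0.0)


def decayed_panel(rng, tau, n_carriers=60, n_other=40, m=4001,
                  length_bp=20_000_000):
    """Panel where carriers share a founder haplotype of age ``tau`` generations.

    Each carrier keeps the founder chromosome out to an Exp(tau)-distributed
    genetic distance on each side of the core (first crossover among tau
    meioses) and random background beyond, so the carrier EHH decays as
    exp(-2 tau d): the haplotype-decay clock's generating model.
    """
    positions = np.linspace(1, length_bp, m).astype(np.int64)
    core = m // 2
    morgans = (positions - positions[core]) / 1e8  # 1 cM/Mb map
    founder = (rng.random(m) < 0.5).astype(np.uint8)
    rows = []
    for _ in range(n_carriers):
        left = -rng.exponential(1.0 / tau)
        right = rng.exponential(1.0 / tau)
        keep = (morgans >= left) & (morgans <= right)
        background = (rng.random(m) < 0.5).astype(np.uint8)
        hap = np.where(keep, founder, background).astype(np.uint8)
        hap[core] = 1
        rows.append(hap)
    for _ in range(n_other):
        hap = (rng.random(m) < 0.5).astype(np.uint8)
        hap[core] = 0
        rows.append(hap)
    return HaplotypePanel(np.asarray(rows, dtype=np.uint8), positions), core


class TestEstimateTMRCA:
    def _candidate(self, panel, core, sihs=5.0):
        return sel.SelectionCandidate(panel.marker_ids[core], "P", sihs, -4, 4)

    def test_recovers_planted_age_within_factor_two(self, rng):
        gmap = GeneticMap.uniform(1.0, 20_000_000)
        for tau in (100, 400, 2000):
            panel, core = decayed_panel(rng, tau)
            result = sel.estimate_tmrca(
                panel, gmap, self._candidate(panel, core), max_span_cm=np.inf
            )
            assert not (result.skipped or result.unresolved), tau
            assert tau / 2 <= result.t_generations <= tau * 2, (
                tau, result.t_generations,
            )

    def test_wide_span_is_skipped(self, rng):
        gmap = GeneticMap.uniform(1.0, 20_000_000)
        panel, core = decayed_panel(rng, tau=50)  # span ~ 2.8 cM > 1.1
        result = sel.estimate_tmrca(panel, gmap, self._candidate(panel, core))
        assert result.skipped and result.reason == "span_exceeds_limit"
        assert result.span_cm > 1.1

    def test_never_reaching_quarter_is_unresolved(self, uniform_map):
        rows = [[1] * 21] * 6 + [[0] * 21] * 4  # carriers identical throughout
        panel = HaplotypePanel(
            np.asarray(rows, dtype=np.uint8),
            np.arange(1, 22) * 100_000,
        )
        cand = sel.SelectionCandidate(panel.marker_ids[10], "P", 5.0, -4, 4)
        result = sel.estimate_tmrca(panel, uniform_map, cand)
        assert result.unresolved and not result.skipped

    def test_favored_allele_follows_sign(self, rng):
        gmap = GeneticMap.uniform(1.0, 20_000_000)
        panel, core = decayed_panel(rng, tau=400)
        # flip polarity: ancestral allele is now the decayed founder haplotype
        flipped = HaplotypePanel(
            (1 - panel.alleles).astype(np.uint8), panel.positions.copy()
        )
        a = sel.estimate_tmrca(
            panel, gmap, self._candidate(panel, core, sihs=5.0),
            max_span_cm=np.inf,
        )
        b = sel.estimate_tmrca(
            flipped, gmap, self._candidate(flipped, core, sihs=-5.0),
            max_span_cm=np.inf,
        )
        assert a.t_generations == pytest.approx(b.t_generations)
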