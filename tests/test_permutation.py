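import numpy as np
import pytest

from gecscan import (
    NullSimConfig,
    Phenotype,
    adjusted_p,
    empirical_threshold,
    minp_distribution,
    orient_and_filter,
    permuted_phenotype,
    simulate_null_study,
)
from gecscan.permutation import MinPDistribution

from conftest import panel_from_sets


class TestPermutedPhenotype:
    def test_preserves_case_count(self):
        rng = np.random.default_rng(0)
        ph = Phenotype([1] * 7 + [0] * 13)
        for _ in range(20):
            perm = permuted_phenotype(ph, rng)
            assert perm.n_case == 7 and perm.n_control == 13

    def test_seeded_determinism(self):
        ph = Phenotype([1] * 5 + [0] * 5)
        seq1 = [permuted_phenotype(ph, np.random.default_rng(4)).labels.tolist()
                for _ in range(3)]
        seq2 = [permuted_phenotype(ph, np.random.default_rng(4)).labels.tolist()
                for _ in range(3)]
        assert seq1 == seq2

    def test_uniform_over_arrangements(self):
        """With labels [1,1,0,0] every one of the 6 distinct arrangements
        appears with frequency ~1/6."""
        rng = np.random.default_rng(42)
        ph = Phenotype([1, 1, 0, 0])
        counts = {}
        n_draws = 6000
        for _ in range(n_draws):
            key = tuple(permuted_phenotype(ph, rng).labels.tolist())
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        for c in counts.values():
            assert abs(c / n_draws - 1 / 6) < 0.02


class TestMinPDistribution:
    def test_reproducible_and_shapes(self, toy_panel, toy_phenotype):
        d1 = minp_distribution([toy_panel], toy_phenotype, r=3,
                               rng=np.random.default_rng(8))
        d2 = minp_distribution([toy_panel], toy_phenotype, r=3,
                               rng=np.random.default_rng(8))
        assert d1.r == 3 and d1.minp_combined.shape == (3,)
        assert np.array_equal(d1.minp_combined, d2.minp_combined)
        assert ((d1.minp_combined > 0) & (d1.minp_combined <= 1)).all()

    def test_combined_is_min_over_thresholds(self, toy_phenotype):
        p1 = panel_from_sets([{0}, {1}, {2, 3}], 4, maf_t=0.01)
        p2 = panel_from_sets([{0}, {0, 1}], 4, maf_t=0.05)
        d = minp_distribution([p1, p2], toy_phenotype, r=25,
                              rng=np.random.default_rng(9))
        stacked = np.vstack([d.minp_by_threshold[t] for t in (0.01, 0.05)])
        assert np.array_equal(d.minp_combined, stacked.min(axis=0))

    def test_single_bin_panel(self):
        panel = panel_from_sets([{0, 1}], 4)
        ph = Phenotype([1, 1, 0, 0])
        d = minp_distribution([panel], ph, r=10, rng=np.random.default_rng(2))
        assert d.minp_combined.shape == (10,)

    def test_invalid_r(self, toy_panel, toy_phenotype):
        with pytest.raises(ValueError):
            minp_distribution([toy_panel], toy_phenotype, r=0,
                              rng=np.random.default_rng(1))

    @pytest.mark.parametrize("seed", range(20))
    def test_fast_path_equals_naive_rescan(self, seed):
        """Enumerate-once + per-replicate recounting is bit-identical to
        re-running the whole scan for every permutation."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(8, 24))
        n_case = int(rng.integers(1, n))
        cfg = NullSimConfig(
            n_individuals=n,
            n_case=n_case,
            chrom_lengths=tuple(rng.integers(2, 15, size=2)),
            maf_max=0.5,
        )
        gt, ph = simulate_null_study(cfg, rng)
        panels = [p for t in (0.1, 0.5) for p in orient_and_filter(gt, t)]
        if all(len(p) == 0 for p in panels):
            pytest.skip("degenerate draw: no polymorphic sites")
        kw = dict(r=11, include_sma=True, genotypes=gt)
        d_fast = minp_distribution(panels, ph, rng=np.random.default_rng(seed), **kw)
        d_naive = minp_distribution(panels, ph, rng=np.random.default_rng(seed),
                                    method="naive", **kw)
        assert np.array_equal(d_fast.minp_combined, d_naive.minp_combined)
        assert np.array_equal(d_fast.minp_sma, d_naive.minp_sma)
        for t in d_fast.minp_by_threshold:
            assert np.array_equal(
                d_fast.minp_by_threshold[t], d_naive.minp_by_threshold[t]
            )


def make_dist(values, r=None):
    v = np.asarray(values, dtype=float)
    return MinPDistribution(
        r=r or v.size, minp_combined=v, minp_by_threshold={0.05: v}
    )


class TestEmpiricalThreshold:
    def test_order_statistic_k1(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(size=19)
        ts = empirical_threshold(make_dist(v), fwer=0.05)
        assert ts.alpha_combined == v.min()

    def test_order_statistic_k50(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(size=999)
        ts = empirical_threshold(make_dist(v), fwer=0.05)
        assert ts.alpha_combined == np.sort(v)[49]  # k = floor(0.05 * 1000)

    def test_r_too_small(self):
        with pytest.raises(ValueError, match="raise r"):
            empirical_threshold(make_dist([0.5] * 10), fwer=0.05)

    def test_degenerate_all_ones_warns(self):
        with pytest.warns(UserWarning, match="significant"):
            ts = empirical_threshold(make_dist([1.0] * 99), fwer=0.05)
        assert ts.alpha_combined == 1.0

    def test_coarse_r_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            empirical_threshold(make_dist([0.1] * 9), fwer=0.1)

    def test_combined_not_above_per_threshold(self, toy_phenotype):
        p1 = panel_from_sets([{0}, {1}, {2, 3}], 4, maf_t=0.01)
        p2 = panel_from_sets([{0}, {0, 1}], 4, maf_t=0.05)
        d = minp_distribution([p1, p2], toy_phenotype, r=39,
                              rng=np.random.default_rng(3))
        ts = empirical_threshold(d, fwer=0.05)
        assert ts.alpha_combined <= min(ts.alpha_by_threshold.values())


class TestAdjustedP:
    def test_below_all_replicates(self):
        d = make_dist(np.linspace(0.2, 0.9, 999))
        assert adjusted_p(1e-9, d) == pytest.approx(1 / 1000)

    def test_p_one(self):
        d = make_dist(np.linspace(0.2, 0.9, 9))
        assert adjusted_p(1.0, d) == 1.0

    def test_median_of_nine(self):
        v = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        assert adjusted_p(0.5, make_dist(v)) == pytest.approx(6 / 10)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(12)
        d = make_dist(rng.uniform(size=99))
        ps = np.linspace(0.01, 1.0, 50)
        adj = [adjusted_p(p, d) for p in ps]
        assert all(x <= y for x, y in zip(adj, adj[1:]))

    def test_consistent_with_threshold(self):
        """adjusted_p at the empirical alpha recovers ~the nominal FWER."""
        rng = np.random.default_rng(13)
        d = make_dist(rng.uniform(size=999))
        ts = empirical_threshold(d, fwer=0.05)
        assert adjusted_p(ts.alpha_combined, d) == pytest.approx(0.05, abs=0.01)
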