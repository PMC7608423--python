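import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.special import expit

from gecscan import (
    DiseaseSimConfig,
    NullSimConfig,
    estimate_power,
    simulate_disease_study,
    simulate_null_study,
    solve_beta0,
)
from gecscan.stats import ContingencyTable2x2, odds_ratio_woolf


class TestNullStudy:
    def test_seeded_determinism(self):
        cfg = NullSimConfig(n_individuals=40, n_case=20, chrom_lengths=(30,))
        gt1, ph1 = simulate_null_study(cfg, np.random.default_rng(7))
        gt2, ph2 = simulate_null_study(cfg, np.random.default_rng(7))
        assert np.array_equal(gt1.dosages, gt2.dosages)
        assert gt1.sites.equals(gt2.sites)
        assert np.array_equal(ph1.labels, ph2.labels)

    def test_uniform_spectrum_mean(self):
        cfg = NullSimConfig(
            n_individuals=100,
            n_case=50,
            chrom_lengths=(10_000,),
            maf_min=0.01,
            maf_max=0.05,
            maf_spectrum="uniform",
        )
        rng = np.random.default_rng(8)
        from gecscan.simulate import _draw_mafs

        mafs = _draw_mafs(cfg, 10_000, rng)
        assert mafs.mean() == pytest.approx(0.03, abs=0.001)
        assert mafs.min() >= 0.01 and mafs.max() <= 0.05

    def test_one_over_x_spectrum_bounds(self):
        cfg = NullSimConfig(n_individuals=200, n_case=100, chrom_lengths=(1,))
        from gecscan.simulate import _draw_mafs

        mafs = _draw_mafs(cfg, 5000, np.random.default_rng(9))
        assert mafs.min() >= 1 / 400 and mafs.max() <= 0.05
        # 1/x spectrum puts most mass near the lower bound
        assert np.median(mafs) < 0.05 / 2

    def test_shapes_positions_and_labels(self):
        cfg = NullSimConfig(n_individuals=100, n_case=40, chrom_lengths=(50, 50))
        gt, ph = simulate_null_study(cfg, np.random.default_rng(10))
        assert gt.dosages.shape == (100, 100)
        assert gt.chromosomes() == ["1", "2"]
        for c in ("1", "2"):
            pos = gt.sites.loc[gt.sites["chrom"] == c, "pos"].to_numpy()
            assert (np.diff(pos) > 0).all()
        assert ph.n_case == 40 and ph.labels[:40].all()

    def test_hardy_weinberg_proportions(self):
        """Dosage counts at simulated sites are consistent with HW: the
        goodness-of-fit test rejects at ~nominal rate."""
        cfg = NullSimConfig(
            n_individuals=2000,
            n_case=1000,
            chrom_lengths=(300,),
            maf_min=0.02,
            maf_max=0.05,
            maf_spectrum="uniform",
        )
        rng = np.random.default_rng(11)
        gt, _ = simulate_null_study(cfg, rng)
        # compare observed dosage counts to HW expectation at the realized
        # allele frequency (2 df -> 1 df after estimating the frequency)
        rejections = 0
        for k in range(gt.n_sites):
            dos = gt.dosages[k]
            n = dos.size
            q = dos.sum() / (2 * n)
            exp = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            obs = np.bincount(dos, minlength=3)[:3]
            stat = ((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum()
            if chi2_dist.sf(stat, 1) < 0.05:
                rejections += 1
        assert rejections / gt.n_sites < 0.12

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NullSimConfig(n_individuals=10, n_case=10, chrom_lengths=(5,))
        with pytest.raises(ValueError):
            NullSimConfig(n_individuals=10, n_case=5, chrom_lengths=(0,))
        with pytest.raises(ValueError):
            NullSimConfig(n_individuals=10, n_case=5, chrom_lengths=(5,), maf_max=0.7)


class TestBeta0:
    def test_closed_form_without_effects(self):
        b0 = solve_beta0(np.array([0.01]), np.array([0.0]), 0.01,
                         np.random.default_rng(1))
        assert b0 == pytest.approx(np.log(1 / 99))

    def test_prevalence_recovery(self):
        """Population incidence at the solved intercept matches K before
        case-control sampling."""
        rng = np.random.default_rng(2)
        mafs = np.full(10, 0.03)
        log_ors = np.log(np.full(10, 2.0))
        b0 = solve_beta0(mafs, log_ors, 0.05, rng)
        dos = rng.binomial(2, mafs[None, :], size=(200_000, 10))
        incidence = expit(b0 + dos @ log_ors).mean()
        assert incidence == pytest.approx(0.05, rel=0.03)


class TestDiseaseStudy:
    def small_config(self, **kw):
        base = NullSimConfig(
            n_individuals=kw.pop("n", 400),
            n_case=kw.pop("n_case", 200),
            chrom_lengths=kw.pop("chrom_lengths", (30,)),
            maf_min=kw.pop("maf_min", None),
            maf_max=kw.pop("maf_max", 0.05),
        )
        kw.setdefault("prevalence", 0.1)
        kw.setdefault("window_size", 5)
        return DiseaseSimConfig(base=base, **kw)

    def test_seeded_determinism(self):
        cfg = self.small_config()
        g1, p1, t1 = simulate_disease_study(cfg, np.random.default_rng(3))
        g2, p2, t2 = simulate_disease_study(cfg, np.random.default_rng(3))
        assert np.array_equal(g1.dosages, g2.dosages)
        assert t1.window_indices == t2.window_indices
        assert np.array_equal(t1.or_values, t2.or_values)

    def test_truth_record(self):
        cfg = self.small_config(window_size=7, pdv=1.0, pnv=0.0,
                                or_interval=(2.0, 3.0))
        _, _, truth = simulate_disease_study(cfg, np.random.default_rng(4))
        i0, i1 = truth.window_indices
        assert i1 - i0 + 1 == 7
        assert truth.roles == ["detrimental"] * 7
        assert ((truth.or_values >= 2.0) & (truth.or_values <= 3.0)).all()

    def test_all_neutral_reduces_to_null(self):
        """With pdv = 0, pnv = 1 the model has no effects: beta0 is the
        closed-form logit and case/control allele counts are exchangeable."""
        cfg = self.small_config(n=1000, n_case=500, pdv=0.0, pnv=1.0,
                                prevalence=0.1, window_size=10)
        gt, ph, truth = simulate_disease_study(cfg, np.random.default_rng(5))
        assert truth.beta0 == pytest.approx(np.log(0.1 / 0.9))
        assert (truth.or_values == 1.0).all()
        cases = ph.labels == 1
        a = int(gt.dosages[:, cases].sum())
        b = int(gt.dosages[:, ~cases].sum())
        # aggregate allele counts: equal in expectation; 6 sigma guard band
        assert abs(a - b) < 6 * np.sqrt(a + b + 1)

    def test_single_variant_or_recovery(self):
        """A single causal variant with per-allele OR 3 at K = 0.5 yields a
        case/control allelic odds ratio consistent with 3."""
        base = NullSimConfig(
            n_individuals=4000, n_case=2000, chrom_lengths=(5,),
            maf_min=0.04, maf_max=0.05, maf_spectrum="uniform",
        )
        cfg = DiseaseSimConfig(
            base=base, prevalence=0.5, window_size=1, pdv=1.0, pnv=0.0,
            or_interval=(3.0, 3.0), window_start=2,
        )
        gt, ph, truth = simulate_disease_study(cfg, np.random.default_rng(6))
        k = truth.window_indices[0]
        cases = ph.labels == 1
        a = int(gt.dosages[k, cases].sum())
        b = int(gt.dosages[k, ~cases].sum())
        table = ContingencyTable2x2(a, b, 2 * 2000 - a, 2 * 2000 - b)
        or_est, _ = odds_ratio_woolf(table)
        assert 2.3 < or_est < 3.9

    def test_window_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="window"):
            self.small_config(chrom_lengths=(3,), window_size=5)


class TestEstimatePower:
    def test_degenerate_thresholds(self):
        cfg = DiseaseSimConfig(
            base=NullSimConfig(n_individuals=60, n_case=30, chrom_lengths=(10,)),
            prevalence=0.2, window_size=3,
        )
        rng = np.random.default_rng(7)
        full = estimate_power(cfg, alpha_gecs=1.0, alpha_sma=1.0, n_reps=3, rng=rng)
        assert full.power_gecs == 1.0 and full.power_sma == 1.0
        none = estimate_power(cfg, alpha_gecs=0.0, alpha_sma=0.0, n_reps=3, rng=rng)
        assert none.power_gecs == 0.0 and none.power_sma == 0.0
        assert none.se_gecs == 0.0

    def test_invalid_reps(self):
        cfg = DiseaseSimConfig(
            base=NullSimConfig(n_individuals=60, n_case=30, chrom_lengths=(10,)),
            prevalence=0.2, window_size=3,
        )
        with pytest.raises(ValueError):
            estimate_power(cfg, 0.5, 0.5, n_reps=0)
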