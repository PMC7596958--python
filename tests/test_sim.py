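"""Simulation generators: null data, penetrance tables, survival layer."""
import numpy as np
import pytest

from esmdr.sim import (
    NullSimConfig,
    SurvivalSimConfig,
    calibrate_log_hr,
    estimate_type1,
    make_penetrance,
    penetrance_heritability,
    simulate_epistatic,
    simulate_null,
)


class TestNullGenerator:
    def test_maf_within_3_binomial_se(self, rng):
        cfg = NullSimConfig(m=30, n=2000, seed=7)
        geno, _ = simulate_null(cfg)
        # regenerate the drawn MAFs from the same stream
        draw = np.random.default_rng(7).uniform(0.1, 0.5, 30)
        se = np.sqrt(draw * (1 - draw) / (2 * cfg.n))
        assert np.all(np.abs(geno.maf - draw) < 3.5 * se)

    def test_outcome_independent_of_genotypes(self):
        corrs = []
        rng = np.random.default_rng(0)
        for s in range(200):
            geno, y = simulate_null(NullSimConfig(m=5, n=100, seed=s))
            corrs.append(np.corrcoef(geno.geno[:, 0], y)[0, 1])
        assert abs(np.mean(corrs)) < 3 / np.sqrt(200 * 100)

    def test_seed_stream_reproducible(self):
        a = simulate_null(NullSimConfig(m=5, n=50, seed=123))
        b = simulate_null(NullSimConfig(m=5, n=50, seed=123))
        np.testing.assert_array_equal(a[0].geno, b[0].geno)
        np.testing.assert_array_equal(a[1], b[1])

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError):
            estimate_type1(NullSimConfig(replicates=50))


class TestPenetrance:
    @pytest.mark.parametrize("maf", [0.2, 0.4])
    @pytest.mark.parametrize("h2", [0.01, 0.1, 0.4])
    def test_no_main_effects_and_exact_heritability(self, maf, h2):
        pm = make_penetrance(maf, h2, seed=1)
        p = pm.genotype_freqs()
        # marginal penetrance of each genotype of each SNP equals K
        marg1 = (pm.f * p[None, :]).sum(axis=1)
        marg2 = (pm.f * p[:, None]).sum(axis=0)
        np.testing.assert_allclose(marg1, pm.K, atol=1e-3)
        np.testing.assert_allclose(marg2, pm.K, atol=1e-3)
        assert (pm.f >= 0).all() and (pm.f <= 1).all()
        # independent brute-force recomputation over the 9 cells
        h2_check = penetrance_heritability(pm.f, maf, pm.K)
        assert h2_check == pytest.approx(h2, rel=0.05)

    def test_brute_force_heritability_definition(self):
        pm = make_penetrance(0.3, 0.2, seed=5)
        p = pm.genotype_freqs()
        acc = 0.0
        for i in range(3):
            for j in range(3):
                acc += p[i] * p[j] * (pm.f[i, j] - pm.K) ** 2
        assert acc / (pm.K * (1 - pm.K)) == pytest.approx(0.2, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_penetrance(0.7, 0.1)
        with pytest.raises(ValueError):
            make_penetrance(0.2, 0.0)


class TestSurvivalLayer:
    def test_calibrated_log_hr_value(self):
        # closed form at the default Weibull(5, 2) baseline, U(0,4) censoring
        assert calibrate_log_hr() == pytest.approx(1.4880, abs=1e-3)

    def test_censoring_fraction_near_40pct(self):
        pm = make_penetrance(0.4, 0.2, seed=3)
        _, data, _ = simulate_epistatic(pm, SurvivalSimConfig(n=10000, seed=5))
        assert 1 - data.status.mean() == pytest.approx(0.40, abs=0.015)

    def test_balanced_risk_groups(self):
        pm = make_penetrance(0.2, 0.1, seed=2)
        _, _, risk = simulate_epistatic(pm, SurvivalSimConfig(n=400, seed=0))
        assert risk.sum() == 200

    def test_null_effect_gives_indistinguishable_groups(self, rng):
        from esmdr.survival import logrank

        pm = make_penetrance(0.4, 0.2, seed=3)
        pvals = []
        for s in range(40):
            cfg = SurvivalSimConfig(n=400, seed=s, beta=0.0)
            _, data, risk = simulate_epistatic(pm, cfg)
            from scipy.stats import norm

            stat = logrank(data, risk.astype(bool)).statistic
            pvals.append(2 * (1 - norm.cdf(abs(stat))))
        assert min(pvals) > 1e-4 and 0.2 < np.mean(pvals) < 0.8

    def test_high_risk_has_earlier_median_onset(self):
        # closed-form Weibull quantile ratio: t_med(high)/t_med(low)
        # = exp(-beta/shape)
        pm = make_penetrance(0.4, 0.2, seed=3)
        cfg = SurvivalSimConfig(n=20000, seed=9)
        _, data, risk = simulate_epistatic(pm, cfg)
        # use uncensored event times only at matched quantiles of T itself
        hi = risk == 1
        ratio = np.exp(-cfg.beta / cfg.shape)
        med_hi = np.median(data.time[hi])
        med_lo = np.median(data.time[~hi])
        assert med_hi < med_lo
        assert med_hi / med_lo == pytest.approx(ratio, rel=0.1)

    def test_functional_snps_lead_columns(self):
        pm = make_penetrance(0.2, 0.05, seed=4)
        geno, _, _ = simulate_epistatic(pm, SurvivalSimConfig(n=100, seed=1))
        assert geno.snp_ids[:2] == ["SNP1", "SNP2"]
        assert geno.m == 20
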