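"""Generator correctness: SNP panel, Mendelian transmission, polygenic score,
assortative mating, schooling and earnings rules."""

import numpy as np
import pandas as pd
import pytest

import genlottery as gl
from genlottery.config import ConfigurationError
from genlottery.simulate import (
    InputError,
    compute_piv,
    draw_snp_panel,
    mendelian_transmit,
    simulate_parent_pairs,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestConfig:
    def test_invalid_frequency_range_rejected(self):
        with pytest.raises(ConfigurationError):
            gl.SimConfig(allele_freq_range=(0.9, 0.1))
        with pytest.raises(ConfigurationError):
            gl.SimConfig(allele_freq_range=(0.0, 0.5))

    def test_assortative_correlation_bounds(self):
        with pytest.raises(ConfigurationError):
            gl.SimConfig(rho_assortative=1.0)

    @pytest.mark.parametrize("field,value", [
        ("pleio_fraction", 1.5), ("n_snps", 0), ("mincer_curvature", -0.01),
        ("schooling_noise_sd", -1.0), ("offspring_dist", (0.5, 0.5, 0.5)),
    ])
    def test_field_validation(self, field, value):
        with pytest.raises(ConfigurationError):
            gl.SimConfig(**{field: value})

    def test_config_file_round_trip(self, tmp_path):
        cfg = gl.preset("family_confounding", n_families=123, seed=9)
        for name in ("c.yaml", "c.json"):
            p = tmp_path / name
            cfg.to_file(p)
            assert gl.SimConfig.from_file(p) == cfg

    def test_unknown_preset_and_field(self):
        with pytest.raises(ConfigurationError):
            gl.preset("nope")
        with pytest.raises(ConfigurationError):
            gl.SimConfig.from_dict({"n_families": 10, "bogus": 1})


class TestSNPPanel:
    @pytest.mark.parametrize("frac,m,expected", [(0.0, 335, 0), (1.0, 10, 10), (0.3, 10, 3)])
    def test_pleiotropic_snp_count(self, frac, m, expected):
        cfg = gl.SimConfig(n_snps=m, pleio_fraction=frac, pleio_effect_sd=0.01)
        panel = draw_snp_panel(cfg, _rng(1))
        assert panel.n_snps == m
        assert int((panel.true_direct_effect != 0).sum()) == expected

    def test_frequencies_inside_range(self):
        cfg = gl.SimConfig(n_snps=200, allele_freq_range=(0.2, 0.6))
        panel = draw_snp_panel(cfg, _rng(2))
        assert panel.freqs.min() > 0.19 and panel.freqs.max() < 0.61

    def test_score_weight_tracks_true_effect(self):
        cfg = gl.SimConfig(n_snps=300)
        panel = draw_snp_panel(cfg, _rng(3))
        r = np.corrcoef(panel.score_weight, panel.true_schooling_effect)[0, 1]
        assert r > 0.9

    def test_true_score_sd_matches_first_stage(self):
        cfg = gl.SimConfig(n_snps=335, pi_first_stage=0.26)
        panel = draw_snp_panel(cfg, _rng(4))
        var = np.sum(panel.true_schooling_effect ** 2
                     * 2 * panel.mean_freq * (1 - panel.mean_freq))
        assert np.sqrt(var) == pytest.approx(0.26, rel=1e-10)


class TestPIV:
    def test_hand_arithmetic(self):
        raw, _ = compute_piv(np.array([[0, 1, 2]]), np.array([0.1, -0.2, 0.05]),
                             standardize=False)
        assert raw[0] == pytest.approx(-0.1)

    def test_zero_genotype(self):
        raw, _ = compute_piv(np.zeros((3, 4)), np.ones(4), standardize=False)
        assert np.all(raw == 0)

    def test_standardization(self, rng):
        g = rng.integers(0, 3, size=(500, 30))
        _, std = compute_piv(g, rng.normal(size=30))
        assert abs(std.mean()) < 1e-10
        assert abs(std.std() - 1) < 1e-10

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            compute_piv(np.zeros((2, 3)), np.ones(4))


class TestTransmission:
    def test_forced_genotypes(self):
        cfg = gl.SimConfig(n_snps=5)
        panel = draw_snp_panel(cfg, _rng(5))
        zero = np.zeros(5, dtype=np.int8)
        assert np.all(mendelian_transmit((zero, zero), panel, _rng(0))[0] == 0)
        two = np.full(5, 2, dtype=np.int8)
        assert np.all(mendelian_transmit((two, zero), panel, _rng(0))[0] == 1)

    def test_het_cross_punnett(self):
        cfg = gl.SimConfig(n_snps=1)
        panel = draw_snp_panel(cfg, _rng(6))
        one = np.ones(1, dtype=np.int8)
        rng = _rng(7)
        draws = np.array([mendelian_transmit((one, one), panel, rng)[0][0]
                          for _ in range(10000)])
        # P(0)=P(2)=0.25, P(1)=0.5 within 3 binomial SEs
        for val, p in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            se = np.sqrt(p * (1 - p) / 10000)
            assert abs((draws == val).mean() - p) < 3 * se

    def test_mz_duplicate_dz_independent(self):
        cfg = gl.SimConfig(n_snps=400)
        panel = draw_snp_panel(cfg, _rng(8))
        gm = _rng(9).integers(0, 3, 400).astype(np.int8)
        gf = _rng(10).integers(0, 3, 400).astype(np.int8)
        mz = mendelian_transmit((gm, gf), panel, _rng(11), zygosity="MZ")
        assert np.array_equal(mz[0], mz[1])
        dz = mendelian_transmit((gm, gf), panel, _rng(11), zygosity="DZ")
        assert not np.array_equal(dz[0], dz[1])

    def test_genetic_lottery_expectation(self):
        """E[offspring genotype | parents] = (G_m + G_f) / 2 per SNP."""
        cfg = gl.SimConfig(n_families=10000, n_snps=30,
                           offspring_dist=(1.0, 0.0, 0.0), twin_prob=0.0, seed=12)
        pop = gl.simulate_population(cfg)
        fam = pop.offspring["family_index"].to_numpy()
        mid = (pop.geno_mother[fam] + pop.geno_father[fam]) / 2.0
        dev = pop.geno_offspring - mid
        # per-SNP mean deviation within 4 Monte-Carlo SEs of 0
        mc_se = dev.std(axis=0) / np.sqrt(len(dev))
        assert np.all(np.abs(dev.mean(axis=0)) < 4 * np.maximum(mc_se, 1e-12))


class TestAssortativeMating:
    @pytest.mark.parametrize("rho", [0.0, 0.4])
    def test_spousal_correlation_hit(self, rho):
        cfg = gl.SimConfig(n_families=10000, rho_assortative=rho, seed=13)
        rng = np.random.default_rng(cfg.seed)
        panel = draw_snp_panel(cfg, rng)
        pairs = simulate_parent_pairs(cfg, panel, rng)
        r = np.corrcoef(pairs.mother_piv_raw, pairs.father_piv_raw)[0, 1]
        assert abs(r - rho) < 0.03

    def test_aligned_stratification_separates_piv(self):
        cfg = gl.SimConfig(n_families=4000, n_subpops=2, subpop_freq_offset=0.1,
                           seed=14)
        rng = np.random.default_rng(cfg.seed)
        panel = draw_snp_panel(cfg, rng)
        pairs = simulate_parent_pairs(cfg, panel, rng)
        piv = pairs.mother_piv_raw
        assert piv[pairs.subpop == 1].mean() > piv[pairs.subpop == 0].mean()


class TestSchooling:
    def test_first_stage_recovery(self):
        """Slope of schooling on the standardized score recovers pi."""
        for pi, seed in [(0.26, 15), (0.0, 16)]:
            cfg = gl.SimConfig(n_families=50000, offspring_dist=(1.0, 0.0, 0.0),
                               twin_prob=0.0, pi_first_stage=pi, seed=seed)
            pop = gl.simulate_population(cfg)
            s = pop.offspring["schooling_years"].to_numpy(dtype=float)
            z = pop.offspring["piv_std"].to_numpy()
            slope = np.cov(z, s)[0, 1] / np.var(z)
            assert abs(slope - pi) < 0.02

    def test_bounds_and_clipping(self):
        cfg = gl.SimConfig(n_families=2000, n_subpops=2, subpop_schooling_offset=40.0,
                           schooling_noise_sd=0.5, seed=17)
        pop = gl.simulate_population(cfg)
        s = pop.offspring["schooling_years"]
        sub = pop.offspring["subpop"]
        assert s.between(6, 23).all()
        assert (s[sub == 1] == 23).all()  # latent ~ 33 clips to the ceiling
        assert (s[sub == 0] == 6).all()


class TestEarnings:
    def test_zero_before_entry(self, null_pop):
        s = null_pop.offspring["schooling_years"].to_numpy()
        x = null_pop.ages[None, :] - (s[:, None] + 7)
        assert np.all(null_pop.earnings[x < 0] == 0)
        assert np.all(null_pop.earnings[x >= 0] > 0)

    def test_noiseless_schooling_premium_at_equal_experience(self):
        cfg = gl.SimConfig(n_families=300, schooling_noise_sd=3.0,
                           earnings_noise_sd=0.0, earnings_person_sd=0.0,
                           pi_first_stage=0.0, seed=18)
        pop = gl.simulate_population(cfg)
        df = pop.offspring
        s = df["schooling_years"].to_numpy()
        i12 = np.flatnonzero(s == 12)[0]
        i13 = np.flatnonzero(s == 13)[0]
        ages = list(pop.ages)
        # same potential experience x=10: age 29 for S=12, age 30 for S=13
        y12 = np.log(pop.earnings[i12, ages.index(29)])
        y13 = np.log(pop.earnings[i13, ages.index(30)])
        assert y13 - y12 == pytest.approx(cfg.beta_true, abs=1e-10)

    def test_crossover_age_in_window(self, null_pop):
        s = null_pop.offspring["schooling_years"].to_numpy()
        hi = null_pop.earnings[s >= 16].mean(axis=0)
        lo = null_pop.earnings[s <= 12].mean(axis=0)
        cross = null_pop.ages[np.argmax(hi > lo)]
        assert 24 <= cross <= 32


class TestSibshipStructure:
    def test_mz_identical_dz_half_correlated(self):
        cfg = gl.SimConfig(n_families=20000, twin_prob=0.5, mz_share=0.5, seed=19)
        pop = gl.simulate_population(cfg)
        off = pop.offspring
        for z, check in (("MZ", "identical"), ("DZ", "half")):
            grp = off[off.zygosity == z].groupby("family_index")["piv_raw"].agg(list)
            pairs = np.array([v for v in grp if len(v) == 2])
            if check == "identical":
                assert np.allclose(pairs[:, 0], pairs[:, 1])
            else:
                assert len(pairs) >= 4000
                r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
                assert abs(r - 0.5) < 0.05

    def test_within_sibship_differences_are_lottery(self):
        """Sibling score differences are mean-zero and uncorrelated with
        parental score, subpopulation and parental earnings even under
        assortment and stratification."""
        cfg = gl.SimConfig(n_families=10000, offspring_dist=(0.0, 1.0, 0.0),
                           twin_prob=0.0, rho_assortative=0.4, n_subpops=2,
                           subpop_freq_offset=0.05, subpop_earnings_offset=0.2,
                           seed=20)
        pop = gl.simulate_population(cfg)
        off = pop.offspring.sort_values(["family_index", "birth_order"])
        first = off.groupby("family_index").head(1).set_index("family_index")
        second = off.groupby("family_index").tail(1).set_index("family_index")
        d = (first["piv_raw"] - second["piv_raw"]).to_numpy()
        assert abs(d.mean()) < 4 * d.std() / np.sqrt(len(d))
        parental = pop.parents.groupby("family_index")["piv_raw"].mean().to_numpy()
        for other in (parental, first["subpop"].to_numpy(),
                      first["parental_earnings"].to_numpy()):
            assert abs(np.corrcoef(d, other)[0, 1]) < 0.03


def test_reproducibility_bit_identical():
    cfg = gl.preset("family_confounding", n_families=500, seed=77)
    a = gl.simulate_population(cfg)
    b = gl.simulate_population(cfg)
    pd.testing.assert_frame_equal(a.offspring, b.offspring)
    pd.testing.assert_frame_equal(a.parents, b.parents)
    assert np.array_equal(a.geno_offspring, b.geno_offspring)
    assert np.array_equal(a.earnings, b.earnings)
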