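"""Normalization, dispersion, NB Wald test and BH adjustment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import pkdcore as pk
from pkdcore.dge import DispersionEstimates, SizeFactors, bh_adjust, vst
from pkdcore.errors import AnalysisError, NormalizationError


def _cm(counts, genotypes, reference="WT"):
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(len(genotypes))],
    )
    geno = pd.Series(genotypes, index=counts.columns)
    return pk.CountMatrix(counts, geno, reference=reference)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestSizeFactors:
    def test_identical_columns_give_ones(self):
        cm = _cm([[4, 4], [9, 9]], ["WT", "KO1"])
        assert np.allclose(pk.size_factors(cm).values, [1.0, 1.0])

    def test_median_of_ratios_hand_example(self):
        # every gene's ratio pair is (1/sqrt(2), sqrt(2))
        cm = _cm([[2, 4], [6, 12], [10, 20]], ["WT", "KO1"])
        s = pk.size_factors(cm).values.to_numpy()
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-6)

    def test_no_zero_free_gene_is_an_error(self):
        cm = _cm([[0, 4], [0, 9]], ["WT", "KO1"])
        with pytest.raises(NormalizationError, match="all-positive"):
            pk.size_factors(cm)


class TestNormalize:
    def test_unit_factors_are_identity(self):
        cm = _cm([[3, 5], [7, 1]], ["WT", "KO1"])
        s = SizeFactors(pd.Series([1.0, 1.0], index=cm.samples))
        pd.testing.assert_frame_equal(pk.normalize(cm, s), cm.counts.astype(float), check_dtype=False)

    def test_scaling_equivariance_of_one_column(self):
        cm = _cm([[3, 5], [7, 1]], ["WT", "KO1"])
        s = SizeFactors(pd.Series([1.0, 2.0], index=cm.samples))
        cm2 = _cm([[3, 10], [7, 2]], ["WT", "KO1"])
        s2 = SizeFactors(pd.Series([1.0, 4.0], index=cm.samples))
        pd.testing.assert_frame_equal(pk.normalize(cm, s), pk.normalize(cm2, s2))

    def test_hand_normalized_values(self):
        cm = _cm([[2, 4], [6, 12], [10, 20]], ["WT", "KO1"])
        norm = pk.normalize(cm, pk.size_factors(cm))
        assert np.allclose(norm.iloc[0], [2.828, 2.828], atol=1e-3)


class TestDispersions:
    def test_variance_below_mean_floors_at_zero(self):
        cm = _cm([[10, 10, 10, 10]], ["WT", "WT", "WT", "WT"], reference="WT")
        s = SizeFactors(pd.Series(np.ones(4), index=cm.samples))
        d = pk.estimate_dispersions(cm, s)
        assert d.raw.iloc[0] == 0.0

    def test_method_of_moments_hand_value(self):
        # one group, normalized counts (10, 20): mean 15, var 50,
        # raw alpha = (50-15)/15^2
        cm = _cm([[10, 20]], ["WT", "WT"])
        s = SizeFactors(pd.Series([1.0, 1.0], index=cm.samples))
        d = pk.estimate_dispersions(cm, s)
        assert np.isclose(d.raw.iloc[0], 35 / 225, atol=1e-6)

    def test_poisson_data_shrinks_to_small_alpha(self):
        cfg = pk.SimConfig(
            n_genes=2000, frac_concordant_up=0, frac_concordant_down=0,
            frac_discordant=0, frac_single=0, clonal_sd=0.0,
            dispersion_a0=0.0, dispersion_a1=0.0, seed=4,
        )
        cm, _ = pk.simulate_counts(cfg)
        d = pk.estimate_dispersions(cm, pk.size_factors(cm))
        assert d.final.median() < 0.02

    def test_singleton_groups_rejected(self):
        cm = _cm([[1, 2]], ["WT", "KO1"])
        s = SizeFactors(pd.Series([1.0, 1.0], index=cm.samples))
        with pytest.raises(AnalysisError, match="singleton"):
            pk.estimate_dispersions(cm, s)


class TestVst:
    def test_vst_tracks_log2_at_high_counts(self):
        d = DispersionEstimates(
            raw=pd.Series(dtype=float), trend_params=(2.0, 0.03), final=pd.Series(dtype=float)
        )
        x = pd.DataFrame({"a": [1000.0, 4000.0]})
        out = vst(x, d)
        # difference of a 4x step approaches 2 on the log2 scale
        assert abs((out.iloc[1, 0] - out.iloc[0, 0]) - 2.0) < 0.1

    def test_vst_is_monotone(self):
        d = DispersionEstimates(
            raw=pd.Series(dtype=float), trend_params=(3.0, 0.02), final=pd.Series(dtype=float)
        )
        x = pd.DataFrame({"a": np.linspace(0, 500, 100)})
        assert (np.diff(vst(x, d).to_numpy().ravel()) > 0).all()


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        out = bh_adjust(np.full(5, 0.2))
        assert np.allclose(out, out[0])

    def test_nan_passthrough_and_denominator(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(out[1])
        # m = 2 tested values
        assert out[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(AnalysisError):
            bh_adjust(np.array([1.5]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, ps):
        p = np.array(ps)
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestDgeTest:
    def _fixture(self, counts, genotypes, alpha=0.1):
        cm = _cm(counts, genotypes)
        s = SizeFactors(pd.Series(np.ones(len(genotypes)), index=cm.samples))
        d = DispersionEstimates(
            raw=pd.Series(alpha, index=cm.counts.index),
            trend_params=(0.0, alpha),
            final=pd.Series(alpha, index=cm.counts.index),
        )
        return cm, s, d

    def test_null_gene_has_zero_lfc_unit_p(self, cfg):
        cm, s, d = self._fixture(
            [[50, 60, 50, 60]], ["WT", "WT", "KO1", "KO1"]
        )
        res = pk.dge_test(cm, s, d, ("KO1", "WT"), cfg)
        assert abs(res["lfc"].iloc[0]) < 1e-8
        assert res["p"].iloc[0] > 0.999

    def test_de_flag_follows_both_thresholds(self, cfg):
        cfgdefault = cfg
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(60, 8))
        counts[:20, 4:] = rng.poisson(400, size=(20, 4))  # strong effects
        cm, s, d = self._fixture(counts, ["WT"] * 4 + ["KO1"] * 4, alpha=0.02)
        res = pk.dge_test(cm, s, d, ("KO1", "WT"), cfgdefault)
        expected = (res["fdr"] < cfgdefault.fdr_max) & (res["lfc"].abs() >= cfgdefault.lfc_min)
        assert (res["de_flag"] == expected.fillna(False)).all()
        assert res["de_flag"].iloc[:20].mean() > 0.9

    def test_wald_agrees_with_likelihood_ratio_oracle(self, cfg):
        # 2v2 fixture, fixed alpha: compare to LR test by direct NB
        # likelihood maximization
        alpha = 0.1
        y_ref, y_ko = np.array([80.0, 95.0]), np.array([140.0, 160.0])
        cm, s, d = self._fixture(
            [[80, 95, 140, 160]], ["WT", "WT", "KO1", "KO1"], alpha=alpha
        )
        res = pk.dge_test(cm, s, d, ("KO1", "WT"), cfg)

        def nll_one(mu, ys):
            n = 1 / alpha
            p = n / (n + mu)
            return -stats.nbinom.logpmf(ys, n, p).sum()

        def nll_null(mu):
            return nll_one(mu, np.concatenate([y_ref, y_ko]))

        null = optimize.minimize_scalar(nll_null, bounds=(1, 1000), method="bounded")
        alt = (
            optimize.minimize_scalar(lambda m: nll_one(m, y_ref), bounds=(1, 1000), method="bounded").fun
            + optimize.minimize_scalar(lambda m: nll_one(m, y_ko), bounds=(1, 1000), method="bounded").fun
        )
        lr = 2 * (null.fun - alt)
        p_lr = stats.chi2.sf(lr, df=1)
        assert abs(res["p"].iloc[0] - p_lr) <= 0.02

    def test_low_mean_genes_reported_untested(self, cfg):
        cm, s, d = self._fixture(
            [[0, 1, 0, 0], [50, 60, 55, 65]], ["WT", "WT", "KO1", "KO1"]
        )
        res = pk.dge_test(cm, s, d, ("KO1", "WT"), cfg)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p"].iloc[0]) and np.isnan(res["fdr"].iloc[0])
        assert res["tested"].iloc[1]

    def test_group_with_one_sample_rejected(self, cfg):
        cm, s, d = self._fixture([[5, 6, 7]], ["WT", "WT", "KO1"])
        with pytest.raises(AnalysisError, match=">= 2 samples"):
            pk.dge_test(cm, s, d, ("KO1", "WT"), cfg)

    def test_inference_invariant_to_global_size_factor_rescaling(self, cfg):
        # multiplying every size factor by a constant shifts only the
        # intercept of the log-link model: lfc/se/p are unchanged
        rng = np.random.default_rng(5)
        counts = rng.poisson(200, size=(40, 6)) + 1
        genos = ["WT"] * 3 + ["KO1"] * 3
        cm = _cm(counts, genos)
        s1 = pk.size_factors(cm)
        s2 = SizeFactors(s1.values * 3.0)
        d = pk.estimate_dispersions(cm, s1)
        r1 = pk.dge_test(cm, s1, d, ("KO1", "WT"), cfg)
        r2 = pk.dge_test(cm, s2, d, ("KO1", "WT"), cfg)
        for col in ("lfc", "se", "p", "fdr"):
            assert np.allclose(r1[col], r2[col], atol=1e-8, equal_nan=True)
        assert (r1["de_flag"] == r2["de_flag"]).all()

    def test_inference_robust_to_rescaling_one_sample(self, cfg):
        # doubling one sample's counts with size factors re-estimated is a
        # genuine data change (that sample carries more information), but the
        # fold-change estimates move by far less than one standard error
        rng = np.random.default_rng(5)
        counts = rng.poisson(200, size=(40, 6)) + 1
        genos = ["WT"] * 3 + ["KO1"] * 3
        scaled = counts.copy()
        scaled[:, 0] *= 2
        out = []
        for c in (counts, scaled):
            cm = _cm(c, genos)
            s = pk.size_factors(cm)
            d = pk.estimate_dispersions(cm, s)
            out.append(pk.dge_test(cm, s, d, ("KO1", "WT"), cfg))
        shift = (out[0]["lfc"] - out[1]["lfc"]).abs()
        assert (shift < out[0]["se"]).all()


class TestCalibrationAndPower:
    def test_null_type_one_error_rate(self):
        # 20 seeded null simulations: pooled p<0.05 fraction in [0.03, 0.07]
        # and DE-flag rate at most 0.0015
        rates, de_rates = [], []
        for seed in range(20):
            cfg_sim = pk.SimConfig(
                n_genes=2000, frac_concordant_up=0, frac_concordant_down=0,
                frac_discordant=0, frac_single=0, clonal_sd=0.0, seed=100 + seed,
            )
            cm, _ = pk.simulate_counts(cfg_sim)
            rc = pk.RunConfig(seed=seed)
            s = pk.size_factors(cm)
            d = pk.estimate_dispersions(cm, s)
            res = pk.dge_test(cm, s, d, ("KO1", "WT"), rc)
            p = res["p"].dropna()
            rates.append((p < 0.05).mean())
            de_rates.append(res["de_flag"].sum() / len(p))
        assert 0.03 <= np.mean(rates) <= 0.07
        assert np.mean(de_rates) <= 0.0015

    def test_power_at_strong_effects(self):
        # |lfc|=2, alpha=0.05, baseline >= 100, 4v4: sensitivity >= 0.90
        sens = []
        for seed in range(5):
            cfg_sim = pk.SimConfig(
                n_genes=2000, frac_concordant_up=0.02, frac_concordant_down=0.02,
                frac_discordant=0, frac_single=0, clonal_sd=0.0,
                dispersion_a0=0.0, dispersion_a1=0.05,
                effect_min_baseline=100.0, seed=300 + seed,
            )
            cm, truth = pk.simulate_counts(cfg_sim)
            rc = pk.RunConfig(seed=seed)
            s = pk.size_factors(cm)
            d = pk.estimate_dispersions(cm, s)
            res = pk.dge_test(cm, s, d, ("KO1", "WT"), rc)
            planted = truth.genes["class"].isin(["concordant_up", "concordant_down"]).to_numpy()
            sens.append(res.loc[planted, "de_flag"].mean())
        assert np.mean(sens) >= 0.90
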