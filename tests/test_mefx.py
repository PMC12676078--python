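"""Microbial-effect response ratio, error propagation, slope comparison."""
import numpy as np
import pandas as pd
import pytest

from rhizoadapt import mefx, synthetic as syn
from rhizoadapt.datatypes import TraitTable


def make_traits(live, sterile, genotype="g1", nitrogen="low", trait="height"):
    rows = []
    for i, v in enumerate(live):
        rows.append(dict(plant_id=f"L{i}", genotype=genotype, block="B1",
                         nitrogen=nitrogen, microbe="live", **{trait: v}))
    for i, v in enumerate(sterile):
        rows.append(dict(plant_id=f"S{i}", genotype=genotype, block="B1",
                         nitrogen=nitrogen, microbe="sterile", **{trait: v}))
    return TraitTable(pd.DataFrame(rows))


class TestMicrobialEffect:
    def test_direct_formula(self):
        traits = make_traits([12.0, 12.0], [10.0, 10.0])
        (est,) = mefx.compute_microbial_effect(traits, "height")
        assert est.me == pytest.approx(0.2)

    def test_equal_means_give_zero(self):
        traits = make_traits([10.0, 12.0], [11.0, 11.0])
        (est,) = mefx.compute_microbial_effect(traits, "height")
        assert est.me == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        live = rng.uniform(8, 15, 6)
        sterile = rng.uniform(8, 15, 6)
        (e1,) = mefx.compute_microbial_effect(make_traits(live, sterile), "height")
        (e2,) = mefx.compute_microbial_effect(make_traits(3.7 * live, 3.7 * sterile),
                                              "height")
        assert e2.me == pytest.approx(e1.me, abs=1e-12)

    def test_me_bounded_below_for_positive_traits(self, rng):
        for s in range(10):
            r = np.random.default_rng(s)
            live = r.uniform(0.1, 30, 5)
            sterile = r.uniform(0.1, 30, 5)
            (est,) = mefx.compute_microbial_effect(make_traits(live, sterile), "height")
            assert est.me >= -1.0

    def test_small_cell_dropped_with_warning(self):
        rows = [dict(plant_id="L1", genotype="g", block="B1", nitrogen="low",
                     microbe="live", height=10.0)]
        rows += [dict(plant_id=f"S{i}", genotype="g", block="B1", nitrogen="low",
                      microbe="sterile", height=10.0) for i in range(3)]
        with pytest.warns(UserWarning, match="dropped"):
            out = mefx.compute_microbial_effect(TraitTable(pd.DataFrame(rows)), "height")
        assert out == []


class TestPropagation:
    def test_delta_method_hand_arithmetic(self):
        est = mefx.MicrobialEffectEstimate("g", "low", "height", 12.0, 10.0,
                                           0.5, 0.4, 7, 7, me=0.2)
        se = mefx.propagate_me_uncertainty(est, "delta")
        assert se == pytest.approx(np.sqrt(0.25 / 100 + 144 * 0.16 / 1e4), abs=1e-12)
        assert se == pytest.approx(0.0693, abs=5e-4)

    def test_zero_ses_give_zero_uncertainty_both_methods(self):
        est = mefx.MicrobialEffectEstimate("g", "low", "height", 12.0, 10.0,
                                           0.0, 0.0, 7, 7, me=0.2)
        assert mefx.propagate_me_uncertainty(est, "delta") == 0.0
        assert mefx.propagate_me_uncertainty(est, "montecarlo", seed=1) == 0.0

    def test_delta_and_montecarlo_agree_at_small_cv(self):
        rng = np.random.default_rng(4)
        rel = []
        for _ in range(100):
            S = rng.uniform(5, 50)
            L = S * rng.uniform(0.8, 1.3)
            est = mefx.MicrobialEffectEstimate(
                "g", "low", "height", L, S,
                live_se=0.1 * L * rng.uniform(0.2, 1.0),
                sterile_se=0.1 * S * rng.uniform(0.2, 1.0),
                n_live=7, n_sterile=7, me=(L - S) / S,
            )
            d = mefx.propagate_me_uncertainty(est, "delta")
            m = mefx.propagate_me_uncertainty(est, "montecarlo", n_draws=40000,
                                              seed=int(rng.integers(2**31 - 1)))
            rel.append(abs(m - d) / d)
        assert np.mean(rel) < 0.05 and np.quantile(rel, 0.9) < 0.08

    def test_heavy_tail_warning_at_large_cv(self):
        est = mefx.MicrobialEffectEstimate("g", "low", "height", 12.0, 10.0,
                                           0.5, 4.0, 7, 7, me=0.2)
        with pytest.warns(UserWarning, match="heavy"):
            mefx.propagate_me_uncertainty(est, "delta")


def make_estimates(me_values, ses, glasshouse_n, genotypes=None):
    genotypes = genotypes or [f"g{i}" for i in range(len(me_values))]
    return [
        mefx.MicrobialEffectEstimate(g, glasshouse_n, "height", 1.0, 1.0,
                                     0.0, 0.0, 7, 7, me=m, me_se=s)
        for g, m, s in zip(genotypes, me_values, ses)
    ]


class TestReactionNorm:
    def test_colinear_points_give_exact_line(self):
        ests = make_estimates([0.0, 1.0, 2.0], [0.1] * 3, "low")
        x = pd.Series([0.0, 1.0, 2.0], index=["g0", "g1", "g2"])
        res = mefx.fit_reaction_norm(ests, x, standardize_x=False)
        assert res["slope"] == pytest.approx(1.0, abs=1e-12)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_permuted_predictor_centers_slope_at_zero(self, rng):
        slopes = []
        base_x = pd.Series(np.arange(8.0), index=[f"g{i}" for i in range(8)])
        me = rng.normal(0.1, 0.05, 8)
        for s in range(50):
            r = np.random.default_rng(s)
            x = pd.Series(r.permutation(base_x.to_numpy()), index=base_x.index)
            ests = make_estimates(me, [0.05] * 8, "low")
            slopes.append(mefx.fit_reaction_norm(ests, x)["slope"])
        assert abs(np.mean(slopes)) < 0.02

    def test_constant_predictor_rejected(self):
        ests = make_estimates([0.1, 0.2, 0.3], [0.1] * 3, "low")
        x = pd.Series([1.0, 1.0, 1.0], index=["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="constant"):
            mefx.fit_reaction_norm(ests, x)


class TestSlopeDifference:
    def test_certain_estimates_give_floor_p(self):
        x = pd.Series(np.linspace(-1, 1, 6), index=[f"g{i}" for i in range(6)])
        low = make_estimates(-0.2 * x.to_numpy(), [0.0] * 6, "low", list(x.index))
        high = make_estimates(0.2 * x.to_numpy(), [0.0] * 6, "high", list(x.index))
        comp = mefx.slope_difference_test(low, high, x, n_sim=1000, seed=0)
        assert comp.p_value == pytest.approx(2.0 / 1001)

    def test_affine_rescaling_of_predictor_rescales_slopes_only(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=8), index=[f"g{i}" for i in range(8)])
        me_l = rng.normal(0, 0.1, 8)
        me_h = rng.normal(0, 0.1, 8)
        low = make_estimates(me_l, [0.05] * 8, "low", list(x.index))
        high = make_estimates(me_h, [0.05] * 8, "high", list(x.index))
        c1 = mefx.slope_difference_test(low, high, x, n_sim=2000, seed=3,
                                        standardize_x=False)
        c2 = mefx.slope_difference_test(low, high, 2.0 * x + 7.0, n_sim=2000,
                                        seed=3, standardize_x=False)
        assert c2.slope_low == pytest.approx(c1.slope_low / 2.0, rel=1e-10)
        assert c2.delta == pytest.approx(c1.delta / 2.0, rel=1e-10)
        assert c2.p_value == pytest.approx(c1.p_value)

    def test_power_monotone_in_effect_size(self, panel40):
        sub = syn.select_spanning_subset(panel40, 10)
        x = sub.data.set_index("genotype")["soil_nitrogen"]
        rates = []
        for mag in (0.0, 0.08, 0.2):
            spec = syn.TraitEffectSpec(me_slope_lowN=-mag, me_slope_highN=mag)
            rej = 0
            for s in range(25):
                traits, _ = syn.gen_experiment2_traits(sub, spec, n_replicates=10,
                                                       seed=1000 * int(mag * 100) + s)
                ests = mefx.compute_microbial_effect(traits, "height")
                mefx.attach_uncertainty(ests, method="delta")
                low = [e for e in ests if e.glasshouse_n == "low"]
                high = [e for e in ests if e.glasshouse_n == "high"]
                comp = mefx.slope_difference_test(low, high, x, n_sim=1000, seed=s)
                rej += comp.p_value <= 0.05
            rates.append(rej / 25)
        assert rates[0] <= 0.16
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.8

    def test_constant_microbiome_trait_rejected(self):
        x = pd.Series(np.linspace(-1, 1, 6), index=[f"g{i}" for i in range(6)])
        low = make_estimates(x.to_numpy() * 0.1, [0.02] * 6, "low", list(x.index))
        high = make_estimates(x.to_numpy() * -0.1, [0.02] * 6, "high", list(x.index))
        const = pd.Series(1.0, index=x.index)
        with pytest.raises(ValueError, match="constant"):
            mefx.me_vs_microbiome(low, high, const, n_sim=1000, seed=0)

    def test_microbiome_predictor_direction_recovered(self, panel40):
        # beneficial-in-low-N planting: ME declines with historic soil N in
        # low-N pots; diazotroph richness declines with soil N; hence ME vs
        # richness has positive slope under low N and negative under high N
        from rhizoadapt import community as com

        sub = syn.select_spanning_subset(panel40, 10)
        ok = 0
        for s in range(10):
            traits, _ = syn.gen_experiment2_traits(sub, n_replicates=10, seed=300 + s)
            tax = syn.gen_taxonomy("nifh", 40, seed=s)
            table, meta = syn.gen_feature_table(panel40, 3, 3, syn.spec_nifh(),
                                                tax, seed=400 + s)
            alpha = com.alpha_metrics(table).merge(
                meta.for_samples(table.sample_ids), on="sample_id"
            )
            rich = alpha.groupby("genotype")["richness"].mean()
            ests = mefx.compute_microbial_effect(traits, "height")
            mefx.attach_uncertainty(ests, method="delta")
            low = [e for e in ests if e.glasshouse_n == "low"]
            high = [e for e in ests if e.glasshouse_n == "high"]
            comp = mefx.me_vs_microbiome(low, high, rich, n_sim=1000, seed=s,
                                         predictor_name="nfix_richness")
            ok += (comp.slope_low > 0) and (comp.slope_high < 0)
        assert ok >= 8
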