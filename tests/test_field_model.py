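"""Split-plot mixed model: df checks, OLS oracle, LSMeans, comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from glucotype import (
    SplitPlotDesign,
    TrialConfig,
    dunnett_vs_control,
    env_correlations,
    fit_split_plot,
    generate_trial,
    lsmeans,
    tukey_all_pairs,
)
from glucotype.field_model import compact_letter_display


class TestDesign:
    def test_published_design_counts(self):
        d = SplitPlotDesign()
        assert d.n_genotypes == 17
        assert d.blocks_per_environment == 40
        assert d.n_blocks == 120
        assert d.n_plots == 12
        assert d.n_plants == 2040

    def test_every_block_contains_every_genotype_once(self):
        lay = SplitPlotDesign(n_genotypes=5, blocks_per_plot=2).layout()
        counts = lay.groupby(["block", "genotype"], observed=True).size()
        assert (counts == 1).all()

    def test_plot_nesting_is_strict(self):
        lay = SplitPlotDesign().layout()
        per_plot = lay.groupby("plot")[["environment", "treatment"]].nunique()
        assert (per_plot == 1).all().all()

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            SplitPlotDesign(n_genotypes=0)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "design, expect",
        [
            (SplitPlotDesign(), {"Genotype": 16, "Genotype:Environment": 32}),
            (
                SplitPlotDesign(n_genotypes=4, blocks_per_plot=3),
                {"Genotype": 3, "Genotype:Environment": 6,
                 "Environment": 2, "Treatment": 1,
                 "Genotype:Environment:Treatment": 6},
            ),
        ],
    )
    def test_closed_form_term_df(self, design, expect):
        rng = np.random.default_rng(1)
        lay = design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        fit = fit_split_plot(lay, "y")
        for term, df in expect.items():
            assert fit.anova.loc[term, "df"] == df, term


class TestOlsOracle:
    def test_zero_plot_variance_reproduces_type2_ols(self, small_design):
        """At theta = 0 the GLS Type II table equals plain OLS ANOVA."""
        rng = np.random.default_rng(0)
        lay = small_design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        fit = fit_split_plot(lay, "y", fix_theta=0.0, denominator="residual")
        ols = smf.ols(
            "y ~ C(genotype)*C(environment)*C(treatment)", data=lay
        ).fit()
        tab = anova_lm(ols, typ=2)
        np.testing.assert_allclose(
            fit.anova["SS"].to_numpy(), tab["sum_sq"].to_numpy()[:7],
            rtol=1e-10,
        )
        np.testing.assert_allclose(
            fit.anova["F"].to_numpy(), tab["F"].to_numpy()[:7], rtol=1e-10
        )
        np.testing.assert_allclose(
            fit.anova["p"].to_numpy(), tab["PR(>F)"].to_numpy()[:7],
            rtol=1e-8,
        )

    def test_reml_matches_independent_mixed_model(self):
        """Profiled REML agrees with statsmodels MixedLM on both components."""
        trial = generate_trial(TrialConfig(seed=7))
        fit = fit_split_plot(trial, "leaf_damage")
        md = smf.mixedlm(
            "leaf_damage ~ C(genotype)*C(environment)*C(treatment)",
            trial, groups=trial["plot"],
        ).fit(reml=True)
        assert fit.var_residual == pytest.approx(md.scale, rel=1e-4)
        assert fit.var_plot == pytest.approx(
            float(md.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )


class TestRandomEffect:
    def test_planted_plot_variance_detected(self):
        cfg = TrialConfig(seed=21)
        cfg.trait_sd["flowering_time"]["plot"] = 2.0
        trial = generate_trial(cfg)
        fit = fit_split_plot(trial, "flowering_time")
        assert fit.var_plot > 0
        assert fit.plot_lrt_p < 0.01

    def test_zero_plot_variance_small_estimate(self):
        cfg = TrialConfig(seed=22)
        cfg.trait_sd["flowering_time"]["plot"] = 0.0
        trial = generate_trial(cfg)
        fit = fit_split_plot(trial, "flowering_time")
        # ratio should collapse toward zero relative to residual variance
        assert fit.var_plot / fit.var_residual < 0.05


class TestLsmeans:
    def test_balanced_lsmeans_equal_cell_means(self, small_design):
        rng = np.random.default_rng(2)
        lay = small_design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        fit = fit_split_plot(lay, "y", fix_theta=0.0)
        ls = lsmeans(fit, "genotype").set_index("genotype")["lsmean"]
        raw = lay.groupby("genotype")["y"].mean()
        np.testing.assert_allclose(
            ls.sort_index().to_numpy(), raw.sort_index().to_numpy(),
            atol=1e-10,
        )

    def test_missing_plant_keeps_equal_weight_marginalization(
        self, small_design
    ):
        rng = np.random.default_rng(3)
        lay = small_design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        g0 = lay["genotype"].iloc[0]
        drop = lay[(lay["genotype"] == g0)].index[0]
        sub = lay.drop(index=drop)
        fit = fit_split_plot(sub, "y", fix_theta=0.0)
        ls = lsmeans(fit, "genotype").set_index("genotype")["lsmean"]
        raw = sub.groupby("genotype")["y"].mean()
        # raw mean and LSMean diverge for the unbalanced genotype ...
        assert ls[g0] != pytest.approx(raw[g0], abs=1e-12)
        # ... and the LSMean equals the equal-weight mean of cell means
        cells = sub[sub["genotype"] == g0].groupby(
            ["environment", "treatment"]
        )["y"].mean()
        assert ls[g0] == pytest.approx(cells.mean(), abs=1e-9)

    def test_factor_combination_grid(self, small_design):
        rng = np.random.default_rng(4)
        lay = small_design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        fit = fit_split_plot(lay, "y", fix_theta=0.0)
        ls = lsmeans(fit, ("genotype", "environment"))
        assert len(ls) == small_design.n_genotypes * small_design.n_environments


class TestDunnett:
    def _fit(self, seed=5, shift=None, design=None):
        design = design or SplitPlotDesign(n_genotypes=6, blocks_per_plot=4)
        rng = np.random.default_rng(seed)
        lay = design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        if shift:
            genotype, amount = shift
            lay.loc[lay["genotype"] == genotype, "y"] += amount
        return fit_split_plot(lay, "y", fix_theta=0.0)

    def test_simulation_not_exceeding_bonferroni(self):
        fit = self._fit()
        sim = dunnett_vs_control(fit, method="simulation", reps=40_000, seed=9)
        bon = dunnett_vs_control(fit, method="bonferroni")
        assert (
            sim["p_adjusted"].to_numpy()
            <= bon["p_adjusted"].to_numpy() + 0.01
        ).all()

    def test_single_comparison_equals_raw_p(self):
        design = SplitPlotDesign(n_genotypes=2, blocks_per_plot=4)
        fit = self._fit(design=design)
        out = dunnett_vs_control(fit, method="bonferroni")
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(
            out["p_raw"].iloc[0]
        )

    def test_planted_shift_flagged(self):
        """A genotype moved by ~4 SE of a contrast is reliably detected."""
        # contrast SE here is sqrt(2/48) ~ 0.20, so 0.82 is ~4 SE
        hits = 0
        for rep in range(50):
            fit = self._fit(seed=100 + rep, shift=("myb29", 0.82))
            out = dunnett_vs_control(
                fit, method="simulation", reps=20_000, seed=rep
            )
            row = out[out["genotype"] == "myb29"]
            hits += float(row["p_adjusted"].iloc[0]) <= 0.05
        assert hits / 50 >= 0.9

    def test_missing_control_rejected(self):
        fit = self._fit()
        with pytest.raises(ValueError, match="control"):
            dunnett_vs_control(fit, control="nonexistent")


class TestTukey:
    def test_two_groups_equal_unadjusted_t(self):
        design = SplitPlotDesign(n_genotypes=2, blocks_per_plot=4)
        rng = np.random.default_rng(8)
        lay = design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        fit = fit_split_plot(lay, "y", fix_theta=0.0)
        pairs, _ = tukey_all_pairs(fit)
        t = pairs["t"].iloc[0]
        p_t = 2 * stats.t.sf(abs(t), fit.residual_df)
        assert pairs["p_adjusted"].iloc[0] == pytest.approx(p_t, rel=1e-4)

    def test_identical_means_share_one_letter(self):
        letters = compact_letter_display(["a", "b", "c"], [])
        assert len(set(letters.values())) == 1

    def test_extreme_group_gets_distinct_letter(self):
        design = SplitPlotDesign(n_genotypes=3, blocks_per_plot=4)
        rng = np.random.default_rng(10)
        lay = design.layout()
        lay["y"] = rng.standard_normal(len(lay))
        lay.loc[lay["genotype"] == "myb29", "y"] += 5.0
        fit = fit_split_plot(lay, "y", fix_theta=0.0)
        _, letters = tukey_all_pairs(fit)
        assert set(letters["myb29"]).isdisjoint(set(letters["Col-0"]))
        assert set(letters["myb29"]).isdisjoint(set(letters["myb28"]))


class TestEnvCorrelations:
    def _means(self, y1, y2, y3=None):
        envs = {"E1": y1, "E2": y2}
        if y3 is not None:
            envs["E3"] = y3
        frames = []
        for env, y in envs.items():
            frames.append(pd.DataFrame({
                "environment": env,
                "genotype": [f"g{i}" for i in range(len(y))],
                "y": y,
            }))
        df = pd.concat(frames)
        return df.set_index(["environment", "genotype"])["y"]

    def test_identical_environments_give_one(self):
        y = np.arange(10.0)
        out = env_correlations(self._means(y, y.copy()))
        assert out["R"].iloc[0] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        y = np.arange(10.0)
        out = env_correlations(self._means(y, -y))
        assert out["R"].iloc[0] == pytest.approx(-1.0)

    def test_independent_environments_average_near_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(500):
            out = env_correlations(
                self._means(rng.standard_normal(17), rng.standard_normal(17))
            )
            rs.append(out["R"].iloc[0])
        assert abs(np.mean(rs)) < 0.05
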