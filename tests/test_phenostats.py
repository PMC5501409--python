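"""Tests of phenotype adjustment, variance components, heritability, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from abqtl import phenostats, simpop
from abqtl.phenostats import (
    VarianceComponents,
    adjusted_line_means,
    anova,
    descriptive_stats,
    heritability,
    pearson_correlations,
    trait_ratio,
    variance_components,
)


def _long(records):
    return pd.DataFrame(records, columns=["line_id", "environment", "n_level", "trait", "value"])


class TestAdjustedLineMeans:
    def test_single_cell_equals_raw_observation(self):
        table = _long([("L1", "E1", "N0", "T", 4.2), ("L2", "E1", "N0", "T", 5.0)])
        means = adjusted_line_means(table)
        assert means.loc["L1", "T"] == pytest.approx(4.2)
        assert means.loc["L2", "T"] == pytest.approx(5.0)

    def test_balanced_equals_plain_average(self, toy_phenotypes):
        means = adjusted_line_means(toy_phenotypes)
        raw = toy_phenotypes.groupby("line_id")["value"].mean()
        np.testing.assert_allclose(means["T"].sort_index(), raw.sort_index())

    def test_environment_offset_absorbed(self, toy_phenotypes):
        """Adding a constant to one environment leaves line means unchanged."""
        shifted = toy_phenotypes.copy()
        shifted.loc[shifted["environment"] == "E2", "value"] += 7.5
        base = adjusted_line_means(toy_phenotypes)["T"]
        after = adjusted_line_means(shifted)["T"]
        np.testing.assert_allclose(after - base, np.full(len(base), 7.5 / 2))
        # contrasts between lines are untouched
        np.testing.assert_allclose(after - after.mean(), base - base.mean(), atol=1e-10)

    def test_unbalanced_matches_normal_equations_oracle(self):
        """One deleted cell: means equal the explicit least-squares solution."""
        table = _long([
            ("L1", "E1", "N0", "T", 10.0), ("L1", "E2", "N0", "T", 14.0),
            ("L2", "E1", "N0", "T", 11.0), ("L2", "E2", "N0", "T", 17.0),
            ("L3", "E1", "N0", "T", 9.0),  # (L3, E2) missing
        ])
        means = adjusted_line_means(table, scope="N0")
        # oracle: solve min ||y - L beta_L - E beta_E||^2 with explicit dummies
        y = np.array([10.0, 14.0, 11.0, 17.0, 9.0])
        X = np.array([
            # L1 L2 L3 E2
            [1, 0, 0, 0],
            [1, 0, 0, 1],
            [0, 1, 0, 0],
            [0, 1, 0, 1],
            [0, 0, 1, 0],
        ], dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        expect = beta[:3] + beta[3] / 2.0  # line effect + mean env effect
        np.testing.assert_allclose(
            means.loc[["L1", "L2", "L3"], "T"].to_numpy(), expect, atol=1e-10
        )

    def test_line_without_observations_absent(self):
        table = _long([
            ("L1", "E1", "N0", "T", 1.0), ("L2", "E1", "N1", "T", 2.0),
        ])
        means = adjusted_line_means(table, scope="N0")
        assert list(means.index) == ["L1"]


class TestTraitRatio:
    def test_identical_means_give_one(self):
        m = pd.Series([1.0, 2.0], index=["L1", "L2"])
        assert (trait_ratio(m, m) == 1.0).all()

    def test_low_to_high_nitrogen_ratio(self):
        """The grain-protein scale: mean 11.42 at N0 over 13.74 at N1 ~ 0.83."""
        n0 = pd.Series([11.42], index=["L1"])
        n1 = pd.Series([13.74], index=["L1"])
        assert trait_ratio(n0, n1).iloc[0] == pytest.approx(0.831, abs=5e-4)

    def test_zero_denominator_dropped_with_warning(self):
        n0 = pd.Series([1.0, 1.0], index=["L1", "L2"])
        n1 = pd.Series([0.0, 2.0], index=["L1", "L2"])
        with pytest.warns(UserWarning):
            out = trait_ratio(n0, n1)
        assert list(out.index) == ["L2"]

    def test_lines_missing_either_side_absent(self):
        n0 = pd.Series([1.0], index=["L1"])
        n1 = pd.Series([2.0, 3.0], index=["L1", "L2"])
        assert list(trait_ratio(n0, n1).index) == ["L1"]


class TestDescriptiveStats:
    def test_hand_computed(self):
        out = descriptive_stats(pd.Series([10.0, 12.0, 14.0]))
        assert out["mean"] == 12.0
        assert out["sd"] == pytest.approx(2.0)
        assert out["cv_percent"] == pytest.approx(100 * 2 / 12, abs=1e-9)
        assert (out["min"], out["max"]) == (10.0, 14.0)

    def test_constant_vector(self):
        out = descriptive_stats(pd.Series([3.0, 3.0, 3.0]))
        assert out["sd"] == 0.0 and out["cv_percent"] == 0.0
        assert out["min"] == out["max"] == out["mean"] == 3.0

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            descriptive_stats(pd.Series([1.0]))

    def test_sd_shift_invariance(self, rng):
        x = pd.Series(rng.normal(size=30))
        a = descriptive_stats(x)
        b = descriptive_stats(x + 100.0)
        assert b["sd"] == pytest.approx(a["sd"])


class TestCorrelations:
    def test_self_and_negated(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"a": x, "b": -x})
        corr = pearson_correlations(df)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError):
            pearson_correlations(df)

    def test_pleiotropic_qtl_induces_expected_correlation(self, small_map):
        """Two traits driven by one shared QTL with independent noise: the
        genetic correlation matches the generative value."""
        scheme = simpop.CrossingScheme(family_sizes={"D": 400, "T": 400})
        genotypes, families = simpop.simulate_population(scheme, small_map, rng=5)
        snp = genotypes.columns[100]
        config = simpop.PhenoModelConfig(
            trait_means={"A": 0.0, "B": 0.0},
            environment_effects={"E1": 0.0},
            n_level_effects={"N0": 0.0},
            v_g=0.0, v_gxe=0.0, v_gxn=0.0, v_r=1.0,
        )
        qtl = [
            simpop.PlantedQtl(snp, "A", 2.0),
            simpop.PlantedQtl(snp, "B", 2.0),
        ]
        table = simpop.simulate_phenotypes(genotypes, qtl, config, rng=6, families=families)
        means = adjusted_line_means(table)
        var_q = 4.0 * genotypes[snp].var(ddof=0)
        expected_r = var_q / (var_q + 1.0)
        got = pearson_correlations(means).loc["A", "B"]
        assert got == pytest.approx(expected_r, abs=0.08)


class TestVarianceComponents:
    def test_constant_response_gives_zeros(self, toy_phenotypes):
        t = toy_phenotypes.copy()
        t["value"] = 1.0
        vc = variance_components(t, "T", "across")
        assert (vc.v_g, vc.v_gxe, vc.v_gxn, vc.v_r) == (0, 0, 0, 0)

    def test_recovery_of_known_components(self):
        """(V_G, V_GxE, V_GxN, V_R) = (2, 1, 1, 2) at 359 x 3 x 2 is recovered
        within +-15% averaged over 50 seeds."""
        config = simpop.PhenoModelConfig(trait_means={"T": 0.0})
        idx = pd.Index([f"L{i}" for i in range(359)], name="line_id")
        genotypes = pd.DataFrame(np.zeros((359, 1)), index=idx, columns=["s0"])
        est = []
        for seed in range(50):
            table = simpop.simulate_phenotypes(genotypes, [], config, rng=seed)
            vc = variance_components(table, "T", "across")
            est.append([vc.v_g, vc.v_gxe, vc.v_gxn, vc.v_r])
        mean = np.mean(est, axis=0)
        np.testing.assert_allclose(mean, [2.0, 1.0, 1.0, 2.0], rtol=0.15)

    def test_zero_genetic_variance_gives_zero_heritability(self):
        config = simpop.PhenoModelConfig(trait_means={"T": 0.0}, v_g=0.0)
        idx = pd.Index([f"L{i}" for i in range(200)], name="line_id")
        genotypes = pd.DataFrame(np.zeros((200, 1)), index=idx, columns=["s0"])
        h2s = []
        for seed in range(10):
            table = simpop.simulate_phenotypes(genotypes, [], config, rng=seed)
            vc = variance_components(table, "T", "across")
            h2s.append(heritability(vc, "across"))
        # zero-truncation pins the estimate at exactly 0 whenever the V_G
        # moment estimate goes negative (~half the time under the null)
        assert sum(h == 0.0 for h in h2s) >= 5
        assert np.mean(h2s) < 0.1

    def test_degenerate_design_rejected(self):
        table = _long([("L1", "E1", "N0", "T", 1.0), ("L2", "E1", "N0", "T", 2.0)])
        with pytest.raises(ValueError):
            variance_components(table, "T", "across")


class TestHeritability:
    def test_boundaries(self):
        assert heritability(VarianceComponents(1.0, 0.0), "across") == 1.0
        assert heritability(VarianceComponents(0.0, 1.0), "across") == 0.0
        assert heritability(VarianceComponents(0.0, 0.0), "across") == 0.0

    def test_printed_across_formula(self):
        vc = VarianceComponents(v_g=2.0, v_r=2.0, v_gxe=1.0, v_gxn=1.0, e=3, n=2)
        assert heritability(vc, "across") == pytest.approx(
            2.0 / (2.0 + 1.0 / 3 + 1.0 / 2 + 2.0 / 6)
        )
        assert heritability(vc, "across") == pytest.approx(0.632, abs=5e-4)

    def test_within_formula(self):
        vc = VarianceComponents(v_g=1.0, v_r=3.0, e=3)
        assert heritability(vc, "within") == pytest.approx(0.5)

    @given(
        vg=st.floats(0.01, 50), vr=st.floats(0, 50),
        vge=st.floats(0, 50), vgn=st.floats(0, 50),
        e=st.integers(1, 5), n=st.integers(1, 3),
    )
    def test_bounded_and_monotone(self, vg, vr, vge, vgn, e, n):
        vc = VarianceComponents(vg, vr, vge, vgn, e=e, n=n)
        h = heritability(vc, "across")
        assert 0.0 <= h <= 1.0
        bigger_g = VarianceComponents(vg * 2, vr, vge, vgn, e=e, n=n)
        more_noise = VarianceComponents(vg, vr + 1, vge, vgn, e=e, n=n)
        assert heritability(bigger_g, "across") >= h
        assert heritability(more_noise, "across") <= h

    def test_entry_mean_convergence_without_interactions(self):
        """With zero interaction variances the across-N heritability converges
        to V_G / (V_G + V_R/(e n))."""
        config = simpop.PhenoModelConfig(
            trait_means={"T": 0.0}, v_g=1.0, v_gxe=0.0, v_gxn=0.0, v_r=3.0
        )
        idx = pd.Index([f"L{i}" for i in range(500)], name="line_id")
        genotypes = pd.DataFrame(np.zeros((500, 1)), index=idx, columns=["s0"])
        h2s = [
            heritability(
                variance_components(
                    simpop.simulate_phenotypes(genotypes, [], config, rng=s), "T", "across"
                ),
                "across",
            )
            for s in range(10)
        ]
        assert np.mean(h2s) == pytest.approx(1.0 / (1.0 + 3.0 / 6.0), abs=0.03)


class TestAnova:
    def test_balanced_two_group_f_statistic(self):
        """F for the line effect equals the hand-computed mean-square ratio."""
        table = _long([
            ("L1", "E1", "N0", "T", 1.0), ("L1", "E2", "N0", "T", 2.0),
            ("L2", "E1", "N0", "T", 5.0), ("L2", "E2", "N0", "T", 8.0),
        ])
        aov = anova(table, "T", "within")
        # grand mean 4; line means 1.5, 6.5; env means 3, 5
        ss_line = 2 * ((1.5 - 4) ** 2 + (6.5 - 4) ** 2)  # 25
        ss_env = 2 * ((3 - 4) ** 2 + (5 - 4) ** 2)  # 4
        ss_tot = (1 - 4) ** 2 + (2 - 4) ** 2 + (5 - 4) ** 2 + (8 - 4) ** 2  # 30
        ss_res = ss_tot - ss_line - ss_env  # 1
        f_hand = (ss_line / 1) / (ss_res / 1)
        assert aov.loc["C(line_id)", "F"] == pytest.approx(f_hand)

    def test_planted_genetic_variance_detected(self, small_population):
        genotypes, families = small_population
        config = simpop.PhenoModelConfig(trait_means={"T": 10.0}, v_g=5.0)
        table = simpop.simulate_phenotypes(genotypes, [], config, rng=2, families=families)
        aov = anova(table, "T", "across")
        assert aov.loc["C(line_id)", "p"] < 0.001
        assert aov.loc["C(n_level)", "p"] < 0.001

    def test_null_rejection_rate_near_alpha(self):
        """Pure-noise simulations reject the genotype effect at ~5%."""
        idx = pd.Index([f"L{i}" for i in range(25)], name="line_id")
        genotypes = pd.DataFrame(np.zeros((25, 1)), index=idx, columns=["s0"])
        config = simpop.PhenoModelConfig(
            trait_means={"T": 0.0}, v_g=0.0, v_gxe=0.0, v_gxn=0.0, v_r=1.0
        )
        pvals = []
        for seed in range(200):
            table = simpop.simulate_phenotypes(genotypes, [], config, rng=seed)
            aov = anova(table, "T", "within")
            pvals.append(float(aov.loc["C(line_id)", "p"]))
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= rate <= 0.09  # binomial envelope around 0.05, n=200
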