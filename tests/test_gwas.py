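"""Tests of cofactor selection, the per-SNP regression scan and Holm adjustment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from abqtl import gwas, simpop
from abqtl.gwas import (
    ModelSpec,
    declare_mtas,
    holm_adjust,
    model_applications,
    run_all_models,
    select_cofactors,
    snp_scan,
)


@pytest.fixture(scope="module")
def scan_population(small_map):
    scheme = simpop.CrossingScheme(family_sizes={"D84": 90, "T84": 110})
    genotypes, families = simpop.simulate_population(scheme, small_map, rng=41)
    return genotypes.astype(float), families


class TestModelSpec:
    def test_table_of_four_models(self):
        specs = model_applications(["D84", "T84"], ["N0", "N1"])
        ids = sorted((s.model_id, s.family_scope, s.n_scope) for s in specs)
        assert len(specs) == 9
        assert ids[0] == (1, "across", "across")
        assert sum(s.model_id == 4 for s in specs) == 4

    def test_ratio_traits_get_three_applications(self):
        specs = model_applications(["D84", "T84"], ["N0", "N1"], ratio=True)
        assert [(s.model_id, s.family_scope) for s in specs] == [
            (1, "across"), (2, "D84"), (2, "T84")
        ]

    def test_inconsistent_scope_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(1, family_scope="D84")
        with pytest.raises(ValueError):
            ModelSpec(4, family_scope="across", n_scope="N0")


class TestSelectCofactors:
    def test_strong_signal_selected_first(self, scan_population, small_map):
        """A SNP with effect 10x the noise SD is picked first (up to a tightly
        linked neighbour, which can carry an identical column) in every seed."""
        genotypes, _ = scan_population
        pos = pd.Series(small_map.positions, index=small_map.snp_ids)
        chrom = pd.Series(small_map.chromosomes, index=small_map.snp_ids)
        target = genotypes.columns[57]
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            y = 10.0 * genotypes[target] + rng.normal(0, 1.0, size=len(genotypes))
            sel = select_cofactors(genotypes, y)
            assert sel, "nothing selected despite overwhelming signal"
            first = sel[0]
            near = (chrom[first] == chrom[target]) and abs(pos[first] - pos[target]) <= 1.0
            hits += first == target or near
        assert hits >= 59  # >= ~99% success

    def test_null_selection_is_nearly_empty(self, scan_population):
        genotypes, _ = scan_population
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            y = pd.Series(rng.normal(size=len(genotypes)), index=genotypes.index)
            sizes.append(len(select_cofactors(genotypes, y)))
        assert np.mean(sizes) <= 1.0

    def test_duplicate_columns_selected_once(self, scan_population):
        genotypes, _ = scan_population
        dup = genotypes.iloc[:, :40].copy()
        dup["dup_of_first"] = dup.iloc[:, 0]
        rng = np.random.default_rng(3)
        y = 5.0 * dup.iloc[:, 0] + rng.normal(0, 1.0, size=len(dup))
        sel = select_cofactors(dup, y)
        assert not (dup.columns[0] in sel and "dup_of_first" in sel)


def _ols_oracle(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """Brute-force normal equations + t-test for coefficient j."""
    from scipy import stats

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    t = beta[j] / se
    return float(beta[j]), float(2 * stats.t.sf(abs(t), df))


class TestSnpScan:
    def test_noiseless_fit_recovers_slope(self, scan_population, small_map):
        genotypes, families = scan_population
        snp = genotypes.columns[10]
        y = 3.0 + 0.35 * genotypes[snp]
        spec = ModelSpec(2, family_scope="D84")
        sub = genotypes.loc[families == "D84"]
        scan = snp_scan(y.loc[sub.index], sub, families, small_map, [], spec)
        assert scan.loc[snp, "slope"] == pytest.approx(0.35, abs=1e-9)
        assert scan.loc[snp, "p_raw"] < 1e-12

    def test_matches_normal_equations_oracle(self, small_map):
        """Six-line fixture: slope and p equal the brute-force OLS + t-test."""
        idx = pd.Index([f"L{i}" for i in range(6)], name="line_id")
        dosages = pd.DataFrame(
            {small_map.snp_ids[0]: [0.0, 1.0, 2.0, 0.0, 2.0, 1.0],
             small_map.snp_ids[1]: [2.0, 0.0, 1.0, 1.0, 0.0, 2.0]},
            index=idx,
        )
        y = pd.Series([1.3, 2.1, 3.9, 1.1, 4.2, 2.4], index=idx)
        families = pd.Series(["D"] * 6, index=idx)
        spec = ModelSpec(2, family_scope="D")
        scan = snp_scan(y, dosages, families, small_map, [], spec)
        for snp in dosages.columns:
            X = np.column_stack([np.ones(6), dosages[snp].to_numpy()])
            slope, p = _ols_oracle(X, y.to_numpy(), 1)
            assert scan.loc[snp, "slope"] == pytest.approx(slope, abs=1e-10)
            assert scan.loc[snp, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_across_family_model_matches_oracle_with_family_terms(
        self, scan_population, small_map
    ):
        genotypes, families = scan_population
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(size=len(genotypes)), index=genotypes.index)
        snp = genotypes.columns[4]
        scan = snp_scan(y, genotypes[[snp]], families, small_map, [], ModelSpec(1))
        d = genotypes[snp].to_numpy()
        fam = (families == "T84").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(d)), d, d * fam, fam])
        slope, p = _ols_oracle(X, y.to_numpy(), 1)
        assert scan.loc[snp, "slope"] == pytest.approx(slope, abs=1e-10)
        assert scan.loc[snp, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_slope_invariant_to_constant_shift(self, scan_population, small_map):
        genotypes, families = scan_population
        rng = np.random.default_rng(12)
        y = pd.Series(rng.normal(size=len(genotypes)), index=genotypes.index)
        a = snp_scan(y, genotypes.iloc[:, :30], families, small_map, [], ModelSpec(1))
        b = snp_scan(y + 1000.0, genotypes.iloc[:, :30], families, small_map, [], ModelSpec(1))
        np.testing.assert_allclose(a["slope"], b["slope"], atol=1e-7)

    def test_null_p_values_uniform(self, small_map):
        """With y independent of all SNPs, raw p-values are uniform."""
        from scipy import stats

        scheme = simpop.CrossingScheme(family_sizes={"D84": 120, "T84": 120})
        genotypes, families = simpop.simulate_population(scheme, small_map, rng=77)
        rng = np.random.default_rng(78)
        y = pd.Series(rng.normal(size=len(genotypes)), index=genotypes.index)
        scan = snp_scan(y, genotypes.astype(float), families, small_map, [], ModelSpec(1))
        p = scan["p_raw"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_monomorphic_snp_skipped(self, small_map):
        idx = pd.Index([f"L{i}" for i in range(8)], name="line_id")
        dosages = pd.DataFrame({small_map.snp_ids[0]: np.zeros(8),
                                small_map.snp_ids[1]: [0, 1] * 4}, index=idx, dtype=float)
        y = pd.Series(np.arange(8.0), index=idx)
        families = pd.Series(["D"] * 8, index=idx)
        scan = snp_scan(y, dosages, families, small_map, [], ModelSpec(2, family_scope="D"))
        assert np.isnan(scan.iloc[0]["slope"])
        assert np.isfinite(scan.iloc[1]["slope"])

    def test_cofactor_exclusion_window(self, scan_population, small_map):
        """Cofactors within 1 cM (same chromosome) are dropped from a SNP's
        model; the tested SNP itself is always dropped if selected."""
        genotypes, families = scan_population
        rng = np.random.default_rng(4)
        snp = genotypes.columns[3]  # ~1 cM spacing: neighbours are within 1 cM
        neighbour = genotypes.columns[4]
        far = genotypes.columns[150]
        y = pd.Series(rng.normal(size=len(genotypes)), index=genotypes.index)
        cols = genotypes[[snp, neighbour, far]]
        with_cof = snp_scan(y, cols, families, small_map,
                            [snp, neighbour, far], ModelSpec(1))
        without = snp_scan(y, cols, families, small_map, [far], ModelSpec(1))
        # near cofactors (itself + neighbour) excluded -> identical fit
        assert with_cof.loc[snp, "slope"] == pytest.approx(without.loc[snp, "slope"])
        assert with_cof.loc[snp, "p_raw"] == pytest.approx(without.loc[snp, "p_raw"])


class TestHolmAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            holm_adjust(np.array([0.01, 0.02, 0.2])), [0.03, 0.04, 0.2]
        )

    def test_single_and_degenerate(self):
        assert holm_adjust(np.array([0.3]))[0] == 0.3
        assert (holm_adjust(np.ones(5)) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust(np.array([0.5, 1.5]))

    def test_matches_reference_implementation(self, rng):
        """Equal to statsmodels' Holm step-down on 1,000 random vectors."""
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            ref = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(200)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()


class TestDeclareMtas:
    def _scan_row(self, p_raw, slope=1.0):
        return pd.DataFrame(
            {"chromosome": ["1A"], "position_cM": [5.0], "slope": [slope],
             "p_raw": [p_raw], "r2_adj": [0.1]},
            index=pd.Index(["s"], name="snp_id"),
        )

    def test_threshold_is_strict(self):
        spec = ModelSpec(1)
        assert len(declare_mtas(self._scan_row(0.049), spec, "T")) == 1
        assert len(declare_mtas(self._scan_row(0.051), spec, "T")) == 0

    def test_exotic_effect_doubles_slope(self):
        out = declare_mtas(self._scan_row(0.001, slope=-4.49), ModelSpec(1), "GH")
        assert out["exotic_effect"].iloc[0] == pytest.approx(-8.98)


class TestRunAllModels:
    def test_application_counts_and_provenance(self, scan_population, small_map):
        genotypes, families = scan_population
        rng = np.random.default_rng(5)
        lines = genotypes.index
        means = {
            key: pd.DataFrame(
                {"T": rng.normal(size=len(lines)), "T_ratio": rng.normal(size=len(lines))},
                index=lines,
            )
            for key in ("across", "N0", "N1")
        }
        mta, scan = run_all_models(
            means, genotypes.iloc[:, :40], families, small_map,
            ratio_traits=["T_ratio"], return_scans=True,
        )
        apps = scan.groupby(["trait", "model", "family_scope", "n_scope"]).ngroups
        assert apps == 9 + 3
        n_ratio_apps = scan[scan.trait == "T_ratio"].groupby(
            ["model", "family_scope", "n_scope"]).ngroups
        assert n_ratio_apps == 3

    def test_planted_qtl_found_with_consistent_sign(self, scan_population, small_map):
        genotypes, families = scan_population
        snp = genotypes.columns[120]
        rng = np.random.default_rng(6)
        base = 0.6 * genotypes[snp]
        means = {
            key: pd.DataFrame(
                {"T": base + rng.normal(0, 0.4, size=len(base))}, index=genotypes.index
            )
            for key in ("across", "N0", "N1")
        }
        mta = run_all_models(means, genotypes, families, small_map)
        pos = pd.Series(small_map.positions, index=small_map.snp_ids)
        chrom = pd.Series(small_map.chromosomes, index=small_map.snp_ids)
        hits = mta[(mta.chromosome == chrom[snp]) & (abs(mta.position_cM - pos[snp]) <= 5)]
        assert len(hits) > 0
        assert (hits["exotic_effect"] > 0).all()
        across = hits[hits.family_scope == "across"]
        within = hits[hits.family_scope != "across"]
        assert len(across) > 0 and len(within) > 0

    def test_empty_output_when_nothing_significant(self, scan_population, small_map):
        genotypes, families = scan_population
        rng = np.random.default_rng(9)
        means = {
            key: pd.DataFrame({"T": rng.normal(size=len(genotypes))}, index=genotypes.index)
            for key in ("across", "N0", "N1")
        }
        mta = run_all_models(means, genotypes.iloc[:, :30], families, small_map,
                             alpha=1e-6)
        assert len(mta) == 0
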