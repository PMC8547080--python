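"""Root-to-tip omega, PGLS, the two-step calibration and phylANOVA."""

import numpy as np
import pandas as pd
import pytest

from omegatrait import simulate as sim
from omegatrait.association import (
    calibrated_association,
    pgls_fit,
    phyl_anova,
    root_to_tip_omega,
)
from omegatrait.codon_model import BranchRates
from omegatrait.trees_io import brownian_covariance, parse_newick


def make_branch_rates(tree, omega, dN=1e-3, dS=1e-3):
    """Hand-built BranchRates table for root-to-tip tests."""
    rows = {}
    for v in tree.branch_indices():
        rows[v] = {
            "omega": omega.get(v, 0.2) if isinstance(omega, dict) else omega,
            "t": float(tree.length[v]),
            "dN": dN[v] if isinstance(dN, dict) else dN,
            "dS": dS[v] if isinstance(dS, dict) else dS,
            "reliable": True,
        }
    return BranchRates(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        kappa=2.0, pi=np.full(61, 1 / 61), lnL=0.0,
    )


class TestRootToTip:
    def test_arithmetic_mean(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        a_path = tree.root_to_tip_nodes("A")
        omega = {a_path[0]: 0.2, a_path[1]: 0.4}
        rates = make_branch_rates(tree, omega)
        out = root_to_tip_omega(rates, tree)
        assert out.loc["A", "omega"] == pytest.approx(0.3)
        assert out.loc["A", "n_branches"] == 2

    def test_low_rate_branch_excluded(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        a_path = tree.root_to_tip_nodes("A")
        omega = {a_path[0]: 0.2, a_path[1]: 0.8}
        dS = {v: 1e-3 for v in tree.branch_indices()}
        dS[a_path[1]] = 1e-4  # below the 2e-4 floor
        rates = make_branch_rates(tree, omega, dS=dS)
        out = root_to_tip_omega(rates, tree)
        assert out.loc["A", "omega"] == pytest.approx(0.2)
        assert out.loc["A", "n_excluded"] == 1

    def test_all_filtered_missing(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        rates = make_branch_rates(tree, 0.3, dN=1e-5)
        out = root_to_tip_omega(rates, tree)
        assert np.isnan(out["omega"]).all()

    def test_zero_floor_equals_plain_mean(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        omega = {v: 0.1 * (i + 1) for i, v in enumerate(tree.branch_indices())}
        rates = make_branch_rates(tree, omega, dN=0.0, dS=0.0)
        out = root_to_tip_omega(rates, tree, min_rate=0.0)
        for sp in tree.tip_labels:
            expected = np.mean([omega[v] for v in tree.root_to_tip_nodes(sp)])
            assert out.loc[sp, "omega"] == pytest.approx(expected)


def whitened_ols_oracle(y, x, C):
    """Independent route: explicit GLS normal equations via matrix inverses."""
    Ci = np.linalg.inv(C)
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ Ci @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ Ci @ X)
    from scipy.stats import t as tdist

    t_stat = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * tdist.sf(abs(t_stat), n - 2)
    return beta[1], float(t_stat), float(p)


class TestPgls:
    def test_identity_covariance_equals_ols(self, rng):
        import statsmodels.api as sm

        n = 12
        x = pd.Series(rng.random(n), index=[f"s{i}" for i in range(n)])
        y = pd.Series(rng.random(n), index=x.index)
        C = pd.DataFrame(np.eye(n), index=x.index, columns=x.index)
        fit = pgls_fit(y, x, C)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.p == pytest.approx(ols.pvalues[1], abs=1e-10)

    def test_matches_gls_oracle(self, rng):
        for seed in range(5):
            tree = sim.simulate_tree(10, seed=seed, depth=1.0)
            C = brownian_covariance(tree)
            sp = list(C.index)
            x = pd.Series(rng.random(10), index=sp)
            y = pd.Series(rng.random(10), index=sp)
            fit = pgls_fit(y, x, C)
            slope, t_stat, p = whitened_ols_oracle(
                y.to_numpy(), x.to_numpy(), C.to_numpy()
            )
            assert fit.slope == pytest.approx(slope, abs=1e-8)
            assert fit.t_stat == pytest.approx(t_stat, abs=1e-8)
            assert fit.p == pytest.approx(p, abs=1e-8)

    def test_perfect_fit(self):
        sp = list("abcdef")
        x = pd.Series(np.arange(6, dtype=float), index=sp)
        y = 2.0 * x + 1.0
        C = pd.DataFrame(np.eye(6), index=sp, columns=sp)
        fit = pgls_fit(y, x, C)
        assert fit.slope == pytest.approx(2.0)
        assert fit.p < 1e-12

    def test_slope_invariant_under_shift(self, rng):
        tree = sim.simulate_tree(8, seed=2, depth=1.0)
        C = brownian_covariance(tree)
        sp = list(C.index)
        x = pd.Series(rng.random(8), index=sp)
        y = pd.Series(rng.random(8), index=sp)
        f1 = pgls_fit(y, x, C)
        f2 = pgls_fit(y + 7.5, x, C)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-10)
        assert f1.p == pytest.approx(f2.p, abs=1e-10)

    def test_too_few_species(self):
        sp = list("abc")
        s = pd.Series([1.0, 2, 3], index=sp)
        C = pd.DataFrame(np.eye(3), index=sp, columns=sp)
        with pytest.raises(ValueError, match="at least 4"):
            pgls_fit(s, s, C)


@pytest.fixture(scope="module")
def setup():
    tree = sim.simulate_tree(20, seed=42, depth=100.0)
    pheno = sim.assign_clade_phenotypes(tree, n_idt=4, n_udt=4)
    y = pheno.encode("two_class")
    C = brownian_covariance(tree, labels=list(y.index))
    return tree, pheno, y, C


class TestCalibration:
    def test_p_max_dominates_loo(self, setup):
        tree, _, y, C = setup
        tab, _ = sim.simulate_trait_rate_dataset(
            tree, y, n_genes=5, signal_fraction=0.4, seed=0
        )
        for g in tab.index:
            res = calibrated_association(g, tab.loc[g], y, C)
            assert res.loo_pvalues
            assert res.p_max >= max(res.loo_pvalues.values()) - 1e-15
            assert res.p_max == pytest.approx(max(res.loo_pvalues.values()))

    def test_outlier_driven_association_rejected(self, setup):
        tree, _, _, C = setup
        pheno = sim.assign_clade_phenotypes(tree, n_idt=3, n_udt=1)
        y3 = pheno.encode("three_class")
        udt = sorted(pheno.foreground_species("UDT"))[0]
        tab, _ = sim.simulate_trait_rate_dataset(
            tree, y3, n_genes=12, signal_fraction=1.0, effect_size=0.15,
            noise_sd=0.05, seed=3, outlier_species=udt,
        )
        C3 = C.loc[y3.index, y3.index]
        results = [calibrated_association(g, tab.loc[g], y3, C3) for g in tab.index]
        hits = [r for r in results if r.p_all < 0.05]
        assert hits, "outlier construction should produce p_all significance"
        assert all(not r.significant for r in hits)
        # the worst leave-one-out refit excludes the planted outlier
        assert sum(r.max_dropped == udt for r in hits) >= len(hits) * 0.8

    def test_constant_response_not_significant(self, setup):
        tree, _, y, C = setup
        x = pd.Series(
            np.linspace(0.1, 0.5, len(y)), index=y.index
        )
        res = calibrated_association("g", x, y * 0.0, C)
        assert not res.significant
        assert res.p_all > 0.5

    def test_insufficient_species_skipped(self, setup):
        tree, _, y, C = setup
        x = pd.Series(np.nan, index=y.index)
        x.iloc[:3] = 0.2
        res = calibrated_association("g", x, y, C)
        assert res.skipped_reason
        assert not res.significant


class TestPhylAnova:
    def test_constant_values(self, fixture_tree, fixture_phenotypes):
        y = fixture_phenotypes.encode("two_class")
        groups = pd.Series(fixture_phenotypes.class2)
        values = pd.Series(5.0, index=y.index)
        F, p = phyl_anova(fixture_tree, values, groups, nsim=200, seed=0)
        assert F == 0.0
        assert p > 0.9

    def test_small_group_rejected(self, fixture_tree):
        values = pd.Series(1.0, index=fixture_tree.tip_labels)
        groups = pd.Series("a", index=fixture_tree.tip_labels)
        groups.iloc[0] = "b"
        with pytest.raises(ValueError, match="fewer than 2"):
            phyl_anova(fixture_tree, values, groups, nsim=100, seed=0)

    def test_seeded_reproducible(self, fixture_tree, fixture_phenotypes, rng):
        groups = pd.Series(fixture_phenotypes.class2)
        values = pd.Series(
            rng.normal(size=len(groups)), index=groups.index
        )
        r1 = phyl_anova(fixture_tree, values, groups, nsim=300, seed=7)
        r2 = phyl_anova(fixture_tree, values, groups, nsim=300, seed=7)
        assert r1 == r2

    def test_strong_shift_detected(self, fixture_tree, fixture_phenotypes, rng):
        groups = pd.Series(fixture_phenotypes.class3)
        values = pd.Series(rng.normal(100, 5, size=len(groups)), index=groups.index)
        values[groups == "IDT"] += 60.0
        F, p = phyl_anova(fixture_tree, values, groups, nsim=500, seed=1)
        assert p < 0.05
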