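"""Codon model likelihoods, fits, LRT/BH machinery and decision rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2

import omegatrait.codon_model as cm
from omegatrait import simulate as sim
from omegatrait.trees_io import CODON_INDEX, SENSE_CODONS, label_branches, parse_newick


def enumeration_loglik(aln, tree, params):
    """Exhaustive marginalization over all internal-node states (<= 3 taxa).

    Independent of the pruning code path: builds transition matrices with
    scipy.linalg.expm and sums the 61^k internal-state combinations.
    """
    from scipy.linalg import expm

    Q = {}
    for v in tree.branch_indices():
        Q[v] = expm(
            cm.build_rate_matrix(params.kappa, params.branch_omega[v], params.pi)
            * params.t[v]
        )
    tips = {tree.tip_index(t): r for r, t in enumerate(aln.taxa)}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    total = 0.0
    for s in range(aln.n_codons):
        like = 0.0
        states = {v: aln.codons[r, s] for v, r in tips.items()}
        import itertools

        for combo in itertools.product(range(61), repeat=len(internal)):
            assign = dict(zip(internal, combo))
            assign.update(states)
            term = params.pi[assign[tree.root]]
            for v in tree.branch_indices():
                term *= Q[v][assign[tree.parent[v]], assign[v]]
            like += term
        total += np.log(like)
    return total


class TestRateMatrix:
    def test_symmetric_limit_uniform(self):
        Q = cm.build_rate_matrix(1.0, 1.0, np.full(61, 1 / 61), scale=False)
        off = Q[~np.eye(61, dtype=bool)]
        nz = off[off > 0]
        assert np.allclose(nz, nz[0])
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_multi_step_zero(self):
        Q = cm.build_rate_matrix(2.0, 0.5, np.full(61, 1 / 61))
        assert Q[CODON_INDEX["TTT"], CODON_INDEX["GGG"]] == 0.0

    def test_synonymous_transition_rate(self):
        # TTT -> TTC is a synonymous transition: unscaled rate = kappa * pi_j
        Q = cm.build_rate_matrix(2.0, 0.7, np.full(61, 1 / 61), scale=False)
        assert Q[CODON_INDEX["TTT"], CODON_INDEX["TTC"]] == pytest.approx(2 / 61)

    def test_scaled_mean_rate_is_one(self):
        pi = np.random.default_rng(0).dirichlet(np.ones(61))
        Q = cm.build_rate_matrix(3.0, 0.2, pi)
        assert -float(pi @ np.diag(Q)) == pytest.approx(1.0, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            cm.build_rate_matrix(2.0, 0.5, np.ones(60) / 60)

    @pytest.mark.parametrize("t", [1e-6, 0.01, 0.5, 5.0])
    def test_transition_rows_sum_to_one(self, t):
        model = cm.CodonRateModel(2.5, 0.4, np.full(61, 1 / 61))
        P = model.transition_matrix(t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= 0


class TestLikelihood:
    def test_single_taxon_closed_form(self):
        aln = sim.CodonAlignment.from_sequences({"A": "ATGAAATTT"})
        tree = parse_newick("(A:1);")
        pi = np.random.default_rng(1).dirichlet(np.ones(61))
        params = cm.CodonModelParams(2.0, pi, {v: 0.5 for v in tree.branch_indices()},
                                     np.array([0.0, 1.0]))
        expected = sum(np.log(pi[CODON_INDEX[c]]) for c in ("ATG", "AAA", "TTT"))
        assert cm.log_likelihood(aln, tree, params) == pytest.approx(expected, abs=1e-10)

    def test_two_taxon_direct_formula(self):
        from scipy.linalg import expm

        tree = parse_newick("(A:0.1,B:0.3);")
        aln, _ = sim.simulate_codon_alignment(tree, 0.4, n_codons=30, seed=2)
        pi = np.full(61, 1 / 61)
        bo = {v: 0.4 for v in tree.branch_indices()}
        t = np.zeros(tree.n_nodes)
        for v in tree.branch_indices():
            t[v] = tree.length[v]
        params = cm.CodonModelParams(2.0, pi, bo, t)
        Q = cm.build_rate_matrix(2.0, 0.4, pi)
        PA = expm(Q * tree.length[tree.tip_index("A")])
        PB = expm(Q * tree.length[tree.tip_index("B")])
        a = aln.codons[aln.taxa.index("A")]
        b = aln.codons[aln.taxa.index("B")]
        direct = sum(
            np.log((pi * PA[:, ca] * PB[:, cb]).sum()) for ca, cb in zip(a, b)
        )
        assert cm.log_likelihood(aln, tree, params) == pytest.approx(direct, abs=1e-8)

    def test_pruning_matches_enumeration_three_taxa(self):
        tree = parse_newick("((A:0.2,B:0.1):0.15,C:0.3);")
        aln, _ = sim.simulate_codon_alignment(tree, 0.5, n_codons=10, seed=3)
        pi = np.random.default_rng(4).dirichlet(np.ones(61) * 5)
        t = np.zeros(tree.n_nodes)
        for v in tree.branch_indices():
            t[v] = tree.length[v]
        params = cm.CodonModelParams(1.7, pi, {v: 0.5 for v in tree.branch_indices()}, t)
        assert cm.log_likelihood(aln, tree, params) == pytest.approx(
            enumeration_loglik(aln, tree, params), abs=1e-6
        )

    def test_missing_data_all_ones(self):
        # a fully missing taxon contributes nothing: lnL equals the reduced tree's
        tree = parse_newick("(A:0.1,B:0.2);")
        aln = sim.CodonAlignment.from_sequences({"A": "ATGAAA", "B": "NNNNNN"})
        pi = np.full(61, 1 / 61)
        t = np.zeros(tree.n_nodes)
        for v in tree.branch_indices():
            t[v] = tree.length[v]
        params = cm.CodonModelParams(2.0, pi, {v: 0.3 for v in tree.branch_indices()}, t)
        expected = 2 * np.log(1 / 61)  # marginal of two uniform-pi codons
        assert cm.log_likelihood(aln, tree, params) == pytest.approx(expected, abs=1e-10)


class TestFits:
    def test_nesting_order(self, small_tree, small_alignment):
        lab = label_branches(small_tree, {"sp01", "sp02"})
        one = cm.fit_one_ratio(small_alignment, lab)
        two = cm.fit_two_ratio(small_alignment, lab, one_ratio=one)
        free = cm.fit_free_ratio(small_alignment, lab, one_ratio=one)
        assert two.lnL >= one.lnL - 1e-4
        assert free.lnL >= two.lnL - 1e-4

    def test_all_foreground_collapses_to_one_ratio(self, small_tree, small_alignment):
        lab = label_branches(small_tree, set(small_tree.tip_labels))
        one = cm.fit_one_ratio(small_alignment, lab)
        two = cm.fit_two_ratio(small_alignment, lab, one_ratio=one)
        assert two.lnL == pytest.approx(one.lnL, abs=1e-4)

    def test_zero_length_branch_rates(self):
        dN, dS = cm.branch_dn_ds(2.0, 0.5, np.full(61, 1 / 61), 0.0)
        assert (dN, dS) == (0.0, 0.0)

    def test_neutral_dn_equals_ds(self):
        dN, dS = cm.branch_dn_ds(2.0, 1.0, np.full(61, 1 / 61), 0.3)
        assert dN == pytest.approx(dS, rel=1e-12)
        assert dN > 0

    def test_lethal_omega_zero_dn(self):
        dN, dS = cm.branch_dn_ds(2.0, 0.0, np.full(61, 1 / 61), 0.3)
        assert dN == 0.0
        assert dS > 0

    def test_dnds_ratio_recovers_omega(self):
        for omega in (0.1, 0.5, 2.0):
            dN, dS = cm.branch_dn_ds(2.0, omega, np.full(61, 1 / 61), 0.2)
            assert dN / dS == pytest.approx(omega, rel=1e-6)

    def test_free_ratio_table_invariants(self, small_tree, small_alignment):
        rates = cm.fit_free_ratio(small_alignment, small_tree)
        tab = rates.table
        assert (tab["dN"] >= 0).all() and (tab["dS"] >= 0).all()
        pos = tab["dS"] > 0
        assert np.allclose(
            tab.loc[pos, "omega"], tab.loc[pos, "dN"] / tab.loc[pos, "dS"], atol=1e-6
        )


@pytest.fixture(scope="module")
def labeled(small_tree):
    return label_branches(small_tree, {"sp01", "sp02"})


@pytest.fixture(scope="module")
def fits(labeled, small_alignment):
    one = cm.fit_one_ratio(small_alignment, labeled)
    null = cm.fit_branch_site(small_alignment, labeled, "null", one_ratio=one)
    alt = cm.fit_branch_site(small_alignment, labeled, "alternative", one_ratio=one)
    return one, null, alt


class TestBranchSite:
    def test_alternative_nests_null(self, fits):
        one, null, alt = fits
        assert alt.lnL >= null.lnL - 1e-4

    def test_posteriors_sum_to_one(self, fits, small_alignment):
        post = cm.site_posteriors(fits[2])
        assert post.class_posterior.shape == (small_alignment.n_codons, 4)
        assert np.allclose(post.class_posterior.sum(axis=1), 1.0, atol=1e-8)
        assert np.all((post.positive >= 0) & (post.positive <= 1))

    def test_class0_component_is_one_ratio_likelihood(self, fits, labeled, small_alignment):
        """Mixture collapse: the class-0 site likelihoods equal a plain
        one-ratio model at (kappa, omega0) with the same branch lengths."""
        one, _, alt = fits
        ll0 = alt.extras["class_site_loglik"][0]
        w = alt.extras["pattern_weights"]
        params = cm.CodonModelParams(
            one.params.kappa, one.params.pi,
            {v: alt.extras["omega0"] for v in labeled.branch_indices()},
            one.params.t,
        )
        assert float(w @ ll0) == pytest.approx(
            cm.log_likelihood(small_alignment, labeled, params), abs=1e-6
        )

    def test_requires_foreground(self, small_tree, small_alignment):
        with pytest.raises(ValueError, match="foreground"):
            cm.fit_branch_site(small_alignment, small_tree, "alternative")


class TestLRT:
    def test_chi_square_tail(self):
        res = cm.lrt(-100.0, -98.0, df=1)
        assert res.stat == pytest.approx(4.0)
        assert res.p == pytest.approx(chi2.sf(4.0, 1), abs=1e-12)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_equal_likelihoods(self):
        assert cm.lrt(-50.0, -50.0, df=1).p == 1.0

    def test_negative_stat_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = cm.lrt(-50.0, -50.1, df=1)
        assert res.stat == 0.0
        assert res.p == 1.0


def brute_force_bh(pvals):
    """Step-up definition: p_(i) * m / i, then min over suffix, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_example(self):
        adj = cm.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force(self, pvals):
        assert np.allclose(cm.bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        direct = cm.bh_adjust(pvals)
        permuted = cm.bh_adjust([pvals[i] for i in perm])
        assert np.allclose([direct[i] for i in perm], permuted, atol=1e-12)

    def test_monotone_and_geq_raw(self, rng):
        p = rng.random(30)
        adj = cm.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestRegRule:
    def test_elevated_clause(self):
        is_reg, clause = cm.classify_reg(0.6, 0.4, 0.01)
        assert is_reg and clause == "elevated"

    def test_ratio_clause(self):
        is_reg, clause = cm.classify_reg(0.3, 0.05, 0.01)
        assert is_reg and clause == "ratio"

    def test_fails_both_clauses(self):
        assert cm.classify_reg(0.4, 0.3, 0.01) == (False, None)

    def test_not_significant_blocks(self):
        assert cm.classify_reg(0.6, 0.05, 0.2)[0] is False

    def test_boundaries_strict(self):
        # ratio exactly 5 and omega_fg exactly 0.5 do NOT fire
        assert cm.classify_reg(0.25, 0.05, 0.01)[0] is False
        assert cm.classify_reg(0.5, 0.1, 0.01)[0] is False
        assert cm.classify_reg(0.5, 0.4, 0.01)[0] is False

    def test_zero_background(self):
        is_reg, clause = cm.classify_reg(0.1, 0.0, 0.01)
        assert is_reg and "ratio" in clause
        assert cm.classify_reg(0.0, 0.0, 0.01)[0] is False


class TestPsgRule:
    def test_requires_both_gates(self):
        post = cm.SiteClassPosterior(
            class_posterior=np.array([[0.05, 0.05, 0.5, 0.4], [0.7, 0.2, 0.05, 0.05]]),
            positive=np.array([0.9, 0.1]),
        )
        assert cm.classify_psg(0.01, post) == (True, [1])
        assert cm.classify_psg(0.2, post) == (False, [1])
        weak = cm.SiteClassPosterior(
            class_posterior=np.array([[0.3, 0.3, 0.2, 0.2]]), positive=np.array([0.4])
        )
        assert cm.classify_psg(0.01, weak) == (False, [])
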