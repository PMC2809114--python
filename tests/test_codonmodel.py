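"""GY94 rate matrices, pruning likelihoods, model fits and LRTs."""

import numpy as np
import pytest

import oracles
from batrh1 import synthetic_data as synth
from batrh1.codonseq import CodonAlignment, standard_code
from batrh1.codonmodel import (
    ModelError,
    Propagator,
    build_q,
    f3x4_frequencies,
    fit_model,
    log_likelihood,
    lrt,
    site_posteriors,
)
from batrh1.treebuild import read_newick


@pytest.fixture(scope="module")
def code():
    return standard_code()


@pytest.fixture(scope="module")
def uniform_pi():
    return np.full(61, 1.0 / 61)


def neighbor_table(code):
    """Brute-force single-nucleotide neighbor enumeration."""
    sense = code.sense_codons
    out = {}
    for i, a in enumerate(sense):
        for j, b in enumerate(sense):
            diffs = [p for p in range(3) if a[p] != b[p]]
            if len(diffs) == 1:
                p = diffs[0]
                out[(i, j)] = (
                    {a[p], b[p]} in ({"A", "G"}, {"C", "T"}),
                    code.codon_to_aa[a] == code.codon_to_aa[b],
                )
    return out


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous_rates(self, code, uniform_pi):
        Q = build_q(2.0, 0.0, uniform_pi, code)
        for (i, j), (_, syn) in neighbor_table(code).items():
            if not syn:
                assert Q[i, j] == 0.0

    def test_neutral_uniform_rates_match_neighbor_enumeration(self, code, uniform_pi):
        Q = build_q(1.0, 1.0, uniform_pi, code)
        nbr = neighbor_table(code)
        vals = {Q[i, j] for (i, j) in nbr}
        assert len(vals) == 1  # every single-nt neighbor equally likely
        # non-neighbors are zero
        mask = np.ones((61, 61), bool)
        np.fill_diagonal(mask, False)
        for (i, j) in nbr:
            mask[i, j] = False
        assert np.all(Q[mask] == 0.0)

    def test_rows_sum_to_zero_and_scaling(self, code):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q = build_q(3.0, 0.4, pi, code)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)

    def test_detailed_balance(self, code):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61) * 2)
        Q = build_q(2.5, 0.7, pi, code)
        F = pi[:, None] * Q
        assert np.allclose(F, F.T, atol=1e-14)

    def test_parameter_validation(self, uniform_pi):
        with pytest.raises(ModelError):
            build_q(-1.0, 0.5, uniform_pi)
        with pytest.raises(ModelError):
            build_q(2.0, 0.5, uniform_pi * 0.5)


class TestPropagator:
    @pytest.mark.parametrize("t", [0.0, 0.01, 0.5, 3.0, 10.0])
    def test_rows_sum_to_one_and_nonnegative(self, code, t):
        rng = np.random.default_rng(7)
        pi = rng.dirichlet(np.ones(61) * 3)
        P = Propagator(build_q(2.0, 0.3, pi, code), pi).expm(t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= 0.0

    def test_identity_at_zero(self, code, uniform_pi):
        P = Propagator(build_q(2.0, 0.3, uniform_pi, code), uniform_pi).expm(0.0)
        assert np.allclose(P, np.eye(61), atol=1e-12)

    def test_stationarity(self, code):
        rng = np.random.default_rng(8)
        pi = rng.dirichlet(np.ones(61) * 3)
        P = Propagator(build_q(2.0, 0.3, pi, code), pi).expm(0.7)
        assert np.allclose(pi @ P, pi, atol=1e-12)


class TestLikelihood:
    def test_identical_pair_zero_branches(self, code):
        aln = CodonAlignment(["a", "b"], ["ATG", "ATG"])
        tree = read_newick("(a:0,b:0);")
        pi = np.zeros(61)
        pi[code.codon_index["ATG"]] = 1.0
        assert log_likelihood(aln, tree, kappa=2.0, omega=1.0, pi=pi) == 0.0

    @pytest.mark.parametrize(
        "nwk,n_internal",
        [
            ("(a:0.1,b:0.25,c:0.4);", 1),
            ("((a:0.1,b:0.2):0.15,c:0.12,d:0.3);", 2),
            ("((a:0.1,b:0.2):0.15,(c:0.12,(d:0.3,e:0.05):0.2):0.08);", 3),
        ],
    )
    def test_pruning_equals_exhaustive_enumeration(self, code, nwk, n_internal):
        """Pruning lnL equals explicit summation over all internal-state
        assignments (61^k terms) on topologies with <= 3 internal nodes."""
        rng = np.random.default_rng(n_internal)
        pi = rng.dirichlet(np.ones(61) * 5)
        kappa, omega = float(rng.uniform(1, 4)), float(rng.uniform(0.05, 2))
        spec = synth.SimSpec(tree=nwk, n_codons=2, kappa=kappa, omega=omega,
                             seed=n_internal + 40)
        aln, truth = synth.simulate_alignment(spec)
        tree = truth.tree
        got = log_likelihood(aln, tree, kappa=kappa, omega=omega, pi=pi)

        prop = Propagator(build_q(kappa, omega, pi, code), pi)
        P = {}
        spec_tree = {}

        def build(nd):
            if nd.is_leaf():
                return nd.taxon.label
            return tuple(
                (build(c), id(c)) for c in nd.child_nodes()
            )

        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                P[id(nd)] = prop.expm(nd.edge.length).tolist()
        tspec = build(tree.seed_node)
        total = 0.0
        for site in range(1, aln.n_codons + 1):
            leaf_states = {
                t: code.codon_index[aln.codon(i, site)]
                for i, t in enumerate(aln.taxa)
            }
            total += oracles.enumerate_tree_loglike(
                tspec, P, pi.tolist(), leaf_states
            )
        assert got == pytest.approx(total, abs=1e-10)

    def test_wrong_omega_lowers_likelihood(self):
        spec = synth.SimSpec(
            tree="((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);",
            n_codons=400, kappa=2.0, omega=0.1, seed=3,
        )
        aln, truth = synth.simulate_alignment(spec)
        at_true = log_likelihood(aln, truth.tree, kappa=2.0, omega=0.1)
        at_wrong = log_likelihood(aln, truth.tree, kappa=2.0, omega=2.0)
        assert at_true > at_wrong

    def test_missing_taxon_error(self):
        aln = CodonAlignment(["a", "b"], ["ATG", "ATG"])
        with pytest.raises(ModelError, match="c"):
            log_likelihood(aln, read_newick("(a:0.1,b:0.1,c:0.1);"),
                           kappa=2.0, omega=1.0)


@pytest.fixture(scope="module")
def m0_data():
    spec = synth.SimSpec(
        tree="((a:0.15,b:0.15):0.08,(c:0.15,d:0.15):0.08,(e:0.15,f:0.15):0.08);",
        n_codons=200, kappa=2.0, omega=0.15, seed=17,
    )
    aln, truth = synth.simulate_alignment(spec)
    return aln, truth.tree


class TestFits:
    def test_free_ratio_constrained_matches_m0(self, m0_data):
        """The free-ratio likelihood at equal branch omegas equals M0's."""
        aln, tree = m0_data
        m0 = fit_model(aln, tree, "M0", n_starts=1, seed=2)
        free_at_m0 = log_likelihood(
            aln, m0.tree, kappa=m0.kappa,
            omega={lab: m0.omega for lab in m0.branch_lengths},
        )
        assert free_at_m0 == pytest.approx(m0.lnL, abs=1e-8)

    def test_nesting_m2a_at_least_m1a(self, m0_data):
        aln, tree = m0_data
        m1a = fit_model(aln, tree, "M1a", n_starts=1, seed=4)
        m2a = fit_model(aln, tree, "M2a", n_starts=1, seed=4, init=m1a)
        assert m2a.lnL >= m1a.lnL - 1e-6
        assert m2a.n_params - m1a.n_params == 2
        assert m1a.proportions.sum() == pytest.approx(1.0)
        assert 0 < m1a.site_class_omegas[0] < 1
        assert m1a.site_class_omegas[1] == 1.0

    def test_two_ratio_and_fixed_null(self, m0_data):
        aln, tree = m0_data
        fg = [frozenset({"a", "b"})]
        alt = fit_model(aln, tree, "two_ratio", foreground_branches=fg,
                        n_starts=1, seed=5)
        null = fit_model(aln, tree, "two_ratio", foreground_branches=fg,
                         fixed_params={"omega_fg": 1.0}, n_starts=1, seed=5)
        assert alt.n_params - null.n_params == 1
        assert alt.lnL >= null.lnL - 1e-6
        r = lrt(null, alt)
        assert r.df == 1 and 0 <= r.p_value <= 1

    def test_branch_site_null_nested(self, m0_data):
        aln, tree = m0_data
        fg = [frozenset({"a", "b"})]
        null = fit_model(aln, tree, "branch_site_A_null",
                         foreground_branches=fg, n_starts=1, seed=6)
        alt = fit_model(aln, tree, "branch_site_A", foreground_branches=fg,
                        n_starts=1, seed=6, init=null)
        assert alt.n_params - null.n_params == 1
        assert alt.lnL >= null.lnL - 1e-6
        assert null.proportions.sum() == pytest.approx(1.0)

    def test_m8_nests_m8a(self, m0_data):
        aln, tree = m0_data
        m8a = fit_model(aln, tree, "M8a", n_starts=1, seed=7)
        m8 = fit_model(aln, tree, "M8", n_starts=1, seed=7, init=m8a)
        assert m8.n_params - m8a.n_params == 1
        assert m8.lnL >= m8a.lnL - 1e-6
        assert m8a.omega_s == 1.0 and len(m8a.site_class_omegas) == 11
        assert m8.proportions.sum() == pytest.approx(1.0)

    def test_foreground_required(self, m0_data):
        aln, tree = m0_data
        with pytest.raises(ModelError):
            fit_model(aln, tree, "two_ratio", n_starts=1, seed=0)


class TestLRT:
    def test_equal_likelihoods(self, m0_data):
        aln, tree = m0_data
        f = fit_model(aln, tree, "M0", n_starts=1, seed=1)
        null = type(f)(**{**f.__dict__})
        null.n_params = f.n_params - 2
        r = lrt(null, f)
        assert r.two_delta_lnL == 0.0 and r.p_value == 1.0

    def test_statistic_clamped_at_zero(self, m0_data):
        aln, tree = m0_data
        f = fit_model(aln, tree, "M0", n_starts=1, seed=1)
        worse = type(f)(**{**f.__dict__})
        worse.lnL = f.lnL - 1e-7  # alt numerically below null
        worse.n_params = f.n_params + 1
        r = lrt(f, worse)
        assert r.two_delta_lnL == 0.0

    def test_df_must_be_positive(self, m0_data):
        aln, tree = m0_data
        f = fit_model(aln, tree, "M0", n_starts=1, seed=1)
        with pytest.raises(ModelError):
            lrt(f, f)


class TestSitePosteriors:
    def test_normalisation(self, m0_data):
        aln, tree = m0_data
        m1a = fit_model(aln, tree, "M1a", n_starts=1, seed=4)
        sp = site_posteriors(m1a, aln)
        assert sp.posteriors.shape == (aln.n_codons, 2)
        assert np.allclose(sp.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_non_mixture_rejected(self, m0_data):
        aln, tree = m0_data
        m0 = fit_model(aln, tree, "M0", n_starts=1, seed=1)
        with pytest.raises(ModelError):
            site_posteriors(m0, aln)

    def test_planted_positive_site_ranks_first(self):
        """A site simulated at omega = 3 inside a 300-codon omega = 0.05
        background (10 taxa, long branches) attains the maximal
        positive-class posterior under M2a."""
        nwk = ("(((a:0.5,b:0.5):0.25,(c:0.5,d:0.5):0.25):0.2,"
               "((e:0.5,f:0.5):0.25,(g:0.5,h:0.5):0.25):0.2,"
               "(i:0.5,j:0.5):0.25);")
        bg = synth.SimSpec(tree=nwk, n_codons=299, kappa=2.0, omega=0.05, seed=31)
        hot = synth.SimSpec(tree=nwk, n_codons=1, kappa=2.0, omega=3.0, seed=32)
        a_bg, _ = synth.simulate_alignment(bg)
        a_hot, _ = synth.simulate_alignment(hot)
        hot_col = {t: a_hot.sequences[a_hot.taxa.index(t)] for t in a_bg.taxa}
        seqs = [s + hot_col[t] for t, s in zip(a_bg.taxa, a_bg.sequences)]
        aln = CodonAlignment(list(a_bg.taxa), seqs)
        tree = synth._prepare_tree(nwk)
        m2a = fit_model(aln, tree, "M2a", n_starts=1, seed=9)
        sp = site_posteriors(m2a, aln)
        pr = sp.pr_positive
        assert pr.argmax() == aln.n_codons - 1

    def test_f3x4_is_simplex(self, m0_data):
        aln, _ = m0_data
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0) and np.all(pi >= 0)
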