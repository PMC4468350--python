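import numpy as np
import pytest
import scipy.linalg

from liemarkov import (Alignment, CartesianParams, Phylogeny,
                       RateHeterogeneity, cartesian_to_rate,
                       equilibrium_frequencies, fit_model, get_model,
                       log_likelihood, log_likelihood_rate_matrix,
                       model_scan, simulate_alignment)
from liemarkov.likelihood import _gamma_category_rates
from liemarkov.simulate import SimulationSpec

_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}


def brute_force_lnl(aln, tree, Q, het):
    """Exhaustive enumeration over internal-node state assignments."""
    rates, probs = het.categories()
    pi = equilibrium_frequencies(Q)
    n_internal = tree.n_nodes - tree.n_leaves
    lik = np.zeros(aln.n_sites)
    for r, w in zip(rates, probs):
        Ms = [scipy.linalg.expm(Q * tree.lengths[i] * r)
              for i in range(tree.n_nodes)]
        for s in range(aln.n_sites):
            leaf = [_CODE[aln.sequence(t)[s]] for t in tree.taxa]
            tot = 0.0
            for combo in np.ndindex(*(4,) * n_internal):
                states = leaf + list(combo)
                p = pi[states[tree.root]]
                for nd in range(tree.n_nodes - 1):
                    p *= Ms[nd][states[nd], states[tree.parent[nd]]]
                tot += p
            lik[s] += w * tot
    return float(np.log(lik).sum())


def test_trivial_identical_pair_ln_quarter():
    aln = Alignment.from_sequences(["a", "b"], ["A", "A"])
    tree = Phylogeny.from_newick("(a:0.0,b:0.0);")
    assert log_likelihood(aln, tree, "1.1", []) \
        == pytest.approx(np.log(0.25), abs=1e-12)


def test_independence_limit_long_branches():
    aln = Alignment.from_sequences(["a", "b"], ["AC", "GT"])
    tree = Phylogeny.from_newick("(a:60.0,b:60.0);")
    assert log_likelihood(aln, tree, "1.1", []) \
        == pytest.approx(4 * np.log(0.25), abs=1e-6)


@pytest.mark.parametrize("kind,kwargs", [
    ("single", {}),
    ("I", {"p_invariant": 0.25}),
    ("G", {"gamma_shape": 0.6}),
    ("IG", {"p_invariant": 0.15, "gamma_shape": 1.3}),
])
def test_oracle_agreement_all_heterogeneity_kinds(kind, kwargs):
    tree = Phylogeny.from_newick(
        "(((a:0.2,b:0.35):0.15,c:0.4):0.1,(d:0.3,e:0.25):0.2);")
    aln = Alignment.from_sequences(
        list("abcde"), ["ACGTA", "AGGTC", "ACCTG", "TCGAT", "ACGTA"])
    model = get_model("RY5.6b")
    Q = cartesian_to_rate(
        CartesianParams(model, [0.5, 0.3, 0.25, -0.35])) / 3.0
    het = RateHeterogeneity(kind, **kwargs)
    lnl = log_likelihood_rate_matrix(aln, tree, Q, het)
    oracle = brute_force_lnl(aln, tree, Q, het)
    assert lnl == pytest.approx(oracle, abs=1e-10)


def test_pattern_compression_invariance():
    tree = Phylogeny.from_newick("((a:0.2,b:0.3):0.1,(c:0.15,d:0.4):0.2);")
    spec = SimulationSpec(tree=tree, model="3.3a", b=(0.4, -0.3),
                          n_sites=500, seed=11)
    aln = simulate_alignment(spec)
    Q = cartesian_to_rate(
        CartesianParams(get_model("3.3a"), np.array([0.4, -0.3]))) / 3.0
    compressed = log_likelihood_rate_matrix(aln, tree, Q,
                                            RateHeterogeneity())
    # per-site sum without compression
    total = 0.0
    for s in range(aln.n_sites):
        single = Alignment(list(aln.taxa), aln.codes[:, s:s + 1])
        total += log_likelihood_rate_matrix(single, tree, Q,
                                            RateHeterogeneity())
    assert compressed == pytest.approx(total, abs=1e-10)


def test_gamma_shape_limit_recovers_single_rate():
    tree = Phylogeny.from_newick("((a:0.2,b:0.3):0.1,(c:0.15,d:0.4):0.2);")
    aln = Alignment.from_sequences(list("abcd"),
                                   ["ACGTA", "AGGTA", "ACCTA", "TCGAA"])
    Q = cartesian_to_rate(
        CartesianParams(get_model("RY2.2b"), np.array([0.6]))) / 3.0
    single = log_likelihood_rate_matrix(aln, tree, Q, RateHeterogeneity())
    gamma = log_likelihood_rate_matrix(
        aln, tree, Q, RateHeterogeneity("G", gamma_shape=1e4))
    assert gamma == pytest.approx(single, abs=1e-4)


def test_gamma_category_rates_mean_one():
    for shape in (0.1, 0.5, 1.0, 5.0, 50.0):
        r = _gamma_category_rates(shape, 8)
        assert len(r) == 8
        assert r.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(r) > 0) and r.min() >= 0


def test_heterogeneity_validation():
    with pytest.raises(ValueError):
        RateHeterogeneity("bogus")
    with pytest.raises(ValueError):
        RateHeterogeneity("I", p_invariant=1.0)
    with pytest.raises(ValueError):
        RateHeterogeneity("G", gamma_shape=0.0)


def test_root_placement_matters_only_for_nonreversible():
    taxa = list("abcd")
    aln = Alignment.from_sequences(taxa, ["ACGTAC", "AGGTAT",
                                          "ACCTGA", "TCGATC"])
    # same unrooted shape, two different root positions along the path
    t1 = Phylogeny.from_newick("((a:0.2,b:0.3):0.08,(c:0.15,d:0.4):0.12);")
    t2 = Phylogeny.from_newick("((a:0.2,b:0.3):0.02,(c:0.15,d:0.4):0.18);")
    # reversible: K3ST is invariant to sliding the root along a branch
    Q_rev = cartesian_to_rate(
        CartesianParams(get_model("3.3a"), np.array([0.4, -0.3]))) / 3.0
    l1 = log_likelihood_rate_matrix(aln, t1, Q_rev, RateHeterogeneity())
    l2 = log_likelihood_rate_matrix(aln, t2, Q_rev, RateHeterogeneity())
    assert l1 == pytest.approx(l2, abs=1e-10)
    # nonreversible: RY5.6b with e1 != e2 is not
    Q_non = cartesian_to_rate(
        CartesianParams(get_model("RY5.6b"),
                        np.array([0.5, 0.3, 0.45, -0.5]))) / 3.0
    l1 = log_likelihood_rate_matrix(aln, t1, Q_non, RateHeterogeneity())
    l2 = log_likelihood_rate_matrix(aln, t2, Q_non, RateHeterogeneity())
    assert abs(l1 - l2) > 1e-6


def test_nonstochastic_rejected(four_taxon_tree, small_alignment):
    from liemarkov import basis_matrix
    with pytest.raises(ValueError, match="stochastic"):
        log_likelihood_rate_matrix(small_alignment, four_taxon_tree,
                                   basis_matrix("D"), RateHeterogeneity())


def test_taxa_mismatch_rejected(four_taxon_tree):
    aln = Alignment.from_sequences(["p", "q", "r", "s"], ["A"] * 4)
    with pytest.raises(ValueError, match="taxa"):
        log_likelihood_rate_matrix(aln, four_taxon_tree,
                                   np.array([[-3., 1, 1, 1],
                                             [1, -3, 1, 1],
                                             [1, 1, -3, 1],
                                             [1, 1, 1, -3]]) / 3.0,
                                   RateHeterogeneity())


def test_fit_recovers_jc_branch_lengths(four_taxon_tree):
    spec = SimulationSpec(tree=four_taxon_tree, model="1.1",
                          n_sites=20000, seed=3)
    aln = simulate_alignment(spec)
    fit = fit_model(aln, four_taxon_tree, "1.1", seed=0, restarts=1)
    np.testing.assert_allclose(
        np.sort(fit.branch_lengths)[2:],  # root pair only jointly known
        np.sort(four_taxon_tree.branch_lengths_vector())[2:],
        atol=0.05)
    assert fit.converged


def test_nested_models_lnl_monotone(four_taxon_tree):
    spec = SimulationSpec(tree=four_taxon_tree, model="RY2.2b", b=(0.5,),
                          n_sites=2000, seed=5)
    aln = simulate_alignment(spec)
    chain = ["1.1", "RY2.2b", "3.3a", "RY6.6", "RY10.12"]
    lnls = [fit_model(aln, four_taxon_tree, m, seed=1, restarts=1).lnL
            for m in chain]
    for lo, hi in zip(lnls, lnls[1:]):
        assert hi >= lo - 1e-3, (chain, lnls)


def test_fit_result_information_criteria(four_taxon_tree):
    aln = simulate_alignment(SimulationSpec(
        tree=four_taxon_tree, model="1.1", n_sites=200, seed=21))
    fit = fit_model(aln, four_taxon_tree, "1.1", seed=0, restarts=1)
    n, k = fit.n_sites, fit.k
    assert fit.bic == pytest.approx(k * np.log(n) - 2 * fit.lnL)
    assert fit.aicc == pytest.approx(
        2 * k - 2 * fit.lnL + 2 * k * (k + 1) / (n - k - 1))
    assert fit.k == 0 + 5 + 0  # JC: no model params, 2T-3 branches
    d = fit.to_dict()
    assert d["model"] == "1.1" and "k_convention" in d


def test_fit_requires_rooted_tree(small_alignment):
    unrooted = Phylogeny.from_newick("(a:1,b:1,(c:1,d:1):1);")
    with pytest.raises(ValueError, match="midpoint_root"):
        fit_model(small_alignment, unrooted, "1.1")


def test_model_scan_ranking(four_taxon_tree):
    spec = SimulationSpec(tree=four_taxon_tree, model="RY2.2b", b=(0.7,),
                          n_sites=4000, seed=9)
    aln = simulate_alignment(spec)
    df = model_scan(aln, four_taxon_tree,
                    ["1.1", "RY2.2b", "3.3a", "GTR"], seed=2, restarts=1)
    assert df.iloc[0]["model"] == "RY2.2b"  # true model wins by BIC
    assert df.iloc[0]["dBIC"] == 0.0
    assert df["dAICc"].min() == 0.0
    assert len(df) == 4


def test_identical_model_two_labels_same_lnl(four_taxon_tree):
    spec = SimulationSpec(tree=four_taxon_tree, model="RY2.2b", b=(0.4,),
                          n_sites=800, seed=13)
    aln = simulate_alignment(spec)
    a = fit_model(aln, four_taxon_tree, "RY2.2b", seed=3, restarts=1)
    b = fit_model(aln, four_taxon_tree, "K2ST", seed=3, restarts=1)
    assert a.lnL == pytest.approx(b.lnL, abs=1e-6)
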