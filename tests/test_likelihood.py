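"""Pruning likelihood: closed forms, exhaustive enumeration, and the
stationary-model reduction."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import gcphylo as g
from gcphylo.likelihood import ModelParams, log_likelihood, marginal_posteriors, PrunedAlignment
from gcphylo.substitution import discrete_gamma_rates, rate_matrix, stationary_distribution

from conftest import random_params


def enumeration_minus_lnl(aln, tree, classes, params):
    """Independent oracle: sum over all internal-state assignments,
    using scipy's expm for the branch matrices."""
    rates, weights = discrete_gamma_rates(params.alpha, params.n_categories)
    pi_root = stationary_distribution(params.theta_root)
    idx = {c: i for i, c in enumerate("ACGT")}
    leaves = {tree.label[i]: i for i in tree.leaves()}
    internals = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    qs = {b: rate_matrix(params.theta[classes.branch_class[b]], params.kappa)
          for b in tree.branches()}
    total = 0.0
    n_sites = len(next(iter(aln.sequences.values())))
    for site in range(n_sites):
        site_lik = 0.0
        for r, w in zip(rates, weights):
            pmats = {b: expm(qs[b] * tree.length[b] * r) for b in tree.branches()}
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assign))
                for taxon, leaf in leaves.items():
                    states[leaf] = idx[aln.sequences[taxon][site]]
                pr = pi_root[states[tree.root]]
                for b in tree.branches():
                    pr *= pmats[b][states[tree.parent[b]], states[b]]
                s += pr
            site_lik += w * s
        total += -np.log(site_lik)
    return total


def test_two_taxon_single_site_closed_form():
    """-lnL = -log sum_x pi(x) P1(x->a) P2(x->b), computed by hand."""
    tree = g.read_newick("(A:0.2,B:0.7);")
    aln = g.Alignment({"A": "G", "B": "T"})
    classes = g.assign_branch_classes(tree, "homogeneous")
    params = ModelParams(theta=[0.6], theta_root=0.4, kappa=2.0, alpha=1e7, n_categories=1)
    by = tree.leaf_by_label()
    p1 = g.transition_probabilities(0.6, 2.0, tree.length[by["A"]])
    p2 = g.transition_probabilities(0.6, 2.0, tree.length[by["B"]])
    pi = stationary_distribution(0.4)
    expected = -np.log(sum(pi[x] * p1[x, 2] * p2[x, 3] for x in range(4)))
    assert log_likelihood(aln, tree, classes, params) == pytest.approx(expected, abs=1e-10)


def test_pruning_equals_enumeration_on_random_instances():
    """20 random trees (<=5 leaves), random non-homogeneous parameters."""
    rng = np.random.default_rng(2024)
    for rep in range(20):
        n_taxa = int(rng.integers(2, 6))
        tree = g.random_tree(n_taxa, seed=rep, depth=float(rng.uniform(0.3, 2.0)))
        classes = g.assign_branch_classes(tree, "per_branch")
        params = random_params(rng, classes.n_classes)
        n_sites = int(rng.integers(1, 4))
        seqs = {
            t: "".join(rng.choice(list("ACGT"), n_sites)) for t in tree.taxa()
        }
        aln = g.Alignment(seqs)
        mine = log_likelihood(aln, tree, classes, params)
        oracle = enumeration_minus_lnl(aln, tree, classes, params)
        assert mine == pytest.approx(oracle, abs=1e-8)


def test_duplicating_columns_doubles_minus_lnl(small_tree, small_alignment):
    classes = g.assign_branch_classes(small_tree, "homogeneous")
    params = ModelParams(theta=[0.5], theta_root=0.5, kappa=2.0, alpha=1.0)
    single = log_likelihood(small_alignment, small_tree, classes, params)
    doubled = g.Alignment({t: s + s for t, s in small_alignment.sequences.items()})
    assert log_likelihood(doubled, small_tree, classes, params) == pytest.approx(
        2 * single, abs=1e-9
    )


def test_invariant_to_child_order_and_leaf_relabeling(small_alignment):
    t1 = g.read_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);")
    t2 = g.read_newick("((D:0.4,C:0.1):0.6,(B:0.5,A:0.3):0.2);")
    params = ModelParams(theta=[0.4], theta_root=0.6, kappa=1.5, alpha=0.8)
    v1 = log_likelihood(small_alignment, t1, g.assign_branch_classes(t1, "homogeneous"), params)
    v2 = log_likelihood(small_alignment, t2, g.assign_branch_classes(t2, "homogeneous"), params)
    assert v1 == pytest.approx(v2, abs=1e-10)


def stationary_t92_gamma_minus_lnl(aln, tree, theta, kappa, alpha, k=4):
    """Independent stationary T92+Gamma implementation (expm matrices,
    explicit per-site recursion over a node dict)."""
    rates, weights = discrete_gamma_rates(alpha, k)
    q = rate_matrix(theta, kappa)
    pi = stationary_distribution(theta)
    idx = {c: i for i, c in enumerate("ACGT")}
    n_sites = len(next(iter(aln.sequences.values())))
    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for r, w in zip(rates, weights):
            def partial(node):
                if tree.is_leaf(node):
                    vec = np.zeros(4)
                    vec[idx[aln.sequences[tree.label[node]][site]]] = 1.0
                    return vec
                out = np.ones(4)
                for ch in tree.children[node]:
                    out = out * (expm(q * tree.length[ch] * r) @ partial(ch))
                return out
            site_lik += w * float(pi @ partial(tree.root))
        total += -np.log(site_lik)
    return total


def test_reduces_to_stationary_t92_gamma():
    """Merged classes + root forced to the stationary composition give
    the classic stationary model; checked on 10 random instances."""
    rng = np.random.default_rng(7)
    for rep in range(10):
        tree = g.random_tree(int(rng.integers(3, 7)), seed=100 + rep)
        theta = float(rng.uniform(0.2, 0.8))
        kappa = float(rng.uniform(0.5, 4.0))
        alpha = float(rng.uniform(0.4, 2.0))
        seqs = {t: "".join(rng.choice(list("ACGT"), 3)) for t in tree.taxa()}
        aln = g.Alignment(seqs)
        classes = g.assign_branch_classes(tree, "homogeneous")
        params = ModelParams(theta=[theta], theta_root=theta, kappa=kappa, alpha=alpha)
        mine = log_likelihood(aln, tree, classes, params)
        oracle = stationary_t92_gamma_minus_lnl(aln, tree, theta, kappa, alpha)
        assert mine == pytest.approx(oracle, abs=1e-8)


def test_ambiguous_leaf_is_missing_data(small_tree):
    """An N leaf state sums over compatible states: likelihood equals the
    sum of the four fully resolved likelihoods."""
    classes = g.assign_branch_classes(small_tree, "homogeneous")
    params = ModelParams(theta=[0.5], theta_root=0.5, kappa=2.0, alpha=1.0)
    with_n = g.Alignment({"A": "N", "B": "C", "C": "G", "D": "T"})
    liks = []
    for base in "ACGT":
        aln = g.Alignment({"A": base, "B": "C", "C": "G", "D": "T"})
        liks.append(np.exp(-log_likelihood(aln, small_tree, classes, params)))
    combined = -np.log(sum(liks))
    assert log_likelihood(with_n, small_tree, classes, params) == pytest.approx(
        combined, abs=1e-10
    )


def test_p_inv_mixture_increases_constant_site_likelihood(small_tree):
    classes = g.assign_branch_classes(small_tree, "homogeneous")
    aln = g.Alignment({"A": "A", "B": "A", "C": "A", "D": "A"})
    base = ModelParams(theta=[0.5], theta_root=0.5, kappa=2.0, alpha=1.0)
    mixed = ModelParams(theta=[0.5], theta_root=0.5, kappa=2.0, alpha=1.0, p_inv=0.5)
    assert log_likelihood(aln, small_tree, classes, mixed) < log_likelihood(
        aln, small_tree, classes, base
    )


def test_marginal_posteriors_sum_to_one(small_tree, small_alignment):
    classes = g.assign_branch_classes(small_tree, "per_branch")
    rng = np.random.default_rng(0)
    params = random_params(rng, classes.n_classes)
    pruned = PrunedAlignment(small_alignment, small_tree)
    post = marginal_posteriors(pruned, classes, params)
    for node, probs in post.items():
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)


def test_zero_sites_rejected(small_tree):
    with pytest.raises(ValueError):
        PrunedAlignment(g.Alignment({t: "" for t in "ABCD"}), small_tree)
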