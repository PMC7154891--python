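"""Felsenstein pruning for the non-homogeneous, non-stationary GC model.

Each branch uses the transition matrix of its class's theta (shared
kappa), evaluated at branch length x gamma-category rate.  The root is
summed against a free root composition (theta_root), which is what makes
the model non-stationary: ancestral and present-day GC may differ.  Site
patterns are compressed once per alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .substitution import BranchProcess, discrete_gamma_rates, stationary_distribution
from .trees import BranchClassMap, PhyloTree


@dataclass
class ModelParams:
    """Parameters of the non-homogeneous T92+Gamma model."""

    theta: np.ndarray  # one equilibrium GC per branch class
    theta_root: float
    kappa: float
    alpha: float
    p_inv: float = 0.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if np.any((self.theta <= 0) | (self.theta >= 1)):
            raise ValueError("all theta values must be in (0,1)")
        if not 0 < self.theta_root < 1:
            raise ValueError("theta_root must be in (0,1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0,1)")

    @property
    def n_free(self) -> int:
        """Free parameter count: thetas + root + kappa + alpha (+ p_inv)."""
        return len(self.theta) + 3 + (1 if self.p_inv > 0 else 0)


class PrunedAlignment:
    """Alignment compressed to unique site patterns on a fixed tree."""

    def __init__(self, alignment: Alignment, tree: PhyloTree):
        taxa = tree.taxa()
        missing = sorted(set(taxa) - set(alignment.taxa))
        if missing:
            raise ValueError(f"tree taxa missing from alignment: {missing}")
        if alignment.n_sites == 0:
            raise ValueError("alignment has zero sites")
        self.tree = tree
        mask = alignment.state_mask(order=taxa)  # (n_leaf, n_sites, 4)
        key = np.packbits(mask.astype(np.uint8), axis=2)[:, :, 0]
        _, idx, inv, counts = np.unique(
            key, axis=1, return_index=True, return_inverse=True, return_counts=True
        )
        self.pattern_weight = counts.astype(float)
        self.site_to_pattern = inv
        self.leaf_partials = {
            leaf: np.ascontiguousarray(mask[i, idx, :])
            for i, leaf in enumerate(tree.leaves())
        }
        self.n_patterns = len(idx)
        self.n_sites = alignment.n_sites
        # invariant-site support: which states are compatible across all leaves
        all_compat = np.ones((self.n_patterns, 4))
        for part in self.leaf_partials.values():
            all_compat *= part
        self.constant_support = all_compat


def _branch_matrices(
    pruned: PrunedAlignment, classes: BranchClassMap, params: ModelParams
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """P matrices indexed [category][node] plus gamma rates/weights."""
    rates, weights = discrete_gamma_rates(params.alpha, params.n_categories)
    procs = [BranchProcess(th, params.kappa) for th in params.theta]
    tree = pruned.tree
    mats: list[np.ndarray] = []
    for r in rates:
        per_node = np.empty((tree.n_nodes, 4, 4))
        for b in tree.branches():
            proc = procs[classes.branch_class[b]]
            per_node[b] = proc.p_matrix(tree.length[b] * r)
        mats.append(per_node)
    return mats, rates, weights


def _site_likelihoods(
    pruned: PrunedAlignment, classes: BranchClassMap, params: ModelParams
) -> np.ndarray:
    """Per-pattern likelihoods, gamma-mixed and p_inv-mixed."""
    tree = pruned.tree
    unclassified = sorted(set(tree.branches()) - set(classes.branch_class))
    if unclassified:
        raise ValueError(f"branches without a class: {unclassified}")
    mats, _, weights = _branch_matrices(pruned, classes, params)
    pi_root = stationary_distribution(params.theta_root)
    post = tree.postorder()
    lik = np.zeros(pruned.n_patterns)
    for cat, per_node in enumerate(mats):
        partials: dict[int, np.ndarray] = {}
        for node in post:
            if tree.is_leaf(node):
                partials[node] = pruned.leaf_partials[node]
                continue
            acc = np.ones((pruned.n_patterns, 4))
            for child in tree.children[node]:
                acc *= partials.pop(child) @ per_node[child].T
            partials[node] = acc
        lik += weights[cat] * (partials[tree.root] @ pi_root)
    if params.p_inv > 0:
        inv_lik = pruned.constant_support @ pi_root
        lik = params.p_inv * inv_lik + (1 - params.p_inv) * lik
    return lik


def minus_log_likelihood(
    pruned: PrunedAlignment, classes: BranchClassMap, params: ModelParams
) -> float:
    """Negative log-likelihood of the alignment on the fixed tree."""
    lik = _site_likelihoods(pruned, classes, params)
    if np.any(lik <= 0):
        return np.inf
    return -float(pruned.pattern_weight @ np.log(lik))


def log_likelihood(
    alignment: Alignment,
    tree: PhyloTree,
    classes: BranchClassMap,
    params: ModelParams,
) -> float:
    """Convenience wrapper: -lnL straight from an alignment."""
    return minus_log_likelihood(PrunedAlignment(alignment, tree), classes, params)


def marginal_posteriors(
    pruned: PrunedAlignment, classes: BranchClassMap, params: ModelParams
) -> dict[int, np.ndarray]:
    """Per-node marginal posterior state distributions, (n_patterns, 4).

    Standard inside-outside two-pass computation with branch-specific
    matrices; gamma categories are mixed by their per-pattern posterior
    weight.  p_inv must be 0 (the mixture assigns no states to nodes).
    """
    if params.p_inv > 0:
        raise ValueError("marginal reconstruction requires p_inv = 0")
    tree = pruned.tree
    mats, _, weights = _branch_matrices(pruned, classes, params)
    pi_root = stationary_distribution(params.theta_root)
    post = tree.postorder()
    joint = {n: np.zeros((pruned.n_patterns, 4)) for n in range(tree.n_nodes)}
    total = np.zeros(pruned.n_patterns)
    for cat, per_node in enumerate(mats):
        up: dict[int, np.ndarray] = {}
        for node in post:
            if tree.is_leaf(node):
                up[node] = pruned.leaf_partials[node]
            else:
                acc = np.ones((pruned.n_patterns, 4))
                for child in tree.children[node]:
                    acc *= up[child] @ per_node[child].T
                up[node] = acc
        down: dict[int, np.ndarray] = {tree.root: np.tile(pi_root, (pruned.n_patterns, 1))}
        for node in post[::-1]:
            for child in tree.children[node]:
                sib = down[node].copy()
                for other in tree.children[node]:
                    if other != child:
                        sib *= up[other] @ per_node[other].T
                down[child] = sib @ per_node[child]
        cat_total = up[tree.root] @ pi_root
        total += weights[cat] * cat_total
        for n in range(tree.n_nodes):
            joint[n] += weights[cat] * up[n] * down[n]
    out = {}
    for n in range(tree.n_nodes):
        out[n] = joint[n] / total[:, None]
    return out
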