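"""Ancestral %GC at nodes and GC* on branches from a fitted model.

Two reconstruction modes:

* ``expected`` (default): deterministic model-expected composition — the
  root gets the fitted root frequencies and each child node's
  composition is the parent's propagated through that branch's
  transition matrix (gamma-averaged).  GC moves monotonically from the
  parent value toward the branch's theta.
* ``marginal``: empirical cross-check — per-site marginal posterior
  state distributions given the observed alignment, averaged over sites.

Branch GC* is the fitted theta of the branch's class: for the T92
generator the AT->GC over total directional rate ratio equals theta
identically, so no separate rate computation is needed.

A pseudo-bootstrap (nonparametric site resampling, refitting thetas with
kappa/alpha held fixed) supplies spread estimates for node GC and GC*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import ModelParams, PrunedAlignment
from .substitution import BranchProcess, discrete_gamma_rates, stationary_distribution
from .trees import PhyloTree


@dataclass
class GCReconstruction:
    """Ancestral GC per node and GC* per branch, with optional bootstrap spread."""

    node_gc: dict[int, float]
    branch_gc_star: dict[int, float]
    tree: "PhyloTree"
    boot_node_gc: dict[int, np.ndarray] = field(default_factory=dict)
    boot_gc_star: dict[int, np.ndarray] = field(default_factory=dict)

    def annotated_newick(self) -> str:
        """Newick with node labels 'GC(GC*)' to 2 decimals, e.g. 0.51(0.48).

        GC* shown is that of the branch above the node; the root label
        carries only its GC.
        """
        missing = [n for n in range(self.tree.n_nodes) if n not in self.node_gc]
        if missing:
            raise ValueError(f"reconstruction missing nodes: {missing}")

        def label(node: int) -> str:
            gc = f"{self.node_gc[node]:.2f}"
            if node == self.tree.root:
                return gc
            if node not in self.branch_gc_star:
                raise ValueError(f"reconstruction missing branch above node {node}")
            return f"{gc}({self.branch_gc_star[node]:.2f})"

        return self.tree.write_newick(label_fn=label)

    def table(self):
        """Per-node TSV-ready frame: node, taxon, GC, GC*, boot mean/sd."""
        import pandas as pd

        rows = []
        for n in sorted(self.node_gc):
            boots = self.boot_node_gc.get(n)
            rows.append(
                {
                    "node": n,
                    "taxon": self.tree.label[n] or "",
                    "GC": self.node_gc[n],
                    "GC_star": self.branch_gc_star.get(n, np.nan),
                    "boot_mean": float(np.mean(boots)) if boots is not None else np.nan,
                    "boot_sd": float(np.std(boots, ddof=1)) if boots is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def node_gc_expected(results) -> dict[int, float]:
    """Model-expected GC at every node of the fitted tree.

    Root composition is the fitted root frequencies; each child's
    composition is parent @ P(branch), averaged over gamma categories.
    """
    tree = results.model.tree
    classes = results.model.classes
    p = results.params
    rates, weights = discrete_gamma_rates(p.alpha, p.n_categories)
    procs = [BranchProcess(th, p.kappa) for th in p.theta]
    comp = {tree.root: stationary_distribution(p.theta_root)}
    for node in tree.postorder()[::-1]:
        for child in tree.children[node]:
            proc = procs[classes.branch_class[child]]
            t = tree.length[child]
            mixed = sum(
                w * (comp[node] @ proc.p_matrix(t * r)) for r, w in zip(rates, weights)
            )
            if p.p_inv > 0:  # invariant fraction keeps the parent composition
                mixed = p.p_inv * comp[node] + (1 - p.p_inv) * mixed
            comp[child] = mixed
    return {n: float(c[1] + c[2]) for n, c in comp.items()}


def node_gc_marginal(results) -> dict[int, float]:
    """Posterior-mean GC at every node given the observed alignment."""
    post = results.marginal_posteriors()
    pruned = results.model.pruned
    w = pruned.pattern_weight / pruned.pattern_weight.sum()
    return {n: float((probs[:, 1] + probs[:, 2]) @ w) for n, probs in post.items()}


def reconstruct(
    results,
    method: str = "expected",
    n_bootstrap: int = 0,
    seed: int = 0,
) -> GCReconstruction:
    """Build a :class:`GCReconstruction` from a fitted model.

    method 'expected' uses the deterministic model-expected composition;
    'marginal' the data-conditional posterior mean.  With
    ``n_bootstrap > 0``, alignment sites are resampled and thetas refit
    (kappa/alpha fixed) to give a pseudo-bootstrap spread.
    """
    if not results.converged:
        raise ValueError(
            "fit did not converge; refusing to reconstruct (refit or force "
            "by setting results.converged = True)"
        )
    if method == "expected":
        node_gc = node_gc_expected(results)
    elif method == "marginal":
        node_gc = node_gc_marginal(results)
    else:
        raise ValueError(f"unknown method {method!r}")
    tree = results.model.tree
    classes = results.model.classes
    gc_star = {
        b: float(results.params.theta[classes.branch_class[b]])
        for b in tree.branches()
    }
    rec = GCReconstruction(node_gc=node_gc, branch_gc_star=gc_star, tree=tree)
    if n_bootstrap > 0:
        boot_gc: dict[int, list[float]] = {n: [] for n in node_gc}
        boot_star: dict[int, list[float]] = {b: [] for b in gc_star}
        for rep_params, rep_results in _bootstrap_fits(results, n_bootstrap, seed):
            rep_gc = (
                node_gc_expected(rep_results)
                if method == "expected"
                else node_gc_marginal(rep_results)
            )
            for n, v in rep_gc.items():
                boot_gc[n].append(v)
            for b in gc_star:
                boot_star[b].append(float(rep_params.theta[classes.branch_class[b]]))
        rec.boot_node_gc = {n: np.array(v) for n, v in boot_gc.items()}
        rec.boot_gc_star = {b: np.array(v) for b, v in boot_star.items()}
    return rec


class _ReplicateFit:
    """Just enough of the results interface for the reconstruction functions."""

    def __init__(self, model_like, params: ModelParams, converged: bool):
        self.model = model_like
        self.params = params
        self.converged = converged

    def marginal_posteriors(self):
        from .likelihood import marginal_posteriors

        return marginal_posteriors(self.model.pruned, self.model.classes, self.params)


class _ModelView:
    def __init__(self, tree, classes, pruned):
        self.tree = tree
        self.classes = classes
        self.pruned = pruned


def _bootstrap_fits(results, n_bootstrap: int, seed: int):
    """Yield (params, results-like) for site-resampled refits of thetas only."""
    from scipy.optimize import minimize
    from scipy.special import expit, logit

    from .likelihood import minus_log_likelihood

    model = results.model
    rng = np.random.default_rng(seed)
    aln = model.alignment
    taxa = list(aln.sequences)
    n_sites = aln.n_sites
    fixed = results.params

    def unpack(x):
        return ModelParams(
            theta=expit(x[:-1]),
            theta_root=float(expit(x[-1])),
            kappa=fixed.kappa,
            alpha=fixed.alpha,
            p_inv=fixed.p_inv,
            n_categories=fixed.n_categories,
        )

    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_sites, size=n_sites)
        res_aln = Alignment(
            {t: "".join(aln.sequences[t][j] for j in idx) for t in taxa}
        )
        pruned = PrunedAlignment(res_aln, model.tree)
        x0 = np.concatenate([logit(fixed.theta), [logit(fixed.theta_root)]])
        opt = minimize(
            lambda x: minus_log_likelihood(pruned, model.classes, unpack(x)),
            x0,
            method="L-BFGS-B",
            options={"ftol": 1e-6, "maxiter": 200},
        )
        params = unpack(opt.x)
        rep = _ReplicateFit(
            _ModelView(model.tree, model.classes, pruned), params, bool(opt.success)
        )
        yield params, rep


def annotate_tree(tree: PhyloTree, reconstruction: GCReconstruction) -> str:
    """Annotated Newick for any reconstruction covering `tree`'s nodes."""
    if reconstruction.tree is not tree:
        raise ValueError("reconstruction was built on a different tree")
    return reconstruction.annotated_newick()
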