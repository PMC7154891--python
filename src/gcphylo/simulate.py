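"""Synthetic data generators: alignments evolved under the
non-homogeneous GC model, Brownian-motion trait sets with a planted
mediation chain, annotated genomes with planted repeats, and random
trees.  Every generator is a pure function of its seed.

These emulate the study conditions of the pipeline's real inputs —
ribosomal alignments on a fixed Streptophyta-like tree with
clade-specific equilibrium GC, per-species mitochondrial genome
variables linked by the chain NRS -> %NC -> %GC (and %NC -> GL), and
circular-genome-sized sequences carrying exact repeats — while staying
small enough to fit a test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import ModelParams
from .substitution import BranchProcess, discrete_gamma_rates, stationary_distribution
from .trees import BranchClassMap, PhyloTree, assign_branch_classes

STATES = "ACGT"


# -- random trees --------------------------------------------------------


def random_tree(
    n_taxa: int,
    seed: int = 0,
    depth: float = 1.0,
    taxa: list[str] | None = None,
) -> PhyloTree:
    """Random rooted binary tree by sequential leaf attachment.

    Branch lengths are exponential with mean depth / log2(n); taxa are
    'T0'..'Tn-1' unless given.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    names = taxa if taxa is not None else [f"T{i}" for i in range(n_taxa)]
    if len(names) != n_taxa:
        raise ValueError("taxa list length mismatch")
    mean_len = depth / max(np.log2(n_taxa), 1.0)
    parent = [-1, 0, 0]
    length = [0.0, *rng.exponential(mean_len, 2).tolist()]
    label: list[str | None] = [None, names[0], names[1]]
    leaves = [1, 2]
    for k in range(2, n_taxa):
        target = leaves[rng.integers(len(leaves))]
        # split the target leaf branch: target becomes internal
        new_leaf, moved = len(parent), len(parent) + 1
        parent.extend([target, target])
        length.extend(rng.exponential(mean_len, 2).tolist())
        label.extend([names[k], label[target]])
        label[target] = None
        leaves.remove(target)
        leaves.extend([new_leaf, moved])
    return PhyloTree(parent=parent, length=length, label=label)


def clade_tree(
    clade_sizes: dict[str, int], seed: int = 0, depth: float = 1.0
) -> tuple[PhyloTree, dict[str, set[str]]]:
    """Random tree whose leaves group into named monophyletic clades.

    Each clade is a random subtree; the clade subtrees are attached to a
    random backbone.  Returns the tree and the clade definitions
    ({name: taxon set}) ready for branch-class assignment.
    """
    rng = np.random.default_rng(seed)
    names = list(clade_sizes)
    if len(names) < 2:
        raise ValueError("need at least two clades")
    mean_len = depth / 2
    clade_defs: dict[str, set[str]] = {}
    # backbone: ladder over clades
    parent: list[int] = [-1]
    length: list[float] = [0.0]
    label: list[str | None] = [None]
    attach_points: list[int] = []
    spine = 0
    for k in range(len(names)):
        if k < len(names) - 1:
            hang, nxt = len(parent), len(parent) + 1
            parent.extend([spine, spine])
            length.extend(rng.exponential(mean_len, 2).tolist())
            label.extend([None, None])
            attach_points.append(hang)
            spine = nxt
        else:
            attach_points.append(spine)

    def graft(par: int, sub: PhyloTree) -> None:
        offset = len(parent)
        for i in range(sub.n_nodes):
            parent.append(par if sub.parent[i] == -1 else sub.parent[i] + offset)
            length.append(sub.length[i] if sub.parent[i] != -1 else rng.exponential(mean_len))
            label.append(sub.label[i])

    for name, point in zip(names, attach_points):
        size = clade_sizes[name]
        taxa = [f"{name}_{i}" for i in range(size)]
        clade_defs[name] = set(taxa)
        if size == 1:
            parent.append(point)
            length.append(rng.exponential(mean_len))
            label.append(taxa[0])
        else:
            sub = random_tree(size, seed=int(rng.integers(2**31)), depth=depth / 2, taxa=taxa)
            graft(point, sub)
    return PhyloTree(parent=parent, length=length, label=label), clade_defs


# -- alignments ----------------------------------------------------------


@dataclass
class SimulationRecipe:
    """Ground-truth description of one simulated alignment."""

    tree: PhyloTree
    classes: BranchClassMap
    params: ModelParams
    n_sites: int
    seed: int
    clade_defs: dict[str, set[str]] = field(default_factory=dict)


def simulate_alignment(recipe: SimulationRecipe) -> Alignment:
    """Evolve an alignment down the tree under the recipe's model.

    Root states are drawn from the root composition; each site draws a
    gamma category (equal weights); each branch multiplies through
    P(length x category rate) for its class's theta.  Deterministic in
    the seed.
    """
    rng = np.random.default_rng(recipe.seed)
    p = recipe.params
    n = recipe.n_sites
    if n < 1:
        raise ValueError("n_sites must be positive")
    rates, weights = discrete_gamma_rates(p.alpha, p.n_categories)
    if p.p_inv > 0:
        invariant = rng.random(n) < p.p_inv
    else:
        invariant = np.zeros(n, dtype=bool)
    site_rate = rates[rng.choice(len(rates), size=n, p=weights)]
    site_rate[invariant] = 0.0
    pi_root = stationary_distribution(p.theta_root)
    states = {recipe.tree.root: rng.choice(4, size=n, p=pi_root)}
    procs = [BranchProcess(th, p.kappa) for th in p.theta]
    for node in recipe.tree.postorder()[::-1]:
        for child in recipe.tree.children[node]:
            proc = procs[recipe.classes.branch_class[child]]
            t = recipe.tree.length[child]
            parent_states = states[node]
            child_states = parent_states.copy()
            for r in np.unique(site_rate):
                idx = np.where(site_rate == r)[0]
                if r == 0.0 or t == 0.0:
                    continue
                pmat = proc.p_matrix(t * r)
                cum = pmat.cumsum(axis=1)
                u = rng.random(len(idx))
                child_states[idx] = (
                    u[:, None] > cum[parent_states[idx]]
                ).sum(axis=1)
            states[child] = child_states
    seqs = {}
    for leaf in recipe.tree.leaves():
        seqs[recipe.tree.label[leaf]] = "".join(STATES[s] for s in states[leaf])
    return Alignment(seqs)


def make_clade_recipe(
    clade_thetas: dict[str, float],
    n_per_clade: int = 3,
    n_sites: int = 2000,
    kappa: float = 2.0,
    alpha: float = 1.0,
    theta_root: float = 0.5,
    depth: float = 0.6,
    seed: int = 0,
    scheme: str = "M1",
) -> SimulationRecipe:
    """Convenience recipe: clade tree + clade-specific thetas."""
    tree, clade_defs = clade_tree(
        {name: n_per_clade for name in clade_thetas}, seed=seed, depth=depth
    )
    classes = assign_branch_classes(tree, scheme, clade_defs)
    theta = np.array([clade_thetas[name] for name in classes.class_names])
    params = ModelParams(
        theta=theta, theta_root=theta_root, kappa=kappa, alpha=alpha
    )
    return SimulationRecipe(
        tree=tree, classes=classes, params=params, n_sites=n_sites,
        seed=seed, clade_defs=clade_defs,
    )


# -- Brownian-motion traits ----------------------------------------------


@dataclass
class TraitRecipe:
    """Planted path model over BM traits on a tree.

    The chain is log(NRS) -> pct_NC -> pct_GC, with pct_NC -> log(GL):
    each downstream trait is coefficient x upstream + independent BM
    noise.  Coefficients of zero remove a path.
    """

    beta_nrs_nc: float = 0.2      # %NC change per unit log-NRS
    beta_nc_gc: float = 0.5       # %GC change per unit %NC
    beta_nc_gl: float = 3.0       # log-GL change per unit %NC
    rate_nrs: float = 1.0         # BM rate of the driving trait
    noise_nc: float = 0.01        # BM rate of %NC residual
    noise_gc: float = 0.01        # BM rate of %GC residual
    noise_gl: float = 0.05        # BM rate of log-GL residual
    root_values: dict = field(
        default_factory=lambda: {
            "log_NRS": 3.0, "pct_NC": 0.5, "pct_GC": 0.45, "log_GL": 11.0
        }
    )
    seed: int = 0


def simulate_bm(tree: PhyloTree, rate: float, root: float, rng) -> dict[str, float]:
    """One Brownian-motion trait: independent N(0, rate*t) increments."""
    vals = {tree.root: root}
    for node in tree.postorder()[::-1]:
        for child in tree.children[node]:
            vals[child] = vals[node] + rng.normal(
                0.0, np.sqrt(rate * tree.length[child])
            ) if tree.length[child] > 0 else vals[node]
    return {tree.label[i]: vals[i] for i in tree.leaves()}


def simulate_bm_traits(tree: PhyloTree, recipe: TraitRecipe):
    """Trait table with the planted mediation chain, plus the truth.

    Returns (DataFrame indexed by species with columns log_NRS, pct_NC,
    pct_GC, log_GL, truth dict of path coefficients).
    """
    import pandas as pd

    rng = np.random.default_rng(recipe.seed)
    r = recipe.root_values
    nrs = simulate_bm(tree, recipe.rate_nrs, 0.0, rng)
    nc_noise = simulate_bm(tree, recipe.noise_nc, 0.0, rng)
    gc_noise = simulate_bm(tree, recipe.noise_gc, 0.0, rng)
    gl_noise = simulate_bm(tree, recipe.noise_gl, 0.0, rng)
    taxa = tree.taxa()
    table = pd.DataFrame(index=pd.Index(taxa, name="species"))
    table["log_NRS"] = [r["log_NRS"] + nrs[t] for t in taxa]
    table["pct_NC"] = [
        r["pct_NC"] + recipe.beta_nrs_nc * nrs[t] + nc_noise[t] for t in taxa
    ]
    dev_nc = table["pct_NC"] - r["pct_NC"]
    table["pct_GC"] = [
        r["pct_GC"] + recipe.beta_nc_gc * dev_nc[t] + gc_noise[t] for t in taxa
    ]
    table["log_GL"] = [
        r["log_GL"] + recipe.beta_nc_gl * dev_nc[t] + gl_noise[t] for t in taxa
    ]
    truth = {
        "beta_nrs_nc": recipe.beta_nrs_nc,
        "beta_nc_gc": recipe.beta_nc_gc,
        "beta_nc_gl": recipe.beta_nc_gl,
    }
    return table, truth


# -- genomes with planted repeats ----------------------------------------


@dataclass
class RepeatPlan:
    """One planted repeat pair: copy length and kind."""

    length: int
    kind: str = "forward"


def synth_genome(
    length: int,
    gc: float,
    coding_fraction: float,
    repeat_plan: list[RepeatPlan] | None = None,
    seed: int = 0,
    n_genes: int | None = None,
):
    """Random genome + GFF3 + ground truth.

    Background bases are i.i.d. at the target GC (so spurious exact
    repeats >= 20 bp are vanishingly unlikely at desk lengths); the
    planted repeat copies are placed at non-overlapping positions; gene
    intervals exactly cover `coding_fraction` of the genome.

    Returns (fasta_text, gff3_text, truth) where truth records planted
    NRS, RSL and the exact non-coding fraction.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0,1)")
    if not 0 <= coding_fraction <= 1:
        raise ValueError("coding_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(list("ACGT"), size=length, p=probs))
    plan = repeat_plan or []
    total_copy = sum(2 * p.length for p in plan)
    if total_copy > length // 2:
        raise ValueError("repeat plan infeasible: copies exceed half the genome")
    # place copies in disjoint slots, evenly spaced
    n_slots = 2 * len(plan)
    placements: list[tuple[int, int, str]] = []  # (start0, length, kind)
    if plan:
        slot = length // n_slots
        if max(p.length for p in plan) >= slot:
            raise ValueError("repeat plan infeasible: copies would overlap")
        k = 0
        from .repeats import _transform

        for p in plan:
            if p.kind not in ("forward", "reverse", "complement", "reverse_complement"):
                raise ValueError(f"unknown repeat kind {p.kind!r}")
            a, b = k * slot, (k + 1) * slot
            k += 2
            motif = "".join(rng.choice(list("ACGT"), size=p.length, p=probs))
            copy2 = _transform(motif, p.kind)
            seq[a : a + p.length] = list(motif)
            seq[b : b + p.length] = list(copy2)
            placements.append((a, p.length, p.kind))
            placements.append((b, p.length, p.kind))
    genome = "".join(seq)
    # gene annotation covering exactly coding_fraction
    n_genes = n_genes or max(1, int(round(coding_fraction * length / 1000))) if coding_fraction > 0 else 0
    gff_lines = ["##gff-version 3"]
    covered = int(round(coding_fraction * length))
    if n_genes and covered:
        gene_len = covered // n_genes
        gap = (length - covered) // max(n_genes, 1)
        pos = 1
        for g in range(n_genes):
            glen = gene_len if g < n_genes - 1 else covered - gene_len * (n_genes - 1)
            start, end = pos, pos + glen - 1
            gff_lines.append(
                f"chr\tsynth\tgene\t{start}\t{end}\t.\t+\t.\tID=gene{g}"
            )
            gff_lines.append(
                f"chr\tsynth\tCDS\t{start}\t{end}\t.\t+\t0\tID=cds{g};Parent=gene{g}"
            )
            pos = end + 1 + gap
    fasta = ">chr synthetic genome\n" + "\n".join(
        genome[i : i + 60] for i in range(0, length, 60)
    )
    truth = {
        "planted_nrs": len(plan),
        "planted_rsl": total_copy,
        "noncoding_fraction": 1.0 - covered / length if length else 1.0,
        "gc_target": gc,
        "placements": placements,
    }
    return fasta, "\n".join(gff_lines) + "\n", truth
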