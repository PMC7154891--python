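"""ML fitting of the hierarchical non-homogeneous GC models, and LRTs.

The model ladder refines the branch-class partition: homogeneous (one
equilibrium GC for the whole tree) -> clade model M1 -> M2 (splits one
group) -> terminal clades -> one GC* per branch.  Each fit shares kappa
(Ts/Tv) and the gamma shape across branches and frees one theta per
class plus the root composition.  Nested fits are compared with the
likelihood-ratio test: deviance = 2 * (lnL_complex - lnL_simple),
referred to a chi-square with df = the difference in free theta count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaincc, logit

from .alignment import Alignment
from .likelihood import (
    ModelParams,
    PrunedAlignment,
    marginal_posteriors,
    minus_log_likelihood,
)
from .trees import BranchClassMap, PhyloTree, assign_branch_classes

LADDER = ("homogeneous", "M1", "M2", "terminal_clades", "per_branch")


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail chi-square probability Q(df/2, x/2).

    Computed with the regularized upper incomplete gamma function, which
    stays accurate in the far tail (values below 1e-300 underflow to 0).
    """
    if x < 0:
        raise ValueError("deviance must be non-negative")
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(gammaincc(df / 2.0, x / 2.0))


@dataclass
class LRTResult:
    """Likelihood-ratio test between two nested fits."""

    deviance: float
    df: int
    p_value: float
    simple_model: str = ""
    complex_model: str = ""

    def __str__(self) -> str:
        return (
            f"LRT {self.simple_model} vs {self.complex_model}: "
            f"deviance={self.deviance:.2f}, df={self.df}, p={self.p_value:.4g}"
        )


def lrt(simple: "NonHomogeneousGCResults", complex: "NonHomogeneousGCResults") -> LRTResult:
    """LRT between a fit and a refinement of it (class-partition nesting)."""
    if not complex.model.classes.refines(simple.model.classes):
        raise ValueError(
            f"{complex.model.scheme!r} does not refine {simple.model.scheme!r}: "
            "models are not nested"
        )
    deviance = 2.0 * (simple.minus_lnl - complex.minus_lnl)
    df = complex.model.classes.n_classes - simple.model.classes.n_classes
    if df < 1:
        raise ValueError("complex model adds no free parameters")
    return LRTResult(
        deviance=deviance,
        df=df,
        p_value=chi2_upper_tail(max(deviance, 0.0), df),
        simple_model=simple.model.scheme,
        complex_model=complex.model.scheme,
    )


class NonHomogeneousGC:
    """Non-homogeneous, non-stationary T92+Gamma model on a fixed tree.

    Parameters
    ----------
    alignment : Alignment
        Gap-free nucleotide alignment covering the tree's taxa.
    tree : PhyloTree
        Rooted tree with fixed topology and branch lengths.
    classes : BranchClassMap
        Partition of branches into theta classes (see
        :func:`gcphylo.trees.assign_branch_classes`).
    n_categories : int
        Discrete-gamma categories (default 4).
    p_inv : bool
        Include a free invariant-site proportion in the mixture.
    scheme : str
        Name used in reports.
    """

    def __init__(
        self,
        alignment: Alignment,
        tree: PhyloTree,
        classes: BranchClassMap,
        n_categories: int = 4,
        p_inv: bool = False,
        scheme: str = "custom",
    ):
        self.alignment = alignment
        self.tree = tree
        self.classes = classes
        self.n_categories = n_categories
        self.use_p_inv = p_inv
        self.scheme = scheme
        self.pruned = PrunedAlignment(alignment, tree)

    # -- parameter packing (unconstrained coordinates) -------------------

    def _pack(self, params: ModelParams) -> np.ndarray:
        x = [logit(params.theta), [logit(params.theta_root)],
             [np.log(params.kappa)], [np.log(params.alpha)]]
        if self.use_p_inv:
            x.append([logit(max(params.p_inv, 1e-6))])
        return np.concatenate(x)

    def _unpack(self, x: np.ndarray) -> ModelParams:
        k = self.classes.n_classes
        return ModelParams(
            theta=expit(x[:k]),
            theta_root=float(expit(x[k])),
            kappa=float(np.exp(x[k + 1])),
            alpha=float(np.exp(x[k + 2])),
            p_inv=float(expit(x[k + 3])) if self.use_p_inv else 0.0,
            n_categories=self.n_categories,
        )

    def minus_loglike(self, params: ModelParams) -> float:
        return minus_log_likelihood(self.pruned, self.classes, params)

    # -- starting points -------------------------------------------------

    def _empirical_start(self) -> ModelParams:
        """Per-class observed GC of the leaves inside each class's branches."""
        leaf_class = {
            leaf: self.classes.branch_class.get(leaf)
            for leaf in self.tree.leaves()
            if leaf != self.tree.root
        }
        gc_by_class: dict[int, list[float]] = {}
        all_gc = []
        for leaf, cls in leaf_class.items():
            g = self.alignment.gc_content(self.tree.label[leaf])
            all_gc.append(g)
            gc_by_class.setdefault(cls, []).append(g)
        mean_gc = float(np.mean(all_gc))
        theta = np.array(
            [
                np.clip(np.mean(gc_by_class.get(c, [mean_gc])), 0.02, 0.98)
                for c in range(self.classes.n_classes)
            ]
        )
        return ModelParams(
            theta=theta,
            theta_root=float(np.clip(mean_gc, 0.02, 0.98)),
            kappa=2.0,
            alpha=1.0,
            p_inv=0.1 if self.use_p_inv else 0.0,
            n_categories=self.n_categories,
        )

    def _neutral_start(self) -> ModelParams:
        return ModelParams(
            theta=np.full(self.classes.n_classes, 0.5),
            theta_root=0.5,
            kappa=2.0,
            alpha=1.0,
            p_inv=0.1 if self.use_p_inv else 0.0,
            n_categories=self.n_categories,
        )

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        start: ModelParams | None = None,
        n_restarts: int = 3,
        seed: int = 0,
        tol: float = 1e-6,
        maxiter: int = 500,
    ) -> "NonHomogeneousGCResults":
        """Maximize the likelihood with bounded quasi-Newton (L-BFGS-B)
        in transformed coordinates (logit thetas, log kappa/alpha).

        Multi-start: a neutral start, the empirical-composition start,
        an optional user start, then perturbations of the best so far.
        Non-convergence after all restarts is flagged, never silent.
        """
        rng = np.random.default_rng(seed)
        starts = [self._neutral_start(), self._empirical_start()]
        if start is not None:
            starts.insert(0, start)
        best_x, best_f, any_converged = None, np.inf, False
        n_tried = 0
        while n_tried < max(n_restarts, len(starts)):
            if n_tried < len(starts):
                x0 = self._pack(starts[n_tried])
            else:
                x0 = best_x + rng.normal(0, 0.3, size=len(best_x))
            res = minimize(
                lambda x: self.minus_loglike(self._unpack(x)),
                x0,
                method="L-BFGS-B",
                options={"ftol": tol, "maxiter": maxiter},
            )
            n_tried += 1
            if res.fun < best_f - 1e-12 or best_x is None:
                best_x, best_f = res.x, float(res.fun)
                any_converged = bool(res.success)
            elif abs(res.fun - best_f) <= 1e-12:
                any_converged = any_converged or bool(res.success)
        return NonHomogeneousGCResults(
            model=self,
            params=self._unpack(best_x),
            minus_lnl=best_f,
            converged=any_converged,
            n_restarts=n_tried,
        )


@dataclass
class NonHomogeneousGCResults:
    """Fitted non-homogeneous GC model.

    Attributes
    ----------
    params : ModelParams
        ML estimates; ``params.theta[c]`` is the GC* of branch class c.
    minus_lnl : float
        Minimized negative log-likelihood.
    converged : bool
        Whether any optimizer start reported convergence at the optimum.
    """

    model: NonHomogeneousGC
    params: ModelParams
    minus_lnl: float
    converged: bool
    n_restarts: int = 0

    @property
    def gc_star(self) -> dict[str, float]:
        """Fitted equilibrium GC (GC*) per branch class, by class name."""
        return {
            name: float(th)
            for name, th in zip(self.model.classes.class_names, self.params.theta)
        }

    @property
    def n_free(self) -> int:
        return self.params.n_free

    def compare_lrt(self, simpler: "NonHomogeneousGCResults") -> LRTResult:
        return lrt(simpler, self)

    def ancestral_gc(self, method: str = "expected"):
        from .ancestral import reconstruct  # local import to avoid a cycle

        return reconstruct(self, method=method)

    def marginal_posteriors(self) -> dict[int, np.ndarray]:
        return marginal_posteriors(self.model.pruned, self.model.classes, self.params)

    def summary(self) -> str:
        lines = [
            "Non-homogeneous GC model fit",
            "=" * 34,
            f"scheme:        {self.model.scheme}",
            f"branch classes:{self.model.classes.n_classes:>5d}",
            f"sites:         {self.model.pruned.n_sites:>5d}"
            f"  (patterns: {self.model.pruned.n_patterns})",
            f"-lnL:          {self.minus_lnl:.2f}",
            f"kappa (Ts/Tv): {self.params.kappa:.4f}",
            f"gamma shape:   {self.params.alpha:.4f}",
            f"root GC:       {self.params.theta_root:.4f}",
        ]
        if self.model.use_p_inv:
            lines.append(f"p_inv:         {self.params.p_inv:.4f}")
        lines.append(f"converged:     {self.converged}")
        lines.append("GC* per class:")
        for name, th in self.gc_star.items():
            lines.append(f"  {name:<24s} {th:.4f}")
        return "\n".join(lines)


@dataclass
class HierarchyResult:
    """Five-model ladder with the LRT between consecutive levels."""

    fits: dict[str, NonHomogeneousGCResults]
    tests: list[LRTResult] = field(default_factory=list)

    def table(self):
        """Ladder report: model, -lnL, deviance, df, p (coarse to fine)."""
        import pandas as pd

        rows = []
        by_complex = {t.complex_model: t for t in self.tests}
        for name, fit in self.fits.items():
            t = by_complex.get(name)
            rows.append(
                {
                    "model": name,
                    "minus_lnL": round(fit.minus_lnl, 2),
                    "deviance": round(t.deviance, 2) if t else np.nan,
                    "df": t.df if t else np.nan,
                    "p_value": t.p_value if t else np.nan,
                }
            )
        return pd.DataFrame(rows)


def fit_hierarchy(
    alignment: Alignment,
    tree: PhyloTree,
    clade_defs: dict[str, dict[str, set[str]]],
    n_categories: int = 4,
    p_inv: bool = False,
    seed: int = 0,
    levels: tuple[str, ...] = LADDER,
) -> HierarchyResult:
    """Fit the model ladder and the LRTs between consecutive levels.

    `clade_defs` maps each clade-based level name ("M1", "M2",
    "terminal_clades") to its named taxon groups; "homogeneous" and
    "per_branch" need none.  Each fit is initialized from the previous
    (coarser) one: a refined class starts at its parent class's theta.
    """
    fits: dict[str, NonHomogeneousGCResults] = {}
    tests: list[LRTResult] = []
    prev: NonHomogeneousGCResults | None = None
    for level in levels:
        classes = assign_branch_classes(tree, level, clade_defs.get(level))
        model = NonHomogeneousGC(
            alignment, tree, classes, n_categories=n_categories,
            p_inv=p_inv, scheme=level,
        )
        start = None
        if prev is not None:
            if not classes.refines(prev.model.classes):
                raise ValueError(
                    f"level {level!r} does not refine {prev.model.scheme!r}; "
                    "check the clade definitions"
                )
            if classes.n_classes == prev.model.classes.n_classes:
                # identical partition (e.g. no group to split at this level):
                # the level adds nothing testable, skip it
                continue
            theta = np.empty(classes.n_classes)
            for b, c in classes.branch_class.items():
                theta[c] = prev.params.theta[prev.model.classes.branch_class[b]]
            start = ModelParams(
                theta=theta,
                theta_root=prev.params.theta_root,
                kappa=prev.params.kappa,
                alpha=prev.params.alpha,
                p_inv=prev.params.p_inv,
                n_categories=n_categories,
            )
        fit = model.fit(start=start, seed=seed)
        fits[level] = fit
        if prev is not None:
            tests.append(lrt(prev, fit))
        prev = fit
    return HierarchyResult(fits=fits, tests=tests)
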