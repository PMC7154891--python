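"""Phylogenetically independent contrasts (crunch), PGLS, mediation
tests, and Bonferroni flags.

Contrasts follow Felsenstein's algorithm: at each internal node the
difference between the two daughter values is standardized by the square
root of the summed (augmented) branch lengths, internal values are
variance-weighted averages, and the branch below each visited node is
augmented by v1*v2/(v1+v2).  All contrast regressions are forced through
the origin, as the method requires (a contrast's sign is arbitrary).

PGLS fits the same Brownian-motion assumption by generalized least
squares with trait covariance proportional to shared root-to-MRCA path
length.  The through-origin regression of y-contrasts on x-contrasts is
algebraically identical to the PGLS slope, which the tests verify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trees import PhyloTree, prune_to_taxa, resolve_polytomies, with_unit_lengths

# Bonferroni-corrected significance thresholds used in the two analysis
# arms: 0.005 for the genome-feature regressions, 0.008 for the six
# between-compartment concomitance comparisons.
ALPHA_FEATURES = 0.005
ALPHA_CONCOMITANCE = 0.008


def pic(tree: PhyloTree, trait: dict[str, float]) -> np.ndarray:
    """Standardized independent contrasts of a trait on a rooted tree.

    Returns n_leaves - 1 contrasts (binary tree; polytomies are resolved
    with near-zero branches first).  Raises if a contrast's combined
    branch length is zero.
    """
    missing = sorted(set(tree.taxa()) - trait.keys())
    if missing:
        raise ValueError(f"trait missing for taxa: {missing}")
    work = resolve_polytomies(tree)
    value: dict[int, float] = {}
    vlen: dict[int, float] = {}
    out: list[float] = []
    for node in work.postorder():
        if work.is_leaf(node):
            value[node] = float(trait[work.label[node]])
            vlen[node] = work.length[node]
            continue
        kids = work.children[node]
        if len(kids) != 2:
            raise AssertionError("tree must be binary after polytomy resolution")
        (a, b) = kids
        v1, v2 = vlen[a], vlen[b]
        if v1 + v2 <= 0:
            raise ValueError(f"zero combined branch length at node {node}")
        out.append((value[a] - value[b]) / np.sqrt(v1 + v2))
        value[node] = (value[a] / v1 + value[b] / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 else (
            value[a] if v1 == 0 else value[b]
        )
        vlen[node] = work.length[node] + v1 * v2 / (v1 + v2)
    return np.asarray(out)


@dataclass
class RegressionResult:
    """Through-origin (or PGLS) regression summary for one trait pair."""

    slope: float
    se: float
    t: float
    p_value: float
    r_squared: float
    df: int
    intercept: float | None = None
    method: str = "crunch"

    def summary(self) -> str:
        parts = [
            f"{self.method}: slope={self.slope:.4g} (se={self.se:.3g})",
            f"t={self.t:.3f}, df={self.df}, p={self.p_value:.4g}, R2={self.r_squared:.3f}",
        ]
        if self.intercept is not None:
            parts.insert(1, f"intercept={self.intercept:.4g}")
        return "; ".join(parts)


def crunch_regression(
    contrasts_x: np.ndarray, contrasts_y: np.ndarray
) -> RegressionResult:
    """Least squares of y-contrasts on x-contrasts through the origin."""
    x = np.asarray(contrasts_x, float)
    y = np.asarray(contrasts_y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("contrast vectors must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 contrasts")
    if np.allclose(x, 0):
        raise ValueError("all x contrasts are zero: slope undefined")
    fit = sm.OLS(y, x[:, None]).fit()
    return RegressionResult(
        slope=float(fit.params[0]),
        se=float(fit.bse[0]),
        t=float(fit.tvalues[0]),
        p_value=float(fit.pvalues[0]),
        r_squared=float(fit.rsquared),
        df=int(fit.df_resid),
        method="crunch",
    )


def bm_covariance(tree: PhyloTree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion trait covariance: shared root-to-MRCA path length."""
    by_label = tree.leaf_by_label()
    paths: dict[str, list[int]] = {}
    for t in taxa:
        path, j = [], by_label[t]
        while j != -1:
            path.append(j)
            j = tree.parent[j]
        paths[t] = path[::-1]
    depth = tree.depths()
    n = len(taxa)
    cov = np.empty((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            shared = [u for u, v in zip(paths[a], paths[b]) if u == v]
            cov[i, j] = depth[shared[-1]]
    return cov


def pgls(
    tree: PhyloTree,
    x: dict[str, float],
    y: dict[str, float],
    intercept: bool = True,
) -> RegressionResult:
    """Generalized least squares of y on x under Brownian-motion covariance."""
    taxa = [t for t in tree.taxa() if t in x and t in y]
    missing = sorted(set(tree.taxa()) - set(taxa))
    if missing:
        raise ValueError(f"traits missing for taxa: {missing}")
    cov = bm_covariance(tree, taxa)
    if np.linalg.matrix_rank(cov) < len(taxa):
        raise ValueError("singular BM covariance (duplicate zero-length tips?)")
    xv = np.array([x[t] for t in taxa])
    yv = np.array([y[t] for t in taxa])
    design = sm.add_constant(xv) if intercept else xv[:, None]
    fit = sm.GLS(yv, design, sigma=cov).fit()
    k = 1 if intercept else 0
    return RegressionResult(
        slope=float(fit.params[k]),
        se=float(fit.bse[k]),
        t=float(fit.tvalues[k]),
        p_value=float(fit.pvalues[k]),
        r_squared=float(fit.rsquared),
        df=int(fit.df_resid),
        intercept=float(fit.params[0]) if intercept else None,
        method="pgls",
    )


@dataclass
class MediationResult:
    """Baron–Kenny mediation decomposition on contrasts.

    total: y ~ x; mediator_path: m ~ x; direct: x's coefficient in
    y ~ x + m; indirect effect = a*b with Sobel z.  Verdict 'mediated'
    means the total and mediator paths are significant while the direct
    effect is not, at the configured alpha.
    """

    total: RegressionResult
    mediator_path: RegressionResult
    direct_p: float
    direct_slope: float
    mediator_in_full_p: float
    indirect_effect: float
    sobel_z: float
    sobel_p: float
    verdict: str
    alpha: float
    flagged_collinear: bool = False


def mediation_test(
    tree: PhyloTree,
    x: dict[str, float],
    mediator: dict[str, float],
    y: dict[str, float],
    alpha: float = ALPHA_FEATURES,
) -> MediationResult:
    """Test whether the x -> y relationship runs through the mediator.

    All three regressions are computed on standardized contrasts and
    forced through the origin.  A near-collinear mediator (|r| > 0.999
    with x) is flagged and no verdict is issued.
    """
    cx = pic(tree, x)
    cm = pic(tree, mediator)
    cy = pic(tree, y)
    r = np.corrcoef(cx, cm)[0, 1]
    if abs(r) > 0.999:
        dummy = crunch_regression(cx, cy)
        return MediationResult(
            total=dummy, mediator_path=dummy, direct_p=np.nan, direct_slope=np.nan,
            mediator_in_full_p=np.nan, indirect_effect=np.nan, sobel_z=np.nan,
            sobel_p=np.nan, verdict="no verdict (collinear)", alpha=alpha,
            flagged_collinear=True,
        )
    total = crunch_regression(cx, cy)
    med_path = crunch_regression(cx, cm)
    full = sm.OLS(cy, np.column_stack([cx, cm])).fit()
    direct_p = float(full.pvalues[0])
    direct_slope = float(full.params[0])
    a, se_a = med_path.slope, med_path.se
    b, se_b = float(full.params[1]), float(full.bse[1])
    sobel_z = a * b / np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    sobel_p = 2 * stats.norm.sf(abs(sobel_z))
    if total.p_value < alpha and med_path.p_value < alpha and direct_p >= alpha:
        verdict = "mediated"
    elif total.p_value < alpha and direct_p < alpha:
        verdict = "direct effect retained"
    else:
        verdict = "not mediated"
    return MediationResult(
        total=total,
        mediator_path=med_path,
        direct_p=direct_p,
        direct_slope=direct_slope,
        mediator_in_full_p=float(full.pvalues[1]),
        indirect_effect=a * b,
        sobel_z=float(sobel_z),
        sobel_p=float(sobel_p),
        verdict=verdict,
        alpha=alpha,
    )


def bonferroni_flag(p_values, alpha_corrected: float) -> list[bool]:
    """Strict-inequality significance flags at a pre-corrected threshold."""
    p = list(p_values)
    if any(not 0 <= v <= 1 for v in p):
        raise ValueError("p-values must lie in [0,1]")
    return [v < alpha_corrected for v in p]


PAIR_SET = (
    ("mtSSU", "mtLSU"),
    ("cpSSU", "cpLSU"),
    ("nSSU", "mtSSU"),
    ("nSSU", "cpSSU"),
    ("mtSSU", "cpSSU"),
    ("mtLSU", "cpLSU"),
)


def concomitance_suite(
    gc_tables: dict[str, dict[str, float]],
    trees: dict[str, PhyloTree],
    pairs=PAIR_SET,
    alpha: float = ALPHA_CONCOMITANCE,
) -> pd.DataFrame:
    """Pairwise concomitant-evolution tests between GC tables.

    For each pair with >= 3 shared species, crunch and PGLS are run
    under three topologies: each member's own tree (pruned to the shared
    species) and a unit-branch-length version; Bonferroni significance
    is flagged at `alpha` with strict inequality.  Pairs with too few
    shared species are skipped with a warning.
    """
    rows = []
    for name_a, name_b in pairs:
        shared = sorted(set(gc_tables[name_a]) & set(gc_tables[name_b]))
        if len(shared) < 3:
            warnings.warn(
                f"pair ({name_a},{name_b}): only {len(shared)} shared species; skipped",
                stacklevel=2,
            )
            continue
        x = {s: gc_tables[name_a][s] for s in shared}
        y = {s: gc_tables[name_b][s] for s in shared}
        tree_a = prune_to_taxa(trees[name_a], set(shared))
        tree_b = prune_to_taxa(trees[name_b], set(shared))
        topologies = {
            f"tree_{name_a}": tree_a,
            f"tree_{name_b}": tree_b,
            "unit_branches": with_unit_lengths(tree_a),
        }
        for topo_name, tree in topologies.items():
            cr = crunch_regression(pic(tree, x), pic(tree, y))
            pg = pgls(tree, x, y)
            for res in (cr, pg):
                rows.append(
                    {
                        "pair": f"{name_a}~{name_b}",
                        "method": res.method,
                        "topology": topo_name,
                        "slope": res.slope,
                        "p_value": res.p_value,
                        "r_squared": res.r_squared,
                        "significant": res.p_value < alpha,
                    }
                )
    return pd.DataFrame(rows)
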