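"""End-to-end orchestration of the two analysis arms.

`run_features` runs genome-feature extraction followed by the three
regression styles (classic OLS, PGLS, crunch contrasts) side by side and
the mediation tests; `run_gc_models` runs the five-model ladder, the LRT
table, and the ancestral %GC/GC* reconstruction.  All randomness flows
from explicit seeds, so equal configs give byte-identical reports.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .alignment import Alignment, read_alignment
from .contrasts import ALPHA_FEATURES, crunch_regression, mediation_test, pgls, pic
from .features import build_feature_table
from .model import LADDER, fit_hierarchy
from .trees import PhyloTree, read_clade_defs, read_newick

log = logging.getLogger("gcphylo")


def _ols(x: dict[str, float], y: dict[str, float], taxa: list[str]):
    xv = np.array([x[t] for t in taxa])
    yv = np.array([y[t] for t in taxa])
    fit = sm.OLS(yv, sm.add_constant(xv)).fit()
    return float(fit.params[1]), float(fit.pvalues[1]), float(fit.rsquared)


def run_features(
    genomes: dict[str, tuple[str, str]],
    tree: PhyloTree,
    min_repeat_len: int = 20,
    alpha: float = ALPHA_FEATURES,
    trait_table: pd.DataFrame | None = None,
) -> dict:
    """Feature arm: feature table + three-way regression report + mediation.

    `genomes` maps species to (fasta, gff3) text; alternatively pass a
    precomputed `trait_table`.  Log transforms are applied to GL and NRS
    before contrasts (linearity), as is standard for these variables.
    """
    if trait_table is None:
        table = build_feature_table(genomes, min_repeat_len=min_repeat_len)
    else:
        table = trait_table.copy()
    unmatched = sorted(set(table.index) ^ set(tree.taxa()))
    if unmatched:
        raise ValueError(f"species/tree mismatch: {unmatched}")
    work = pd.DataFrame(index=table.index)
    if "GL" in table:
        work["log_GL"] = np.log(table["GL"].astype(float))
    for col in ("pct_GC", "pct_NC", "NPG"):
        if col in table:
            work[col] = table[col].astype(float)
    if "NRS" in table:
        if (table["NRS"] <= 0).any():
            log.warning("NRS has zero counts; log(NRS) uses log1p")
            work["log_NRS"] = np.log1p(table["NRS"].astype(float))
        else:
            work["log_NRS"] = np.log(table["NRS"].astype(float))
    for col in table.columns:
        if col not in ("GL", "NRS") and col not in work:
            work[col] = table[col].astype(float)
    constant = [c for c in work.columns if work[c].nunique() <= 1]
    if constant:
        log.info("dropping constant traits from regressions: %s", constant)
        work = work.drop(columns=constant)
    taxa = [t for t in tree.taxa() if t in work.index]
    rows = []
    for xcol, ycol in itertools.combinations(work.columns, 2):
        x = work[xcol].to_dict()
        y = work[ycol].to_dict()
        slope, p, r2 = _ols(x, y, taxa)
        rows.append({"x": xcol, "y": ycol, "method": "ols", "slope": slope,
                     "p_value": p, "r_squared": r2, "significant": p < alpha})
        pg = pgls(tree, x, y)
        rows.append({"x": xcol, "y": ycol, "method": "pgls", "slope": pg.slope,
                     "p_value": pg.p_value, "r_squared": pg.r_squared,
                     "significant": pg.p_value < alpha})
        cr = crunch_regression(pic(tree, x), pic(tree, y))
        rows.append({"x": xcol, "y": ycol, "method": "crunch", "slope": cr.slope,
                     "p_value": cr.p_value, "r_squared": cr.r_squared,
                     "significant": cr.p_value < alpha})
    report = pd.DataFrame(rows)
    mediations = {}
    if {"log_NRS", "pct_NC", "pct_GC"} <= set(work.columns):
        mediations["log_NRS->pct_NC->pct_GC"] = mediation_test(
            tree, work["log_NRS"].to_dict(), work["pct_NC"].to_dict(),
            work["pct_GC"].to_dict(), alpha=alpha,
        )
    if {"log_NRS", "pct_NC", "log_GL"} <= set(work.columns):
        mediations["log_NRS->pct_NC->log_GL"] = mediation_test(
            tree, work["log_NRS"].to_dict(), work["pct_NC"].to_dict(),
            work["log_GL"].to_dict(), alpha=alpha,
        )
    return {"features": table, "regressions": report, "mediations": mediations}


def run_gc_models(
    alignment: Alignment,
    tree: PhyloTree,
    clade_defs: dict[str, dict[str, set[str]]],
    p_inv: bool = False,
    seed: int = 0,
    levels: tuple[str, ...] = LADDER,
    reconstruct_on: str = "terminal_clades",
) -> dict:
    """Model arm: five-model ladder, LRT table, ancestral reconstruction."""
    hierarchy = fit_hierarchy(
        alignment, tree, clade_defs, p_inv=p_inv, seed=seed, levels=levels
    )
    recon_fit = hierarchy.fits.get(reconstruct_on) or list(hierarchy.fits.values())[-1]
    reconstruction = recon_fit.ancestral_gc(method="expected")
    return {
        "hierarchy": hierarchy,
        "table": hierarchy.table(),
        "reconstruction": reconstruction,
        "annotated_newick": reconstruction.annotated_newick(),
    }


def load_inputs(
    alignment_path: str | Path | None = None,
    tree_path: str | Path | None = None,
    clades_path: str | Path | None = None,
):
    """Read the standard input files (FASTA, Newick, clade TSV)."""
    out = {}
    if alignment_path:
        out["alignment"] = read_alignment(str(alignment_path))
    if tree_path:
        out["tree"] = read_newick(Path(tree_path).read_text())
    if clades_path:
        out["clades"] = read_clade_defs(Path(clades_path).read_text())
    return out
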