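"""Independent contrasts, PGLS, mediation, Bonferroni, concomitance."""

import dendropy
import numpy as np
import pytest

import gcphylo as g
from gcphylo.contrasts import bm_covariance
from gcphylo.simulate import simulate_bm


class TestPIC:
    def test_two_taxon_formula(self):
        tree = g.read_newick("(A:1,B:1);")
        contrasts = g.pic(tree, {"A": 3.0, "B": 1.0})
        assert contrasts == pytest.approx([np.sqrt(2.0)])

    def test_constant_trait_gives_zero_contrasts(self):
        tree = g.random_tree(10, seed=0)
        assert np.allclose(g.pic(tree, {t: 5.0 for t in tree.taxa()}), 0.0)

    def test_count_is_nleaves_minus_one(self):
        tree = g.random_tree(17, seed=1)
        trait = {t: float(i) for i, t in enumerate(tree.taxa())}
        assert len(g.pic(tree, trait)) == 16

    def test_linearity(self):
        tree = g.random_tree(12, seed=2)
        rng = np.random.default_rng(0)
        x = {t: float(v) for t, v in zip(tree.taxa(), rng.normal(size=12))}
        y = {t: float(v) for t, v in zip(tree.taxa(), rng.normal(size=12))}
        combo = {t: 2.0 * x[t] - 3.0 * y[t] for t in x}
        assert g.pic(tree, combo) == pytest.approx(
            2.0 * g.pic(tree, x) - 3.0 * g.pic(tree, y), abs=1e-10
        )

    def test_against_dendropy_oracle(self):
        """Contrast values match dendropy's PIC implementation."""
        tree = g.random_tree(9, seed=5)
        rng = np.random.default_rng(3)
        trait = {t: float(v) for t, v in zip(tree.taxa(), rng.normal(size=9))}
        mine = sorted(np.abs(g.pic(tree, trait)))
        dtree = dendropy.Tree.get(data=tree.write_newick(), schema="newick")
        cm = dendropy.ContinuousCharacterMatrix.from_dict(
            {t: [v] for t, v in trait.items()},
            taxon_namespace=dtree.taxon_namespace,
        )
        pic = dendropy.model.continuous.PhylogeneticIndependentContrasts(
            tree=dtree, char_matrix=cm
        )
        ctree = pic.contrasts_tree(character_index=0, annotate_pic_statistics=True)
        oracle = sorted(
            abs(nd.pic[0]["pic_contrast_standardized"])
            for nd in ctree.preorder_internal_node_iter()
        )
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_variance_homogeneity_of_standardized_contrasts(self):
        """On BM data, |contrast| is uncorrelated with its expected SD."""
        tree = g.random_tree(50, seed=8, depth=1.0)
        rng = np.random.default_rng(8)
        trait = simulate_bm(tree, 1.0, 0.0, rng)
        contrasts = g.pic(tree, trait)
        heights = np.arange(len(contrasts), dtype=float)
        r = np.corrcoef(np.abs(contrasts), heights)[0, 1]
        assert abs(r) < 0.3

    def test_missing_taxon_rejected(self):
        tree = g.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            g.pic(tree, {"A": 1.0})


class TestCrunch:
    def test_exact_linear_contrasts(self):
        x = np.array([1.0, -2.0, 0.5, 3.0])
        res = g.crunch_regression(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_through_origin_no_intercept(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10.0  # strong offset must NOT be absorbed
        res = g.crunch_regression(x, y)
        assert res.slope != pytest.approx(1.0, abs=0.5)

    def test_null_calibration(self):
        """Independent contrasts: p-values behave uniformly under the null."""
        rng = np.random.default_rng(12)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            hits += g.crunch_regression(x, y).p_value < 0.05
        assert 0.02 <= hits / n_reps <= 0.09

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            g.crunch_regression(np.zeros(5), np.ones(5))


class TestPGLS:
    def test_star_tree_equals_ols(self):
        tree = g.read_newick("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(4)
        x = {t: float(v) for t, v in zip(tree.taxa(), rng.normal(size=5))}
        y = {t: float(v) for t, v in zip(tree.taxa(), rng.normal(size=5))}
        import statsmodels.api as sm

        xv = np.array([x[t] for t in tree.taxa()])
        yv = np.array([y[t] for t in tree.taxa()])
        ols = sm.OLS(yv, sm.add_constant(xv)).fit()
        res = g.pgls(tree, x, y)
        assert res.slope == pytest.approx(float(ols.params[1]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ols.pvalues[1]), abs=1e-10)

    def test_crunch_slope_equals_pgls_slope(self):
        """Through-origin regression on contrasts is algebraically the
        BM-PGLS slope: checked on 10 random BM datasets."""
        rng = np.random.default_rng(44)
        for rep in range(10):
            tree = g.random_tree(12, seed=rep, depth=1.0)
            x = simulate_bm(tree, 1.0, 0.0, rng)
            noise = simulate_bm(tree, 0.5, 0.0, rng)
            y = {t: 3.0 * x[t] + noise[t] for t in x}
            cr = g.crunch_regression(g.pic(tree, x), g.pic(tree, y))
            pg = g.pgls(tree, x, y)
            assert cr.slope == pytest.approx(pg.slope, abs=1e-8)

    def test_slope_recovery_under_bm(self):
        rng_seeds = range(50)
        hit = 0
        for s in rng_seeds:
            tree = g.random_tree(20, seed=s, depth=1.0)
            rng = np.random.default_rng(1000 + s)
            x = simulate_bm(tree, 1.0, 0.0, rng)
            noise = simulate_bm(tree, 0.3, 0.0, rng)
            y = {t: 3.0 * x[t] + noise[t] for t in x}
            res = g.pgls(tree, x, y)
            hit += abs(res.slope - 3.0) <= 2 * res.se
        assert hit >= 45  # ~90% nominal coverage of 2 SE

    def test_covariance_is_shared_path_length(self):
        tree = g.read_newick("((A:1,B:1):2,C:3);")
        cov = bm_covariance(tree, ["A", "B", "C"])
        assert cov[0, 0] == pytest.approx(3.0)
        assert cov[0, 1] == pytest.approx(2.0)
        assert cov[0, 2] == pytest.approx(0.0)

    def test_singular_covariance_rejected(self):
        tree = g.read_newick("((A:0,B:0):1,C:1);")
        x = {"A": 1.0, "B": 2.0, "C": 3.0}
        with pytest.raises(ValueError, match="singular"):
            g.pgls(tree, x, x)


class TestMediation:
    def test_planted_chain_detected(self):
        """x -> m -> y with no direct path: verdict 'mediated' in >=80%."""
        detected = 0
        for rep in range(50):
            tree = g.random_tree(40, seed=300 + rep, depth=1.0)
            table, _ = g.simulate_bm_traits(tree, g.TraitRecipe(seed=300 + rep))
            m = g.mediation_test(
                tree,
                table["log_NRS"].to_dict(),
                table["pct_NC"].to_dict(),
                table["pct_GC"].to_dict(),
            )
            detected += m.verdict == "mediated"
        assert detected >= 40

    def test_independent_mediator_not_mediated(self):
        tree = g.random_tree(40, seed=77, depth=1.0)
        rng = np.random.default_rng(77)
        x = simulate_bm(tree, 1.0, 0.0, rng)
        m = simulate_bm(tree, 1.0, 0.0, rng)
        y = simulate_bm(tree, 1.0, 0.0, rng)
        res = g.mediation_test(tree, x, m, y)
        assert res.verdict == "not mediated"

    def test_deterministic_direct_path_retained(self):
        tree = g.random_tree(30, seed=13, depth=1.0)
        rng = np.random.default_rng(13)
        x = simulate_bm(tree, 1.0, 0.0, rng)
        noise = simulate_bm(tree, 1.0, 0.0, rng)
        y = dict(x)  # y = x exactly
        res = g.mediation_test(tree, x, noise, y)
        assert res.verdict == "direct effect retained"
        assert res.direct_p < 0.005

    def test_collinear_mediator_flagged(self):
        tree = g.random_tree(20, seed=21, depth=1.0)
        rng = np.random.default_rng(21)
        x = simulate_bm(tree, 1.0, 0.0, rng)
        y = simulate_bm(tree, 1.0, 0.0, rng)
        res = g.mediation_test(tree, x, dict(x), y)
        assert res.flagged_collinear
        assert "no verdict" in res.verdict


class TestBonferroni:
    def test_strict_inequality_at_threshold(self):
        flags = g.bonferroni_flag([0.004, 0.0079, 0.008, 0.5], 0.008)
        assert flags == [True, True, False, False]

    def test_feature_arm_threshold(self):
        assert g.bonferroni_flag([0.004, 0.005], 0.005) == [True, False]

    def test_empty(self):
        assert g.bonferroni_flag([], 0.005) == []

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            g.bonferroni_flag([1.2], 0.005)


@pytest.fixture(scope="module")
def gc_data():
    names = ["mtSSU", "mtLSU", "cpSSU", "cpLSU", "nSSU"]
    taxa = [f"S{j}" for j in range(12)]
    trees = {
        n: g.random_tree(12, seed=i, depth=1.0, taxa=taxa)
        for i, n in enumerate(names)
    }
    rng = np.random.default_rng(0)
    gc = {}
    for n in names:
        values = simulate_bm(trees[n], 1.0, 0.0, rng)
        gc[n] = {t: 0.5 + 0.05 * values[t] for t in taxa}
    return gc, trees


class TestConcomitance:

    def test_output_bookkeeping(self, gc_data):
        gc, trees = gc_data
        report = g.concomitance_suite(gc, trees)
        assert len(report) == 6 * 3 * 2  # pairs x topologies x methods
        assert set(report["method"]) == {"crunch", "pgls"}

    def test_identical_gc_vectors_fully_concomitant(self, gc_data):
        gc, trees = gc_data
        tables = {"mtSSU": gc["mtSSU"], "mtLSU": dict(gc["mtSSU"])}
        report = g.concomitance_suite(
            tables, {"mtSSU": trees["mtSSU"], "mtLSU": trees["mtSSU"]},
            pairs=[("mtSSU", "mtLSU")],
        )
        assert np.allclose(report["slope"], 1.0)
        assert np.allclose(report["r_squared"], 1.0)
        assert report["significant"].all()

    def test_independent_evolution_rarely_significant(self):
        """Null suite: with GC evolving independently on the accepted
        phylogeny, none of the six Bonferroni-corrected pairwise
        comparisons is significant in >=90% of replicates.  The decision
        unit is the six pairs under the pair's own phylogeny; the
        equal-branch-length rows are robustness output whose contrasts
        are deliberately mis-standardized, so they are not part of the
        corrected family."""
        taxa = [f"S{j}" for j in range(12)]
        names = ["mtSSU", "mtLSU", "cpSSU", "cpLSU", "nSSU"]
        clean = 0
        n_reps = 30
        for rep in range(n_reps):
            rng = np.random.default_rng(9000 + rep)
            base = g.random_tree(12, seed=rep, depth=1.0, taxa=taxa)
            trees = {n: base for n in names}
            gc = {}
            for n in names:
                values = simulate_bm(base, 1.0, 0.0, rng)
                gc[n] = {t: 0.5 + 0.05 * values[t] for t in taxa}
            report = g.concomitance_suite(gc, trees)
            primary = report[report["topology"] != "unit_branches"]
            clean += not primary["significant"].any()
        assert clean >= int(0.9 * n_reps) - 1

    def test_too_few_shared_species_skipped_with_warning(self, gc_data):
        gc, trees = gc_data
        tables = {"mtSSU": gc["mtSSU"], "mtLSU": {"S0": 0.5, "S1": 0.6}}
        with pytest.warns(UserWarning, match="shared species"):
            report = g.concomitance_suite(
                tables, trees, pairs=[("mtSSU", "mtLSU")]
            )
        assert report.empty
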