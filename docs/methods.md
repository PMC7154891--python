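# Methods

## Substitution model

Each branch class *c* evolves under a Tamura-92-type process with
equilibrium GC content θ_c ∈ (0,1) and transition/transversion ratio κ
shared across the tree.  Off-diagonal rates are κ·π_j for transitions
and π_j for transversions with π_G = π_C = θ_c/2 and
π_A = π_T = (1−θ_c)/2.  The process on a single branch is reversible
with respect to its own equilibrium; non-stationarity and
non-homogeneity are tree-level properties: the root composition θ_root
is a free parameter distinct from any branch equilibrium, and branch
classes carry different θ.

Two deliberate conventions:

* **Branch-length normalization.**  Each class's generator is rescaled
  so the expected substitution rate *at its own equilibrium* is one per
  site.  Under a non-stationary model the notion "one substitution per
  unit branch length" is ambiguous (the process is not at equilibrium
  along the branch); normalizing at the class's own equilibrium keeps
  branch lengths comparable across classes and across ladder levels.
* **GC\* identity.**  The directional substitution rates of the
  generator satisfy r(AT→GC)/(r(AT→GC)+r(GC→AT)) = θ identically, so
  the fitted θ of a class is reported directly as the GC* of its
  branches; no separate rate computation is needed (the identity is
  asserted in the test suite to 1e-12).

Rate heterogeneity uses the discrete-gamma approximation with k = 4
equal-weight categories.  Category rates are the conditional *means*
over the quantile bands (not medians), renormalized to mean exactly 1.
An optional invariant-site proportion p_inv mixes a constant-site term
with the gamma mixture; it is off by default and enabled per run to
check robustness.

P(t) is computed by symmetric eigendecomposition of the reversible
generator (D^{1/2} Q D^{-1/2} with D = diag(π) is symmetric), which is
stable for the long branches used in equilibrium checks; the test suite
verifies it against scipy's independent matrix exponential to 1e-10.

## Likelihood and fitting

Felsenstein pruning with branch-specific transition matrices (class θ,
shared κ, branch length × category rate), root partials summed against
the free root composition, gamma mixture averaged per site, site
patterns compressed once per alignment.  Ambiguity codes are missing
data (partial likelihood 1 over compatible states); alignment columns
containing any gap are removed on load, because per-sequence stripping
would desynchronize sites.

Optimization is L-BFGS-B in transformed coordinates (logit for all θ
and p_inv, log for κ and α) with multi-start: a neutral start
(θ = 0.5, κ = 2, α = 1), an empirical start (per-class observed leaf
GC), an optional warm start from the coarser ladder level, and
perturbations of the best point.  Convergence tolerance is 1e-6 on
−lnL; non-convergence after all restarts is flagged on the results
object, and ancestral reconstruction refuses unconverged fits unless
forced.

### Model ladder and LRT

The five levels refine the branch-class partition: homogeneous (1
class) → major-clade model → the same with one group split → terminal
clades → one θ per branch.  Each level is warm-started from the
previous fit (a refined class inherits its parent class's θ).  A level
whose partition is identical to the previous one (e.g. no group to
split in a given dataset) is skipped — datasets genuinely lack some
clades, and a 0-df test is meaningless.

LRT degrees of freedom equal the difference in free θ count, i.e. the
class-count difference; κ, α and the root are shared across levels of a
ladder.  Published tables of this kind print dataset-specific dfs that
depend on which clades each alignment contains; the generic rule here
reproduces them when the same groups are present.  The chi-square upper
tail is computed with the regularized upper incomplete gamma function,
accurate in the far tail.

### Branch-class assignment

Named clades must be monophyletic; the branch subtending a clade's MRCA
belongs to the clade's class, as do all branches inside it.  A backbone
branch whose descendant leaves span several named groups takes the
class of the earliest-listed group below it.  This is one deterministic
choice among several defensible ones (reference software for these
models does not document its rule); it guarantees every branch is
classified and that finer schemes refine coarser ones.

## Ancestral %GC and GC*

The primary reconstruction is the deterministic model-expected
composition: the root gets the fitted root frequencies and each child
node's composition is its parent's propagated through the branch's
transition matrix, gamma-averaged.  Expected GC therefore moves
monotonically from the parent value toward the branch's θ.  A
cross-check mode computes per-site marginal posterior state
distributions (inside-outside, gamma categories mixed by posterior
weight) and averages the posterior GC over sites; on simulated data the
two agree to about ±0.02 at 2000 sites.  The pseudo-bootstrap resamples
alignment sites with replacement and refits the θ vector with κ/α held
fixed (B = 100 by default).

Annotated trees carry node labels `GC(GC*)` at two decimals; labels are
quoted in the Newick output so the annotation round-trips through the
parser.

## Genome features and repeats

Per-genome variables: GL (length), pct_GC (unambiguous bases only),
pct_NC (1 − union of annotated gene intervals / GL; overlaps counted
once; 1-based inclusive GFF3 coordinates), NPG (gene features with a
CDS child — rRNA/tRNA genes are deliberately excluded), NRS, RSL and
GC-within-repeats.

The repeat finder enumerates *maximal exact repeat pairs* in four
orientations (forward, reverse, complement, reverse complement) by
seed-and-extend on exact k-mers with k equal to the minimum length:
every maximal match of length ≥ k contains an aligned seed, and
extension from any seed reconstructs the same maximal pair, so the
enumeration is exact — the suite asserts exact agreement with a
brute-force all-substring-pairs oracle on sequences up to 200 bp for
all four kinds.  NRS counts maximal pairs; RSL is the per-base union of
all copies, so nested and overlapping hits are not double-counted
(repeat-family counting and copy-summed lengths are alternative
definitions the literature does not pin down; these are ours, stated).
Genomes are treated as linear by default; a circular flag doubles the
sequence virtually and maps hits back modulo the length.

## Contrasts, PGLS, mediation

Independent contrasts follow Felsenstein's algorithm (differences of
daughter values standardized by the square root of summed augmented
branch lengths).  Polytomies are resolved arbitrarily with 1e-8-length
branches to keep covariance matrices nonsingular.  All contrast
regressions are forced through the origin.  PGLS uses generalized least
squares with covariance equal to shared root-to-MRCA path length
(Brownian motion).  The through-origin contrast slope is algebraically
identical to the PGLS slope of the intercept model — contrasts are
orthogonal to the constant — and the suite asserts this to 1e-8;
PGLS without an intercept is a different estimator and is available via
a flag but is not the comparison target.

Mediation is Baron–Kenny on contrasts: y~x, m~x, y~x+m, all through the
origin; the verdict is "mediated" when the first two are significant
and x's coefficient in the third is not, at the configured α; the Sobel
z is reported as supplementary output.  A mediator nearly collinear
with x (|r| > 0.999) is flagged with no verdict.

Significance thresholds are Bonferroni-style fixed cutoffs with strict
inequality: 0.005 for the genome-feature arm and 0.008 for the six
between-compartment concomitance comparisons.  The concomitance suite
reports each pair under three topologies (each member's own tree and an
all-branch-lengths-one tree) and both methods; the corrected family is
the six pairwise decisions under the pair's own phylogeny — the
unit-branch rows deliberately mis-standardize contrasts as a robustness
probe and are not part of the corrected family.

## Synthetic data: what it emulates, and what it does not

* `simulate_alignment` draws root states from the root composition and
  evolves them down the tree with branch- and category-specific
  transition matrices — exactly the fitted model's generative process.
  It does not emulate alignment error, indels, or among-site
  compositional heterogeneity beyond the gamma mixture, so passing
  recovery tests shows correctness of the estimator under the model,
  not robustness to real-data misspecification.
* `simulate_bm_traits` plants the chain log-repeat-count → non-coding
  fraction → GC (and non-coding → log-length) with independent BM
  noise.  Default path coefficients are chosen so the mediator
  relationships explain roughly half to four-fifths of trait variance,
  the regime reported for real organellar genome tables; real traits
  are bounded and heteroscedastic, which BM is not.
* `synth_genome` uses i.i.d. background bases at a target GC: spurious
  maximal repeats of ≥ 20 bp are then vanishingly improbable at desk
  lengths, so planted-truth comparisons are clean.  Real organellar
  genomes have skewed oligonucleotide composition and repeat families;
  none of that is modeled.

Every generator is a pure function of its seed.

## Problem sizes and numerical choices

Stochastic suites use 12-taxon 4-clade trees with 2000 sites for
parameter recovery (20 replicates), 8-taxon 500-site homogeneous
simulations for LRT calibration (50 replicates), and 40-leaf trees for
mediation (50 replicates) — sizes at which the quantities of interest
(recovery error ≤ 0.05, type-I error near 0.05, detection rate ≥ 80%)
are stable across seeds while the whole suite stays fast.  Optimizer
ties between restarts are broken by lowest −lnL; degenerate inputs
(zero-length branches, constant traits, all-ambiguous sequences) either
have defined limits (P(0) = I, zero contrasts) or raise informative
errors, as exercised in the tests.

## Known limitations

* κ and α are shared across branch classes; the ladder frees only θ.
* Branch lengths are fixed inputs (joint re-optimization is out of
  scope for the ladder; trees are expected to come with re-optimized
  lengths).
* No GTR-family matrices: the model space is deliberately the
  θ/κ family in which GC* is identified.
* The mediation verdict is the classical decision rule on contrasts,
  not a counterfactual-inference estimator.
* PGLS assumes plain Brownian motion (no Pagel's λ or OU transforms).
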