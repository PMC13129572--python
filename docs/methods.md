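# Methods

## Problem and approach

`shapqtl` maps quantitative trait loci (QTL) and QTL–QTL interactions
(epistasis) in biparental cross populations by fitting gradient-boosted
regression trees to marker genotypes and attributing the fitted phenotype to
markers and marker pairs with Shapley additive explanations (SHAP).  Tree
ensembles capture non-additive structure that single-marker scans miss;
Shapley attribution turns the black-box fit into per-line, per-marker
effect estimates with the local-accuracy guarantee that the attributions of
a line sum to its fitted value.

The mapping signal for a marker is a *global* score obtained by averaging
absolute per-line attributions; for a marker pair it is the mean absolute
total pairwise attribution.  Detection is a ranking problem, evaluated with
ROC curves and AUC against ground-truth windows around the simulated QTL.

## Cross simulation

Meiosis uses the Haldane model: per chromosome, crossover counts are
Poisson with mean L/100 (L in cM) and crossover positions are uniform — no
interference.  The recombination fraction between loci d cM apart is
r = (1 − e^(−2d/100))/2; this closed form is the calibration oracle for the
simulator tests.

* **F2**: each line is the sum of two independent F1 gametes; dosages count
  parent-A alleles (0/1/2) and segregate 1:2:1 per locus.
* **RIL** (recombinant inbred lines by selfing): lines are fully homozygous
  (dosages 0/2); parental origin along a chromosome is simulated directly
  as a Markov chain with adjacent-interval switch probability
  r\* = 2r/(1 + 2r), the standard asymptotic map expansion for selfed RIL.
  We simulate the limit process rather than discrete selfing generations,
  so there is no residual heterozygosity by construction.

QTL are extra loci simulated on the same gametes as the markers (exact
linkage) and then hidden from the analysis.  Positions are continuous cM
values on a per-chromosome axis starting at 0 and need not coincide with
markers.

## Study scenarios

All nine scenarios share a map of 8 chromosomes × 120 cM with 20 uniformly
placed markers each (160 markers), 5 QTL, and broad-sense heritability 0.8.
Scenarios vary: population type (F2 or RIL), gene action (additive,
complete dominance, overdominance), population size (200 or 400),
interaction-effect variance (1 or 16), the number of QTL with non-zero main
effects (5 or 2), and linkage (scenario 9 places a 30-cM-spaced triple on
one chromosome and a 30-cM-spaced duo on another).  In scenarios 1–8 the
five QTL land on five random chromosomes and 5 of the 10 QTL pairs are
declared interacting at random; in scenario 9 the interacting pairs are the
three within-triple pairs, the within-duo pair, and one random
cross-chromosome pair.  The linked-island start positions in scenario 9 are
uniform subject to fitting on the chromosome.

## Phenotype model

Genotype dosages are coded per target gene action: additive (−1, 0, 1),
complete dominance (0, 1, 1), overdominance (0, 1, 0).  Main effects a_q
and pairwise interaction effects b_qr are drawn from N(0, sd²) (sd = 1 by
default; sd = 4 for the high-epistasis scenario).  Genetic values are

    g_i = Σ_q a_q z_iq + Σ_(q,r) b_qr z_iq z_ir

over the interacting pairs.  Residuals are N(0, σe²) with
σe² = Var(g)·(1 − H²)/H², scaled against the *realized* sample variance of
each replicate's genetic values, so every replicate targets H² = 0.8
regardless of the drawn effects.  Realized variance shares are reported as
Var(main)/Var(phenotype) and Var(interaction)/Var(phenotype) with the n−1
denominator, ignoring the (random-sign) covariance terms — across
replicates the two shares sum to ≈ H² in expectation.

Because both main and interaction effects are random draws, the realized
shares vary strongly between replicates (the main share has an
across-replicate SD near 0.16 at these settings); 10-replicate means of the
shares should be read with that sampling width in mind.

## Boosting

Fitting is squared-error gradient tree boosting (xgboost).  Three presets
pin the fitting regimes studied:

| preset   | learning rate | max depth | stopping |
|----------|--------------|-----------|----------|
| moderate | 0.3 (default) | 6 (default) | early stop after 3 stalled rounds |
| underfit | 0.1          | 3         | early stop after 3 stalled rounds |
| overfit  | 0.3          | 6         | exactly 50 rounds, no early stop |

Other hyperparameters are pinned to L2 penalty 1, γ 0, no row/column
subsampling, so the presets stay reproducible if library defaults drift.
Early stopping monitors RMSE on a held-out set and the returned ensemble is
truncated to the best iteration.  The round cap for the early-stopped
presets is 200, far above where stopping triggers at these sample sizes.
The base prediction is the training-phenotype mean (not the library's 0.5
default), so leaf weights model deviations from the mean and SHAP base
values are interpretable for regression.  The tree structure (split
features, thresholds, children, leaf weights, covers) is extracted
losslessly; routing is "strictly less than goes left" everywhere.

## Shapley attribution

The value function is the path-dependent conditional expectation: routing
follows the instance at nodes splitting on conditioned features and takes
cover-weighted averages of both branches elsewhere.  The exact engine
enumerates feature subsets and applies the Shapley weights of the
cooperative-game definition directly, for both per-feature values and
pairwise interaction indices; the diagonal ("pure" main effect) is defined
by φ_ii = φ_i − Σ_{j≠i} φ_ij.  Enumeration runs over the features actually
used by the ensemble (unused features are dummy players with exactly zero
attribution), with configurable guards at 15 features (values) and 12
(interactions) to keep runtime in seconds.

The fast route delegates to the fitting library's exact tree-SHAP
contribution and interaction outputs when a fitted booster is attached;
hand-built ensembles fall back to the enumeration.  The two routes agree to
about 1e−7 on randomized small ensembles (the library returns float32;
attribution magnitudes here are order 1), and the test suite enforces
agreement at 1e−6 together with local accuracy, symmetry, and the
φ_i = φ_ii + Σ φ_ij decomposition.  Returned interaction matrices are
symmetrized (averaging with the transpose) to remove float32 round-off
asymmetry; the exact object is symmetric.

## The bootstrap pipeline

Each of n_boot = 100 replicates (default) draws n lines with replacement;
in-bag lines train the booster and the out-of-bag complement drives early
stopping.  SHAP and SHAP-interaction values are computed for **all**
original lines under each replicate's model and averaged across replicates.
Evaluating all lines (rather than in-bag only) gives every line equal
weight in every replicate and makes the average well-defined; the
alternative reading (in-bag only) would weight lines by their bootstrap
multiplicity.  Replicate seeds are master_seed + replicate index.  An empty
out-of-bag set triggers a logged redraw (vanishing probability at n ≥ 20).

Global scores: compound = mean_i |mean_b φ_i(j)|, pure =
mean_i |mean_b φ_ii(j)|, pair score = mean_i |2·mean_b φ_ij| (the factor 2
because the symmetric matrix splits each pair's effect across both
entries).  The interaction tensor is n × p × p and costs roughly two orders
of magnitude more than the per-feature contributions; `compute_interactions=False`
skips it for main-effect-only scans.  A min-distance filter can drop
tightly linked same-chromosome pairs from pair reports (off by default);
such pairs reflect linkage disequilibrium rather than biological epistasis.

## Evaluation

A marker is a detection positive when it lies within ±10 cM (inclusive —
the boundary convention is ours) of a QTL on the same chromosome; a marker
pair is positive when its members tag the two *distinct* QTL of an
interacting pair, in either orientation.  Two markers tagging the same QTL
are a negative pair.  AUC uses the rank statistic with half credit for
ties.

## Problem sizes and numerical choices

The powered end-to-end checks run scaled-down: 5 scenario-1 replicates with
n_boot = 25 for the detection-power and fitting-regime comparisons, and 3
high-epistasis (scenario-5) replicates with n_boot = 25 for the
pair-ranking check (requiring the top-ranked pair to be a true interacting
pair in at least 2 of 3).  These sizes were chosen to keep the full suite
in the minutes range on a single core while leaving the qualitative
contrasts far from their decision boundaries; the variance-recovery and
calibration checks run at the full stated conditions (10 replicates;
10⁵ gametes/lines).

A note on detectability: a pure product term b·z_q·z_r with symmetric
codings has zero marginal effect at each locus, and greedy tree induction
rarely finds it unless the interacting loci also carry main effects or the
tree is already splitting on one of them.  The simulator draws main effects
for all QTL (except the deliberately main-free QTL of scenario 6), which is
what makes epistatic pairs recoverable; test fixtures plant main effects on
interacting loci for the same reason.

## What the simulator does and does not emulate

It reproduces biparental F2/RIL segregation, Haldane linkage, random marker
spacing, pairwise epistasis of the stated gene actions, and
per-replicate-calibrated heritability.  It does not model crossover
interference, genotyping errors or missing data, multi-parent or backcross
designs, G×E, non-Gaussian residuals, or higher-order epistasis.  Passing
tests therefore demonstrate correctness of the method's behaviour under
these idealized conditions, not performance on real data with LD between
dense markers, where attribution is known to spread across linked markers
and shrink per-marker scores.

## Known limitations

* No significance thresholds are provided for the global scores; ranking
  quality (AUC) is the supported inference mode.
* The n × p × p interaction tensor limits marker counts to the low
  thousands in memory; prune markers first for denser panels.
* Path-dependent conditional expectations assume feature independence;
  correlated (linked) markers bias attributions toward zero.
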