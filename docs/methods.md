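# Methods

This note records the statistical models, the defaults and the design
choices behind `trichoselect`, in the spirit of a model-documentation page:
what is computed, under which assumptions, and what the shipped tests do and
do not establish.

## Bioassay phenotyping

**Whitefly (no-choice clip cages).**  The unit of observation is a cage of
~15 adults scored alive/dead after the exposure period; two cages per plant,
three or more plants per accession.  Descriptive survival follows the assay
design: cage fraction → mean over a plant's cages → mean over plants, with
the SE across plant means.  Classification uses a fixed-effects binomial GLM
with logit link on per-plant aggregated counts, accession as the only
covariate and a designated susceptible standard as the intercept.  An
accession is *resistant* when its coefficient is **negative** and
Wald-significant at α = 0.05.  The sign requirement is deliberate: a bare
significance rule would also flag accessions with significantly *higher*
survival than the standard, which is the opposite phenotype.  Accessions
with 0% overall survival have no finite logit; they are excluded from the
fit, flagged, and labelled resistant directly (nothing survived).  Any other
separation (e.g. 100% survival) is reported per-accession as non-estimable
rather than raised.  A plant-level random effect (`glmer`-style) was
considered and rejected: with 2 cages × 3 plants the variance component is
weakly identified and the fixed-effects fit is deterministic and auditable.

**Thrips (leaf-disc larval survival).**  One L1 larva per well, status
recorded daily, right-censored at the follow-up horizon (parameter, default
19 days).  Kaplan–Meier curves are fitted per accession (lifelines); the
median survival time is the smallest *observed* day with S(t) ≤ 0.5 and is
reported as `inf` ("beyond horizon") when the curve never reaches 0.5.  An
optional linear interpolation of the step curve reproduces the half-day
medians some survival GUIs report; it is off by default because the data
live on a daily grid.  The joint model is a Cox proportional-hazards
regression on accession with the **Efron** tie correction — on a daily grid
most events are tied, where Breslow's approximation is known to attenuate
coefficients; Breslow remains available (`ties="breslow"`, via statsmodels
PHReg) for comparison with older toolchains.  *Resistant* means hazard ratio
> 1 versus the standard with p < 0.01 — larvae die faster on the resistant
host.  Accessions with zero deaths give a monotone partial likelihood; they
are excluded, flagged non-estimable, and labelled susceptible (the most
hospitable possible host).

## Metabolite annotation

Acylsugar nomenclature S*k*:*N* (sucrose backbone) / G*k*:*N* (glucose)
assumes **saturated, non-hydroxylated acyl chains**: esterifying one acid
CcH2cO2 adds (C_c, H_{2c−2}, O_1) to the backbone and one double-bond
equivalent (the ester carbonyl), on top of the backbone rings (2 for
sucrose, 1 for glucose), so DBE = rings + k and the label and the CHO
formula determine each other exactly.  The inverse map tries both backbones
and accepts only an exact H/O match; at equal C and O the two backbones'
implied H counts differ by 8, so no formula can match both (exhaustively
tested for k ≤ 6, N ≤ 40).  Unsaturated or hydroxylated chains fail the
bookkeeping and are rejected with a reason, never silently corrected — if a
printed mass and a printed label disagree, this layer reports the
stoichiometric mass for the label and leaves the conflict visible.
Masses are monoisotopic with the electron mass neglected, which reproduces
nominal printed adduct masses (S3:15 + Na⁺ → 617.2785 → 617).  Known
adducts: [M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+HCOO]⁻.

Retention indices use the temperature-programmed van den Dool–Kratz form
(linear interpolation between bracketing alkanes of a C8–C20 ladder), the
correct choice for a linearly ramped GC oven; the isothermal logarithmic
Kovats form is available behind a flag.  Extrapolation beyond the ladder is
an explicit opt-in.  Normalisation is (raw/IS) × dilution / fresh weight;
because lab conventions differ on whether the recorded dilution factor
multiplies or divides, `dilution_divides=True` flips it.  Structural isomers
(same formula, different retention) get "-1, -2, …" suffixes in
retention-time order.

## Random-forest permutation selection

Input is the accession × feature matrix of replicate means, untransformed
(forests are invariant to monotone per-feature scaling, so log-scaling is
cosmetic here), and the binary phenotype labels.

*Observed importances.*  Stratified 6-fold cross-validation; per training
fold a 1000-tree forest; per-fold impurity importances averaged over folds;
the scheme repeated 5× with fresh fold and tree seeds, giving a mean and SD
per feature.  Accuracy is the unweighted mean of per-fold test accuracies
over all folds × repeats (a pooled-prediction accuracy is a one-liner for
users who prefer it).  Stratification is on by default: with ~19 samples
and an 8/11 split, unstratified folds can produce single-class training
sets; if that still happens the split is re-drawn and logged.  On very
small inputs the fold count is clamped to the minority-class count.

*Null.*  Each permuted model uniformly permutes y and runs **one** full CV
pass, identical to an observed repeat.  All 500 models are computed once;
the 100- and 250-model nulls are prefix-consistent subsets under the same
seed.  Using single passes (not 5-repeat averages) for the nulls makes the
null slightly wider than the observed statistic's sampling distribution,
which errs on the conservative side for noise features.

*p-values.*  Add-one empirical p, p = (1 + #{null ≥ observed}) / (1 + n);
it can never return 0, and at n = 100 the smallest attainable value is
1/101 ≈ 0.0099, so "p < 0.01" is exactly "observed beats every one of 100
nulls".  Both the stringent 0.01 default and the laxer 0.05 threshold are
meaningful in practice; the selected flag applies the configured α to the
largest computed null, and every p column is reported so the reader can
apply either.

*Engine.*  The forest is a numba-compiled CART implementation with
scikit-learn semantics: bootstrap n-of-n, Gini impurity, a fresh
√p-feature draw per node (redrawing past the quota while only constant
features have been seen), growth to purity, per-tree normalised
mean-decrease-in-impurity importances averaged over splitting trees and
renormalised, and tree-averaged leaf frequencies for prediction.  The
motivation is throughput: the procedure needs thousands of 1000-tree fits
on tiny tables, a regime dominated by per-tree orchestration overhead in
general-purpose libraries (measured ~100× faster here at equal tree count).
`engine="sklearn"` switches to `RandomForestClassifier`, and the test suite
asserts agreement between the two (top feature, importance-profile
correlation, predictions) on planted data.

## Synthetic screens

The generator emulates the study design the pipeline targets, with ground
truth returned next to every dataset.

| parameter | default | meaning |
|---|---|---|
| `n_accessions` / `n_resistant` | 19 / 8 | panel size and true class split |
| `n_features` / `n_planted` | 80 / 2 | metabolite features, truly discriminative ones |
| `presence_prob_resistant` q_r | 0.9 | planted-feature presence in resistant lines |
| `presence_prob_susceptible` q_s | 0.1 | planted-feature presence elsewhere |
| `background_presence` p_bg | 0.15 | background-feature presence (per accession) |
| `planted_fold` | 8 | abundance multiplier, planted × resistant |
| `lognormal_mu`, `lognormal_sigma` | 10, 1 | nonzero abundance distribution (ion-count scale) |
| `n_replicates` | 6 | biological replicates (use 4 for volatile-like tables) |
| `cage_size`, `cages_per_plant`, `plants_per_accession` | 15, 2, 3 | whitefly design |
| `n_larvae`, `followup_days` | 30, 19 | thrips design |
| `baseline_daily_hazard`, `log_hr_resistant` | 0.04/day, ln 5 | thrips event-time model |
| `survival_prob_resistant/susceptible` | 0.25 / 0.75 | whitefly binomial survival |

Structure: every table entry is zero with probability 1 − presence
probability, else LogNormal(μ, σ), times `planted_fold` for planted
features in resistant accessions.  Planted features draw presence per
replicate entry (a producing genotype shows the compound in most replicate
measurements — a graded, quantitative signal), while background features
draw presence once per (accession, feature) — reproducing the hallmark
sparsity of trichome screens, where most metabolites are detected in only
one or a few accessions and all replicates of a non-producer are zero.
Both levels are configurable.  Planted features act through presence *and*
abundance because real discriminants differ in both.  Event times are
exponential (Weibull optional) with rate = baseline × exp(log HR), rounded
**up** to the observation day, censored at the horizon; the exponential
default keeps closed-form oracles available (median day = ⌈ln 2 / rate⌉,
log-HR MLE = log rate ratio with SE √(1/d₁ + 1/d₀)).  Randomness: one
`SeedSequence` per config spawns an independent PCG64 stream per stage
(features / whitefly / thrips / trichomes), so a fixed seed is bit-stable
and stages regenerate independently.

**What the synthetic screens do not emulate:** correlated metabolite
families (biosynthetic pathways co-produce compounds), batch and positional
greenhouse effects, replicate-level measurement error beyond log-normal
spread, censoring causes other than end-of-study, and accession relatedness
(phylogenetic structure).  Passing tests therefore demonstrate that the
*procedure* recovers planted signals and is calibrated under its own
assumptions — not that any particular real screen satisfies those
assumptions.

## Reporting

Relative survival scores scale the per-accession mean (whitefly) or median
(thrips) survival so the highest accession is 100%.  Trichome densities
aggregate disc → plant × surface → surface rule → accession, where the
surface rule reflects insect behaviour: whiteflies move across both leaf
surfaces (mean of abaxial and adaxial), thrips larvae are confined to the
adaxial side.  Density–survival relationships use ordinary least squares
with r² and the slope t-test p.  Metabolite clustering is complete-linkage
on Euclidean distances of log10(x+1) abundances — the transform tames the
orders-of-magnitude spread between trace and dominant compounds; raw-scale
and correlation distances are selectable, and features are pre-sorted by id
so ties break deterministically.  Abundance panels report log10 of the
replicate mean with a first-order (delta-method) SE, SE(mean)/(mean·ln 10).

## Problem sizes and numerical choices

The shipped statistical tests run: 20 seeded recovery screens and 20 pure
-noise screens at the default 19 × 80 conditions with a 100-model null
each; 500 two-arm Cox replicates (200 larvae/arm) for CI coverage; the
exhaustive 410-label stoichiometry grid.  The acceptance script uses one
screen, five noise screens and 200 Cox replicates.  Forest arithmetic is
float32 (inputs) with float64 accumulators; importances use a 1e-12
improvement tolerance so exactly-tied splits resolve to the first feature
drawn; GLM/Cox separations are flagged at SE > 50 on the link scale.
Known limitations: the native forest supports only dense numeric features
and binary-or-small class counts (all that is needed here), and empirical
p-values are lower-bounded by 1/(n_null + 1), so α below that is
unattainable by construction.
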