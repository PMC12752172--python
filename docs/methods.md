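# Methods

This note records the statistical models implemented in `microcore`, the
conventions and defaults chosen where the field offers more than one, and
what the synthetic surveys used by the test suite do and do not emulate.

## Preprocessing

Samples are retained when their library size strictly exceeds
`min_reads` (default 5,000). Contaminants (mitochondria, chloroplasts by
default) are removed by case-insensitive substring match over the joined
lineage string, so the screen catches the terms at any rank. "Unassigned"
removal defaults to OTUs with an empty lineage at *every* rank; the
stricter reading (empty at any single rank) is available via
`unassigned_mode="any"`, since rank-level annotation coverage varies
widely between reference databases.

TSS/CLR uses a half-count pseudocount by default
(`p = (x + 0.5) / Σ(x + 0.5)`, `clr = log p − mean(log p)`): zero handling
is a convention, not a estimand, so the pseudocount is exposed.

## Diversity and ordination

Alpha diversity (Shannon in nats; bias-corrected Chao1) is computed on
counts rarefied to the minimum library size by multivariate-hypergeometric
subsampling (without replacement), which is measure-preserving in
expectation. Beta diversity defaults to Bray–Curtis on TSS proportions —
rarefaction before distance computation is available but not the default,
because proportion normalisation removes library-size artefacts without
discarding reads — and unweighted UniFrac on presence/absence over the
rooted tree (computed through scikit-bio's validated implementation).

PCoA is classical metric scaling: double-centre −D²/2, eigendecompose,
keep positive-eigenvalue axes. Negative eigenvalues (non-Euclidean
distances) are reported verbatim and excluded from the
proportion-explained denominator; no Cailliez/Lingoes correction is
applied by default, so the variance fractions refer to the representable
(positive-inertia) part of the geometry.

## PERMANOVA and db-RDA selection

PERMANOVA partitions the Gower-centred squared-distance matrix
sequentially (Type I) over an ordered term list; each term's pseudo-F uses
the full-model residual, and p-values come from free permutation of
sample labels with the (1 + exceedances)/(1 + n_perm) estimator
(n_perm = 999 default). Permuted statistics are compared with a relative
tolerance of 1e-10 so permutations that are exact symmetries of the
design (e.g. within-group relabelings) count as ties; without this, the
reported p depends on floating-point summation order. A consequence worth
noting: for perfectly separated clusters the attainable p-value floor is
the fraction of partition-preserving permutations, not 1/(n_perm + 1).

Stepwise db-RDA regresses principal-coordinate scores (axes retained to
≥ 95% of positive inertia) on candidate covariates: forward steps add the
candidate with the smallest permutation p of its partial pseudo-F when
p ≤ 0.05; after each addition a backward pass drops terms whose
conditional p exceeds 0.10; the trace of every tested step is returned.

The "resilience" comparison between a taxonomic and any secondary
(e.g. functional) distance matrix is an OLS of paired distances; its slope
is a descriptive index (lower = secondary distance less responsive to
taxonomic turnover). The n(n−1)/2 pairs are not independent, so the
standard error is not a basis for formal inference.

## βMNTD / βNTI

βMNTD between samples j and k is the abundance-weighted (default) or
presence-weighted mean of each taxon's patristic distance to its nearest
taxon in the other sample; a taxon shared by both samples contributes
zero. The null shuffles tip labels on the patristic distance matrix —
richness, abundances and occupancy structure are all preserved — and
βNTI is the per-pair z-score over `n_null` (default 999) shuffles.

Sign convention: βNTI < 0 means the observed communities are
phylogenetically *closer* than the null (consistent with homogeneous
selection when < −2); βNTI > 0 means more dispersed than the null. Some
papers describe the same "more similar than chance" situation with a
positive sign; this package always uses the standard z-score direction,
so readers comparing against such descriptions should flip the narrative,
not the numbers.

The taxon pool handed to `beta_nti` defines the null: passing a table
subset to an environment while *keeping* the full taxon list (zero rows
included) asks "are these communities clustered relative to the regional
pool?", which is the question a selection test needs. Dropping all-zero
taxa first silently shrinks the pool to the observed clade and erases the
signal.

## Sloan neutral model

With metacommunity relative abundance pᵢ (estimated as the mean of
per-sample proportions), mean depth N and immigration parameter m, the
local proportion of taxon i is Beta(Nmpᵢ, Nm(1−pᵢ)) and its count in a
depth-N sample is beta-binomial. Predicted occupancy is therefore the
exact detection probability

    O_i = 1 − B(Nmpᵢ, Nm(1−pᵢ) + N) / B(Nmpᵢ, Nm(1−pᵢ)),

with the classical threshold approximation 1 − BetaCDF(1/N; ·, ·)
available as `detection="threshold"`. The exact form matters at depth:
on data simulated from the model itself the threshold form biases the
fitted m upward by ~25–30%, while the exact form recovers it within a few
percent. m is fitted by bounded 1-D least squares on occupancy;
R² = 1 − SSE/SST.

The 95% envelope is the central acceptance region of
Binomial(n_samples, O_i)/n_samples — a prediction interval for *observed*
occupancy, so a neutrally behaving taxon lands inside with ≥ 95%
probability even when O_i saturates near 0 or 1. A Wilson interval on the
prediction (`envelope="wilson"`) is retained for comparison, but it
misclassifies fully occupant taxa whenever the prediction is below ~0.99.
Taxa above the envelope are more consistently present than neutral
sampling explains (environmental selection of the "reliable presence"
kind); taxa below are patchier than neutral (dispersal limitation — or
strong sample-to-sample selection: a taxon boosted in some samples and
suppressed in others has an inflated mean abundance relative to its
occupancy and lands below, not above).

## Core microbiome

Taxa are ranked by Index = (site-specific occupancy + replication
consistency)/2, where site-specific occupancy is the group-averaged
detection fraction and replication consistency the fraction of groups in
which the taxon occurs in every replicate; both terms lie in [0, 1], so
the index does too. Ties break by total abundance, then OTU id. The
grouping variable ("site") is a parameter: amendment level for the
occupancy models, farm within a level.

The contribution curve keeps full-table sample sums in the Bray–Curtis
denominator while restricting the numerator to the top-k taxa, so
E(k) = BC_core(k)/BC_all rises monotonically from 0 to 1. The printed
complement C(k) = 1 − E(k) is reported alongside. The stopping rule adds
taxa until the next increment of E falls below 2 percentage points
(absolute, 0.02 on the [0,1] scale); at least one taxon is always
selected. Detection is count > 0.

Per-level occupancy models rerun the whole ranking/curve/selection inside
each amendment level (levels with < 2 samples are skipped with a
warning), and overlaps are reported as exclusive Venn-region counts plus
Jaccard sharing percentages after restricting each core to taxa at a
prevalence threshold (default 1.0 = present in every sample of the
level).

## GLLVM

Each taxon follows a log-link count GLM whose predictor adds a shared
latent score per sample: η_ij = β₀ⱼ + xᵢᵀβⱼ + uᵢᵀθⱼ, uᵢ ~ N(0, I_d),
d = 2 by default, family negative-binomial (Poisson available). Optional
per-sample effects are off by default. Estimation is joint-mode
(penalised quasi-likelihood): alternating per-taxon IRLS fits (our own,
with damped steps so quasi-separated dummies cannot explode the working
response) and Newton updates of the scores under their N(0, I) prior,
with convergence declared on the penalised joint log-likelihood. During
estimation the scores are kept orthogonal to the design span for
identifiability; loadings are rotated to the
upper-triangular-zero/positive-diagonal form. With d = 0 the procedure
reduces exactly to independent per-taxon GLMs, which the test suite
verifies against statsmodels.

Inference needed care, because naive conditional Wald intervals are badly
anticonservative here (~19% false-positive rate at a nominal 5% in our
calibration experiments). Three corrections bring them to ~5%:

1. **Cross-fitted scores** — each taxon's final GLM uses scores
   re-estimated from the *other* taxa only, so a taxon's own noise cannot
   leak into covariates of its own fit;
2. **Score-uncertainty and in-span variance** — the per-sample posterior
   covariance of the scores enters as extra dispersion (θⱼᵀΣᵢθⱼ), and the
   in-span component of the latent realisation — formally unidentifiable
   from covariate effects within a single taxon — is priced into the
   coefficient covariance as a random-effect term;
3. **ML dispersion + Pearson guard** — the NB dispersion is profiled by
   maximum likelihood at the inference stage (the moment estimator is
   biased low when fitted means vary widely, deflating standard errors),
   with a Pearson χ²/df ≥ 1 factor as a final guard.

Directionality is then CI-based: positive if the 95% interval lies above
zero, negative if below, none otherwise. Taxa with > 95% zero counts are
excluded with a warning. Standard errors remain conditional on the
estimated loadings; coverage was verified by simulation (power 1.0, null
false-call rate ~5% on the recovery design in the acceptance suite), not
claimed asymptotically.

## CODA-LASSO

Features are log(TSS proportion + pseudocount), with the pseudocount
(default 1e-6) added on the proportion scale so predictions are exactly
invariant to per-sample count rescaling under the zero-sum constraint.
The estimator minimises squared error (continuous response) or logistic
deviance (binary split) plus an elastic-net penalty subject to Σβ = 0.
The solver is pairwise coordinate descent on the Gram system — every
update moves mass between two taxa, so the constraint holds exactly at
every iterate — JIT-compiled with numba when available.

The penalty weight is chosen by seeded k-fold cross-validation over a
log-spaced path from the smallest all-zero λ down three decades, with two
defaults that matter for support recovery: candidate supports are refit
*unpenalised* (still zero-sum) both inside CV and for the returned model
(relaxed fits — the penalty only chooses the support, the reported
coefficients are unshrunk), and λ is picked by the one-standard-error
rule on the relaxed CV curve. Without the relaxation, shrinkage bias
drags the CV-optimal λ far down the path and the selected support
over-includes noise taxa (measured: ~10% exact support recovery on a
two-taxon log-contrast signal, vs ~98% with relaxed + 1-SE);
`relax=False` / `lambda_rule="min"` restore the plain behaviour.

## Synthetic surveys

The generator composes: a Yule topology with iid exponential branch
lengths (tips OTU_1..n); a lognormal metacommunity (log-sd 1.5);
per-sample environmental filtering p_ij ∝ p_i·exp(Σ effects·z) on
standardised covariates, by default confined to one clade (the internal
node whose tip count is closest to the requested size) with effect 1.0 on
Ca and LOI; and Sloan-type neutral sampling — Dirichlet(N·m·p) local
proportions (exact Beta marginals) followed by a multinomial count draw.
The design mirrors a 116-sample, 14-farm survey with amendment
frequencies None 0.55 / FYM 0.38 / Digestate 0.035 / Slurry 0.035 (the
two rare levels reproduce the power caveats of real surveys), four
textures, and depths uniform on [5079, 41827]. Soil chemistry is normal
with group shifts (higher LOI under digestate/slurry, higher Ca in silty
clay loam) chosen to mirror the qualitative covariate structure of
amended arable soils; no claim is made of matching any particular soil
archive's values. Default taxon count is 300, which keeps the full
pipeline under ~3 minutes on one CPU while leaving every analysis
non-trivial.

What the generator does *not* emulate: spatial autocorrelation between
fields, temporal dynamics, PCR/chimera artefacts, taxonomic mis-annotation,
or realistic phylogenetic signal in the metacommunity abundances.
Passing calibration and recovery tests on these surveys therefore shows
the estimators are correct under their stated assumptions — not that real
soil data satisfy those assumptions.

Test and acceptance problem sizes (e.g. 500 taxa × 50 samples for neutral
recovery, 30 taxa × 100 samples for GLLVM recovery, 24-sample
environments for the βNTI selection signal) were chosen as the smallest
scales at which the measured quantities stabilise.

## Pipeline

`run_pipeline` executes filter → rarefied alpha diversity → distances →
PCoA → PERMANOVA (→ optional stepwise RDA) → βNTI → Sloan → core models →
GLLVM → CODA-LASSO. One global seed is fanned out per stage through fixed
stage keys (SeedSequence), so adding or reordering stages never changes
another stage's draws; rerunning a config reproduces every numeric output
byte-for-byte. βNTI subsamples to at most `bnti_max_samples` (default 40)
samples — pair count grows quadratically and the z-scores are a per-pair
quantity, so a subsample changes precision, not meaning. The resolved
config, a run log, and per-stage TSV/JSON outputs land in the output
directory.

## Known limitations

- GLLVM standard errors are simulation-calibrated, conditional
  constructions, not marginal-likelihood asymptotics; very small taxon
  counts (p < ~10) leave the cross-fitted scores noisy.
- The Sloan fit assumes one well-mixed metacommunity; strong group
  structure (e.g. the clade-filtered environments the simulator can
  produce) pushes heterogeneous taxa *below* the envelope, which is a
  feature of the model, not a detection of dispersal limitation.
- db-RDA selection uses free permutation, which is slightly liberal for
  partial tests compared with residual permutation under the reduced
  model.
- Bray–Curtis on proportions and the core-curve's full-sum denominators
  are conventions; both have switches, and results should cite which was
  used.
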