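# Methods

This note documents the models the package implements, the defaults and why
they are set where they are, what the synthetic generators do and do not
emulate, and the numerical choices a user changing settings should know
about.

## Time conventions

Ages are Ma before present.  All time-series machinery works on forward time
t = −age (Myr, increasing toward the present), so that "X precedes Y" reads
in the ordinary direction; conversion happens only at module boundaries and
timestamps are echoed in every output.  The default stage table has 33
contiguous intervals from the Tithonian (152.1 Ma) to the present, with ICS
boundary ages; the post-Calabrian Pleistocene and the Holocene are merged
into the terminal interval to close the table at 0 Ma.  Users can supply
their own table as CSV.

## Assemblage proportions and the crossover age

Each locality/horizon with both clades present contributes one cheilostome
species proportion at its age-range midpoint.  The headline filter keeps
assemblages with ≥15 species (10 and 20 are provided as sensitivity
presets), following the sensitivity ladder of within-assemblage analyses of
this kind.

Two smoothers are fit and both crossovers reported:

* **LOESS** — local quadratic regression with tricube weights over the
  ⌈span·n⌉ nearest neighbours, span 0.75 by default.  The 95% band is the
  linear-smoother variance ‖l(x₀)‖²σ̂² with σ̂² estimated from the residual
  sum of squares corrected by the equivalent degrees of freedom
  (δ₁ = n − 2·tr L + tr LᵀL).  Evaluation is on the observed ages united
  with a uniform 200-point grid.
* **Smoothing spline** — the natural-cubic-spline minimizer of
  Σwᵢ(yᵢ−f(xᵢ))² + λ∫f″², solved in the Reinsch form
  A(λ) = I − λW⁻¹Q(R + λQᵀW⁻¹Q)⁻¹Qᵀ, which is well conditioned for all λ
  (the naive (W+λK)⁻¹W solve fails in the large-penalty limit).  λ is
  chosen by generalized cross-validation over a log-spaced bracket refined
  by bounded minimization.  We carry our own solver because the bands and
  the GCV trace need the explicit smoother matrix; scipy's
  equal-criterion smoother is used as an independent cross-check in the
  test suite.

The crossover age is where the fitted cheilostome and cyclostome curves
cross (equivalently, where either crosses 0.5, since the proportions are
complementary), located by linear interpolation on the shared grid.  Both
smoothers' crossings are reported and flagged if they disagree by more than
5 Myr.

Stage-mean proportions (one point per stage, at the stage midpoint) carry
SE = sd/√n across localities; a stage with a single locality receives the
global median per-stage SE, because a zero observation variance would be
indefensible when the series enters the observation-error-aware link
analysis.

## Capture–mark–recapture estimators

Detection matrices are genus × stage 0/1 histories.  Age-ranged records are
assigned to the stage containing their range midpoint by default (an
all-overlapped-stages policy exists for sensitivity).

**Jolly–Seber (direct).**  The classical closed-form estimators, with
m, z, r tabulated per occasion, M̂ₜ = mₜ + Rₜzₜ/rₜ, N̂ₜ = nₜM̂ₜ/mₜ,
φ̂ₜ = M̂ₜ₊₁/(M̂ₜ−mₜ+Rₜ), B̂ₜ = N̂ₜ₊₁ − φ̂ₜ(N̂ₜ−nₜ+Rₜ).  Terminal occasions
and zero-denominator occasions are flagged inestimable; direct φ̂ may exceed
one and is then reported raw with a flag, never truncated.  Confidence
intervals for richness assume a Poisson sampling model and use the exact
chi-square quantile relation (a normal-approximation option exists).  The
direct estimator assumes equal catchability; genera resident for only part
of a stage have lower exposure, so heavy turnover relative to stage length
biases N̂ — a model property, not an implementation artifact, documented in
the test suite where recovery is checked in a low-turnover regime.

**Pradel seniority.**  Fully time-varying survival φ (T−1), seniority γ
(occasions 2..T) and detection p (T), estimated on the logit scale by
multi-start L-BFGS.  The likelihood conditions each history on ≥1 detection
and closes the generative model by deriving entry probabilities from the
seniority parameters through the relative cohort sizes aₜ = aₜ₋₁φₜ₋₁/γₜ:
this makes the conditional probabilities of the observable histories sum to
exactly one, which the tests verify by brute-force enumeration at T = 3.
The likelihood reduces to O(T) sufficient statistics (first/last detection
counts, boundary-crossing counts, inside-range detection counts), so fitting
cost is independent of the number of genera.  Standard errors come from the
inverse observed information; the confounded terminal pairs (φ_{T−1} with
p_T; γ₂ with p₁) are always flagged, and a point is "well-constrained" iff
its logit-scale SE is below 2.0 (configurable).

**Rates.**  Probabilities convert to per-Myr rates under an exponential
waiting-time model.  Because occasions are stage *presences*, each boundary
probability is exposed over a specific stage: survival across boundary i
accumulates over stage i's duration, seniority at boundary i over stage
i+1's, and sampling over the stage's own duration.  The
mean-of-adjacent-durations alternative is available as a sensitivity option
(`boundary_dt="mean"`), but it is not the default: with unequal stages it
injects the same deterministic log(duration-ratio) pattern into every
clade's series, which then masquerades as between-clade correlation in the
link analysis.  SEs propagate by the delta method and the series are
log-transformed (rates) before entering the link models; proportions are
transformed as log(p + 10⁻⁴), with the small offset allowing p = 0 and SEs
propagated as se/(p + 10⁻⁴).

Even with exposure-matched intervals, stage-presence discretization leaves
residual biases of order (rate × stage length) with stage-specific
patterns; when the biological signal is weak these shared patterns can
still induce mild spurious association between series estimated on the same
stage grid.  Users comparing weak-signal series should treat correlated-
noise/one-directional wins with caution.

## Link models

Five classes for a pair of observed series, each marginally OU with mean μ,
half-life t½ = ln2/α and stationary sd s (diffusion intensity σ = s√(2α)):
A independent; B drift coupling β from series 1 into series 2's drift
(−α₂(X₂−μ₂−β(X₁−μ₁))); C the reverse; D both couplings (stable iff
β₁₂β₂₁ < 1 for the scaled drift matrix, checked numerically); E shared
Brownian shocks with correlation ρ and no drift coupling.  Model B always
means "first-listed series drives second"; outputs echo the pair order.

Transitions on an irregular grid are exact: Φ(Δ) = e^{−AΔ} by the 2×2
closed form, stationary covariance S from the Lyapunov equation, and
conditional covariance Q(Δ) = S − ΦSΦᵀ.  Observations are state plus
independent Gaussian noise with *known* per-point SEs taken from the
upstream estimators (an attitude of "embrace the uncertainties" rather than
re-estimating them); the likelihood is a Kalman filter started from the
stationary law, handling times where only one component is observed.  The
filter kernels are numba-compiled scalar code because evidence estimation
needs ~10⁴ likelihood evaluations per model.

**Priors** (declared, echoed in outputs): μ ~ N(series mean, (2·series
sd)²); t½ log-uniform on [0.1, 1000] Myr; s log-normal(ln series sd, 1);
β ~ N(0, 2.5²); ρ uniform on (−1, 1).  The coupling-prior scale was
calibrated on null simulations: a tight β prior makes the causal classes
nearly indistinguishable from the null, so evidence comparison loses
specificity and chance correlations win; at scale 2.5 the null retains a
clear majority in the moderate-memory regime while the penalty paid by true
couplings (~log 2.5 ≈ 0.9 nats) is negligible against strong signals.
Couplings far beyond |β| ≈ 2.5 are implausible in any case, since
bidirectional stability requires β₁₂β₂₁ < 1.

**Posteriors** are sampled with an affine-invariant ensemble sampler
(32 walkers, differential-evolution moves, seeded), summarized as
mean/median/95% bounds for μ, t½, the stationary variance s², and β or ρ.
Split-R̂ and bulk ESS are computed across walkers; R̂ > 1.1 on any parameter
flags the result not-converged.  Note the stationary-variance column is s²;
the diffusion intensity σ is a different quantity (σ² = 2αs²) and is not
reported, to avoid the ambiguity between the two.

**Evidence** is estimated by stepping-stone sampling along the power ladder
β_k = (k/K)^{1/0.3} (default K = 16 rungs × 2000 retained draws; pipeline
default 8 × 600, sufficient when the decisive gaps are several nats).  Rung
0 is iid from the prior with a 4× draw budget, since the prior-side ratio
dominates the estimator variance under diffuse priors; higher rungs run an
adaptive random-walk Metropolis chain warm-started from the previous rung.
The reported MC SE combines per-rung delta-method variances with a crude
autocorrelation correction.  Posterior model probabilities assume equal
model priors; Bayes factors are probability ratios, printed to 1 decimal.

**What model selection can and cannot do at these sizes.**  Selection
consistency was measured directly.  With strong signal and n = 500 points
the generating class wins essentially always.  On short series (n ≈ 30)
the discriminating quantity is the number of independent excursions of the
latent processes — span/(2·t½) — not the point count: with half-life
10 Myr over 150 Myr (~8 effective samples) chance cross-correlations of
|r| ≈ 0.4 are routine and honest Bayes factors then *correctly* report
mild support for association, so the null wins only a minority of
replicates; with half-life ~5 Myr and moderate observation noise the null
wins a clear majority.  Bidirectional feedback (D) is the hardest class to
identify: at 32 points even noise-free series generated from symmetric
positive feedback put B, C or E first in most replicates.  The packaged
strong-signal scenario therefore plants a fast (t½ = 2.5 Myr), finely
resolved (76 × 2 Myr stages), deeply sampled negative feedback loop
(β = +0.9/−0.9 — competitive release), whose rotational cross-correlation
signature only D reproduces.  Conclusions from series as short and as
slow as typical stage-level paleontological data should lean on the
weight *pattern*, not on any single pair's best model.

## Synthetic generators

* **Birth–death fossil record** — per-genus continuous-time birth–death
  with piecewise-constant per-stage rates; detection in a stage with
  probability 1 − e^{−r·(residence time)}; never-detected genera are
  dropped from the matrix but kept in the truth record, and the truth
  bookkeeping (richness = N₀ + births − deaths) is asserted in tests.
* **Assemblages** — per-stage localities at uniform ages; total species
  negative-binomial(mean 25, dispersion 5); cheilostome share binomial with
  a logistic trend (default crossover 80 Ma, slope 0.08/Myr).
* **Linked series** — sequential draws from the exact Gaussian transition
  of any model class, observed with specified noise; distinct grids per
  series are supported.
* **Seniority histories** — direct draws from the Pradel generative law
  (entry from the seniority-implied cohort masses), used for estimator
  validation because they match the fitted likelihood exactly.

All generators are pure functions of (config, seed).  What they do *not*
emulate: geographic structure and hemispheric sampling bias, taxonomic
error, within-genus species dynamics, abundance (only species counts),
correlated detection across genera (monographic effects), and age-model
uncertainty in stage assignments.  Passing tests therefore demonstrate
estimator correctness under the models' own assumptions, not robustness to
every artifact of real compilations.

## Numerical notes and degenerate inputs

* 2×2 matrix exponentials use the Cayley–Hamilton closed form with a series
  branch near the defective point; Lyapunov solves use Cramer's rule; both
  are cross-checked against scipy in the tests.
* Filter covariance updates use the form Φ(P−S)Φᵀ + S, which keeps the
  prediction step exact and stable, with symmetrization after joint
  updates.
* The rate transform drops (with a flag) points whose probability sits on a
  boundary (φ ∈ {0,1}), since the log rate is undefined there; missing
  points stay missing, never imputed.
* LOESS requires ≥ degree+2 distinct abscissae; duplicate abscissae in the
  spline are collapsed to weighted means; all-equal abscissae are an error.
* Synonymy maps must be fixed-point after one application (no chains) and
  clade-preserving; applying a map twice is a no-op.
* The birth–death simulator aborts above 2×10⁶ lineages rather than loop on
  a supercritical configuration.

## Known limitations

* Tier-level reproduction of the motivating study's real-data numbers
  requires its supplementary occurrence databases, which are not bundled;
  the pipeline accepts them as CSVs but nothing is downloaded.
* The Jolly–Seber direct estimator inherits equal-catchability bias under
  heavy within-stage turnover (see above).
* Evidence values carry Monte-Carlo error (reported); pairs whose model
  weights differ by less than a few percent should be called ties.
* The merged-database deduplication rule used by the motivating study is
  not documented there; the loader offers exact-duplicate removal only.
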