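# cladelink

Tools for asking whether one fossil clade displaced another — and whether the
displacement was *causal* — from nothing more than species occurrence lists.

The motivating system is the two great clades of calcified marine bryozoans,
cheilostomes and cyclostomes, whose reversal of local dominance during the
Late Cretaceous is a textbook example of apparent clade displacement.  The
package takes occurrence tables binned into geologic stages and produces:

1. **Within-assemblage species proportions** per locality, smoothed through
   time by locally weighted quadratic regression (tricube weights,
   nearest-neighbour span) and by a penalized cubic smoothing spline
   (penalty by generalized cross-validation), with pointwise 95% bands and
   an estimated **crossover age** — when the smoothed cheilostome proportion
   first exceeds the cyclostome proportion.
2. **Sampling-corrected global genus richness** from capture–mark–recapture
   (CMR) detection histories: the classical direct Jolly–Seber estimators
   with Poisson-sampling confidence intervals, alongside naive range-through
   counts for comparison.
3. **Instantaneous origination, extinction and sampling rates** (per Myr)
   from the fully time-varying Pradel seniority model — survival φ
   (complement: extinction), seniority γ (complement: origination) and
   detection p estimated jointly by maximum likelihood, then converted via
   an exponential waiting-time model, e.g. extinction rate = −ln(φ)/Δt.
4. **Granger-causal link analysis** between any two resulting series using
   five linear stochastic differential equation model classes.  Each series
   is marginally an Ornstein–Uhlenbeck process
   dX = −α(X − μ)dt + σ dB, reported via its half-life t½ = ln 2/α and
   stationary standard deviation s.  The classes are: A — independent;
   B — series 1 drives series 2 through a drift coupling β; C — the
   reverse; D — bidirectional feedback; E — correlated noise (association
   without causation).  Likelihoods are exact on irregular grids with known
   per-point observation error (Kalman filter started from the stationary
   law); posteriors are sampled by an ensemble MCMC sampler; models are
   compared by stepping-stone marginal likelihoods, posterior model
   probabilities and Bayes factors.

A synthetic-data module generates all of these inputs with known truth —
birth–death genus histories with stage-varying rates and residence-time
detection, locality assemblages following a controllable proportion trend,
and series pairs drawn from the exact transition law of any link-model
class — so the entire pipeline is testable end to end without any data
download.

## Worked example

Run the packaged strong-signal synthetic scenario — a two-clade world with a
planted proportion crossover at 80 Ma and a planted feedback coupling
between the clades' extinction rates — through the full analysis:

```bash
cladelink run-all --seed 0 --out runs/demo
```

which logs, after about a minute:

```
pipeline finished in 58.5s (config hash 50579c66d89eb576)
  cheil:origination|cycl:origination: best model A (56.9%)
  cheil:extinction|cycl:extinction: best model D (81.5%)
  cheil:origination|cycl:extinction: best model A (49.3%)
  cheil:extinction|cycl:origination: best model A (47.2%)
  ...
```

and writes `runs/demo/crossover.json`:

```json
{
  "loess_crossings_ma": [78.9983865633],
  "spline_crossings_ma": [79.0483448092],
  "methods_agree_within_5myr": true
}
```

Reading: the smoothed within-assemblage proportions cross at ~79 Ma (truth:
80 Ma), and for the extinction-rate pair the bidirectional feedback model D
takes 81.5% of the posterior model probability — the planted causal
structure — while the origination pair, generated independent, is assigned
to the no-relationship model A.  Per-pair percent support for all five models is in
`model_weights.csv`, the Jolly–Seber richness trajectories with 95% CIs in
`js_richness_*.csv`, and the logged rate series with SEs in `rates_*_*.csv`.

The same stages run individually (`cladelink simulate / proportions / cmr /
link`) and accept user-supplied CSVs in the documented schemas, so a real
occurrence compilation flows through the identical code path.

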