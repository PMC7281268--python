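# Methods

This note records the statistical models the package implements, the
choices made where conventions differ, and what the simulation-based
tests do and do not establish.

## Outcome and data model

The unit of analysis is a randomized trial arm with a dichotomous
count: the number of participants classified as *non-responders* to
iron supplementation out of the arm size.  Non-response is a composite
"bad" endpoint (insufficient hemoglobin rise, ESA initiation or
intensification, iron escalation, or transfusion); adjudication of the
composite is upstream of this package, which only consumes the counts.
Treatment nodes are defined by compound × route × monthly
elemental-iron dose band (e.g. `ferumoxytol_1020` = ferumoxytol at
1020 mg/month IV).  Dose-band node definitions are editorial, so the
registry is data: the shipped vocabulary (ten IV dose-band nodes, oral
iron, and a distinct no-iron/placebo comparator) can be replaced
wholesale.  Oral iron and no-iron are kept as separate nodes because
trials use both as comparators and the two are not clinically
interchangeable.

The first-listed arm of each study is its baseline arm.  The posterior
for relative treatment effects is invariant to this convention, so no
attempt is made to harmonize baselines across studies.

## Pairwise track

For a study with treatment cells (a, b) and control cells (c, d):

* `y = ln(ad/bc)`, `se² = 1/a + 1/b + 1/c + 1/d`.  If any cell is 0,
  0.5 is added to all four cells (Haldane–Anscombe); studies with no
  events in either arm, or all events in both arms, carry no
  information about the odds ratio and are excluded from pooling with
  a distinct signal rather than an error.
* Fixed effect: Mantel–Haenszel on uncorrected cells,
  `OR_MH = Σ(a_i d_i/N_i) / Σ(b_i c_i/N_i)`, with the
  Robins–Breslow–Greenland variance for the CI of the log OR.
* Random effects: DerSimonian–Laird.  `Q = Σ w*_i (y_i − ȳ_w)²` on
  fixed-effect weights `w* = 1/se²`,
  `τ̂² = max(0, (Q − df)/C)` with `C = Σw* − Σw*²/Σw*`, pooled effect
  on weights `1/(se² + τ̂²)`, normal 95% CI (a t-based CI is not
  offered; the normal multiplier is the convention of the standard
  meta-analysis software this track mirrors).
* Heterogeneity: `I² = max(0, (Q − df)/Q)`.
* Egger's test in its original form: unweighted OLS of the
  standardized effect `y/se` on precision `1/se`; the intercept is the
  asymmetry coefficient, tested two-sided against t with k − 2 df.
  At least three studies are required; identical precisions make the
  design singular and raise an error.

The DerSimonian–Laird and Egger implementations are cross-checked in
the test suite against values computed once with R `metafor` 4.8
(`rma(method="DL")`, `regtest(model="lm", predictor="sei")`,
`rma.mh`) and frozen.

IV-versus-PO contrast selection for this track: each study contributes
one estimate, first-listed IV arm versus first-listed non-IV arm
(oral preferred over no-iron when both appear).  Multi-arm studies
therefore contribute one contrast only, avoiding correlated estimates
at the cost of discarding some within-study information.

## Network track

Arm-based binomial-logit random-effects model: per arm
`r ~ Binomial(p, n)`, `logit(p) = μ_i + δ_ik` with `δ = 0` in the
baseline arm, and trial contrasts `δ_ik ~ N(d_{t_ik} − d_{t_ib}, τ²)`
under consistency, `d_reference = 0`.  Multi-arm trials use the
compound-symmetric covariance with pairwise correlation 1/2 (the
standard exchangeable-arm construction).  Zero-event arms are handled
by the likelihood itself; no continuity correction is ever applied on
this track, and the posterior stays proper through the priors.

Priors are deliberately vague: `d_k, μ_i ~ N(0, 100²)` (precision
10⁻⁴) and `τ ~ Uniform(0, 5)` on the log-odds scale.  These constants,
and the posterior-median point estimate with equal-tailed 2.5–97.5
percentile intervals, follow the conventions of the widely used
spreadsheet/WinBUGS NMA front-ends; all are configurable
(`NmaConfig`).

### Sampler

Adaptive Metropolis-within-Gibbs, advancing all chains in lock-step
through vectorized numpy operations:

1. study baselines `μ_i`: independent scalar random-walk updates;
2. contrasts `δ_i·`: blocked random-walk per study against the joint
   compound-symmetric prior (closed-form inverse and determinant);
3. basic parameters `d`: exact draw from their multivariate-normal
   full conditional, which is conjugate given `δ` and `τ` — this step
   is what makes mixing fast on hub-shaped networks;
4. heterogeneity SD `τ`: random-walk with reflection at 0 and at the
   prior's upper bound (reflection keeps the proposal symmetric and
   lets chains mix near τ = 0).

Proposal scales adapt by Robbins–Monro only during burn-in (targets
0.44 for scalar, 0.30 for blocked updates), so the kept draws target
the exact posterior.  Default run length is 3 chains × (20,000 burn-in
+ 40,000 kept), which holds the Brooks–Gelman–Rubin PSRF comfortably
below 1.05 on networks of the shipped scale; the simulation studies in
the test suite use shorter, explicitly stated runs.  Initial values
are empirical logits jittered per chain; chain starts are
overdispersed by construction.

The convergence diagnostic is the classic PSRF
`sqrt(((n−1)/n · W + B/n)/W)` per monitored parameter (W = mean
within-chain variance, B = n × variance of chain means).  The
rank-normalized split-R̂ of modern samplers is deliberately not
substituted, because the classic formula is the stated contract.

### Ranking

League tables, rank probabilities, and SUCRA all derive from the same
pooled draw set, with the reference node participating at d = 0.  For
the non-response outcome, rank 1 = smallest d (default direction
`bad_outcome`; reversing the direction maps SUCRA to its complement
exactly).  `SUCRA_v = Σ_{b≤a−1} cum_{v,b}/(a−1)`; the identities
Σ SUCRA = a/2 and mean = 1/2 are exact and asserted to 1e-9.  Ties
within a draw are broken by node label order — reproducible and
probability-zero for continuous posteriors.

### Inconsistency

The unrelated-mean-effects (UME) model keeps the likelihood and
heterogeneity structure but gives each directly observed comparison
its own mean, oriented by the first study that contributes it.
Model comparison uses DIC with the saturated binomial deviance:
`Dbar` = posterior mean deviance, `pD = Dbar − D(p̄)` where `p̄` is the
posterior mean of the arm-level event probabilities (the plug-in scale
must be chosen; the probability scale is used because the deviance is
a function of p), `DIC = Dbar + pD`.  `|ΔDIC| < 3` is reported as "no
material inconsistency" — a conventional heuristic, labelled as such,
not a hypothesis test.  On networks without independent loops (pure
hubs, two-node networks) the UME and consistency designs coincide and
ΔDIC is exactly 0.  Node-splitting and design-by-treatment
decompositions are out of scope.

## Synthetic networks

`simulate_network` draws data from exactly the model the analysis
assumes: baseline logits `μ_i ~ N(mean, sd)`, contrasts around the true
`d` with between-study SD τ (the correlation-1/2 construction
`δ_k = m_k + τ(u + z_k)/√2` for multi-arm trials), binomial counts.
Two planted distortions support power studies: a small-study effect
(each study's contrast shifted by `β₀ × anticipated se`, the Egger
intercept scale) and loop inconsistency (a log-OR offset on one direct
comparison).

Topologies: `hub_on_reference` (every study includes the reference),
`hub_with_crosslinks` (every fifth study compares two non-reference
nodes head to head, closing evidence loops), `random_connected`
(spanning tree plus random comparisons), `triangle`.

The shipped presets imitate the *shape* of the two published subgroup
networks — `ckd_g3a5`: 10 nodes / 19 trials; `dialysis`: 7 nodes / 12
trials; both hubs on oral iron with occasional head-to-head IV
comparisons and 15% three-arm trials — with true effects placed near
the published posterior odds ratios (ferumoxytol 1020 mg/mo OR 0.28
and ferric carboxymaltose 750–1500 mg/mo OR 0.36 before dialysis;
iron sucrose ≥400 mg/mo OR 0.13 and iron dextran ≥400 mg/mo OR 0.08 on
dialysis) and between-study SD τ = 0.25–0.30, consistent with the
substantial pairwise heterogeneity (I² > 50%) the trials show.  The
trial-level composition of the real networks is unpublished, so the
presets are illustrative stand-ins, not a reproduction: effects
estimated from them demonstrate the pipeline, they do not re-estimate
the literature.  Arm sizes (40–300 per arm) and baseline non-response
odds (≈35–45%) are set to the scale typical of these trials (all
under 1,000 participants, ~10,000 in total across two dozen trials).

What the generator does **not** emulate: per-patient outcome
adjudication, continuous co-outcomes (hemoglobin, ferritin),
dropout, ESA co-intervention dynamics, or non-random site effects.
Passing simulation tests therefore establishes internal validity of
the estimators under the assumed model, not robustness to violations
of it.

## Problem sizes used in the validation suite

Chosen as the package's own trade-off between Monte-Carlo error and
turnaround; all are stated in the tests themselves:

* two-node reduction: 8 trials × 500/arm, τ = 0, NMA 2 chains ×
  (2,000 + 6,000) versus DerSimonian–Laird, agreement within 0.1;
* parameter recovery: 6 nodes / 24 trials / 200 per arm, τ = 0.15,
  100 replicates at 2 chains × (800 + 2,400) — per-node |bias| < 0.1,
  95% CrI coverage within [88%, 99%];
* Egger calibration: 2,000 symmetric-null replicates of 19 balanced
  trials — type-I error within 5% ± 2%;
* Egger power: intercept 1.5 planted in 30 trials spanning 5–300 per
  arm — rejection in > 50% of 150 replicates;
* inconsistency: 12-trial triangles at 500/arm, τ = 0.1, fits at
  3 chains × (3,000 + 9,000); a +1.0 planted loop offset must make
  DIC favour the UME model, and the clean triangle must stay inside
  |ΔDIC| < 3.

## Known limitations

* The pairwise track's one-contrast-per-study rule discards arms in
  multi-arm trials.
* DIC comparison is insensitive on loop-poor networks by construction.
* The DerSimonian–Laird CI uses the normal multiplier and is known to
  undercover slightly at small k under heterogeneity.
* The random-walk components of the sampler, although adapted, mix
  more slowly than gradient-based samplers would on much larger
  networks; run lengths were chosen for the shipped network scale
  (≤ ~12 nodes, ≤ ~30 trials).
* Egger's test applied to odds ratios has a structural correlation
  between effect and standard error; with strong true effects it can
  flag asymmetry without any reporting bias, which is visible in the
  preset-based demonstration output.
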