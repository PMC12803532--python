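# Methods

## The model

Late-life systolic and diastolic function are summarized by two echo
measures: LV ejection fraction (LVEF, %) and the mitral E/A ratio. We
model their joint evolution with age as a finite mixture of group-level
polynomial curves. For participant *i* with visits *v* and targets
*d ∈ {lvef, ea}*,

    y_ivd | z_i = g  ~  Normal( x(a_iv)' β_gd , σ²_gd ),

where `x(a) = (1, z, z²)` with `z = (a − 70)/10` (standardized age), and the
latent group `z_i` follows a truncated stick-breaking (Dirichlet-process)
prior: `v_k ~ Beta(1, α)`, `π_k = v_k ∏_{j<k} (1 − v_j)`, truncation `K`.
The two targets are conditionally independent given the group, and the
group curves — not individual random effects — carry all structure. Two
consequences matter:

* unbalanced panels are free: a participant contributes whichever
  (visit, target) cells were observed;
* membership is computable from any subset of observations, including a
  single echo, by Bayes' rule:
  `P(g | obs) ∝ π_g ∏ Normal(y | x'β_gd, σ²_gd)`.

Within-group dispersion (σ_gd) is a *residual* SD around the group curve:
there are no per-person intercepts, so the cross-sectional within-group SD
equals the model's residual SD. That is how the synthetic generator's
defaults are anchored (below).

### Inference

Coordinate-ascent variational Bayes with conjugate normal-gamma priors on
(β, τ=1/σ²) per (group, target), Beta posteriors on the sticks, and
categorical responsibilities per participant. Updates are exact conditional
conjugate steps, so the evidence lower bound (ELBO) is non-decreasing; the
fitter asserts this at every iteration with tolerance
`1e-8 × max(1, |ELBO|)` (relative, because the ELBO's magnitude is ~1e4 on
a realistic cohort and exact CAVI steps still carry float64 accumulation
noise well below this level but above an absolute 1e-8).

Defaults: `K = 20`, `α = 1`, degree-2 basis (reference 70 y, scale 10 y),
convergence at relative ELBO change `< 1e-8` or 2000 iterations, 20
restarts from a root seed (even restarts: smoothed one-hot from k-means on
per-participant level/slope summaries; odd restarts: random Dirichlet
responsibilities), best final ELBO wins. Priors are set empirically:
coefficient prior mean from a pooled single-group least-squares fit with
×100 variance inflation; `Gamma(1, σ̂²_pooled)` on each precision. All of
these are config-overridable; they are this package's choices where the
underlying approach leaves them open.

Reported quantities: mixing weights are `E[π]` under the fitted sticks;
group coefficients are posterior means; residual SDs are `sqrt(E[1/τ]⁻¹)`
i.e. `sqrt(b/a)`. Membership (both `posterior_membership` and the batch
assigner) uses the plug-in Bayes rule with these point parameters. MAP ties
break toward the lower (larger-weight) index for determinism.

## The synthetic generator

The generator emulates the two cohort designs the pipeline targets:

* **derivation style** — n = 747, six groups at prevalences
  50/17/22/4/2/4 %, visits at ages 64.7/74.7/80.5 (SD ≈ 5, one shared
  per-person offset plus 1-y jitter, clipped to [45, 100]), attendance
  1.0 / 731⁄747 / 488⁄747 (independent Bernoulli after baseline, MAR),
  12 y administrative censoring;
* **testing style** — n = 4419, prevalences 50/15/21/4/2/8 %, a single
  echo at 75.3 ± 5.1 y, 7.4 y censoring.

Group curves are linear in standardized age, anchored so the curve at age
64.5 equals the published per-group baseline mean exactly (LVEF
66.3/79.6/72.3/56.8/82.8/71.5; E/A 1.01/0.96/0.69/0.72/0.93/1.19), with
per-decade slopes chosen once to match the qualitative group descriptions
(pink +4, light green +3, red 0, dark green −6, orange −12, blue +3 LVEF
units; E/A −0.10/−0.08/−0.05/−0.03/+0.15/+0.12). Residual SDs are the
published within-group SDs (the mixture of these groups reproduces the
published cohort-wide 70.1 ± 13.6 % LVEF exactly). E/A is floored at 0.2
to avoid non-physiologic values.

**Outcomes.** Any-HF event times are exponential with group proportional
hazards (baseline 0.0107 /py; HRs 1/0.65/1.18/3.26/2.32/1.64 in testing
mode); an independent exponential death process (0.025 /py, HR 1)
competes; first event before censoring wins. Each HF event is then typed
HFpEF / HFrEF / unknown-EF by a group-specific multinomial. Under this
thinning, the cause-specific hazard of subtype *s* in group *g* is
`λ_any · HR_any(g) · p_s(g)`, so subtype hazard ratios are exact
configurable quantities. The default splits are derived from the published
subtype-vs-any hazard-ratio quotients anchored at the reference group's
observed 87/50/26 event split; one group's implied shares exceed 1 by 3%
and are renormalized (its subtype HRs become 2.26/3.63 rather than
2.33/3.74 — the published three-endpoint table is not exactly consistent
with any common-censoring proportional-hazards generator, and the
renormalization is the smallest perturbation that makes it one).

**Proteome.** Null aptamers are iid standard normal (optional
equicorrelation via a shared latent factor); signal aptamers get a mean
shift (default 0.5 SD) in their target group(s), with configurable
per-group counts and shared patterns. **GWAS pairs.** Instrument exposure
effects have magnitude ~ `instrument_strength` with random signs; outcome
effects are `causal effect × exposure effect` plus noise at the reported
SEs; a configurable fraction of outcome rows is allele-swapped and/or
strand-complemented, and palindromic variants can be injected, to exercise
harmonization.

What the generator does *not* emulate: LD between instruments, aptamer
cross-reactivity and assay QC structure, non-MAR missed visits,
measurement-era drift between visits (harmonization is exercised on its
own synthetic inputs), covariate-dependent hazards (covariates correlate
with group but do not enter the hazard, so adjusted and unadjusted HR
recovery coincide). Passing recovery tests therefore show estimator
correctness under the stated design, not robustness to those real-data
features.

## Downstream estimators

* **Harmonization** — LVEF from M-mode dimensions by the Teichholz
  cube-formula volumes `V = 7.0/(2.4 + D) · D³`; cross-era recalibration as
  moment (mean/SD) alignment to reference moments, which is well defined
  without assuming within-person stability across a decade. A paired
  regression variant can be layered on by supplying its fitted moments.
* **Survival** — cause-specific Cox models (statsmodels PHReg, Breslow
  ties; Efron available): competing HF subtypes and unknown-EF events are
  censored at their event time, death censors HF endpoints, derivation
  mode uses the composite HF-or-death endpoint. BFGS fit followed by
  Newton polishing on the analytic score (‖score‖ < 1e-10) so coefficients
  match partial-likelihood oracles to 1e-6 and Wald CIs use the curvature
  at the maximum. Discrimination: Harrell's C (ties 0.5) and a paired
  bootstrap for ΔC (normal approximation on the bootstrap SE; default 1000
  resamples, floor 100); the bootstrap choice is this package's, as no
  named analytic variance is prescribed by the approach it follows.
* **Proteomics** — per-aptamer multinomial logit over all effective groups
  (reference = largest group), protein and age standardized (population-SD
  convention), Wald tests per non-reference contrast, BH q-values within
  each contrast across aptamers (pooled option available). The multinomial
  Newton solver is hand-written with analytic gradient/Hessian so a
  proteome-wide scan of thousands of aptamers stays cheap; complete
  separation is detected by estimate divergence (|log-odds| > 12) and such
  aptamers are excluded from the FDR family with a log entry.
* **MR** — inner-join harmonization with sign flips for swapped alleles,
  strand complements where needed, unconditional palindromic drops; Wald
  ratio with first-order delta SE; fixed-effect IVW with Cochran's Q;
  cis iff same chromosome and |pos − TSS| ≤ 1 Mb (inclusive); Bonferroni
  across protein×outcome tests by default.

## Problem sizes and replication

Recovery checks run at the published design sizes: trajectory fitting at
n = 750 (one fit, 20 restarts, ~1 min on one CPU), Cox recovery at
n = 4419 with 100 replicates in `scripts/acceptance.py` (20 in the test
suite), proteome null calibration at 20 replicates × 1000 aptamers ×
n = 1000, signal recall at n = 4000. Replicate hazard ratios are pooled on
the log scale with a 10% trimmed mean: the log-HR of a 2%-prevalence
group's endpoint has a heavy left tail in replicates that draw few events,
and a trimmed mean is a standard robust location estimate for it.

## Known limitations

* Mean-field VB underestimates the number of occupied mixture components
  when a broad group overlaps small ones. With the published within-group
  SDs (the largest group's LVEF SD is 15.5 %), the two smallest groups
  (2% and 4%) merge at n = 750: the best 6-group solution sits ~15 nats
  below the 5-group optimum in ELBO, and this is insensitive to prior
  scale and concentration. Recovering all six groups at this overlap
  needs either more participants or collapsed/MCMC inference.
* For the same reason, single-echo assignment against those overlapping
  groups has a Bayes-optimal accuracy well below 1 (≈0.8 for the largest
  group, lower for groups nested inside it); multi-visit assignment is
  substantially better.
* The bootstrap ΔC test is approximate (slightly conservative in the null
  calibration at ~0.035 rejection for nominal 0.05).
* Wald inference in the proteomic scan assumes large-n per contrast; rare
  groups with very few members can be separation-prone and are dropped
  per aptamer rather than imputed.
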