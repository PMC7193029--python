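# Methods

## Model

For subject *i* in entry-age stratum *j* with marker value `z`, observed
follow-up age `X_ij`, event indicator `δ_ij` and at-risk process
`Y_ij(s) = 1(X_ij ≥ s)`, the working model is a two-component mixture with
marginal survival

    S(a | j, z) = exp(-θⱼ e^{αz}) + (1 - exp(-θⱼ e^{αz})) · exp(-Λ₀ⱼ(a) e^{βz}).

`exp(-θⱼ e^{αz})` is the probability of being non-susceptible within the
projection window (the *tail defect* of the improper marginal distribution);
α is the marker's effect on that propensity, β its proportional-hazards effect
among susceptible subjects. Independent censoring given entry age is assumed;
competing risks, time-varying markers and marker-dependent censoring are out
of scope.

## The Δ criterion

All quantities are evaluated under H₀: α = β = 0, so no alternative-model fit
is ever required.

1. **Null nuisance estimates, per stratum** (`survdelta.nullfit`): the
   marginal survival is the Fleming–Harrington estimator
   `Ŝⱼ(s) = exp(-Âⱼ(s))` with `Âⱼ` the Nelson–Aalen cumulative hazard
   (Breslow handling of ties: the d events at a common age share one risk
   set). Event-age evaluations use the **left-continuous** version `Ŝⱼ(a−)`.
   The tail defect is estimated from the survival plateau just after the last
   failure age `t_max`: `θ̂ⱼ = -log Ŝⱼ(t_max+)`, so `exp(-θ̂ⱼ)` *is* the
   estimated non-susceptible fraction — the quantity the mixture model calls
   the tail defect. (An alternative convention `-log(1 - Ŝⱼ(t_max+))`, which
   swaps the two mixture fractions, is retained behind
   `theta_convention="printed"` for audit; it is not used anywhere.) The
   baseline conditional cumulative hazard is the plug-in inversion
   `Λ̂₀ⱼ(s) = -log[(Ŝⱼ(s) - e^{-θ̂ⱼ}) / (1 - e^{-θ̂ⱼ})]`; where `Ŝⱼ(s)` does
   not exceed the plateau (possible only through ties/noise) the value is
   clipped to the largest finite preceding value and counted in `n_clipped`.
   A plateau of exactly zero (last observation is an event) gives
   `θ̂ⱼ = +∞` flagged; the inversion then degenerates to `Âⱼ` and Δ is
   undefined for the cohort (see degeneracy below).

2. **Score components** (`survdelta.scores`): at an event age `a` the two
   per-event score contributions of the partial likelihood are
   `U_k = w_k(a) (z_i - z̄(a))`, `k = 1` (propensity) and `2` (dynamic), with
   weights

       w₁(s) = e^{-θ̂} θ̂ / Ŝ(s−)
       w₂(s) = [e^{-θ̂}(1 - e^{-Λ̂₀(s−)} - Λ̂₀(s−)) + e^{-Λ̂₀(s−)}] / Ŝ(s−)

   and `z̄(a)` the risk-set mean of the marker (the weight is constant across
   a risk set at fixed age, so it cancels inside the bracket; the code
   asserts this cancellation). `w₂` legitimately changes sign once the
   cumulative hazard is large under a substantial tail defect; it is applied
   literally, and only enters Δ through squared/cross terms. An equivalent
   leave-one-out *separability* factorization (contrast between the failing
   subject and those still at risk) is implemented separately and checked to
   1e-10 against the risk-set-mean form.

3. **Robust shifts** (Lin–Wei): raw contributions are dependent across
   subjects; subtracting the estimated compensator makes them i.i.d. For
   every subject (event or censored),

       Ũ_k(i) = Σ_{a_l ≤ X_i} w_k(a_l) (d_l / r_l) (z_i - z̄(a_l)),
       W_k(i) = U_k(i) - Ũ_k(i),

   summing over distinct event ages `a_l` with `d_l` events and `r_l` at
   risk. With weights ≡ 1 (the no-plateau limit θ̂ → ∞ forces w₂ ≡ 1) this is
   exactly the classical Cox score residual at β = 0, which the tests verify
   against an independent transcription.

4. **Δ** (`survdelta.delta`): restrict to the K event-time rows `W*`
   (K ≥ 3 required). With sums pooled over strata (the 1/(K−1) factor
   cancels),

       det(Σ)  = (ΣW₁*²)(ΣW₂*²) - (ΣW₁*W₂*)²                      (mean pinned at 0)
       det(Σ*) = same with each stratum centered by its own mean
       Δ = clip[(det(Σ) - det(Σ*)) / det(Σ), 0, 1].

   Finite-sample Monte-Carlo noise can push the raw ratio marginally outside
   [0, 1]; clipping is recorded in the `clipped` flag. Δ is invariant under
   affine transformations of the marker (U and W are translation-invariant
   and scale linearly, so both determinants scale by the fourth power).

**Degenerate cohorts.** Δ is undefined when K < 3, when det(Σ) is not
positive — including determinants below 1e-12 of the diagonal product
(ΣW₁*²)(ΣW₂*²), which signal score components collinear to machine precision,
where the ratio would be rounding noise — or when the survival plateau is 0. These
raise `DegenerateCohortError`; the study harness drops and counts such
replications (flagging any cell with > 5% of them) rather than imputing.

## Simulator

`survdelta.simulate` generates the study conditions used throughout the
tests: marker `Z ~ N(0,1)` (or Student t with 10 df for the covariate
robustness design), baseline tail defect `exp(-θ) ∈ {0.3, 0.5, 0.7}`,
`Λ₀(t) = t`, n = 500 subjects by default, hazard ratios `e^α, e^β` from 1 up
to 500, 2-level Bernoulli(0.5) labels for the stratified design. Subjects are
non-susceptible with probability `exp(-θ e^{αz})`; susceptible event times
are `E·e^{-βz}` with `E ~ Exp(1)` for the exponential-two-part family, or
drawn by closed-form inverse-CDF from the normalized conditional law of the
improper Gompertz `S(t|z) = exp(-θ e^{αz} (1 - e^{-t e^{βz}}))` for the
misspecification design.

Conventions the data do not dictate, fixed here:

- **Administrative horizon (uncensored designs):** non-susceptible subjects
  are censored at 1.01× the largest susceptible event time, so every
  susceptible subject's event is observed and the plateau is estimable.
- **Uniform censoring:** `C ~ U[0, u]` is drawn for *every* subject
  (independent censoring); `u` solves `E[min(T, u)]/u = target` over the
  susceptible event-time law — i.e. the censored percentage refers to
  susceptible subjects only — by root-finding on a fixed 200,000-draw
  Monte-Carlo sample (deterministic given the configuration, attained
  fraction accurate well within 0.005).
- **Determinism:** one `numpy.random.default_rng(seed)` stream per cohort
  with a documented draw order; study replications use `seed + replication`
  and study cells a fixed stride, all kept below 2³¹.

The simulator emulates the mixture mechanism exactly; it does *not* emulate
features of real cohorts such as delayed entry on the age scale (entry_age is
0 in all simulated designs, though the estimators support delayed entry),
marker measurement error, non-proportional dynamic effects, or
marker-dependent censoring — passing tests say nothing about those.

## Comparator indices

`survdelta.comparators` fits the single-covariate, stratum-stratified Cox
model by Newton–Raphson on the Breslow partial likelihood (score tolerance
1e-8, ≤ 50 iterations; `|β̂| > 15` is treated as a monotone likelihood and
flagged, leaving the indices undefined). With `G = 2(ℓ(β̂) - ℓ(0))`, n
subjects and k events:

- `N = 1 - exp(-G/n)` — the likelihood-ratio transform without the
  max-rescaling denominator (the behavior of the standard survival-analysis
  implementations);
- `XO` — the Xu–O'Quigley explained-randomness transform; its
  likelihood-ratio form coincides numerically with `1 - exp(-G/n)`, which is
  why N and XO rows of comparison tables agree to printed precision. The
  definition is a swappable strategy (`xo_strategy="per-event"` gives the
  per-event variant) for cross-checking against other implementations;
- `OXS = 1 - exp(-G/k)` — normalised per event, hence ≥ N whenever k < n.

The OF (Schoenfeld-process) and RMB (robust-score) indices from the wider
literature are not implemented; they can be attached externally since all
comparators consume only the cohort frame.

## PRS module

`PRS_i = Σ_k dosage_ik · log_OR_k` over a published weight table. Dosages are
expected effect-allele counts in [0, 2], assumed pre-oriented to the effect
allele; QC, imputation and ancestry filtering belong upstream. Missing data
policy is explicit: `error` (default), `mean-impute` (per-variant mean of
observed dosages), or `skip` (drop the contribution; weights deliberately not
renormalized, so scores from differing variant subsets are not comparable —
the caller must opt in).

## Problem sizes and tolerances

The bundled Monte-Carlo checks use 300 replications of n = 500 cohorts per
cell (n = 200 for the small-sample cell; 150 replications for the saturation
cell, whose replication SD is ~0.006), giving Monte-Carlo standard errors
near 0.002 and comfortably below the 0.03 comparison band used in the tests;
`scripts/acceptance.py` and `survdelta simulate-study --full` can rerun any
cell at 1000 replications. Large-sample recovery checks (plateau, Λ̂₀
linearity, hazard-ratio recovery) use single cohorts of n = 20,000.

Numerical conventions worth knowing: Breslow ties everywhere (the simulated
laws are continuous, so ties arise only in user data); risk sets
`1(X ≥ s)` by default with delayed entry `1(entry < s ≤ X)` opt-in (off in
all simulation runs); the minimum event count K = 3 for a non-degenerate 2×2
generalized variance; Δ clipped to [0, 1] with a flag.

## Known limitations

- Δ is model-based: it quantifies explained separability *under the mixture
  working model*; a badly misspecified susceptibility structure (beyond the
  Gompertz variant studied) degrades its interpretation.
- Like all R²-type measures it is sensitive to marker outliers and heavy
  tails; inspect the marker distribution first.
- No variance/CI for Δ is provided (the criterion is a point measure here);
  no competing risks; no multi-covariate comparator fits.
- Comparisons of Δ across different tail-defect levels are not meaningful:
  the effects are conditional on differently-normalized defective
  distributions.
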