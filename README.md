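# survdelta

Pseudo-R² for scalar risk markers — polygenic risk scores in particular — on
**time-to-event** outcomes, when a fraction of the cohort is simply not
susceptible to the event within the risk-projection window.

## The problem

Polygenic risk scores (PRS) are usually evaluated with binary-outcome
pseudo-R² measures, ignoring *when* events happen. For incident-disease
prediction over a fixed horizon (say, 5 years after cohort entry), a
time-to-event evaluation is needed, and the usual Cox-model pseudo-R² indices
presuppose that everyone is eventually at risk. In an incident-event cohort
most participants will never experience the event inside the window: the
population is a **mixture** of non-susceptible and susceptible subjects, and a
marker can act on either part.

`survdelta` implements a pseudo-R² criterion, **Δ**, built on an
entry-age-stratified two-component mixture survival model with marginal
survival

    S(a | j, z) = exp(-θⱼ e^{αz}) + (1 - exp(-θⱼ e^{αz})) · exp(-Λ₀ⱼ(a) e^{βz})

where, per entry-age stratum *j*, `exp(-θⱼ e^{αz})` is the probability of
being non-susceptible (the *tail defect*), **α** is the marker's *propensity*
effect, **β** its *dynamic* effect on the hazard among susceptible subjects,
and Λ₀ⱼ an unspecified baseline cumulative hazard.

Δ is computed from the two score components of the model's partial likelihood
evaluated under the null (no marker effect), made i.i.d. by the Lin–Wei robust
(shifted) score construction, and restricted to event times, where they act as
*separability measures* — weighted contrasts between the marker of the failing
subject and the risk set. With `W* = (W₁*, W₂*)` the 2-vector of shifted
scores at the K event times,

    Δ = [det(Σ) - det(Σ*)] / det(Σ)

where det(Σ) is the generalized variance of W* with mean pinned at 0 (the
null) and det(Σ*) the within-stratum-centered one (the alternative). Δ ∈
[0, 1] is the proportion of the generalized variance of the separability
measures explained by the marker, requires **no fit of the alternative
model**, and — unlike likelihood-ratio based indices — detects a purely
dynamic effect (β ≠ 0, α = 0).

Also included:

- a **simulator** for the mixture model and its robustness variants
  (Gompertz-improper misspecification, Student-t marker, uniform censoring
  calibrated to a target censored fraction, nuisance stratification);
- the **comparator indices** N (Nagelkerke-type, `1 - exp(-G/n)`), XO
  (Xu–O'Quigley explained randomness) and OXS (O'Quigley–Xu–Stare,
  `1 - exp(-G/k)`), from an in-package stratified partial-likelihood fit;
- **PRS construction** as a weighted allele-dosage sum from a published
  weight table;
- a **simulation-study harness** producing mean/SD comparison tables over
  grids of effect sizes, tail defects, sample sizes and designs.

## Worked example

Simulate a 500-subject cohort with a 70% tail defect and both effects present
(e^α = 1.25 propensity, e^β = 2.5 dynamic), then evaluate the marker:

```sh
$ survdelta simulate --alpha 0.22 --beta 0.92 --tail-defect 0.7 \
      --n 500 --seed 42 --out cohort.csv
$ survdelta delta --input cohort.csv
{"delta": 0.308656742954996, "det_null": 2080.00589169592, "det_alt": 1437.9980478378552, "k_total": 151, "per_stratum_k": {"0": 151}, "clipped": false}
Delta = 0.3087  (det_null=2080.01, det_alt=1438, K=151)
$ survdelta indices --input cohort.csv --with-delta
{"beta_hat": 0.2915135252562563, "G": 11.68575758274278, "n": 500, "k": 151, "converged": true, "N": 0.023100516625852885, "XO": 0.023100516625852885, "OXS": 0.0744703614022203, "delta": 0.308656742954996}
```

The marker explains ~31% of the generalized variance of the event-time
separability measures (Δ = 0.31 from K = 151 events), while the
likelihood-ratio-based indices — blind to most of the dynamic effect — report
2–7%. The same analysis runs on any cohort CSV with columns `entry_age,
followup_age, event, marker, stratum` (column names remappable via
`--marker-col`/`--strata-col`; `--delayed-entry` switches the risk sets to
`1(entry < s ≤ X)` for real age-scale cohorts).

From Python:

```python
from survdelta import SimulationConfig, simulate_cohort, delta_from_cohort

cohort = simulate_cohort(SimulationConfig(beta=0.92, tail_defect=0.7, seed=42))
print(delta_from_cohort(cohort).delta)
```

A PRS column can be built first from dosage and weight tables:
`survdelta prs --dosages dosages.csv --weights weights.tsv --out prs.csv`.

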