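# precisionrct

Post hoc precision-medicine subgroup analysis for two-arm randomized
controlled trials.

Many RCTs — the motivating case is an 18-month behavioral-counseling trial
in adolescents with type 1 diabetes — report a null *average* treatment
effect that can mask subgroups who benefit, subgroups who do better under
usual care, and subgroups for whom the two arms are genuinely equivalent.
`precisionrct` implements a data-driven reanalysis of such trials: it
estimates an **individualized treatment rule (ITR)** `d(X)` from baseline
covariates with a reinforcement-learning-tree (RLT) forest, partitions
participants into *intervention* / *control* / *muted* response subgroups,
evaluates the rule's value against blanket treatment policies, and profiles
the discovered subgroups statistically.

It is intended for biostatisticians and trialists running exploratory
heterogeneity-of-treatment-effect analyses, and ships a synthetic-cohort
generator (calibrated to the published baseline distribution of the
motivating trial) so that every step can be exercised, tested, and
benchmarked against known ground truth without access to participant-level
trial data.

## The method

1. **Clinical rewards.** 18-month changes are mapped to rewards where higher
   is better: HbA1c change and PedsQL quality-of-life change are linearly
   scaled to [0, 1]; the BMI z-score reward is 1 for participants finishing
   at a healthy BMIz (≤ 1.04, the 85th percentile) or improving on baseline,
   otherwise a linear penalty on the worsening. A hierarchical composite
   reward in [0, 3] encodes glycemia ≻ quality of life ≻ weight status by
   tiering: unacceptable HbA1c ⇒ `r_C = r_H ∈ [0,1)`; acceptable HbA1c but
   unacceptable QoL ⇒ `r_C = 1 + r_Q`; both acceptable ⇒ `r_C = 2 + r_B`.

2. **Imputation.** Missing non-CGM baseline covariates are completed by
   multiple imputation with chained equations (predictive-mean matching,
   k = 5 donors), producing m = 11 datasets — an odd count so the final
   vote cannot tie between the two arms.

3. **ITR estimation.** Per completed dataset, an RLT regression forest is
   fit to (standardized X, arm A) → reward R. The forest's distinguishing
   mechanism is **variable muting**: at each node a small embedded ensemble
   scores candidate variables honestly (out-of-bag, with one-step
   lookahead), and low-scoring variables are removed from the candidate set
   of the entire subtree. Counterfactual predictions `r̂₁ = Ê[R | X, A=1]`
   and `r̂₀ = Ê[R | X, A=0]` assign each participant to *intervention*
   (r̂₁ > r̂₀), *control* (r̂₀ > r̂₁), or *muted* (r̂₁ ≡ r̂₀ exactly, which
   happens precisely when A was muted off every routing path). The final
   label is the plurality vote over the 11 per-imputation assignments.

4. **Value.** A rule d is evaluated by the normalized inverse-probability-
   weighted estimator over rule-concordant participants,

       V̂(d) = Σᵢ I{Aᵢ = d(Xᵢ)} wᵢ Rᵢ / Σᵢ I{Aᵢ = d(Xᵢ)} wᵢ ,
       wᵢ = Aᵢ/p + (1 − Aᵢ)/(1 − p),

   and compared against the fixed regimes V̂_trt (everyone treated) and
   V̂_ctrl (everyone usual care) with percentile bootstrap CIs.

5. **Profiles.** Baseline characteristics are summarized per subgroup
   (mean (SD), median (IQR), n (%)) and compared by ANOVA / Kruskal–Wallis /
   χ² with a Fisher fallback, with Benjamini–Hochberg FDR control.

## Worked example

A demonstration cohort of 258 adolescents with a strong heterogeneous
HbA1c effect (benefit stratum −2 % units, harm stratum +2, true-null middle
band, keyed to a psychosocial self-management score):

```python
from precisionrct import (
    default_cohort_spec, generate_cohort, apply_eligibility, compute_rewards,
    generate_imputations, estimate_itr, RLTParams,
    rule_from_labels, value_comparison,
)

spec = default_cohort_spec(n_enrolled=258, seed=1, effect_scale=4.0)
cohort, counts = apply_eligibility(generate_cohort(spec))
cohort = compute_rewards(cohort)
stack = generate_imputations(cohort, m=11, seed=2)
itr = estimate_itr(stack, "r_H", RLTParams(n_trees=100, seed=3))

A = cohort.df["arm"].to_numpy()
R = cohort.df["r_H"].to_numpy()
comp = value_comparison(A, R, rule_from_labels(itr.final, A), p=0.5,
                        B=1000, seed=4)
```

which prints, via the obvious reporting loop:

```
enrolled 258, excluded 38 CGM-incomplete, 0 outcome-missing -> analyzed 220
intervention: 123
muted: 0
control: 97
V_opt  = 0.5325
V_trt  = 0.4668
V_ctrl = 0.4697
v_opt - v_trt = 0.0657 (95% CI 0.0352 to 0.0954)
v_opt - v_ctrl = 0.0628 (95% CI 0.0389 to 0.0866)
```

The rule recovers the planted strata almost perfectly (66 of 67 analyzed
benefit-stratum participants are assigned to intervention, 69 of 70
harm-stratum participants to control), and its estimated value exceeds both
blanket policies with bootstrap CIs excluding zero. At the generator's
*default* effect size (±0.5 % HbA1c units), the same pipeline assigns most
participants to the muted group — the method's honest answer when a small
trial cannot distinguish a marginal effect from zero.

With the default generator settings, changes in every outcome include
regression toward the population mean, so a null trial still carries
prognostic baseline signal; the forest then mutes the treatment indicator
rather than everything.

A command-line interface mirrors the library
(`precisionrct simulate | rewards | fit-itr | evaluate | profile | run-all | recommend`);
`run-all` executes the full pipeline from a YAML config and writes
CONSORT-style flow counts, per-outcome assignment, value and profile CSVs,
and a reproducibility manifest.

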