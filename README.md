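# ppsbayes

Hierarchical Bayesian analysis of crossmodal congruency effects in
spinal-cord-injury (SCI) rehabilitation, with a fully synthetic study
generator so the entire pipeline runs end to end with no data download.

## The problem

After a spinal cord injury, the brain's representation of the
disconnected body parts — and of the peripersonal space (PPS) around
them — degrades.  Rehabilitation studies probe these representations
with reaction-time paradigms: a visuo-tactile crossmodal congruency
task around the feet (LLCCT), where the congruency cost of a visual
distractor is larger inside PPS (homolateral > bilateral), and a
Simon-like body-sidedness task (BST), where a task-irrelevant body
photograph interferes with responses if the body part is still
represented.  The scientific questions — does motor rehabilitation,
with or without motor-imagery training, restore these representations
at post-test and follow-up? — turn into inference on *Congruency
Effects* (CE: incongruent minus congruent RT) across Space/Background,
Group and Time.

This package implements that analysis as a tested, reusable library
for researchers in rehabilitation neuroscience and RT modelling:

* **trial-level CE estimation**: reaction times are ex-Gaussian,
  `rt ~ ExGaussian(b0 + a_p + c * CE_cell, sigma, tau)`, with the
  latent CE carrying the 12-term design (Space/Background, Group,
  linear + quadratic Time, all interactions) and participant-level
  varying effects — no averaging into difference scores;
* **Savage-Dickey Bayes factors** from a BIC-selected polynomial
  log-density fit (H1 if BF10 > 5, H0 if < 1/5), mode + 95% HDI
  summaries, and contrast-matrix marginal posteriors decided at
  Pr(x > 0) >= 83.5% / <= 16.5% (5:1 posterior odds);
* **clinical-scale models**: cumulative-logit ordinal regression
  (spasm, spasticity, strength and imagery-vividness scales) and
  robust Student-t models (age, lesion onset), plus T1 covariate
  models with z-scored clinical predictors;
* **MCMC diagnostics** gating every reported effect: split-chain
  Gelman-Rubin R-hat < 1.1, effective draws n_eff > 10, and a
  posterior-predictive p-value near 0.5;
* **a synthetic study module** reproducing the two task designs
  (162-trial LLCCT blocks, 96-trial BST sessions, 24-item
  motor-imagery training), the published 15-participant cohort table,
  and ex-Gaussian RTs with known ground-truth effects for recovery
  testing.

Sampling uses a purpose-built engine (vectorised chains; Hamiltonian
updates with analytic gradients for the mean structure; adaptive
Metropolis, ridge and funnel-scaling moves for the rest).  See
`docs/methods.md` for the model, priors and numerical choices.

## Worked example

Simulate the study at its published scale and test for the PPS
signature (the homolateral-minus-bilateral CE difference per group and
timepoint; ground truth places a 30 ms signature only in the Motor+MI
group at T1):

```python
from ppsbayes import (
    CongruencyModelSpec, cell_contrast, default_truth,
    fit_congruency_model, marginal_cell, table1_cohort,
)
from ppsbayes.designs import (
    llcct_frame, simulate_llcct_study, with_clinical_scores,
)

profiles = with_clinical_scores(table1_cohort(), seed=0)
trials = simulate_llcct_study(profiles, default_truth(), seed=0,
                              conditions=("REAL",))
post = fit_congruency_model(
    llcct_frame(trials),
    CongruencyModelSpec(seed=0, iterations=4000, warmup=1500),
)
for group in ("Motor", "Motor+MI"):
    for tp in ("T0", "T1", "T2"):
        c = (cell_contrast("homolateral", group, tp)
             - cell_contrast("bilateral", group, tp))
        mc = marginal_cell(post, c, label=f"{group}/{tp}")
        print(f"{group:9s} {tp}  Pr(x>0) = {mc.pr_positive:6.2f}%  "
              f"-> {mc.decision}")
```

```
Motor     T0  Pr(x>0) =  34.80%  -> no_decision
Motor     T1  Pr(x>0) =   5.10%  -> effect_negative
Motor     T2  Pr(x>0) =   9.99%  -> effect_negative
Motor+MI  T0  Pr(x>0) =  20.15%  -> no_decision
Motor+MI  T1  Pr(x>0) = 100.00%  -> effect_positive
Motor+MI  T2  Pr(x>0) =  15.46%  -> effect_negative
```

Only the Motor+MI/T1 cell crosses the positive (>= 83.5%) threshold:
the analysis recovers the built-in finding that the combined motor +
motor-imagery training temporarily restores the peripersonal-space
signature.  The `effect_negative` cells reflect the ground truth's
small bilateral-greater gaps elsewhere (a pattern the decision rule
reads as "no PPS representation").  Effect
tables in the study's reporting format (mode {HDI}, n_eff, R-hat,
BF10, hypothesis) come from `ppsbayes.pipeline.effect_table(post)`.

The numbered scripts under `analysis/` run the same steps as a
narrative (01 simulate, 02 clinical scales, 03 LLCCT REAL/VOID,
04 BST, 05 covariate models, 06 combined report), writing their tables
under `results/`; `ppsbayes run-all --seed 0` does the same from the
command line.

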