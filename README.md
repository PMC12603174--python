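# bmcea

Brain-metastasis-aware cost-effectiveness analysis of atezolizumab plus
chemotherapy for extensive-stage small-cell lung cancer (ES-SCLC).

Most economic evaluations of first-line atezolizumab treat the ES-SCLC
population as homogeneous, yet brain metastases (BM) change treatment
benefit, quality of life and cost at once.  `bmcea` implements a
four-state semi-Markov cohort model — progression-free (PF), progressed
disease without BM, progressed disease with BM, death — that lets BM
develop naturally after progression, and evaluates atezolizumab +
carboplatin/etoposide against chemotherapy alone from a single-payer
(Taiwan NHI) perspective.  It is written for health-economics researchers
who want a fully scriptable, testable version of this class of model.

## What the package computes

* **Parametric multistate survival extrapolation** — the six transition
  pathways (TP1: PF→PD without BM, TP2: PF→PD with BM, TP3: PF→death,
  TP4: PD without BM→PD with BM, TP5: PD without BM→death, TP6: PD with
  BM→death) are fitted per arm by maximum likelihood with six standard
  families (exponential, Weibull, Gompertz, log-logistic, log-normal,
  generalized gamma) under clock-reset (time-since-state-entry) semantics,
  and ranked by AIC/BIC.
* **Cohort simulation** — competing cause-specific hazards are converted
  to per-cycle transition probabilities
  (`p_k = (ΔH_k/ΔH)(1 − e^{−ΔH})` with ΔH the cycle's cumulative-hazard
  increment) and propagated over duration-expanded tunnel states with
  3-week cycles, a 15-year horizon, 3% annual discounting and half-cycle
  correction, accruing discounted QALYs, life-years and costs.
* **Cycle-resolved rewards** — PF utility is estimated from longitudinal
  EQ-5D-3L panels by generalized estimating equations
  (`utility ~ response + AE indicators`, patient-clustered), then weighted
  per cycle by the response proportion and adverse-event prevalence;
  medication cost is weighted by the on-treatment proportion.
* **Decision metrics and uncertainty** — ICER, incremental net monetary
  benefit (INMB = λ·ΔE − ΔC at WTP λ = NT$3,023,055/QALY), one-way DSA
  with tornado ordering, 5,000-draw PSA, cost-effectiveness acceptability
  curves, per-person EVPI, and a nine-scenario framework (alternative
  survival fits, horizons of 5/10/20/40 years, pooled PD utilities).
* **Synthetic trial data** — because the originating trial IPD and the
  claims-based cost data are access-restricted, the package ships a
  generator that simulates trial-like individual patient data (multistate
  event histories, utility panels, AE episodes, discontinuation times)
  with known ground truth, so every estimation step is testable end to end.

## Worked example

The shipped default parameter set is a synthetic base case calibrated to
ES-SCLC clinical anchors (it is not the unpublished trial fit).  Running

```bash
bmcea run
```

prints:

```
                                intervention      comparator
Total cost (NT$)                   1,000,305         545,468
  medication                         409,878          58,462
  other PF cost                      122,430          98,127
  PD-state cost                      351,954         271,996
  terminal care                      116,042         116,883
QALYs                                  0.842           0.664
Life-years                             1.116           0.879

Incremental cost  : NT$454,836
Incremental QALYs : 0.179   Incremental LYs: 0.237
ICER (per QALY)   : NT$2,544,886
ICER (per LY)     : NT$1,919,568
INMB (per QALY)   : NT$85,461   INMB (per LY): NT$261,468
WTP threshold     : NT$3,023,055 per QALY
```

Adding atezolizumab buys 0.179 QALYs for an extra NT$454,836 — an ICER of
NT$2.54M per QALY, below the NT$3.02M willingness-to-pay threshold, hence
the positive INMB: cost-effective, but close to the line, which is exactly
the regime where the uncertainty analyses (`bmcea dsa`, `bmcea psa`,
`bmcea scenarios`) are informative.

The same pipeline is available as a library:

```python
import bmcea

cohort = bmcea.simulate(bmcea.GeneratorConfig(seed=7))      # synthetic IPD
datasets = bmcea.to_transition_datasets(cohort)             # clock-reset layout
fits = [bmcea.fit_mle(datasets[("TP1", "intervention")], f)
        for f in bmcea.FAMILY_ORDER]
print(bmcea.select_model(fits).table())                     # AIC/BIC ranking

model = bmcea.default_model()
result = model.run()
print(result.cea_qaly.rounded())
```

## Layout

```
src/bmcea/
  survival.py      six parametric families, MLE fitting, AIC/BIC selection
  transitions.py   competing-risk cycle probabilities (TP1..TP6 schedule)
  cohort.py        tunnel-expanded Markov cohort engine and rewards
  metrics.py       ICER / NMB / INMB / plane quadrants
  utilities.py     GEE utility estimation, time-varying curves
  uncertainty.py   DSA, PSA, CEAC, EVPI
  scenarios.py     the nine-scenario framework
  synthetic.py     synthetic trial-data generator
  model.py         assembled two-strategy model with override interface
  parameters.py    shipped default (fixture) parameter set
  config.py,cli.py,plots.py   configuration, CLI, figures
```

See `docs/methods.md` for the modelling assumptions, default parameters
and numerical choices.
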